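"""Reporting figures: profile curves and polar bleb histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_profile_with_fit(profile, fit=None, path: str | Path = None,
                          title: str = "Front-rear actin profile"):
    """Intensity profile along the front-rear axis, with the fitted
    exponential overlaid on its window when a fit is given."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.positions_um, profile.intensities, ".", ms=3,
            color="0.3", label="measured")
    if fit is not None and fit.converged:
        x0, x1 = fit.window
        xs = np.linspace(x0, x1, 200)
        ax.plot(xs, fit.I0 * np.exp(-(xs - x0) / fit.lam) + fit.I_bg,
                color="crimson", lw=2,
                label=(f"fit: $\\lambda$={fit.lam:.2f} µm, "
                       f"$r^2$={fit.r_squared:.3f}"))
        ax.axvspan(x0, x1, color="crimson", alpha=0.08)
    ax.set_xlabel("distance from front (µm)")
    ax.set_ylabel("intensity (a.u.)")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bleb_angle_histogram(stats, path: str | Path = None,
                              title: str = "Bleb initiation angles"):
    """Polar histogram of bleb angles (0 deg = front), with the paired
    normalized actin intensity per bin when available."""
    fig = plt.figure(figsize=(4.2, 4.2))
    ax = fig.add_subplot(projection="polar")
    edges = np.deg2rad(stats.histogram_bin_edges_deg)
    counts = stats.histogram_counts
    widths = np.diff(edges)
    total = max(counts.sum(), 1)
    ax.bar(edges[:-1], counts / total, width=widths, align="edge",
           color="steelblue", alpha=0.7, label="bleb fraction")
    if stats.histogram_actin is not None:
        centres = edges[:-1] + widths / 2
        scale = (counts / total).max() or 1.0
        ax.plot(centres, stats.histogram_actin
                / max(stats.histogram_actin.max(), 1e-9) * scale,
                "o-", color="crimson", ms=4, label="actin (scaled)")
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    ax.set_theta_zero_location("N")
    ax.set_title(title, fontsize=10)
    ax.legend(loc="lower left", fontsize=7, frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_perimeter_profile(profile, path: str | Path = None,
                           title: str = "Perimeter ratio profile"):
    """Mean-normalized marker/membrane ratio around the cell outline
    (arc position 0 = leading edge)."""
    fig, ax = plt.subplots(figsize=(5, 3.0))
    ax.plot(profile.arc_positions, profile.ratios, color="0.2", lw=1)
    ax.axhline(1.0, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel("normalized arc position (0 = leading edge)")
    ax.set_ylabel("ratio (mean = 1)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
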