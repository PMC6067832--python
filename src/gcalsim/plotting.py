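"""Report rendering: map images, tuning histograms, contrast-response curves.

Every plotted number also lands in a CSV twin so reports are auditable without
reading pixels.  Orientation preference maps use the standard HSV hue wheel
(hue = preference angle over [0, pi)); combined maps modulate hue by per-unit
activation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .measurement import MeasurementResult, OrientationMapResult, TuningHistogram

__all__ = [
    "preference_map_rgb",
    "plot_orientation_map",
    "plot_activation_map",
    "plot_tuning_histogram",
    "plot_contrast_response",
    "render_report",
]


def preference_map_rgb(
    omap: OrientationMapResult, activation: np.ndarray | None = None
) -> np.ndarray:
    """HSV-encoded preference map; value channel optionally carries activation."""
    hue = np.where(omap.defined, omap.preference / np.pi, 0.0)
    sat = np.where(omap.defined, 1.0, 0.0)
    if activation is None:
        val = np.ones_like(hue)
    else:
        a = np.asarray(activation, dtype=float)
        val = a / a.max() if a.max() > 0 else np.zeros_like(a)
    return hsv_to_rgb(np.stack([hue, sat, val], axis=-1))


def _orientation_key(ax):
    """Hue wheel legend mapping colors to orientations."""
    angles = np.linspace(0, np.pi, 180)
    key = hsv_to_rgb(
        np.stack([angles / np.pi, np.ones_like(angles), np.ones_like(angles)], axis=-1)
    )[None, :, :]
    ax.imshow(key, aspect="auto", extent=[0, 180, 0, 1])
    ax.set_yticks([])
    ax.set_xlabel("preferred orientation (deg)")


def plot_orientation_map(omap: OrientationMapResult, path: Path, activation=None, title=""):
    fig, (ax, key) = plt.subplots(
        2, 1, figsize=(4.2, 5), gridspec_kw={"height_ratios": [10, 1]}
    )
    ax.imshow(preference_map_rgb(omap, activation), origin="lower")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or "orientation preference map")
    _orientation_key(key)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_activation_map(activity: np.ndarray, path: Path, title=""):
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(activity, origin="lower", cmap="gray", vmin=0)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or "V1 activation")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tuning_histogram(hist: TuningHistogram, path: Path, title=""):
    fig, ax = plt.subplots(figsize=(5, 3.2))
    width = hist.bin_edges[1] - hist.bin_edges[0]
    ax.bar(hist.bin_centers, hist.weights, width=width * 0.9, color="tab:blue")
    ax.axvline(np.pi / 2, color="k", ls=":", lw=0.8)
    ax.set_xlabel("orientation (rad)")
    ax.set_ylabel("activation-weighted count")
    ax.set_title(
        title
        or f"tuning histogram (excess kurtosis {hist.excess_kurtosis:+.3f})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_contrast_response(tables: dict[str, pd.DataFrame], path: Path):
    """Per-SF panels of mean activation vs contrast, one line per model."""
    sfs = sorted(
        {sf for t in tables.values() for sf in t["spatial_frequency"].unique()}
    )
    fig, axes = plt.subplots(1, len(sfs), figsize=(4.5 * len(sfs), 3.4), squeeze=False)
    for ax, sf in zip(axes[0], sfs):
        for i, (name, table) in enumerate(tables.items()):
            sub = table[
                (table["spatial_frequency"] == sf)
                & (np.isclose(table["orientation"], np.pi / 2))
            ].sort_values("contrast")
            lw = 2.5 if i == 0 else 1.2
            ax.plot(sub["contrast"] * 100, sub["mean_activation"], marker="o", lw=lw, label=name)
        ax.set_xlabel("contrast (%)")
        ax.set_ylabel("mean V1 activation")
        ax.set_title(f"{sf:g} cycles/image")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _no_data_panel(path: Path, label: str):
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.text(0.5, 0.5, f"no data: {label}", ha="center", va="center")
    ax.set_axis_off()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_report(results: dict[str, MeasurementResult], outdir: str | Path) -> Path:
    """Emit PNG panels and CSV twins for a set of measured checkpoints.

    ``results`` maps checkpoint labels to measurements.  Missing or empty
    entries produce explicit "no data" panels rather than silent omissions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {}
    for label, res in results.items():
        if res is None:
            _no_data_panel(outdir / f"{label}_missing.png", label)
            continue
        plot_orientation_map(res.omap, outdir / f"{label}_orientation_map.png", title=label)
        plot_orientation_map(
            res.omap,
            outdir / f"{label}_orientation_activation_map.png",
            activation=res.probe_activity,
            title=f"{label} (activation-weighted)",
        )
        plot_activation_map(
            res.probe_activity, outdir / f"{label}_activation_map.png", title=label
        )
        plot_tuning_histogram(res.histogram, outdir / f"{label}_tuning_histogram.png", title=label)
        res.contrast_table.to_csv(outdir / f"{label}_contrast_response.csv", index=False)
        pd.DataFrame(
            {
                "bin_center_rad": res.histogram.bin_centers,
                "weighted_count": res.histogram.weights,
            }
        ).to_csv(outdir / f"{label}_tuning_histogram.csv", index=False)
        tables[label] = res.contrast_table
    if tables:
        plot_contrast_response(tables, outdir / "contrast_response.png")
    else:
        _no_data_panel(outdir / "contrast_response.png", "contrast response")
    return outdir
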