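"""Minimal plotting helpers for the standard outputs.

Matplotlib is an optional dependency; importing this module without it
installed raises at call time, not at package import.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .association import ScatterResult
from .indices import PriceIndexComparison
from .segments import SegmentSeries


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_segment_series(series: Mapping[str, SegmentSeries], field: str,
                        path: str | Path, ylabel: str | None = None) -> None:
    """One line per segment of the chosen field (e.g. ``wap_real`` or
    ``net_revenue_real``) against period."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, s in series.items():
        ax.plot([str(p) for p in s.periods], getattr(s, field), marker="o",
                label=name, markersize=3)
    ax.set_ylabel(ylabel or f"{field} (pence/pack)")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_indices(cmp: PriceIndexComparison, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = [str(p) for p in cmp.periods]
    ax.plot(labels, cmp.mppc_index, marker="o", markersize=3, label="MPPC")
    ax.plot(labels, cmp.wap_index, marker="s", markersize=3, label="WAP")
    if cmp.external_index is not None:
        ax.plot(labels, cmp.external_index, marker="^", markersize=3, label="external")
    ax.set_ylabel("index (base = 100)")
    ax.legend(fontsize=8)
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter(result: ScatterResult, path: str | Path,
                 segments: Sequence[str] | None = None) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    frame = result.to_frame()
    for seg, group in frame.groupby("segment"):
        if segments is not None and seg not in segments:
            continue
        ax.scatter(group["x"], group["y"], s=14, label=seg)
    ax.set_xlabel(result.x_label)
    ax.set_ylabel(result.y_label)
    if result.rho is not None:
        ax.set_title(f"rho = {result.rho:.2f} (p = {result.p_value:.3g})", fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
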