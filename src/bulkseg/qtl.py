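"""QTL interval calling from the Δ(SNP-index) window track.

A window is significant when its mean Δ lies outside its null band.
Maximal runs of consecutive same-direction significant windows become
candidate intervals; runs separated by at most ``max_gap`` non-significant
windows are merged, and runs shorter than ``min_run`` windows are dropped
(single isolated windows at a pointwise alpha are expected false
positives).  An interval spans from the first window's start to the last
window's end, so on a 50 kb grid with 2 Mb windows the reported bounds are
50 kb-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QtlInterval", "call_qtl", "report_candidates", "intervals_frame", "plot_scan"]


@dataclass(frozen=True)
class QtlInterval:
    """A contiguous run of significant windows (1-based, half-open)."""

    chrom: str
    start: int
    end: int
    peak_start: int
    peak_delta: float
    direction: int  # +1: delta above the upper band, -1: below the lower
    n_windows: int
    sb_index_at_peak: float
    hb_index_at_peak: float

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def call_qtl(
    track: pd.DataFrame,
    max_gap: int = 0,
    min_run: int = 2,
) -> list[QtlInterval]:
    """Call QTL intervals from a window track carrying null bands.

    ``track`` must hold the columns produced by ``sliding_windows`` plus
    ``lower``/``upper`` from ``threshold_track``.  Both directions are
    called; windows with missing statistics or thresholds are never
    significant.
    """
    for col in ("lower", "upper"):
        if col not in track.columns:
            raise ValueError("track carries no null thresholds; run threshold_track")
    intervals: list[QtlInterval] = []
    for chrom, grp in track.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        delta = grp["delta"].to_numpy(float)
        lo = grp["lower"].to_numpy(float)
        hi = grp["upper"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            sign = np.where(delta > hi, 1, np.where(delta < lo, -1, 0))
        sign[np.isnan(delta) | np.isnan(lo)] = 0
        runs = _runs_with_gaps(sign, max_gap)
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        for i0, i1, direction in runs:
            members = np.arange(i0, i1 + 1)
            members = members[sign[members] == direction]
            if members.size < min_run:
                continue
            peak = members[np.argmax(np.abs(delta[members]))]
            intervals.append(
                QtlInterval(
                    chrom=str(chrom),
                    start=int(starts[i0]),
                    end=int(ends[i1]),
                    peak_start=int(starts[peak]),
                    peak_delta=float(delta[peak]),
                    direction=int(direction),
                    n_windows=int(members.size),
                    sb_index_at_peak=float(grp["sb_index"].to_numpy(float)[peak]),
                    hb_index_at_peak=float(grp["hb_index"].to_numpy(float)[peak]),
                )
            )
    return intervals


def _runs_with_gaps(sign: np.ndarray, max_gap: int) -> list[tuple[int, int, int]]:
    """Maximal same-sign runs, merging runs separated by <= max_gap zeros."""
    runs: list[tuple[int, int, int]] = []
    n = sign.size
    i = 0
    while i < n:  # maximal pure runs first
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i]:
            j += 1
        runs.append((i, j, int(sign[i])))
        i = j + 1
    merged: list[tuple[int, int, int]] = []
    for run in runs:
        if (
            merged
            and merged[-1][2] == run[2]
            and run[0] - merged[-1][1] - 1 <= max_gap
        ):
            merged[-1] = (merged[-1][0], run[1], run[2])
        else:
            merged.append(run)
    return merged


def intervals_frame(intervals: list[QtlInterval]) -> pd.DataFrame:
    """Intervals as a DataFrame (1-based, half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "peak_start": iv.peak_start,
                "peak_delta": iv.peak_delta,
                "direction": iv.direction,
                "n_windows": iv.n_windows,
                "sb_index_at_peak": iv.sb_index_at_peak,
                "hb_index_at_peak": iv.hb_index_at_peak,
            }
            for iv in intervals
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "peak_start",
            "peak_delta",
            "direction",
            "n_windows",
            "sb_index_at_peak",
            "hb_index_at_peak",
        ],
    )


def report_candidates(
    intervals: list[QtlInterval], genes: pd.DataFrame
) -> pd.DataFrame:
    """Genes falling inside any called interval.

    ``genes`` needs columns ``gene_id``, ``chrom``, ``pos``.  Intervals are
    half-open, so a gene exactly at ``end`` is outside.  The reported
    distance is from the gene to the start of the interval's peak window.
    """
    rows = []
    for _, g in genes.iterrows():
        for iv in intervals:
            if iv.contains(g["chrom"], int(g["pos"])):
                rows.append(
                    {
                        "gene_id": g["gene_id"],
                        "chrom": g["chrom"],
                        "pos": int(g["pos"]),
                        "interval_start": iv.start,
                        "interval_end": iv.end,
                        "peak_start": iv.peak_start,
                        "peak_delta": iv.peak_delta,
                        "distance_to_peak": abs(int(g["pos"]) - iv.peak_start),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "pos",
            "interval_start",
            "interval_end",
            "peak_start",
            "peak_delta",
            "distance_to_peak",
        ],
    )


def plot_scan(track: pd.DataFrame, intervals: list[QtlInterval] | None = None):
    """Simple Δ(SNP-index) track figure with null bands, one panel per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(track["chrom"]))
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.6 * len(chroms)), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        grp = track[track["chrom"] == chrom]
        mb = (grp["start"] + grp["end"]) / 2e6
        ax.plot(mb, grp["delta"], lw=0.8, color="tab:blue")
        if "upper" in grp.columns:
            ax.plot(mb, grp["upper"], lw=0.6, ls=":", color="gray")
            ax.plot(mb, grp["lower"], lw=0.6, ls=":", color="gray")
        if intervals:
            for iv in intervals:
                if iv.chrom == chrom:
                    ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="tab:red", alpha=0.2)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center", fontsize=8)
        ax.axhline(0.0, color="k", lw=0.4)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.suptitle("Δ(SNP-index) scan")
    fig.tight_layout()
    return fig
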