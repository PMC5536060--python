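"""SNP-index, Δ(SNP-index), the low-index filter, and sliding-window scans.

The SNP-index of a bulk at a SNP is the fraction of reads that differ from
the reference parent's allele, ``alt / (ref + alt)`` — an estimate of the
pooled non-reference allele frequency.  Δ(SNP-index) is the single-branch
bulk's index minus the highly-branched bulk's index; it is near zero
genome-wide and large near a causal locus.

SNPs where *both* bulks show an index below 0.2 are excluded (suspected
repeat/alignment artifacts); dropping on one bulk alone would erase the true
signal at a QTL where the reference-parent bulk is fixed.  Window statistics
are unweighted means of the retained SNPs inside 2 Mb windows advanced on a
50 kb grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "ScanConfig",
    "snp_index",
    "delta_index",
    "compute_snp_indices",
    "filter_snps",
    "sliding_windows",
    "swap_reference",
    "window_at",
    "average_depth",
]

COUNT_COLUMNS = ("sb_ref", "sb_alt", "hb_ref", "hb_alt")


@dataclass
class ScanConfig:
    """Sliding-window scan parameters.

    window/step in bp (defaults 2 Mb / 50 kb); ``min_index`` is the
    low-index exclusion threshold; ``min_depth`` the per-bulk coverage
    requirement; windows retaining fewer than ``min_snps`` SNPs are flagged
    missing.  ``filter_mode`` selects whether a SNP is dropped when *both*
    bulks fall below ``min_index`` (default) or when *either* does.
    ``weight_by_depth`` switches window means from unweighted (default) to
    depth-weighted.
    """

    window: int = 2_000_000
    step: int = 50_000
    min_index: float = 0.2
    min_depth: int = 1
    min_snps: int = 3
    filter_mode: str = "both"
    weight_by_depth: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be positive")
        if self.step > self.window:
            raise ValueError("step must not exceed window size")
        if not 0 <= self.min_index <= 1:
            raise ValueError("min_index must be in [0, 1]")
        if self.filter_mode not in ("both", "either"):
            raise ValueError("filter_mode must be 'both' or 'either'")


def snp_index(ref_count: int, alt_count: int) -> float:
    """Fraction of reads differing from the reference: alt / (ref + alt).

    A site with zero depth is uncovered, not index 0, and raises.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        raise ValueError("uncovered site: zero read depth")
    return alt_count / depth


def delta_index(sb_index: float, hb_index: float) -> float:
    """Δ(SNP-index): single-branch bulk index minus highly-branched index."""
    return sb_index - hb_index


def compute_snp_indices(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach per-bulk depths, SNP-indices and Δ to a SnpCounts table.

    Uncovered bulks (zero depth) get NaN indices; Δ is NaN unless both
    bulks are covered.
    """
    df = counts.copy()
    for tag in ("sb", "hb"):
        depth = df[f"{tag}_ref"] + df[f"{tag}_alt"]
        if (depth < 0).any():
            raise ValueError("negative read counts")
        idx = np.where(depth > 0, df[f"{tag}_alt"] / np.maximum(depth, 1), np.nan)
        df[f"{tag}_depth"] = depth
        df[f"{tag}_index"] = idx
    df["delta"] = df["sb_index"] - df["hb_index"]
    return df


def filter_snps(records: pd.DataFrame, cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Apply the coverage and low-index exclusion rules, preserving order.

    A SNP is dropped iff (a) either bulk's depth is below ``min_depth``, or
    (b) the bulk indices fall below ``min_index`` in both bulks (default
    mode) or in either bulk (``filter_mode="either"``).
    """
    cfg = cfg or ScanConfig()
    df = records
    if "sb_index" not in df.columns:
        df = compute_snp_indices(df)
    covered = (df["sb_depth"] >= cfg.min_depth) & (df["hb_depth"] >= cfg.min_depth)
    low_sb = df["sb_index"] < cfg.min_index
    low_hb = df["hb_index"] < cfg.min_index
    low = (low_sb & low_hb) if cfg.filter_mode == "both" else (low_sb | low_hb)
    return df[covered & ~low].copy()


def swap_reference(records: pd.DataFrame) -> pd.DataFrame:
    """Exchange the reference orientation: ref/alt alleles and counts swap.

    Before filtering, every covered SNP's index becomes 1 - old index;
    applying the swap twice restores the original table.
    """
    df = records.copy()
    for a, b in (("ref", "alt"), ("sb_ref", "sb_alt"), ("hb_ref", "hb_alt")):
        if a in df.columns and b in df.columns:
            df[a], df[b] = records[b], records[a]
    if "sb_index" in records.columns:
        df = compute_snp_indices(df)
    return df


def window_starts(length: int, cfg: ScanConfig) -> np.ndarray:
    """1-based window start grid for a chromosome: 1, 1+step, ... <= length."""
    return np.arange(1, length + 1, cfg.step, dtype=np.int64)


def sliding_windows(
    records: pd.DataFrame,
    genome: GenomeModel | Mapping[str, int],
    cfg: ScanConfig | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Aggregate retained SNPs over half-open windows [start, start + W).

    Windows start at 1, 1 + step, ... on every chromosome; a SNP contributes
    to every window overlapping its position.  Means are unweighted over the
    retained SNPs (or depth-weighted when configured); windows retaining
    fewer than ``min_snps`` SNPs keep their count but have their means
    flagged missing (NaN).  Input must be sorted by position within each
    chromosome.
    """
    cfg = cfg or ScanConfig()
    lengths = genome.chrom_lengths if isinstance(genome, GenomeModel) else dict(genome)
    chrom_order = (
        list(genome.chrom_names)
        if isinstance(genome, GenomeModel)
        else list(lengths)
    )
    df = records if prefiltered else filter_snps(records, cfg)
    for chrom, grp in df.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) < 0):
            raise ValueError(f"records on {chrom} are not sorted by position")
    rows = []
    value_cols = ("sb_index", "hb_index", "delta", "sb_depth", "hb_depth")
    for chrom in chrom_order:
        grp = df[df["chrom"] == chrom]
        pos = grp["pos"].to_numpy(dtype=np.int64)
        starts = window_starts(lengths[chrom], cfg)
        left = np.searchsorted(pos, starts, side="left")
        right = np.searchsorted(pos, starts + cfg.window, side="left")
        n = right - left
        sums = {}
        if cfg.weight_by_depth:
            w = {
                "sb": grp["sb_depth"].to_numpy(float),
                "hb": grp["hb_depth"].to_numpy(float),
            }
            wsum = {k: np.concatenate([[0.0], np.cumsum(v)]) for k, v in w.items()}
            for col in value_cols:
                tag = col.split("_")[0] if col != "delta" else None
                if col == "delta":
                    v = grp["sb_index"].to_numpy(float) * w["sb"]
                    c = np.concatenate([[0.0], np.cumsum(v)])
                    num_sb = c[right] - c[left]
                    v = grp["hb_index"].to_numpy(float) * w["hb"]
                    c = np.concatenate([[0.0], np.cumsum(v)])
                    num_hb = c[right] - c[left]
                    den_sb = wsum["sb"][right] - wsum["sb"][left]
                    den_hb = wsum["hb"][right] - wsum["hb"][left]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        sums[col] = num_sb / den_sb - num_hb / den_hb
                elif col.endswith("_index"):
                    v = grp[col].to_numpy(float) * w[tag]
                    c = np.concatenate([[0.0], np.cumsum(v)])
                    den = wsum[tag][right] - wsum[tag][left]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        sums[col] = (c[right] - c[left]) / den
                else:
                    c = np.concatenate([[0.0], np.cumsum(grp[col].to_numpy(float))])
                    with np.errstate(invalid="ignore", divide="ignore"):
                        sums[col] = (c[right] - c[left]) / n
        else:
            for col in value_cols:
                c = np.concatenate([[0.0], np.cumsum(grp[col].to_numpy(float))])
                with np.errstate(invalid="ignore", divide="ignore"):
                    sums[col] = (c[right] - c[left]) / n
        block = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + cfg.window,
                "n_snps": n,
            }
        )
        for col in value_cols:
            vals = np.asarray(sums[col], dtype=float)
            vals[n < cfg.min_snps] = np.nan
            block[col] = vals
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def window_at(track: pd.DataFrame, chrom: str, pos: int) -> pd.Series:
    """The window covering ``pos`` whose centre lies nearest to it.

    Many overlapping windows on the step grid contain any given position;
    this picks the one centred on it, which is the natural summary of the
    local signal.
    """
    hit = track[(track["chrom"] == chrom) & (track["start"] <= pos) & (track["end"] > pos)]
    if hit.empty:
        raise KeyError(f"no window covers {chrom}:{pos}")
    centre = (hit["start"] + hit["end"]) / 2.0
    return hit.loc[(centre - pos).abs().idxmin()]


def average_depth(n_reads: float, read_length: float, genome_length: float) -> float:
    """Fold coverage from read count N, read length L, genome length G: N·L/G."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if n_reads <= 0 or read_length <= 0:
        raise ValueError("read count and read length must be positive")
    return n_reads * read_length / genome_length
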