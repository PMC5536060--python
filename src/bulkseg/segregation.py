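"""Mendelian segregation tests and quantitative statistics for the F2 tables.

Covers the single-marker side of the study: Pearson chi-square
goodness-of-fit against arbitrary segregation ratios (3:1, 15:1, 1:2:1),
branch-type classification of plants, broad-sense heritability from the
non-segregating generations, single-marker percentage of variance explained
(one-way R^2 on log2 branch number), the Jonckheere-Terpstra ordered trend
test, and distribution moments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GofResult",
    "JtResult",
    "chi_square_gof",
    "classify_branch_type",
    "branch_bins",
    "broad_sense_heritability",
    "pve_single_marker",
    "jonckheere_terpstra",
    "moments",
    "genotype_class_table",
    "parse_ratio",
]

#: Branch-number bin edges for the five-way plant classification; a plant
#: with median BN in (1], (1,4], (4,16], (16,64], (64, inf) falls in the
#: corresponding bin.  The two-way split (highly branched iff BN > 16) is
#: the third edge.
BRANCH_BIN_EDGES = (1, 4, 16, 64)
BRANCH_BIN_LABELS = ("1", "2-4", "5-16", "17-64", ">64")


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class JtResult:
    statistic: float
    z: float
    p_value: float  # two-sided
    p_greater: float  # one-sided, increasing trend
    method: str = "normal"


def parse_ratio(text: str) -> tuple[float, ...]:
    """Parse a segregation ratio string like ``"1:2:1"`` or ``"15:1"``."""
    try:
        parts = tuple(float(x) for x in text.split(":"))
    except ValueError as err:
        raise ValueError(f"invalid ratio string {text!r}") from err
    if len(parts) < 2 or any(p <= 0 for p in parts):
        raise ValueError(f"invalid ratio string {text!r}: need >=2 positive terms")
    return parts


def chi_square_gof(
    observed: Sequence[float], expected_ratio: Sequence[float] | str
) -> GofResult:
    """Pearson goodness-of-fit of observed class counts to a ratio.

    The statistic is ``sum (O - E)^2 / E`` with expectations from the
    normalized ratio, no continuity correction; the p-value is the upper
    chi-square tail with ``classes - 1`` degrees of freedom.  The result is
    invariant to rescaling the ratio (3:1 is the same as 75:25).
    """
    if isinstance(expected_ratio, str):
        expected_ratio = parse_ratio(expected_ratio)
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.size < 2 or obs.size != ratio.size:
        raise ValueError("need >= 2 classes and matching ratio length")
    if np.any(ratio <= 0):
        raise ValueError("expected ratio weights must be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    expected = ratio / ratio.sum() * total
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.size - 1
    return GofResult(statistic, df, float(stats.chi2.sf(statistic, df)))


def classify_branch_type(bn_median: float) -> tuple[str, str]:
    """Two-way and five-way branch-type labels for a plant-level BN.

    Highly branched iff the median BN is strictly greater than 16 (a plant
    at exactly 16 is not highly branched).
    """
    if bn_median < 1:
        raise ValueError("BN must be >= 1")
    two_way = "highly-branched" if bn_median > 16 else "single-or-moderate"
    return two_way, branch_bins(bn_median)


def branch_bins(bn_median: float) -> str:
    for edge, label in zip(BRANCH_BIN_EDGES, BRANCH_BIN_LABELS):
        if bn_median <= edge:
            return label
    return BRANCH_BIN_LABELS[-1]


def broad_sense_heritability(
    var_f2: float,
    var_p1: float,
    var_p2: float,
    var_f1: float,
    weighting: str = "mean",
) -> float:
    """Broad-sense heritability H^2 = (V_F2 - V_E) / V_F2, clamped to [0, 1].

    The environmental variance is estimated from the non-segregating
    generations: the unweighted mean of the two parental and F1 variances
    (default), or the ``(V_P1 + V_P2 + 2 V_F1) / 4`` weighting
    (``weighting="f1_weighted"``).
    """
    if min(var_p1, var_p2, var_f1) < 0 or var_f2 < 0:
        raise ValueError("variances must be non-negative")
    if var_f2 == 0:
        raise ValueError("F2 variance must be positive")
    if weighting == "mean":
        var_e = (var_p1 + var_p2 + var_f1) / 3.0
    elif weighting == "f1_weighted":
        var_e = (var_p1 + var_p2 + 2.0 * var_f1) / 4.0
    else:
        raise ValueError("weighting must be 'mean' or 'f1_weighted'")
    return float(min(1.0, max(0.0, (var_f2 - var_e) / var_f2)))


def pve_single_marker(
    phenotypes: Sequence[float], classes: Sequence
) -> float:
    """Fraction of phenotypic variance explained by one marker (one-way R^2).

    ``between-class sum of squares / total sum of squares`` on the given
    (already transformed, e.g. log2) phenotype.  Invariant to affine
    transforms of the phenotype; always in [0, 1].
    """
    y = np.asarray(phenotypes, dtype=float)
    g = np.asarray(classes)
    if y.size != g.size:
        raise ValueError("phenotype and class vectors must have equal length")
    labels = pd.unique(g)
    if sum((g == lab).any() for lab in labels) < 2:
        raise ValueError("need >= 2 non-empty marker classes")
    grand = y.mean()
    sst = float(np.sum((y - grand) ** 2))
    if sst == 0:
        raise ValueError("phenotype is constant")
    ssb = 0.0
    for lab in labels:
        sel = y[g == lab]
        ssb += sel.size * (sel.mean() - grand) ** 2
    return float(ssb / sst)


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for a, b in itertools.combinations(groups, 2):
        diff = b[None, :] - a[:, None]
        jt += float((diff > 0).sum()) + 0.5 * float((diff == 0).sum())
    return jt


def jonckheere_terpstra(
    groups: Iterable[Sequence[float]],
    method: str = "normal",
) -> JtResult:
    """Jonckheere-Terpstra test for a trend across ordered groups.

    The statistic is the sum over ordered group pairs of Mann-Whitney
    counts, ties counting one half.  ``method="normal"`` standardizes with
    the standard null mean and variance (no tie correction beyond the 1/2
    counting) and returns a two-sided normal p-value; ``method="exact"``
    enumerates all assignments of the pooled values to the group sizes
    (small samples only).  With two groups the statistic reduces to the
    Mann-Whitney U of the second group versus the first.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 ordered groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("all groups must be non-empty")
    jt = _jt_statistic(gs)
    sizes = np.array([g.size for g in gs])
    n = int(sizes.sum())
    mean = (n * n - np.sum(sizes**2)) / 4.0
    var = (n * n * (2 * n + 3) - np.sum(sizes**2 * (2 * sizes + 3))) / 72.0
    z = 0.0 if var == 0 or jt == mean else float((jt - mean) / math.sqrt(var))
    if method == "normal":
        p_greater = float(stats.norm.sf(z))
        p_two = float(2 * stats.norm.sf(abs(z)))
        return JtResult(jt, z, min(p_two, 1.0), p_greater, "normal")
    if method != "exact":
        raise ValueError("method must be 'normal' or 'exact'")
    pooled = np.concatenate(gs)
    if pooled.size > 12:
        raise ValueError("exact enumeration limited to <= 12 observations")
    ge = le = total = 0
    idx = np.arange(pooled.size)
    for perm in _group_assignments(idx, sizes):
        stat = _jt_statistic([pooled[list(p)] for p in perm])
        total += 1
        ge += stat >= jt
        le += stat <= jt
    p_greater = ge / total
    p_two = min(1.0, 2 * min(ge, le) / total)
    return JtResult(jt, z, p_two, p_greater, "exact")


def _group_assignments(idx: np.ndarray, sizes: np.ndarray):
    """All partitions of ``idx`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    for first in itertools.combinations(idx, int(sizes[0])):
        rest = np.array(sorted(set(idx) - set(first)))
        for tail in _group_assignments(rest, sizes[1:]):
            yield (first,) + tail


def moments(values: Sequence[float]) -> tuple[float, float]:
    """Adjusted Fisher-Pearson skewness and excess kurtosis of a sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.var(x) == 0:
        raise ValueError("zero variance")
    return (
        float(stats.skew(x, bias=False)),
        float(stats.kurtosis(x, fisher=True, bias=False)),
    )


def genotype_class_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Nine-way FA x S genotype table with log2(BN) summaries and BN bins.

    Expects the phenotype table written by the simulator (``bn_median``,
    ``genotype_FA``, ``genotype_S`` columns).  Adds the four-way collapsed
    class (F dominant over f, S over s) and per-class counts of the five
    branch-type bins.
    """
    df = phenotypes.copy()
    df["log2_bn"] = np.log2(df["bn_median"].astype(float))
    df["bin"] = [branch_bins(v) for v in df["bn_median"]]
    rows = []
    for (gfa, gs), grp in df.groupby(["genotype_FA", "genotype_S"], sort=True):
        row = {
            "genotype_FA": gfa,
            "genotype_S": gs,
            "class4": ("ff" if gfa == "ff" else "F_") + ("ss" if gs == "ss" else "S_"),
            "n": len(grp),
            "mean_log2_bn": grp["log2_bn"].mean(),
            "sd_log2_bn": grp["log2_bn"].std(ddof=1) if len(grp) > 1 else 0.0,
        }
        for label in BRANCH_BIN_LABELS:
            row[f"bin_{label}"] = int((grp["bin"] == label).sum())
        rows.append(row)
    return pd.DataFrame(rows)
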