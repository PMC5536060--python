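"""Independent oracles used by the test suite.

Everything here recomputes expected values from first principles —
exact enumeration, closed forms, or brute-force loops — without calling
the library code paths under test.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy import stats

N_INFLORESCENCES = 10

# ---------------------------------------------------------------------------
# exact plant-level phenotype distribution
# ---------------------------------------------------------------------------

def inflorescence_bn_pmf(mu: float, sd: float, kmax: int = 4096):
    """Exact pmf of one inflorescence BN = max(1, round(2**N(mu, sd)))."""
    ks = np.arange(1, kmax + 1)
    upper = np.log2(ks + 0.5)
    lower = np.log2(np.maximum(ks - 0.5, 1e-12))
    cdf_hi = stats.norm.cdf(upper, mu, sd) if sd > 0 else (upper >= mu).astype(float)
    cdf_lo = stats.norm.cdf(lower, mu, sd) if sd > 0 else (lower >= mu).astype(float)
    pmf = cdf_hi - cdf_lo
    pmf[0] = cdf_hi[0]  # BN=1 absorbs everything below 1.5
    pmf[-1] += 1.0 - cdf_hi[-1]
    keep = pmf > 1e-14
    return ks[keep], pmf[keep] / pmf[keep].sum()


def median10_pmf(ks: np.ndarray, pmf: np.ndarray):
    """Exact distribution of the median of 10 iid draws from a discrete pmf.

    The median is (X(5) + X(6)) / 2; the joint law of the 5th and 6th order
    statistics is enumerated directly.  Returns (values, probabilities).
    """
    n = N_INFLORESCENCES
    half = n // 2
    cdf = np.cumsum(pmf)
    cdf_prev = cdf - pmf
    out: dict[float, float] = {}
    c_split = math.comb(n, half)
    for i, a in enumerate(ks):
        # X(5) = X(6) = a : at most 4 strictly below, at least 6 at or below
        p_lt, p_eq, p_gt = cdf_prev[i], pmf[i], 1.0 - cdf[i]
        p_same = 0.0
        for low in range(half):
            for eq in range(max(0, (half + 1) - low), n - low + 1):
                gt = n - low - eq
                p_same += (
                    math.comb(n, low)
                    * math.comb(n - low, eq)
                    * p_lt**low
                    * p_eq**eq
                    * p_gt**gt
                )
        if p_same > 0:
            out[float(a)] = out.get(float(a), 0.0) + p_same
        # X(5) = a < X(6) = b : 5 values <= a (max exactly a), 5 >= b (min b)
        low5_max_a = cdf[i] ** half - cdf_prev[i] ** half
        if low5_max_a <= 0:
            continue
        for j in range(i + 1, len(ks)):
            b = ks[j]
            hi5_min_b = (1.0 - cdf_prev[j]) ** half - (1.0 - cdf[j]) ** half
            if hi5_min_b <= 0:
                continue
            p = c_split * low5_max_a * hi5_min_b
            m = float(a + b) / 2.0
            out[m] = out.get(m, 0.0) + p
    vals = np.array(sorted(out))
    probs = np.array([out[v] for v in vals])
    return vals, probs / probs.sum()


CLASS_PROBS = {"F_S_": 9 / 16, "F_ss": 3 / 16, "ffS_": 3 / 16, "ffss": 1 / 16}


def class_median_stats(mu: float, sd: float) -> dict[str, float]:
    """Exact summaries of the plant-level (median) BN for one class mean."""
    ks, pmf = inflorescence_bn_pmf(mu, sd)
    vals, probs = median10_pmf(ks, pmf)
    log2v = np.log2(vals)
    p_single_infl = float(pmf[ks == 1][0]) if (ks == 1).any() else 0.0
    return {
        "mean_log2": float(np.sum(probs * log2v)),
        "var_log2": float(np.sum(probs * log2v**2) - np.sum(probs * log2v) ** 2),
        "p_median_1": float(probs[vals == 1].sum()),
        "p_hb": float(probs[vals > 16].sum()),
        # single-branch rule: >= 7 of 10 inflorescences with BN = 1
        # (which also forces median 1)
        "p_sb_rule": float(stats.binom.sf(6, N_INFLORESCENCES, p_single_infl)),
    }


def population_phenotype_moments(class_means: dict[str, float], sd: float):
    """Exact mean/variance of log2(plant BN) over the F2 class mixture."""
    m1 = m2 = 0.0
    per_class = {}
    for cls, p in CLASS_PROBS.items():
        st = class_median_stats(class_means[cls], sd)
        per_class[cls] = st
        m1 += p * st["mean_log2"]
        m2 += p * (st["var_log2"] + st["mean_log2"] ** 2)
    return m1, m2 - m1**2, per_class


def exact_p_highly_branched(class_means: dict[str, float], sd: float) -> float:
    """Exact probability that a random F2 plant has median BN > 16."""
    return sum(
        p * class_median_stats(class_means[c], sd)["p_hb"]
        for c, p in CLASS_PROBS.items()
    )


def analytic_fa_pve(class_means: dict[str, float], sd: float) -> float:
    """Exact one-way R^2 of the FA marker (FF/Ff/ff) on log2 plant BN."""
    _, var_total, per_class = population_phenotype_moments(class_means, sd)
    grand = sum(CLASS_PROBS[c] * per_class[c]["mean_log2"] for c in CLASS_PROBS)
    # marker classes: FF and Ff each mix S_ : ss = 3 : 1 within the F_ rows
    mean_f = 0.75 * per_class["F_S_"]["mean_log2"] + 0.25 * per_class["F_ss"]["mean_log2"]
    mean_ff = 0.75 * per_class["ffS_"]["mean_log2"] + 0.25 * per_class["ffss"]["mean_log2"]
    between = (
        0.25 * (mean_f - grand) ** 2
        + 0.50 * (mean_f - grand) ** 2
        + 0.25 * (mean_ff - grand) ** 2
    )
    return between / var_total


def analytic_genetic_fraction(class_means: dict[str, float], sd: float) -> float:
    """Variance of the noise-free class phenotype over total variance."""
    g = {
        c: math.log2(max(1, round(2 ** class_means[c]))) for c in CLASS_PROBS
    }
    eg = sum(CLASS_PROBS[c] * g[c] for c in CLASS_PROBS)
    var_g = sum(CLASS_PROBS[c] * (g[c] - eg) ** 2 for c in CLASS_PROBS)
    _, var_total, _ = population_phenotype_moments(class_means, sd)
    return var_g / var_total


# ---------------------------------------------------------------------------
# null delta enumeration at bulk size 1 / depth 1
# ---------------------------------------------------------------------------

def enumerate_null_delta_bulk1_depth1():
    """Exact Δ(SNP-index) pmf: one plant per bulk, one read, no error.

    Enumerates the 3x3 dosage pairs (1:2:1 each) times the 2x2 read
    outcomes (one Bernoulli(f) read per bulk).
    """
    dosage_p = {0: 0.25, 1: 0.5, 2: 0.25}
    pmf: dict[float, float] = {}
    for d_sb, d_hb in product(dosage_p, dosage_p):
        f_sb, f_hb = d_sb / 2.0, d_hb / 2.0
        for read_sb, read_hb in product((0, 1), (0, 1)):
            p = (
                dosage_p[d_sb]
                * dosage_p[d_hb]
                * (f_sb if read_sb else 1 - f_sb)
                * (f_hb if read_hb else 1 - f_hb)
            )
            if p == 0:
                continue
            delta = float(read_sb - read_hb)
            pmf[delta] = pmf.get(delta, 0.0) + p
    vals = np.array(sorted(pmf))
    return vals, np.array([pmf[v] for v in vals])


def discrete_quantile(vals: np.ndarray, probs: np.ndarray, q: float) -> float:
    """Lower quantile of a discrete distribution (inverse CDF)."""
    cdf = np.cumsum(probs)
    return float(vals[np.searchsorted(cdf, q, side="left")])


# ---------------------------------------------------------------------------
# misc brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_windows(chrom_len, window, step, positions, values, min_snps):
    """Window means by explicit loops over every window and SNP."""
    out = []
    start = 1
    while start <= chrom_len:
        inside = [v for p, v in zip(positions, values) if start <= p < start + window]
        mean = float(np.mean(inside)) if len(inside) >= min_snps else np.nan
        out.append((start, len(inside), mean))
        start += step
    return out


#: Standard nuclear genetic code written out independently (TCAG order).
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TO_AA = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def classify_substitution(codon: str, within: int, alt_base: str) -> tuple[str, str, str]:
    """(ref_aa, alt_aa, effect) for one codon substitution, via the table."""
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa, alt_aa = CODON_TO_AA[codon], CODON_TO_AA[alt_codon]
    if ref_aa == alt_aa:
        effect = "silent"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return ref_aa, alt_aa, effect
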