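"""Monte-Carlo confidence bands for Δ(SNP-index) under "no QTL".

Under the null hypothesis the two bulks are random draws of F2 plants, so
at any locus the bulk allele frequencies are means of 1:2:1 dosages — the
variance is dominated by the small bulk sizes (60 and 11 plants), not by
read sampling.  Each replicate draws one frequency pair per window
(complete linkage: all SNPs 2 Mb apart in an F2 are tightly linked), then
simulates per-SNP depths and binomial read counts with the same per-read
error and applies the same low-index filter as the real scan, and averages
Δ over the retained SNPs.  Band edges are the alpha/2 and 1 - alpha/2
quantiles of the replicate window means.

No normal approximation is used anywhere; the asymmetric bulk sizes are
respected as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["NullConfig", "NullSample", "null_window_delta", "threshold_track"]


@dataclass
class NullConfig:
    """Null-simulation parameters.

    ``depth_model`` is ``"poisson"`` (per-SNP Poisson around the per-bulk
    means) or ``"fixed"``; ``linkage`` is ``"complete"`` (one genotype draw
    per bulk per window, the default and the conservative choice) or
    ``"independent"`` (fresh genotype draw per SNP).
    """

    n_sb: int = 60
    n_hb: int = 11
    depth_sb: float = 12.0
    depth_hb: float = 12.0
    depth_model: str = "poisson"
    n_snps: int = 50
    replicates: int = 10_000
    alpha: float = 0.05
    error_rate: float = 0.01
    min_index: float = 0.2
    min_depth: int = 1
    filter_mode: str = "both"
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if self.n_sb < 1 or self.n_hb < 1:
            raise ValueError("bulk sizes must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.replicates < 100:
            raise ValueError("need at least 100 replicates")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.depth_sb <= 0 or self.depth_hb <= 0:
            raise ValueError("depths must be positive")
        if self.depth_model not in ("poisson", "fixed"):
            raise ValueError("depth_model must be 'poisson' or 'fixed'")
        if self.linkage not in ("complete", "independent"):
            raise ValueError("linkage must be 'complete' or 'independent'")
        if self.filter_mode not in ("both", "either", "none"):
            raise ValueError("filter_mode must be 'both', 'either' or 'none'")


@dataclass
class NullSample:
    """A sample of null window-mean Δ values plus bookkeeping."""

    deltas: np.ndarray
    n_redrawn: int
    config: NullConfig

    def quantiles(self, alpha: float | None = None) -> tuple[float, float]:
        a = self.config.alpha if alpha is None else alpha
        lo, hi = np.quantile(self.deltas, [a / 2.0, 1.0 - a / 2.0])
        return float(lo), float(hi)


def _bulk_frequencies(
    rng: np.random.Generator, n_plants: int, shape: tuple[int, ...]
) -> np.ndarray:
    # dosage of 2n independent alleles at 1/2 each == sum of two Bernoulli
    # draws per plant, i.e. 1:2:1 per plant; returned as allele *numerators*
    # (0 .. 2n) so cells can be grouped by exact frequency
    return rng.binomial(2 * n_plants, 0.5, size=shape)


def _sample_reads(
    rng: np.random.Generator,
    f_num: np.ndarray,
    denom: int,
    n_snps: int,
    mean_depth: float,
    depth_model: str,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (alt, depth) read counts grouped by exact bulk frequency.

    ``f_num`` holds allele-count numerators, shaped ``(replicates, 1)``
    under complete linkage or ``(replicates, n_snps)`` for independent
    SNPs.  Cells sharing a frequency are drawn with scalar-parameter RNG
    calls.  For Poisson depths the (depth, alt) pair is drawn as two
    independent Poissons — alt ~ Poisson(lambda p), ref ~
    Poisson(lambda (1 - p)) — which is exactly equivalent to Poisson depth
    with binomial thinning.
    """
    r, s = f_num.shape[0], n_snps
    per_row = f_num.shape[1] == 1  # complete linkage: one frequency per row
    flat = f_num[:, 0] if per_row else f_num.ravel()
    uniq, inv, counts = np.unique(flat, return_inverse=True, return_counts=True)
    order = np.argsort(inv, kind="stable")
    if per_row:
        alt = np.empty((r, s), dtype=np.int64)
        depth = np.empty((r, s), dtype=np.int64)
    else:
        alt = np.empty(flat.size, dtype=np.int64)
        depth = np.empty(flat.size, dtype=np.int64)
    pos = 0
    for u, c in zip(uniq, counts):
        f = u / denom
        p = f * (1 - error_rate) + (1 - f) * error_rate
        sel = order[pos : pos + c]
        size = (c, s) if per_row else c
        if depth_model == "poisson":
            a = rng.poisson(mean_depth * p, size)
            b = rng.poisson(mean_depth * (1 - p), size)
            alt[sel] = a
            depth[sel] = a + b
        else:
            d = int(round(mean_depth))
            alt[sel] = rng.binomial(d, p, size)
            depth[sel] = d
        pos += c
    if per_row:
        return alt, depth
    return alt.reshape(f_num.shape), depth.reshape(f_num.shape)


def null_window_delta(
    cfg: NullConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> NullSample:
    """Simulate window-mean Δ(SNP-index) under the no-QTL null.

    Replicates in which every SNP is filtered out are redrawn; their count
    is reported in ``n_redrawn``.
    """
    cfg = cfg or NullConfig()
    rng = np.random.default_rng(seed)
    out = np.empty(cfg.replicates)
    todo = np.arange(cfg.replicates)
    n_redrawn = 0
    while todo.size:
        r, s = todo.size, cfg.n_snps
        shape = (r, 1) if cfg.linkage == "complete" else (r, s)
        fnum = {
            "sb": _bulk_frequencies(rng, cfg.n_sb, shape),
            "hb": _bulk_frequencies(rng, cfg.n_hb, shape),
        }
        idx = {}
        depth = {}
        for tag, n_plants, mean_depth in (
            ("sb", cfg.n_sb, cfg.depth_sb),
            ("hb", cfg.n_hb, cfg.depth_hb),
        ):
            alt, d = _sample_reads(
                rng, fnum[tag], 2 * n_plants, s, mean_depth, cfg.depth_model, cfg.error_rate
            )
            # uncovered cells (d == 0) get a dummy index; they are always
            # excluded by the coverage mask below
            idx[tag] = alt / np.maximum(d, 1)
            depth[tag] = d
        min_depth = max(cfg.min_depth, 1)
        keep = (depth["sb"] >= min_depth) & (depth["hb"] >= min_depth)
        if cfg.filter_mode == "both":
            keep &= ~((idx["sb"] < cfg.min_index) & (idx["hb"] < cfg.min_index))
        elif cfg.filter_mode == "either":
            keep &= ~((idx["sb"] < cfg.min_index) | (idx["hb"] < cfg.min_index))
        delta = idx["sb"] - idx["hb"]
        delta[~keep] = 0.0
        n_keep = keep.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = delta.sum(axis=1) / n_keep
        ok = n_keep > 0
        out[todo[ok]] = means[ok]
        todo = todo[~ok]
        n_redrawn += int((~ok).sum())
    return NullSample(out, n_redrawn, cfg)


def threshold_track(
    windows: pd.DataFrame,
    cfg: NullConfig | None = None,
    seed: int = 0,
    cache: dict | None = None,
) -> pd.DataFrame:
    """Attach per-window null band edges (``lower``/``upper`` columns).

    Thresholds are matched to each window's retained SNP count and per-bulk
    mean depths (rounded to the nearest integer) and cached per such key,
    so windows with identical keys share identical thresholds.  The child
    RNG for each key is derived from ``seed`` and the key itself, making
    the track independent of window order.  Missing windows (means flagged
    NaN) get no thresholds.  A ``cache`` dict may be passed to reuse
    quantiles across multiple tracks scanned under the same config/seed.
    """
    cfg = cfg or NullConfig()
    out = windows.copy()
    lower = np.full(len(out), np.nan)
    upper = np.full(len(out), np.nan)
    valid = out["delta"].notna().to_numpy()
    keys = cache if cache is not None else {}
    n_snps = out["n_snps"].to_numpy()
    d_sb = out["sb_depth"].to_numpy(float)
    d_hb = out["hb_depth"].to_numpy(float)
    for i in np.flatnonzero(valid):
        key = (int(n_snps[i]), int(round(d_sb[i])), int(round(d_hb[i])))
        if key not in keys:
            kcfg = replace(
                cfg,
                n_snps=key[0],
                depth_sb=max(key[1], 1),
                depth_hb=max(key[2], 1),
            )
            child = np.random.default_rng(
                np.random.SeedSequence((seed,) + tuple(abs(k) for k in key))
            )
            keys[key] = null_window_delta(kcfg, child).quantiles()
        lower[i], upper[i] = keys[key]
    out["lower"] = lower
    out["upper"] = upper
    return out
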