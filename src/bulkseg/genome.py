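"""Genome and causal-locus models for the simulated biparental cross.

The default genome mimics the 12 tomato (*Solanum lycopersicum*) chromosomes
at SL2.40-like physical lengths, carries ~15,640 biallelic SNP markers placed
uniformly at random, and a uniform recombination rate in cM/Mb.  Two causal
loci are planted by default: *FALSIFLORA* (FA) on chromosome 3 and
*COMPOUND INFLORESCENCE* (S) on chromosome 2, at the physical positions of
the candidate SNPs genotyped in the mapping study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CausalLocus",
    "GenomeModel",
    "DEFAULT_CAUSAL_LOCI",
    "TOMATO_CHROMOSOMES",
]

#: SL2.40-like chromosome lengths in bp (chromosome 0 / unanchored scaffolds
#: are not modelled).
TOMATO_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chr01", 90_304_244),
    ("chr02", 49_918_294),
    ("chr03", 64_840_714),
    ("chr04", 64_064_312),
    ("chr05", 65_021_438),
    ("chr06", 46_041_636),
    ("chr07", 65_268_621),
    ("chr08", 63_032_657),
    ("chr09", 67_662_091),
    ("chr10", 64_834_305),
    ("chr11", 53_386_025),
    ("chr12", 65_486_253),
)


@dataclass(frozen=True)
class CausalLocus:
    """A planted trait locus.

    ``label`` identifies which gene of the two-locus branching model the
    locus stands for: ``"FA"`` (*FALSIFLORA*, major) or ``"S"``
    (*COMPOUND INFLORESCENCE*, minor).
    """

    chrom: str
    pos: int
    label: str


#: Candidate-SNP positions of the FA and S genes on SL2.40 coordinates.
DEFAULT_CAUSAL_LOCI: tuple[CausalLocus, ...] = (
    CausalLocus("chr03", 61_167_529, "FA"),
    CausalLocus("chr02", 36_916_232, "S"),
)


@dataclass
class GenomeModel:
    """Marker map of the cross: chromosomes, SNP positions, recombination.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    recombination_rate
        Uniform recombination rate in cM per Mb (default 2, ~120 cM for a
        60 Mb chromosome).
    snp_positions
        Mapping from chromosome name to a sorted array of 1-based bp
        positions (strictly increasing, within ``[1, length]``).
    causal_loci
        Loci whose positions are guaranteed to be present among the SNPs.
    """

    chromosomes: Sequence[tuple[str, int]]
    recombination_rate: float = 2.0
    snp_positions: Mapping[str, np.ndarray] = field(default_factory=dict)
    causal_loci: tuple[CausalLocus, ...] = ()

    def __post_init__(self) -> None:
        self.chromosomes = tuple((str(n), int(l)) for n, l in self.chromosomes)
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        lengths = dict(self.chromosomes)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.recombination_rate < 0:
            raise ValueError("recombination rate must be non-negative")
        positions = {}
        for name, pos in dict(self.snp_positions).items():
            if name not in lengths:
                raise ValueError(f"SNP positions given for unknown chromosome {name!r}")
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError(f"SNP positions on {name} must be strictly increasing")
            if arr.size and (arr[0] < 1 or arr[-1] > lengths[name]):
                raise ValueError(f"SNP positions on {name} outside [1, {lengths[name]}]")
            positions[name] = arr
        self.snp_positions = positions
        for locus in self.causal_loci:
            if locus.chrom not in lengths:
                raise ValueError(f"causal locus {locus.label} on unknown chromosome")
            if not 1 <= locus.pos <= lengths[locus.chrom]:
                raise ValueError(f"causal locus {locus.label} outside its chromosome")

    # -- convenience ------------------------------------------------------

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def n_snps(self) -> int:
        return int(sum(a.size for a in self.snp_positions.values()))

    def morgans(self, chrom: str) -> float:
        """Genetic length of ``chrom`` in Morgans under the uniform map."""
        length = self.chrom_lengths[chrom]
        return length / 1e6 * self.recombination_rate / 100.0

    def locus(self, label: str) -> CausalLocus:
        for loc in self.causal_loci:
            if loc.label == label:
                return loc
        raise KeyError(f"no causal locus labelled {label!r}")

    def snp_frame(self):
        """All SNPs as a ``(chrom, pos)`` pandas DataFrame in genome order."""
        import pandas as pd

        chroms: list[str] = []
        pos: list[np.ndarray] = []
        for name in self.chrom_names:
            arr = self.snp_positions.get(name, np.empty(0, dtype=np.int64))
            chroms.extend([name] * arr.size)
            pos.append(arr)
        return pd.DataFrame(
            {"chrom": chroms, "pos": np.concatenate(pos) if pos else np.empty(0, np.int64)}
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def tomato(
        cls,
        n_snps: int = 15_640,
        recombination_rate: float = 2.0,
        causal_loci: Sequence[CausalLocus] = DEFAULT_CAUSAL_LOCI,
        seed: int | np.random.Generator = 0,
    ) -> "GenomeModel":
        """Default 12-chromosome tomato-like genome with random SNP placement.

        SNP counts are apportioned to chromosomes proportionally to physical
        length (largest-remainder rounding); positions are drawn uniformly
        without replacement and then the causal-locus positions are swapped
        in for their nearest marker so that every planted locus is itself a
        scored SNP.
        """
        rng = np.random.default_rng(seed)
        lengths = np.array([l for _, l in TOMATO_CHROMOSOMES], dtype=float)
        share = n_snps * lengths / lengths.sum()
        counts = np.floor(share).astype(int)
        remainder = share - counts
        for i in np.argsort(remainder)[::-1][: n_snps - counts.sum()]:
            counts[i] += 1
        positions: dict[str, np.ndarray] = {}
        for (name, length), k in zip(TOMATO_CHROMOSOMES, counts):
            pos = _sample_unique_positions(rng, length, int(k))
            positions[name] = pos
        for locus in causal_loci:
            arr = positions[locus.chrom]
            nearest = int(np.argmin(np.abs(arr - locus.pos)))
            arr = arr.copy()
            arr[nearest] = locus.pos
            positions[locus.chrom] = np.unique(arr)
        return cls(
            chromosomes=TOMATO_CHROMOSOMES,
            recombination_rate=recombination_rate,
            snp_positions=positions,
            causal_loci=tuple(causal_loci),
        )


def _sample_unique_positions(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """Draw ``k`` distinct 1-based positions uniformly from ``[1, length]``."""
    if k > length:
        raise ValueError("more SNPs requested than available positions")
    got: np.ndarray = np.empty(0, dtype=np.int64)
    while got.size < k:
        extra = rng.integers(1, length + 1, size=2 * (k - got.size) + 16)
        got = np.unique(np.concatenate([got, extra]))
    if got.size > k:
        got = rng.choice(got, size=k, replace=False)
    return np.sort(got.astype(np.int64))
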