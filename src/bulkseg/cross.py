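"""Forward simulation of the F2 mapping population and bulk sequencing.

The cross emulated here is ``10AS111A x PI124039``: the highly-branched
cultivated parent (10AS111A) is also the read-mapping reference, so at every
marker the simulator tracks the *dosage* (0/1/2) of the PI124039-type,
non-reference allele.  Gametes are produced under a Haldane model (crossover
count per chromosome ~ Poisson(genetic length in Morgans), crossover
positions uniform, no interference), so every marker segregates 1:2:1 in
expectation.

Branch number (BN) per inflorescence follows a duplicate-recessive two-locus
model on the log2 scale: the four genotype classes at the planted FA and S
loci (``F_S_``, ``F_ss``, ``ffS_``, ``ffss``; upper-case alleles from
PI124039) each have a mean log2(BN), only the double homozygote for the
10AS111A alleles (``ffss``) is highly branched, and a plant's BN is the
median over its first ten inflorescences — giving the ~15:1 segregation of
non-highly-branched to highly-branched plants.

Bulk read counts emulate "mixing equal amounts of DNA": the bulk allele
frequency at a SNP is the mean member dosage / 2, per-SNP per-bulk depth is
Poisson, and alternate-read counts are binomial with a flat per-read error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "PhenotypeModel",
    "ReadSimConfig",
    "F2Individual",
    "F2Population",
    "BulkSelectionError",
    "simulate_gametes",
    "simulate_f2",
    "assign_phenotypes",
    "select_bulks",
    "simulate_bulk_reads",
    "simulate_study",
    "StudyData",
]

GENOTYPE_CLASSES = ("F_S_", "F_ss", "ffS_", "ffss")

#: Thresholds of the single-branch rule used for the SB bulk: plant median
#: BN equal to 1 and at least this fraction of inflorescences single.
SINGLE_BRANCH_FRACTION = 0.7
#: Plants with median BN strictly greater than this are highly branched.
HIGHLY_BRANCHED_MIN_BN = 16


class BulkSelectionError(ValueError):
    """Raised when fewer plants qualify for a bulk than were requested."""


@dataclass
class PhenotypeModel:
    """Two-locus epistatic model for log2 branch number per inflorescence.

    ``class_means`` maps the four FA x S genotype classes to the mean of the
    latent Normal on the log2(BN) scale; ``class_sd`` is the common
    inflorescence-to-inflorescence standard deviation.  Each inflorescence
    BN is ``max(1, round(2**x))`` and the plant-level BN is the median over
    ``n_inflorescences`` inflorescences.

    The default means (0.0, 1.2, 2.0, 5.0; sd 0.7) centre the single-branch
    class on BN = 1 (so that ~60 of 129 plants meet the single-branch bulk
    rule), keep the ``ffss`` class around BN = 32 (>16, highly branched)
    and preserve the ordering of class means observed for the four genotype
    groups.  They are calibration defaults, not estimates.
    """

    class_means: Mapping[str, float] = field(
        default_factory=lambda: {"F_S_": 0.0, "F_ss": 1.2, "ffS_": 2.0, "ffss": 5.0}
    )
    class_sd: float = 0.7
    n_inflorescences: int = 10

    def __post_init__(self) -> None:
        means = dict(self.class_means)
        missing = set(GENOTYPE_CLASSES) - set(means)
        if missing:
            raise ValueError(f"class means missing for {sorted(missing)}")
        if not (
            means["F_S_"] < means["F_ss"]
            and means["F_S_"] < means["ffS_"]
            and means["ffss"] > max(means["F_S_"], means["F_ss"], means["ffS_"])
        ):
            raise ValueError(
                "class means must satisfy F_S_ < F_ss, F_S_ < ffS_, all < ffss"
            )
        if self.class_sd < 0:
            raise ValueError("class_sd must be non-negative")
        if self.n_inflorescences < 1:
            raise ValueError("n_inflorescences must be >= 1")
        self.class_means = means


@dataclass
class ReadSimConfig:
    """Bulk read-count model: depth, per-read error, reference orientation.

    ``mean_depth`` is the expected reads per SNP per bulk (12x in the study);
    ``error_rate`` is the probability that a read reports the wrong allele.
    ``reference="10AS111A"`` (the default, as in the study) makes the
    SNP-index count PI124039-type reads; ``"PI124039"`` flips orientation.
    """

    mean_depth: float = 12.0
    error_rate: float = 0.01
    depth_model: str = "poisson"  # or "fixed"
    reference: str = "10AS111A"

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth_model not in ("poisson", "fixed"):
            raise ValueError("depth_model must be 'poisson' or 'fixed'")
        if self.reference not in ("10AS111A", "PI124039"):
            raise ValueError("reference must be '10AS111A' or 'PI124039'")


@dataclass(frozen=True)
class F2Individual:
    """Read-only view of one simulated plant."""

    index: int
    dosage: Mapping[str, np.ndarray]
    genotype_fa: str
    genotype_s: str
    bn_values: np.ndarray | None
    bn_median: float | None

    @property
    def genotype_class(self) -> str:
        return _class_label(self.genotype_fa, self.genotype_s)


class F2Population:
    """A simulated F2 population: dosage matrix plus (optional) phenotypes.

    ``dosage`` is an ``(n, n_snps)`` uint8 matrix of PI124039-allele dosages
    in genome order; per-chromosome blocks are addressed through
    ``chrom_slices``.
    """

    def __init__(self, genome: GenomeModel, dosage: np.ndarray):
        self.genome = genome
        self.dosage = dosage
        self.chrom_slices: dict[str, slice] = {}
        off = 0
        for name in genome.chrom_names:
            k = genome.snp_positions.get(name, np.empty(0)).size
            self.chrom_slices[name] = slice(off, off + k)
            off += k
        if dosage.shape != (dosage.shape[0], off):
            raise ValueError("dosage matrix does not match genome SNP count")
        # phenotype fields, populated by assign_phenotypes
        self.bn: np.ndarray | None = None  # (n, n_inflorescences) ints
        self.bn_median: np.ndarray | None = None
        self.pct_single: np.ndarray | None = None
        self.phenotype_model: PhenotypeModel | None = None

    def __len__(self) -> int:
        return self.dosage.shape[0]

    @property
    def phenotyped(self) -> bool:
        return self.bn is not None

    def dosage_at(self, chrom: str, pos: int) -> np.ndarray:
        """Dosage column at an exact marker position."""
        arr = self.genome.snp_positions[chrom]
        i = int(np.searchsorted(arr, pos))
        if i >= arr.size or arr[i] != pos:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return self.dosage[:, self.chrom_slices[chrom].start + i]

    def causal_dosage(self, label: str) -> np.ndarray:
        locus = self.genome.locus(label)
        return self.dosage_at(locus.chrom, locus.pos)

    def genotype_labels(self, label: str) -> np.ndarray:
        """Two-letter genotype strings at a causal locus (e.g. FF/Ff/ff)."""
        d = self.causal_dosage(label)
        upper, lower = (label[0].upper(), label[0].lower())
        lut = np.array([lower * 2, upper + lower, upper * 2])
        return lut[d]

    def genotype_classes(self) -> np.ndarray:
        """Four-way class labels (F_S_, F_ss, ffS_, ffss) per plant."""
        dfa = self.causal_dosage("FA")
        ds = self.causal_dosage("S")
        out = np.empty(len(self), dtype="U4")
        out[(dfa >= 1) & (ds >= 1)] = "F_S_"
        out[(dfa >= 1) & (ds == 0)] = "F_ss"
        out[(dfa == 0) & (ds >= 1)] = "ffS_"
        out[(dfa == 0) & (ds == 0)] = "ffss"
        return out

    def individual(self, i: int) -> F2Individual:
        dos = {
            name: self.dosage[i, sl] for name, sl in self.chrom_slices.items()
        }
        return F2Individual(
            index=i,
            dosage=dos,
            genotype_fa=str(self.genotype_labels("FA")[i]),
            genotype_s=str(self.genotype_labels("S")[i]),
            bn_values=None if self.bn is None else self.bn[i],
            bn_median=None if self.bn_median is None else float(self.bn_median[i]),
        )

    def phenotype_frame(self) -> pd.DataFrame:
        """Per-plant phenotype/genotype table (requires phenotypes)."""
        if not self.phenotyped:
            raise ValueError("population has no phenotypes yet")
        return pd.DataFrame(
            {
                "plant_id": [f"F2_{i:04d}" for i in range(len(self))],
                "bn_median": self.bn_median,
                "pct_single": self.pct_single,
                "genotype_FA": self.genotype_labels("FA"),
                "genotype_S": self.genotype_labels("S"),
                "genotype_class": self.genotype_classes(),
            }
        )


def _class_label(geno_fa: str, geno_s: str) -> str:
    fa = "ff" if geno_fa == "ff" else "F_"
    s = "ss" if geno_s == "ss" else "S_"
    return fa + s


# ---------------------------------------------------------------------------
# gametes and genotypes
# ---------------------------------------------------------------------------

def simulate_gametes(
    genome: GenomeModel,
    n_gametes: int,
    rng: np.random.Generator,
    chrom: str | None = None,
) -> dict[str, np.ndarray]:
    """Simulate F1 gametes: per-SNP parental-origin indicators.

    Returns, per chromosome, an ``(n_gametes, n_snps)`` uint8 matrix where 1
    marks the PI124039-derived allele.  Crossovers follow the Haldane model:
    the count per chromosome is Poisson with mean equal to the genetic
    length in Morgans, positions are uniform along the chromosome, and the
    starting parental phase of each gamete is a fair coin.
    """
    if n_gametes < 1:
        raise ValueError("n_gametes must be >= 1")
    chroms = [chrom] if chrom is not None else list(genome.chrom_names)
    out: dict[str, np.ndarray] = {}
    for name in chroms:
        pos = genome.snp_positions.get(name)
        length = genome.chrom_lengths[name]
        if pos is None or pos.size == 0:
            out[name] = np.zeros((n_gametes, 0), dtype=np.uint8)
            continue
        morgans = genome.morgans(name)
        k = rng.poisson(morgans, size=n_gametes)
        start = rng.integers(0, 2, size=n_gametes, dtype=np.uint8)
        maxk = int(k.max()) if k.size else 0
        if maxk == 0:
            out[name] = np.repeat(start[:, None], pos.size, axis=1)
            continue
        # padded breakpoint matrix; +inf pads never count as a crossover
        brk = np.full((n_gametes, maxk), np.inf)
        mask = np.arange(maxk)[None, :] < k[:, None]
        brk[mask] = rng.uniform(0.0, float(length), size=int(k.sum()))
        alleles = np.empty((n_gametes, pos.size), dtype=np.uint8)
        chunk = max(1, int(4e6 // max(1, n_gametes * maxk)))
        for lo in range(0, pos.size, chunk):
            p = pos[lo : lo + chunk].astype(float)
            crossings = (brk[:, None, :] < p[None, :, None]).sum(axis=2)
            alleles[:, lo : lo + chunk] = (start[:, None] + crossings) % 2
        out[name] = alleles
    return out


def simulate_f2(
    genome: GenomeModel,
    n: int,
    seed: int | np.random.Generator = 0,
) -> F2Population:
    """Simulate ``n`` F2 plants (genotypes only).

    Each plant receives two independent gametes per chromosome; the dosage
    at a SNP is the number of PI124039-type alleles, so any single marker
    segregates 1:2:1 in expectation.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if genome.n_snps == 0:
        raise ValueError("genome carries no SNPs")
    rng = np.random.default_rng(seed)
    blocks = []
    for name in genome.chrom_names:
        g = simulate_gametes(genome, 2 * n, rng, chrom=name)[name]
        blocks.append((g[0::2] + g[1::2]).astype(np.uint8))
    return F2Population(genome, np.hstack(blocks))


# ---------------------------------------------------------------------------
# phenotypes and bulks
# ---------------------------------------------------------------------------

def assign_phenotypes(
    pop: F2Population,
    model: PhenotypeModel | None = None,
    seed: int | np.random.Generator = 0,
) -> F2Population:
    """Draw per-inflorescence branch numbers and plant-level medians.

    For a plant of genotype class ``c``, each inflorescence draws
    ``x ~ Normal(class_means[c], class_sd)`` and scores
    ``BN = max(1, round(2**x))``; the plant BN is the median over its
    inflorescences.  Modifies ``pop`` in place and returns it.
    """
    model = model or PhenotypeModel()
    rng = np.random.default_rng(seed)
    classes = pop.genotype_classes()  # raises if causal loci absent
    means = np.array([model.class_means[c] for c in classes])
    x = rng.normal(
        means[:, None], model.class_sd, size=(len(pop), model.n_inflorescences)
    )
    bn = np.maximum(1, np.rint(np.exp2(x))).astype(np.int64)
    pop.bn = bn
    pop.bn_median = np.median(bn, axis=1)
    pop.pct_single = (bn == 1).mean(axis=1)
    pop.phenotype_model = model
    return pop


def single_branch_mask(pop: F2Population) -> np.ndarray:
    """Plants meeting the single-branch rule (median 1, >=70% single)."""
    if not pop.phenotyped:
        raise ValueError("population has no phenotypes yet")
    return (pop.bn_median == 1) & (pop.pct_single >= SINGLE_BRANCH_FRACTION)


def highly_branched_mask(pop: F2Population) -> np.ndarray:
    """Plants with median BN > 16."""
    if not pop.phenotyped:
        raise ValueError("population has no phenotypes yet")
    return pop.bn_median > HIGHLY_BRANCHED_MIN_BN


def select_bulks(
    pop: F2Population,
    n_sb: int = 60,
    n_hb: int = 11,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the single-branch (SB) and highly-branched (HB) bulks.

    SB plants have median BN = 1 with >=70% single inflorescences; HB
    plants have median BN > 16.  Members are sampled uniformly among
    qualifiers; the two sets are disjoint by construction.  Raises
    :class:`BulkSelectionError` naming the deficit when a bulk cannot be
    filled.
    """
    rng = np.random.default_rng(seed)
    sb_pool = np.flatnonzero(single_branch_mask(pop))
    hb_pool = np.flatnonzero(highly_branched_mask(pop))
    if sb_pool.size < n_sb:
        raise BulkSelectionError(
            f"requested {n_sb} single-branch plants but only {sb_pool.size} qualify"
        )
    if hb_pool.size < n_hb:
        raise BulkSelectionError(
            f"requested {n_hb} highly-branched plants but only {hb_pool.size} qualify"
        )
    sb = np.sort(rng.choice(sb_pool, size=n_sb, replace=False))
    hb = np.sort(rng.choice(hb_pool, size=n_hb, replace=False))
    return sb, hb


def simulate_bulk_reads(
    pop: F2Population,
    sb_ids: Sequence[int],
    hb_ids: Sequence[int],
    cfg: ReadSimConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate pooled read counts for both bulks at every SNP.

    The bulk allele frequency is the mean member dosage / 2 ("mixing equal
    amounts of DNA"); depth per SNP per bulk is Poisson (or fixed) around
    ``mean_depth``; alternate reads are
    ``Binomial(depth, f (1 - e) + (1 - f) e)``.

    Returns the SnpCounts table with columns ``chrom, pos, ref, alt,
    sb_ref, sb_alt, hb_ref, hb_alt``.
    """
    cfg = cfg or ReadSimConfig()
    rng = np.random.default_rng(seed)
    sb_ids = np.asarray(sb_ids, dtype=np.intp)
    hb_ids = np.asarray(hb_ids, dtype=np.intp)
    if sb_ids.size == 0 or hb_ids.size == 0:
        raise ValueError("bulks must be non-empty")
    snps = pop.genome.snp_frame()
    n_snps = len(snps)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n_snps)
    alt = (ref + rng.integers(1, 4, size=n_snps)) % 4
    counts: dict[str, np.ndarray] = {}
    for tag, ids in (("sb", sb_ids), ("hb", hb_ids)):
        f = pop.dosage[ids].mean(axis=0) / 2.0
        if cfg.reference == "PI124039":
            f = 1.0 - f
        p = f * (1 - cfg.error_rate) + (1 - f) * cfg.error_rate
        if cfg.depth_model == "poisson":
            depth = rng.poisson(cfg.mean_depth, size=n_snps)
        else:
            depth = np.full(n_snps, int(round(cfg.mean_depth)))
        alt_reads = rng.binomial(depth, p)
        counts[f"{tag}_ref"] = depth - alt_reads
        counts[f"{tag}_alt"] = alt_reads
    out = snps.copy()
    out["ref"] = bases[ref]
    out["alt"] = bases[alt]
    for key in ("sb_ref", "sb_alt", "hb_ref", "hb_alt"):
        out[key] = counts[key]
    return out


# ---------------------------------------------------------------------------
# end-to-end study driver
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Output of one end-to-end simulated study."""

    genome: GenomeModel
    population: F2Population
    sb_ids: np.ndarray
    hb_ids: np.ndarray
    counts: pd.DataFrame
    n_population_draws: int
    seed: int | None = None


def simulate_study(
    n: int = 129,
    n_sb: int = 60,
    n_hb: int = 11,
    genome: GenomeModel | None = None,
    phenotype_model: PhenotypeModel | None = None,
    read_config: ReadSimConfig | None = None,
    seed: int = 0,
    max_tries: int = 400,
) -> StudyData:
    """Simulate a full study: population, phenotypes, bulks, bulk reads.

    Mendelian sampling makes the requested bulks infeasible in a fair
    share of 129-plant populations (e.g. >= 11 ffss plants arise only in
    ~18% of draws), whereas the emulated study design starts from a
    population in which both bulks exist.  The driver therefore redraws the
    population until both bulks are feasible, reporting the number of draws
    in ``n_population_draws``.
    """
    genome = genome or GenomeModel.tomato(seed=np.random.default_rng(seed))
    phenotype_model = phenotype_model or PhenotypeModel()
    read_config = read_config or ReadSimConfig()
    ss = np.random.SeedSequence(seed)
    for tries in range(1, max_tries + 1):
        pop_seed, phen_seed, bulk_seed, read_seed = ss.spawn(4)
        pop = simulate_f2(genome, n, np.random.default_rng(pop_seed))
        assign_phenotypes(pop, phenotype_model, np.random.default_rng(phen_seed))
        try:
            sb, hb = select_bulks(pop, n_sb, n_hb, np.random.default_rng(bulk_seed))
        except BulkSelectionError:
            ss = np.random.SeedSequence((seed, tries))
            continue
        counts = simulate_bulk_reads(
            pop, sb, hb, read_config, np.random.default_rng(read_seed)
        )
        return StudyData(genome, pop, sb, hb, counts, tries, seed)
    raise BulkSelectionError(
        f"no population of {n} supported bulks of {n_sb}/{n_hb} in {max_tries} draws"
    )
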