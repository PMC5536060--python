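"""Gene-region and codon-effect classification of candidate SNPs.

Gene models are strand-aware: exons (1-based, inclusive), a CDS span, and a
promoter defined as the 2 kb immediately 5' of the transcript start.  A SNP
is located to one of ``upstream`` (promoter), ``exon_cds``, ``exon_utr``,
``intron`` or ``downstream``; CDS hits are additionally translated under
the standard nuclear genetic code and classified as silent, missense or
nonsense.  Only biallelic SNPs are handled — indels are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "GeneModel",
    "Consequence",
    "locate",
    "codon_effect",
    "annotate_snp",
    "annotate_table",
    "read_gene_models",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
#: Codon -> amino acid under the standard nuclear code ('*' for stop).
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

REGIONS = ("upstream", "exon_cds", "exon_utr", "intron", "downstream")


@dataclass
class GeneModel:
    """Strand-aware exon/CDS/promoter structure of one gene.

    ``exons`` are 1-based inclusive genomic (start, end) pairs in genomic
    order; ``cds_start``/``cds_end`` bound the translated span on the
    genome; ``cds_sequence`` is the spliced CDS in coding orientation
    (5' -> 3' of the mRNA), whose length must be a multiple of three.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Sequence[tuple[int, int]]
    cds_start: int
    cds_end: int
    cds_sequence: str = ""
    promoter_length: int = 2_000

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        if not exons or any(a > b for a, b in exons):
            raise ValueError("exons must be non-empty (start, end) with start <= end")
        for (a0, b0), (a1, b1) in zip(exons, exons[1:]):
            if a1 <= b0:
                raise ValueError("exons must be non-overlapping and ordered")
        self.exons = tuple(exons)
        if not (exons[0][0] <= self.cds_start <= self.cds_end <= exons[-1][1]):
            raise ValueError("CDS span must lie within the transcript")
        seq = self.cds_sequence.upper()
        if seq and len(seq) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if seq and set(seq) - set("ACGT"):
            raise ValueError("CDS sequence must be ACGT only")
        self.cds_sequence = seq
        expected = sum(
            min(b, self.cds_end) - max(a, self.cds_start) + 1
            for a, b in exons
            if b >= self.cds_start and a <= self.cds_end
        )
        if seq and len(seq) != expected:
            raise ValueError(
                f"spliced CDS length {len(seq)} does not match exon structure ({expected})"
            )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position into the spliced CDS."""
        if locate(pos, self) != "exon_cds":
            raise ValueError(f"position {pos} is not in the CDS of {self.gene_id}")
        off = 0
        for a, b in self.exons:
            lo, hi = max(a, self.cds_start), min(b, self.cds_end)
            if hi < lo:
                continue
            if lo <= pos <= hi:
                off += pos - lo
                break
            if pos > hi:
                off += hi - lo + 1
        if self.strand == "-":
            total = sum(
                min(b, self.cds_end) - max(a, self.cds_start) + 1
                for a, b in self.exons
                if b >= self.cds_start and a <= self.cds_end
            )
            off = total - 1 - off
        return off


@dataclass(frozen=True)
class Consequence:
    """Classification of one SNP against one gene model."""

    gene_id: str
    region: str
    codon_number: int | None = None  # 1-based protein position
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str | None = None  # silent / missense / nonsense


def locate(pos: int, gene: GeneModel) -> str:
    """Strand-aware gene-region classification of a genomic position.

    The promoter is the ``promoter_length`` bp immediately 5' of the
    transcript start (upstream on the coding strand); positions past the 3'
    end are ``downstream``; exonic positions split into ``exon_cds`` and
    ``exon_utr``; the rest of the transcript is ``intron``.
    """
    if gene.strand == "+":
        if gene.tx_start - gene.promoter_length <= pos < gene.tx_start:
            return "upstream"
        if pos < gene.tx_start:
            return "upstream" if pos >= gene.tx_start - gene.promoter_length else "downstream"
        if pos > gene.tx_end:
            return "downstream"
    else:
        if gene.tx_end < pos <= gene.tx_end + gene.promoter_length:
            return "upstream"
        if pos > gene.tx_end:
            return "downstream"
        if pos < gene.tx_start:
            return "downstream"
    if pos < gene.tx_start or pos > gene.tx_end:
        return "downstream"
    for a, b in gene.exons:
        if a <= pos <= b:
            if gene.cds_start <= pos <= gene.cds_end:
                return "exon_cds"
            return "exon_utr"
    return "intron"


def codon_effect(
    cds_sequence: str, cds_offset: int, ref_base: str, alt_base: str
) -> Consequence:
    """Translate a single-base CDS substitution and classify its effect.

    ``cds_offset`` is the 0-based position in the spliced CDS (coding
    orientation); ``ref_base`` must match the sequence there, else a
    coordinate error is signalled.  A change producing a stop codon is
    "nonsense"; a change destroying the start codon is reported as
    missense with a warning.
    """
    seq = cds_sequence.upper()
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if not 0 <= cds_offset < len(seq):
        raise ValueError("CDS offset outside the coding sequence")
    if seq[cds_offset] != ref_base:
        raise ValueError(
            f"reference base mismatch at CDS offset {cds_offset}: "
            f"sequence has {seq[cds_offset]}, variant says {ref_base}"
        )
    codon_i = cds_offset // 3
    within = cds_offset % 3
    ref_codon = seq[3 * codon_i : 3 * codon_i + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        effect = "silent"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "missense"
        if codon_i == 0 and ref_codon == "ATG":
            warnings.warn(
                "substitution destroys the start codon; reported as missense",
                stacklevel=2,
            )
    return Consequence(
        gene_id="",
        region="exon_cds",
        codon_number=codon_i + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect=effect,
    )


def annotate_snp(
    gene: GeneModel, chrom: str, pos: int, ref: str, alt: str
) -> Consequence:
    """Full classification of one genomic SNP against one gene model.

    ``ref``/``alt`` are on the forward genomic strand; for minus-strand
    genes they are complemented before translation, so the protein-level
    call matches the equivalent forward-strand construction.
    """
    if chrom != gene.chrom:
        raise ValueError(f"SNP on {chrom} but gene {gene.gene_id} on {gene.chrom}")
    region = locate(pos, gene)
    if region != "exon_cds":
        return Consequence(gene_id=gene.gene_id, region=region)
    if not gene.cds_sequence:
        raise ValueError(f"gene {gene.gene_id} has no CDS sequence attached")
    if gene.strand == "-":
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    result = codon_effect(gene.cds_sequence, gene.cds_offset(pos), ref, alt)
    return Consequence(
        gene_id=gene.gene_id,
        region="exon_cds",
        codon_number=result.codon_number,
        ref_codon=result.ref_codon,
        alt_codon=result.alt_codon,
        ref_aa=result.ref_aa,
        alt_aa=result.alt_aa,
        effect=result.effect,
    )


def annotate_table(
    snps: pd.DataFrame, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Classify every SNP against every same-chromosome gene model.

    ``snps`` needs columns ``chrom``, ``pos``, ``ref``, ``alt``.  SNPs that
    fall ``downstream`` of a gene (i.e. unrelated to it) are omitted from
    the output.
    """
    rows = []
    for _, s in snps.iterrows():
        for gene in genes:
            if s["chrom"] != gene.chrom:
                continue
            c = annotate_snp(gene, s["chrom"], int(s["pos"]), s["ref"], s["alt"])
            if c.region == "downstream":
                continue
            rows.append(
                {
                    "chrom": s["chrom"],
                    "pos": int(s["pos"]),
                    "ref": s["ref"],
                    "alt": s["alt"],
                    "gene_id": gene.gene_id,
                    "region": c.region,
                    "codon_number": c.codon_number,
                    "ref_codon": c.ref_codon,
                    "alt_codon": c.alt_codon,
                    "ref_aa": c.ref_aa,
                    "alt_aa": c.alt_aa,
                    "effect": c.effect,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "gene_id",
            "region",
            "codon_number",
            "ref_codon",
            "alt_codon",
            "ref_aa",
            "alt_aa",
            "effect",
        ],
    )


def read_gene_models(
    gff_path: str, fasta_path: str | None = None, promoter_length: int = 2_000
) -> list[GeneModel]:
    """Read a minimal GFF3 subset (gene/exon/CDS features) into gene models.

    When a FASTA is given, the spliced CDS is extracted with pyfaidx and
    reverse-complemented for minus-strand genes.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    fasta = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path))
    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            (f.start, f.end) for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start, f.end) for f in db.children(gene, featuretype="CDS", order_by="start")
        ]
        if not exons or not cds:
            continue
        seq = ""
        if fasta is not None:
            parts = [str(fasta[gene.seqid][a - 1 : b]) for a, b in cds]
            seq = "".join(parts).upper()
            if gene.strand == "-":
                seq = seq.translate(_COMPLEMENT)[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds_start=min(a for a, _ in cds),
                cds_end=max(b for _, b in cds),
                cds_sequence=seq,
                promoter_length=promoter_length,
            )
        )
    return models
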