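"""Classify candidate SNPs within a gene model.

Builds a small two-exon gene with a 2 kb promoter and classifies three
SNPs: one in the promoter, one silent, and one missense (His -> Gln, the
kind of coding change reported for the FA candidate).
"""

import bulkseg as bs

#            v codon 2 = CAC (His)
cds = "ATG" + "CAC" + "GGC" + "GTA" + "TAA"  # M H G V *
gene = bs.GeneModel(
    gene_id="candidate",
    chrom="chr03",
    strand="+",
    exons=[(10_001, 10_006), (10_101, 10_109)],
    cds_start=10_001,
    cds_end=10_109,
    cds_sequence=cds,
)

for pos, ref, alt, note in [
    (9_500, "G", "A", "promoter SNP (within 2 kb upstream)"),
    (10_006, "C", "G", "His -> Gln substitution in codon 2"),
    (10_103, "C", "G", "third-base change in a GGC glycine codon"),
]:
    c = bs.annotate_snp(gene, "chr03", pos, ref, alt)
    if c.region == "exon_cds":
        print(
            f"{pos}: {c.region}, codon {c.codon_number} "
            f"{c.ref_codon}->{c.alt_codon} ({c.ref_aa}->{c.alt_aa}, {c.effect})"
            f"  # {note}"
        )
    else:
        print(f"{pos}: {c.region}  # {note}")
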