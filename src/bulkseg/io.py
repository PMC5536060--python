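"""File formats and reproducibility plumbing shared by all stages.

Tab-separated text is the canonical interchange format; VCF 4.2 (two pooled
samples carrying allele depths) and BED are provided for interoperability.
All internal and TSV coordinates are 1-based; BED output is 0-based
half-open.  Every writer stamps a header comment with the tool version, a
hash of the generating configuration, and the seed, so identical
config + seed reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import GenomeModel
from .qtl import QtlInterval

logger = logging.getLogger("bulkseg")

__all__ = [
    "read_counts",
    "write_counts_tsv",
    "write_counts_vcf",
    "read_counts_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_windows",
    "read_windows",
    "write_intervals_bed",
    "load_config",
    "save_config",
    "config_hash",
]

COUNT_SCHEMA = ("chrom", "pos", "ref", "alt", "sb_ref", "sb_alt", "hb_ref", "hb_alt")


def config_hash(config: Mapping | None) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def _header_lines(seed=None, config: Mapping | None = None, **extra) -> list[str]:
    lines = [
        f"# bulkseg v{__version__}",
        f"# config_hash={config_hash(config)}",
        f"# seed={seed}",
    ]
    lines += [f"# {k}={v}" for k, v in extra.items()]
    return lines


def _write_tsv(df: pd.DataFrame, path, seed, config, **extra) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(seed, config, **extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- SnpCounts ---------------------------------------------------------------

def write_counts_tsv(
    counts: pd.DataFrame, path, seed=None, config: Mapping | None = None
) -> None:
    """Write a SnpCounts table as tab-separated text."""
    _write_tsv(counts[list(COUNT_SCHEMA)], path, seed, config)


def read_counts(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a SnpCounts table from TSV or VCF (detected from the suffix).

    The table is validated (schema, non-negative counts, positions >= 1)
    and sorted by chromosome (order of appearance) and position.
    """
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "tsv")
    if fmt == "vcf":
        df = read_counts_vcf(path)
    elif fmt == "tsv":
        df = _read_tsv(path)
    else:
        raise ValueError("format must be 'tsv' or 'vcf'")
    missing = set(COUNT_SCHEMA) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    bad_rows = []
    for col in ("sb_ref", "sb_alt", "hb_ref", "hb_alt"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        bad_rows.extend((df.index[bad] + 2).tolist())  # +2: 1-based + header
        df[col] = vals
    bad = pd.to_numeric(df["pos"], errors="coerce")
    bad_rows.extend((df.index[bad.isna() | (bad < 1)] + 2).tolist())
    if bad_rows:
        raise ValueError(
            f"malformed rows (file lines, excluding comments): {sorted(set(bad_rows))[:20]}"
        )
    df["pos"] = df["pos"].astype(np.int64)
    for col in ("sb_ref", "sb_alt", "hb_ref", "hb_alt"):
        df[col] = df[col].astype(np.int64)
    order = {c: i for i, c in enumerate(dict.fromkeys(df["chrom"]))}
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    return df.reset_index(drop=True)


def write_counts_vcf(
    counts: pd.DataFrame,
    genome: GenomeModel | Mapping[str, int],
    path,
    seed=None,
    config: Mapping | None = None,
) -> None:
    """Write the SnpCounts table as VCF 4.2 with two AD-carrying samples."""
    import pysam

    lengths = genome.chrom_lengths if isinstance(genome, GenomeModel) else dict(genome)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for name, length in lengths.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line(f"##bulkseg_version={__version__}")
    header.add_line(f"##bulkseg_config_hash={config_hash(config)}")
    header.add_line(f"##bulkseg_seed={seed}")
    header.add_sample("SB")
    header.add_sample("HB")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in counts.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom,
                start=row.pos - 1,
                stop=row.pos,
                alleles=(row.ref, row.alt),
            )
            rec.samples["SB"]["AD"] = (int(row.sb_ref), int(row.sb_alt))
            rec.samples["HB"]["AD"] = (int(row.hb_ref), int(row.hb_alt))
            vcf.write(rec)


def read_counts_vcf(path, sb_sample: str = "SB", hb_sample: str = "HB") -> pd.DataFrame:
    """Read bulk allele depths from a two-sample VCF.

    Multiallelic records are skipped; their count is logged and stored in
    ``df.attrs["n_multiallelic_skipped"]``.
    """
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for name in (sb_sample, hb_sample):
            if name not in samples:
                raise ValueError(f"VCF lacks designated sample {name!r}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            try:
                sb_ad = rec.samples[sb_sample]["AD"]
                hb_ad = rec.samples[hb_sample]["AD"]
            except KeyError as err:
                raise ValueError(f"record {rec.contig}:{rec.pos} lacks AD") from err
            if sb_ad is None or hb_ad is None or None in sb_ad or None in hb_ad:
                raise ValueError(f"record {rec.contig}:{rec.pos} lacks AD values")
            rows.append(
                {
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "sb_ref": int(sb_ad[0]),
                    "sb_alt": int(sb_ad[1]),
                    "hb_ref": int(hb_ad[0]),
                    "hb_alt": int(hb_ad[1]),
                }
            )
    if skipped:
        logger.info("skipped %d multiallelic records", skipped)
    df = pd.DataFrame(rows, columns=list(COUNT_SCHEMA))
    df.attrs["n_multiallelic_skipped"] = skipped
    return df


# -- phenotype, window, interval tables -------------------------------------

def write_phenotypes(
    phenotypes: pd.DataFrame, path, seed=None, config: Mapping | None = None
) -> None:
    _write_tsv(phenotypes, path, seed, config)


def read_phenotypes(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_windows(
    windows: pd.DataFrame, path, seed=None, config: Mapping | None = None, **extra
) -> None:
    """Write the window track (optionally with threshold columns) as TSV."""
    _write_tsv(windows, path, seed, config, **extra)


def read_windows(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_intervals_bed(
    intervals: Sequence[QtlInterval], path, seed=None, config: Mapping | None = None
) -> None:
    """Write called intervals as BED (0-based half-open) with a peak column."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        for iv in intervals:
            name = f"peak@{iv.peak_start - 1}:delta={iv.peak_delta:+.3f}"
            score = int(round(min(abs(iv.peak_delta), 1.0) * 1000))
            strand = "+" if iv.direction > 0 else "-"
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end - 1}\t{name}\t{score}\t{strand}\n"
            )


# -- configuration -----------------------------------------------------------

def load_config(path) -> dict:
    """Load a human-readable key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def save_config(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
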