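"""Variant-table input/output, filtering and coding-effect annotation.

Variants are carried as a pandas DataFrame with the columns

    chrom, pos (1-based), ref, alt, qual, depth, alt_depth, f,
    context (96-channel label, optional), effect (optional)

where f = alt_depth/depth is the observed allele frequency. VCF access goes
through pysam; TSV through pandas; FASTA through Biopython; the genetic code
comes from Bio.Data.CodonTable. Coordinates are 1-based, fully closed, as in
VCF, everywhere in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Data import CodonTable

from .signatures import CHANNELS_96, channel_of

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "depth", "alt_depth"]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
#: codon -> amino acid, stops mapped to "*"
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
_SNV_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Reading and writing variant tables

def _f_from_fields(alt_depth, depth, af):
    if depth and depth > 0 and alt_depth is not None:
        return alt_depth / depth
    return af


def read_variants(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read biallelic SNVs from a VCF (4.x) or TSV variant table.

    Multiallelic sites are split into one row per alternate allele; non-SNV
    alleles are skipped with a logged count. The observed frequency f comes
    from allele depths when present (FORMAT AD of the first sample, or the
    INFO depth pair), else from INFO AF.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf", ".gz"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _info_get(info, key, index=0):
    """Scalar INFO access tolerant of keys absent from the header."""
    try:
        val = info[key]
    except (KeyError, ValueError):
        return None
    if isinstance(val, tuple):
        return val[index] if index < len(val) else None
    return val


def _read_vcf(path: Path) -> pd.DataFrame:
    rows = []
    n_skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: malformed VCF header: {exc}") from exc
    for rec in vcf:
        if rec.alts is None:
            n_skipped += 1
            continue
        info = rec.info
        for ai, alt in enumerate(rec.alts):
            if len(rec.ref) != 1 or len(alt) != 1 or rec.ref not in _SNV_BASES \
                    or alt not in _SNV_BASES:
                n_skipped += 1
                continue
            depth = _info_get(info, "TCN")
            if depth is None:
                depth = _info_get(info, "DP")
            alt_depth = _info_get(info, "ACN", ai)
            if rec.samples and alt_depth is None:
                sample = rec.samples[0]
                ad = sample.get("AD") if "AD" in sample else None
                if ad is not None:
                    alt_depth = ad[ai + 1]
                    depth = sum(x for x in ad if x is not None)
            af = _info_get(info, "AF", ai)
            f = _f_from_fields(alt_depth, depth, af)
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt,
                "qual": rec.qual, "depth": depth, "alt_depth": alt_depth,
                "f": f, "context": _info_get(info, "CTX"),
                "effect": _info_get(info, "EFF"),
                "true_f": _info_get(info, "TRUEF"),
            })
    if n_skipped:
        logger.info("read_variants: skipped %d non-SNV alleles/records", n_skipped)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual", "depth",
                                     "alt_depth", "f", "context", "effect", "true_f"])
    return df


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: line 1: missing required columns {missing}")
    snv = df["ref"].isin(_SNV_BASES) & df["alt"].isin(_SNV_BASES)
    n_skipped = int((~snv).sum())
    if n_skipped:
        bad_lines = (df.index[~snv] + 2).tolist()[:5]
        logger.info("read_variants: skipped %d non-SNV rows (lines %s...)",
                    n_skipped, bad_lines)
    df = df[snv].reset_index(drop=True)
    if "f" not in df.columns:
        df["f"] = df["alt_depth"] / df["depth"]
    return df


def write_variants(records: pd.DataFrame, path: str | Path,
                   format: str | None = None) -> None:
    """Write a variant table as TSV or VCF 4.3.

    The VCF carries INFO fields TCN (total depth), ACN (alt depth),
    CTX (trinucleotide channel), EFF (coding effect), TRUEF (simulated
    true frequency) when the corresponding columns are present.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "tsv":
        records.to_csv(path, sep="\t", index=False)
        return
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.3')
    for chrom in pd.unique(records["chrom"]):
        length = int(records.loc[records["chrom"] == chrom, "pos"].max()) + 1000
        header.contigs.add(str(chrom), length=length)
    header.info.add("TCN", 1, "Integer", "Total read depth")
    header.info.add("ACN", 1, "Integer", "Alternate-allele read depth")
    header.info.add("CTX", 1, "String", "Trinucleotide substitution channel")
    header.info.add("EFF", 1, "String", "Coding effect (syn|nonsyn|stopgain|noncoding)")
    header.info.add("TRUEF", 1, "Float", "True (simulated) allele frequency")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in records.iterrows():
            rec = out.new_record(contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                                 alleles=(row["ref"], row["alt"]))
            if "qual" in row and pd.notna(row.get("qual")):
                rec.qual = float(row["qual"])
            if pd.notna(row.get("depth")):
                rec.info["TCN"] = int(row["depth"])
            if pd.notna(row.get("alt_depth")):
                rec.info["ACN"] = int(row["alt_depth"])
            if pd.notna(row.get("context")):
                rec.info["CTX"] = str(row["context"])
            if pd.notna(row.get("effect")):
                rec.info["EFF"] = str(row["effect"])
            if pd.notna(row.get("true_f")):
                rec.info["TRUEF"] = float(row["true_f"])
            out.write(rec)


# ---------------------------------------------------------------------------
# Filtering

@dataclass
class FilterSpec:
    """Quality/depth thresholds applied to a variant table.

    Defaults follow the accumulation-curve filter (QUAL >= 30, depth >= 10,
    alternate depth >= 3); the strict trio-rate filter uses qual >= 35 and
    depth in [50, 200].
    """

    min_qual: float | None = 30.0
    min_depth: int | None = 10
    max_depth: int | None = None
    min_alt_depth: int | None = 3

    def __post_init__(self) -> None:
        if (self.min_depth is not None and self.max_depth is not None
                and self.min_depth > self.max_depth):
            raise ValueError("min_depth exceeds max_depth")


def apply_filters(records: pd.DataFrame, spec: FilterSpec
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep records meeting all thresholds; report drops per criterion.

    The report counts, for each criterion, how many records fail it
    (a record may fail several); "kept" is the number surviving all.
    """
    n = len(records)
    mask = pd.Series(True, index=records.index)
    report: dict[str, int] = {"input": n}
    checks = [
        ("min_qual", spec.min_qual, lambda df, v: df["qual"] >= v),
        ("min_depth", spec.min_depth, lambda df, v: df["depth"] >= v),
        ("max_depth", spec.max_depth, lambda df, v: df["depth"] <= v),
        ("min_alt_depth", spec.min_alt_depth, lambda df, v: df["alt_depth"] >= v),
    ]
    for name, value, fn in checks:
        if value is None:
            continue
        ok = fn(records, value)
        report[f"dropped_{name}"] = int((~ok).sum())
        mask &= ok
    out = records[mask].reset_index(drop=True)
    report["kept"] = len(out)
    logger.info("apply_filters: kept %d of %d records (%s)", len(out), n, report)
    return out, report


# ---------------------------------------------------------------------------
# Coding-effect annotation against a toy coding model

@dataclass
class CodingSequence:
    chrom: str
    start: int          # 1-based position of the first CDS base, forward strand
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) % 3 != 0:
            raise ValueError(f"CDS at {self.chrom}:{self.start} has length "
                             f"{len(self.seq)}, not a multiple of 3")

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1


class CodingModel:
    """A set of forward-strand CDS intervals with known frame."""

    def __init__(self, cds_list: list[CodingSequence]):
        self.cds_list = list(cds_list)

    @classmethod
    def from_fasta(cls, path: str | Path, chrom: str = "sim1",
                   spacing: int = 100) -> "CodingModel":
        """Lay FASTA CDS records head-to-tail on one chromosome."""
        cds, start = [], 1
        for rec in SeqIO.parse(str(path), "fasta"):
            cds.append(CodingSequence(chrom=chrom, start=start, seq=str(rec.seq)))
            start += len(rec.seq) + spacing
        return cls(cds)

    def locate(self, chrom: str, pos: int) -> tuple[CodingSequence, int] | None:
        for cds in self.cds_list:
            if cds.chrom == chrom and cds.start <= pos <= cds.end:
                return cds, pos - cds.start
        return None


def annotate_effect(chrom: str, pos: int, ref: str, alt: str,
                    model: CodingModel) -> str:
    """Classify a substitution as syn | nonsyn | stopgain | noncoding.

    syn if the amino acid is unchanged, stopgain if the new codon is a stop,
    otherwise nonsyn; noncoding if the position is outside every CDS.
    """
    hit = model.locate(chrom, pos)
    if hit is None:
        return "noncoding"
    cds, offset = hit
    if cds.seq[offset] != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos}: CDS has "
                         f"{cds.seq[offset]}, record has {ref}")
    ci, within = divmod(offset, 3)
    codon = cds.seq[3 * ci:3 * ci + 3]
    new = codon[:within] + alt.upper() + codon[within + 1:]
    if new == codon:
        raise ValueError("ref and alt are identical")
    aa_old, aa_new = CODON_TO_AA[codon], CODON_TO_AA[new]
    if aa_new == aa_old:
        return "syn"
    if aa_new == "*":
        return "stopgain"
    return "nonsyn"


def annotate_table(records: pd.DataFrame, model: CodingModel) -> pd.DataFrame:
    """Annotate every record lacking an effect label; a precomputed effect
    column overrides annotation (splice labels etc. pass through)."""
    out = records.copy()
    if "effect" not in out.columns:
        out["effect"] = pd.NA
    needs = out["effect"].isna()
    out.loc[needs, "effect"] = [
        annotate_effect(r.chrom, int(r.pos), r.ref, r.alt, model)
        for r in out.loc[needs].itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# Signature catalogs

def read_signature_catalog(path: str | Path, tol: float = 1e-2) -> pd.DataFrame:
    """Read a COSMIC-style signature TSV into a 96 x S matrix.

    The first column must carry the 96 channel labels (any order; rows are
    reordered to the canonical substitution-major order). Columns are
    validated to be nonnegative and to sum to 1 within ``tol``, then
    renormalised to sum exactly to 1 (within 1e-6).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"{path}: expected 96 channel rows, found {df.shape[0]}")
    if set(df.index) != set(CHANNELS_96):
        missing = sorted(set(CHANNELS_96) - set(df.index))[:3]
        raise ValueError(f"{path}: channel labels invalid (e.g. missing {missing})")
    df = df.loc[list(CHANNELS_96)]
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative catalog entries")
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(f"{path}: columns do not sum to 1 within {tol}: "
                         f"{dict(bad.round(4))}")
    df = df / sums
    df.index.name = "channel"
    return df


def compute_contexts(records: pd.DataFrame, reference: dict[str, str]) -> pd.DataFrame:
    """Fill the 96-channel context column from a reference sequence dict
    (chrom -> sequence, 1-based positions)."""
    out = records.copy()
    ctx = []
    for r in out.itertuples():
        seq = reference[r.chrom]
        tri = seq[int(r.pos) - 2:int(r.pos) + 1].upper()
        ctx.append(channel_of(r.ref, r.alt, tri))
    out["context"] = ctx
    return out
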