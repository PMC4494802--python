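"""Clinical variant filtering/annotation and fusion-candidate ingestion.

Variants (pre-called upstream, supplied as VCF) are filtered by population
evidence — removed when flagged common/no-known-medical-impact or when the
population minor allele frequency strictly exceeds a threshold (default
0.1); absent MAF retains the variant — then joined to clinical annotation
tables (COSMIC-like, ClinVar-like, CADD-like) by exact allele match on
(chrom, pos, ref, alt).  Positional matches with a different allele never
attach.  Fusion candidates arrive as a FusionCatcher-style table and are
ranked by ascending predicted oncogenic p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .errors import FormatError

VariantKey = tuple[str, int, str, str]

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]
RESERVED_BUNDLE_FILES = {"common_variants", "population_maf", "variant_drug_rules"}

__all__ = [
    "VariantRecord",
    "AnnotatedVariant",
    "AnnotationBundle",
    "read_vcf",
    "load_bundle",
    "filter_variants",
    "annotate_variants",
    "ingest_fusions",
    "variants_to_frame",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so all tables share one chromosome convention."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    effect: str | None = None
    qual: float | None = None
    info: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class AnnotatedVariant:
    variant: VariantRecord
    annotations: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def n_annotations(self) -> int:
        return sum(len(v) for v in self.annotations.values())


def read_vcf(path) -> list[VariantRecord]:
    """Read a VCF (v4.x); multi-allelic rows are split one record per alt."""
    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                flags = []
                if alt.startswith("<"):
                    flags.append("symbolic-alt")
                v = VariantRecord(
                    chrom=normalize_chrom(rec.chrom),
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=_info_str(rec, "GENE"),
                    effect=_info_str(rec, "EFFECT"),
                    qual=rec.qual,
                    info={k: _scalar(v) for k, v in rec.info.items()},
                    flags=flags,
                )
                if not v.is_snv and "symbolic-alt" not in flags:
                    # the exact-allele rule is stated for SNVs; indels are
                    # joined by the same key and flagged
                    v.flags.append("indel-beyond-snv-rule")
                records.append(v)
    return records


def _info_str(rec, key):
    try:
        val = rec.info.get(key)
    except ValueError:  # key not declared in the VCF header
        return None
    if val is None:
        return None
    if isinstance(val, tuple):
        val = val[0]
    return str(val)


def _scalar(v):
    if isinstance(v, tuple) and len(v) == 1:
        return v[0]
    return v


def _read_keyed_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    return df


@dataclass
class AnnotationBundle:
    """Local annotation tables keyed by exact variant allele."""

    common_flags: set[VariantKey] = field(default_factory=set)
    maf: dict[VariantKey, float] = field(default_factory=dict)
    clinical_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    variant_drug_rules: pd.DataFrame | None = None


def load_bundle(directory) -> AnnotationBundle:
    """Load an annotation bundle from a directory of TSVs.

    Recognized files: ``common_variants.tsv`` (key columns only),
    ``population_maf.tsv`` (key columns + ``maf``),
    ``variant_drug_rules.tsv`` (key columns + ``drug_id``); every other
    ``*.tsv`` with the key columns becomes a named clinical table.
    """
    directory = Path(directory)
    bundle = AnnotationBundle()
    for path in sorted(directory.glob("*.tsv")):
        stem = path.stem
        df = _read_keyed_tsv(path)
        keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
        if stem == "common_variants":
            bundle.common_flags = set(keys)
        elif stem == "population_maf":
            if "maf" not in df.columns:
                raise FormatError(f"{path}: missing required column 'maf'")
            maf = df["maf"].astype(float)
            if ((maf < 0) | (maf > 1)).any():
                raise FormatError(f"{path}: MAF values outside [0, 1]")
            bundle.maf = dict(zip(keys, maf))
        elif stem == "variant_drug_rules":
            bundle.variant_drug_rules = df
        else:
            bundle.clinical_tables[stem] = df
    return bundle


def filter_variants(
    variants: list[VariantRecord],
    bundle: AnnotationBundle,
    maf_threshold: float = 0.1,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Population filter: drop common-flagged variants and MAF > threshold.

    Returns (retained, removed-with-reason).  A variant whose key cannot be
    formed is retained with a warning flag.  The operation is idempotent.
    """
    retained: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for v in variants:
        if not v.ref or not v.alt or v.ref == v.alt or v.pos < 1:
            warnings.warn(f"malformed variant key {v.label}; retained with flag",
                          stacklevel=2)
            if "malformed-key" not in v.flags:
                v.flags.append("malformed-key")
            retained.append(v)
            continue
        if v.key in bundle.common_flags:
            removed.append((v, "common-flag"))
        elif v.key in bundle.maf and bundle.maf[v.key] > maf_threshold:
            removed.append((v, "maf-above-threshold"))
        else:
            retained.append(v)
    return retained, removed


def annotate_variants(
    variants: list[VariantRecord], bundle: AnnotationBundle
) -> list[AnnotatedVariant]:
    """Attach clinical-table entries whose key exactly equals the variant's.

    The variant set is never changed; annotation only adds evidence.
    """
    indexes = {}
    for name, df in bundle.clinical_tables.items():
        idx: dict[VariantKey, list[dict]] = {}
        payload_cols = [c for c in df.columns if c not in KEY_COLUMNS]
        for _, row in df.iterrows():
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            idx.setdefault(key, []).append({c: row[c] for c in payload_cols})
        indexes[name] = idx
    out = []
    for v in variants:
        ann = {}
        for name, idx in indexes.items():
            hits = idx.get(v.key, [])
            if hits:
                ann[name] = hits
        out.append(AnnotatedVariant(variant=v, annotations=ann))
    return out


FUSION_REQUIRED = ["gene_5p", "gene_3p"]
FUSION_OPTIONAL = ["description", "oncogenic_p", "expression_gain_loss"]


def ingest_fusions(path) -> pd.DataFrame:
    """Read fusion candidates and rank by ascending oncogenic p (absent last).

    The sort is stable so ties preserve input order; exact duplicate rows are
    kept and flagged in a ``duplicate`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_5p": str, "gene_3p": str})
    for col in FUSION_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in FUSION_OPTIONAL:
        if col not in df.columns:
            df[col] = pd.NA
    df["oncogenic_p"] = pd.to_numeric(df["oncogenic_p"], errors="coerce")
    df["duplicate"] = df.duplicated(subset=FUSION_REQUIRED + ["description"], keep=False)
    return df.sort_values(
        "oncogenic_p", kind="mergesort", na_position="last", ignore_index=True
    )


def variants_to_frame(annotated: list[AnnotatedVariant]) -> pd.DataFrame:
    """Flatten annotated variants into a report/CSV-friendly table."""
    rows = []
    for av in annotated:
        v = av.variant
        row = {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.gene, "effect": v.effect, "qual": v.qual,
            "flags": ";".join(v.flags),
            "n_annotations": av.n_annotations,
        }
        for name, hits in av.annotations.items():
            row[name] = "; ".join(
                ",".join(f"{k}={h[k]}" for k in sorted(h)) for h in hits
            )
        rows.append(row)
    return pd.DataFrame(rows)
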