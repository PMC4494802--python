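"""Add-on preprocessing of one new patient sample against a frozen reference.

The patient's raw counts are scaled by a median-of-ratios size factor against
the frozen per-gene geometric means, log2(x+1)-transformed, and screened for
reliable expression: the noise ceiling is a high quantile (default 0.95) of
the patient's expression over the reference's background genes (genes silent
in every cohort sample), and only genes strictly above it are analyzed
further.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CutoffUndefinedError,
    InvalidInputError,
    SizeFactorUndefinedError,
)
from .reference import FrozenReference

__all__ = [
    "PatientProfile",
    "addon_size_factor",
    "log_transform",
    "expression_cutoff",
    "reliability_filter",
    "build_profile",
]


def addon_size_factor(patient_counts: np.ndarray, geo_means: np.ndarray,
                      patient_id: str = "patient") -> float:
    """Median of patient_count / geometric-mean over genes positive in both.

    This is the same eligibility rule the cohort normalization uses, so a
    sample that was part of the cohort recovers its cohort size factor.
    """
    counts = np.asarray(patient_counts, dtype=float)
    geo = np.asarray(geo_means, dtype=float)
    if counts.shape != geo.shape:
        raise InvalidInputError("patient counts not aligned to reference genes")
    if (counts < 0).any():
        raise InvalidInputError("patient counts must be non-negative")
    eligible = (geo > 0) & (counts > 0)
    if not eligible.any():
        raise SizeFactorUndefinedError(patient_id)
    return float(np.median(counts[eligible] / geo[eligible]))


def log_transform(norm_counts) -> np.ndarray:
    """Elementwise log2(x + 1)."""
    arr = np.asarray(norm_counts, dtype=float)
    if (arr < 0).any():
        raise InvalidInputError("normalized counts must be non-negative")
    return np.log2(arr + 1.0)


def expression_cutoff(log_expr: pd.Series, background_genes, quantile: float = 0.95) -> float:
    """Reliability cutoff: a quantile of the patient's background-gene expression.

    Background genes are silent in every reference sample, so their patient
    values estimate the noise floor; the cutoff is their ``quantile``
    (linear-interpolation) value.
    """
    bg = [g for g in background_genes if g in log_expr.index]
    if not bg:
        raise CutoffUndefinedError("no background genes present in patient profile")
    if not 0.0 <= quantile <= 1.0:
        raise InvalidInputError(f"quantile {quantile} outside [0, 1]")
    return float(np.quantile(log_expr.loc[bg].to_numpy(), quantile))


def reliability_filter(log_expr: pd.Series, cutoff: float) -> set[str]:
    """Genes with expression strictly greater than the cutoff."""
    if not np.isfinite(cutoff) and cutoff > 0:
        raise InvalidInputError("cutoff must not be +inf")
    return set(log_expr.index[log_expr.to_numpy() > cutoff])


@dataclass
class PatientProfile:
    """One patient's normalized expression and reliability calls."""

    patient_id: str
    gene_ids: list[str]
    counts: pd.Series
    size_factor: float
    norm_counts: pd.Series
    log_expr: pd.Series
    expression_cutoff: float
    reliable_genes: set[str]
    bg_quantile: float = 0.95
    n_unmatched_dropped: int = 0
    provenance: dict = field(default_factory=dict)


def build_profile(
    patient_counts: pd.Series,
    reference: FrozenReference,
    bg_quantile: float = 0.95,
    patient_id: str | None = None,
) -> PatientProfile:
    """Run the full add-on preprocessing for one sample.

    Patient genes absent from the reference are dropped (warning); reference
    genes absent from the patient are treated as count 0.  The frozen
    reference defines the gene universe.
    """
    patient_id = patient_id or (patient_counts.name or "patient")
    if patient_counts.index.duplicated().any():
        raise InvalidInputError("duplicate gene identifiers in patient counts")
    ref_genes = pd.Index(reference.gene_ids)
    extra = patient_counts.index.difference(ref_genes)
    if len(extra):
        warnings.warn(
            f"{patient_id}: dropped {len(extra)} patient genes absent from the "
            "reference",
            stacklevel=2,
        )
    counts = patient_counts.reindex(ref_genes, fill_value=0).astype(float)
    if (counts < 0).any():
        raise InvalidInputError("patient counts must be non-negative")

    sf = addon_size_factor(counts.to_numpy(), reference.geo_means, patient_id)
    norm = counts / sf
    log_expr = pd.Series(log_transform(norm.to_numpy()), index=ref_genes, name=patient_id)
    cutoff = expression_cutoff(log_expr, reference.background_genes, bg_quantile)
    reliable = reliability_filter(log_expr, cutoff)
    return PatientProfile(
        patient_id=str(patient_id),
        gene_ids=list(ref_genes),
        counts=counts,
        size_factor=sf,
        norm_counts=norm,
        log_expr=log_expr,
        expression_cutoff=cutoff,
        reliable_genes=reliable,
        bg_quantile=bg_quantile,
        n_unmatched_dropped=int(len(extra)),
        provenance={"bg_quantile": bg_quantile, "size_factor": sf,
                    "expression_cutoff": cutoff,
                    "n_reliable_genes": len(reliable)},
    )
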