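"""Frozen reference model: documentation-by-value for n-of-1 processing.

A reference cohort (tumor + normal breast tissue) is summarized once into a
small set of frozen quantities — per-gene geometric means for median-of-ratios
size factors, the background gene set (genes silent in every cohort sample),
and negative-binomial parameters of the normal-tissue samples — so that any
later patient sample can be normalized and tested identically without
reprocessing the cohort.

Size factors follow the median-of-ratios convention: a gene with any zero
count across the cohort receives geometric mean 0 and is excluded from the
ratio medians; ratios additionally require a positive count in the sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientNormalsError,
    InvalidInputError,
    ReferenceFormatError,
    SizeFactorUndefinedError,
)
from .nsc import CentroidModel

FORMAT_VERSION = "nof1seq-reference/1"
DISPERSION_FLOOR = 1e-8

__all__ = [
    "FrozenReference",
    "compute_geometric_means",
    "compute_size_factors",
    "identify_background_genes",
    "fit_normal_params",
    "DISPERSION_FLOOR",
]


def _as_count_matrix(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("counts must be a non-empty genes x samples matrix")
    if (arr < 0).any():
        raise InvalidInputError("counts must be non-negative")
    return arr


def compute_geometric_means(counts) -> np.ndarray:
    """Per-gene geometric mean of counts across samples.

    Genes with any zero count get geometric mean 0, so they are excluded from
    downstream ratio medians (median-of-ratios convention).
    """
    arr = _as_count_matrix(counts)
    all_positive = (arr > 0).all(axis=1)
    geo = np.zeros(arr.shape[0])
    if all_positive.any():
        geo[all_positive] = np.exp(np.log(arr[all_positive]).mean(axis=1))
    return geo


def compute_size_factors(counts, geo_means, sample_ids=None) -> np.ndarray:
    """Median-of-ratios size factor per sample.

    For each sample, the median of count / geometric-mean over genes where
    both are positive.  Raises :class:`SizeFactorUndefinedError` naming the
    first sample with no eligible gene.
    """
    arr = _as_count_matrix(counts)
    geo = np.asarray(geo_means, dtype=float)
    if geo.shape[0] != arr.shape[0]:
        raise InvalidInputError("geo_means not aligned to counts' genes")
    if sample_ids is None:
        sample_ids = [str(j) for j in range(arr.shape[1])]
    factors = np.empty(arr.shape[1])
    ref_pos = geo > 0
    for j in range(arr.shape[1]):
        eligible = ref_pos & (arr[:, j] > 0)
        if not eligible.any():
            raise SizeFactorUndefinedError(str(sample_ids[j]))
        factors[j] = np.median(arr[eligible, j] / geo[eligible])
    return factors


def identify_background_genes(counts_df: pd.DataFrame) -> set[str]:
    """Genes with raw count 0 in every cohort sample (the silent background)."""
    arr = _as_count_matrix(counts_df.to_numpy())
    silent = (arr == 0).all(axis=1)
    return set(counts_df.index[silent])


def fit_normal_params(
    counts,
    geo_means,
    sample_group,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments NB parameters of the normal samples.

    Counts are size-factor normalized jointly over the whole cohort; per
    gene, the mean and (sample, ddof=1) variance over normal samples give
    dispersion = max((var - mean) / mean^2, floor), with (0, floor) for
    silent genes.  Returns (mean, dispersion) arrays.
    """
    arr = _as_count_matrix(counts)
    group = np.asarray(sample_group)
    normal_mask = group == "normal"
    if normal_mask.sum() < 2:
        raise InsufficientNormalsError(
            f"need >= 2 normal samples, found {int(normal_mask.sum())}"
        )
    size_factors = compute_size_factors(arr, geo_means)
    normed = arr / size_factors[None, :]
    normal = normed[:, normal_mask]
    mean = normal.mean(axis=1)
    var = normal.var(axis=1, ddof=1)
    dispersion = np.full(arr.shape[0], dispersion_floor)
    pos = mean > 0
    dispersion[pos] = np.maximum((var[pos] - mean[pos]) / mean[pos] ** 2, dispersion_floor)
    mean = np.where(pos, mean, 0.0)
    return mean, dispersion


@dataclass
class FrozenReference:
    """The serialized reference: everything a new patient sample needs."""

    gene_ids: list[str]
    geo_means: np.ndarray
    background_genes: set[str]
    normal_mean: np.ndarray | None = None
    normal_dispersion: np.ndarray | None = None
    classifiers: dict[str, CentroidModel] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.geo_means = np.asarray(self.geo_means, dtype=float)
        if len(self.gene_ids) != self.geo_means.shape[0]:
            raise InvalidInputError("gene_ids and geo_means lengths differ")
        if not self.background_genes <= set(self.gene_ids):
            raise InvalidInputError("background_genes not a subset of gene_ids")
        bg_idx = [i for i, g in enumerate(self.gene_ids) if g in self.background_genes]
        if bg_idx and (self.geo_means[bg_idx] != 0).any():
            raise InvalidInputError("background genes must have geometric mean 0")
        if self.normal_mean is not None:
            self.normal_mean = np.asarray(self.normal_mean, dtype=float)
            self.normal_dispersion = np.asarray(self.normal_dispersion, dtype=float)
            if (self.normal_mean < 0).any():
                raise InvalidInputError("normal means must be non-negative")

    # -- construction -----------------------------------------------------
    @classmethod
    def build(
        cls,
        counts_df: pd.DataFrame,
        sample_group=None,
        dispersion_floor: float = DISPERSION_FLOOR,
        provenance: dict | None = None,
    ) -> "FrozenReference":
        """Summarize a cohort count matrix into a frozen reference.

        ``sample_group`` (per-sample 'tumor'/'normal') enables NB parameter
        fitting for the single-sample DE test; without it only normalization
        and reliability quantities are frozen.
        """
        arr = counts_df.to_numpy()
        geo = compute_geometric_means(arr)
        background = identify_background_genes(counts_df)
        normal_mean = normal_dispersion = None
        if sample_group is not None:
            normal_mean, normal_dispersion = fit_normal_params(
                arr, geo, sample_group, dispersion_floor=dispersion_floor
            )
        prov = {
            "n_samples": int(counts_df.shape[1]),
            "n_genes": int(counts_df.shape[0]),
            "n_background_genes": len(background),
            "dispersion_floor": dispersion_floor,
        }
        if sample_group is not None:
            group = np.asarray(sample_group)
            prov["n_normal"] = int((group == "normal").sum())
            prov["n_tumor"] = int((group == "tumor").sum())
        if provenance:
            prov.update(provenance)
        return cls(
            gene_ids=list(counts_df.index),
            geo_means=geo,
            background_genes=background,
            normal_mean=normal_mean,
            normal_dispersion=normal_dispersion,
            provenance=prov,
        )

    # -- serialization ----------------------------------------------------
    def freeze(self, path) -> None:
        """Write the reference as a versioned, self-describing JSON archive."""
        doc = {
            "format_version": FORMAT_VERSION,
            "gene_ids": list(self.gene_ids),
            "geo_means": self.geo_means.tolist(),
            "background_genes": sorted(self.background_genes),
            "normal_mean": None if self.normal_mean is None else self.normal_mean.tolist(),
            "normal_dispersion": (
                None if self.normal_dispersion is None else self.normal_dispersion.tolist()
            ),
            "classifiers": {name: m.to_dict() for name, m in self.classifiers.items()},
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def thaw(cls, path) -> "FrozenReference":
        """Load a frozen reference; version mismatch or truncation errors out."""
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise ReferenceFormatError(f"{path}: unreadable or truncated archive") from exc
        if not isinstance(doc, dict) or doc.get("format_version") != FORMAT_VERSION:
            raise ReferenceFormatError(
                f"{path}: format version {doc.get('format_version') if isinstance(doc, dict) else None!r}"
                f" does not match {FORMAT_VERSION!r}"
            )
        required = {"gene_ids", "geo_means", "background_genes", "provenance"}
        missing = required - doc.keys()
        if missing:
            raise ReferenceFormatError(f"{path}: missing fields {sorted(missing)}")
        return cls(
            gene_ids=list(doc["gene_ids"]),
            geo_means=np.asarray(doc["geo_means"], dtype=float),
            background_genes=set(doc["background_genes"]),
            normal_mean=(
                None if doc.get("normal_mean") is None
                else np.asarray(doc["normal_mean"], dtype=float)
            ),
            normal_dispersion=(
                None if doc.get("normal_dispersion") is None
                else np.asarray(doc["normal_dispersion"], dtype=float)
            ),
            classifiers={
                name: CentroidModel.from_dict(d)
                for name, d in doc.get("classifiers", {}).items()
            },
            provenance=dict(doc["provenance"]),
        )

    def equals(self, other: "FrozenReference") -> bool:
        """Exact field-for-field equality (used by round-trip checks)."""
        if self.gene_ids != other.gene_ids:
            return False
        if not np.array_equal(self.geo_means, other.geo_means):
            return False
        if self.background_genes != other.background_genes:
            return False
        for a, b in ((self.normal_mean, other.normal_mean),
                     (self.normal_dispersion, other.normal_dispersion)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        if set(self.classifiers) != set(other.classifiers):
            return False
        for name in self.classifiers:
            if self.classifiers[name].to_dict() != other.classifiers[name].to_dict():
                return False
        return self.provenance == other.provenance
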