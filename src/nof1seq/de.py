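"""Single-sample differential expression against frozen normal parameters.

Each reliably expressed gene is tested with a two-sided negative-binomial
tail test: under the null the patient's raw count is NB-distributed with
mean = (frozen normal mean) x (patient size factor) and the frozen per-gene
dispersion (variance mu + alpha mu^2); the two-sided p-value doubles the
smaller tail, capped at 1.  Dispersion 0 is the Poisson limit.  P-values are
Benjamini-Hochberg adjusted over the tested genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError
from .preprocess import PatientProfile
from .reference import FrozenReference

__all__ = ["nb_two_sided_p", "log2_fc", "call_de"]


def nb_two_sided_p(observed, expected, dispersion) -> np.ndarray:
    """Two-sided NB tail p-value, vectorized.

    p = min(1, 2 * min(P[X <= obs], P[X >= obs])) with X ~ NB(mean=expected,
    dispersion).  ``dispersion`` 0 uses the exact Poisson tails.
    """
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    mu = np.atleast_1d(np.asarray(expected, dtype=float))
    alpha = np.atleast_1d(np.asarray(dispersion, dtype=float))
    obs, mu, alpha = np.broadcast_arrays(obs, mu, alpha)
    if (mu <= 0).any():
        raise InvalidInputError("expected counts must be positive")
    if (alpha < 0).any():
        raise InvalidInputError("dispersion must be >= 0")

    lower = np.empty(obs.shape)
    upper = np.empty(obs.shape)
    pois = alpha == 0
    if pois.any():
        lower[pois] = stats.poisson.cdf(obs[pois], mu[pois])
        upper[pois] = stats.poisson.sf(obs[pois] - 1, mu[pois])
    nb = ~pois
    if nb.any():
        n = 1.0 / alpha[nb]
        p_param = n / (n + mu[nb])
        lower[nb] = stats.nbinom.cdf(obs[nb], n, p_param)
        upper[nb] = stats.nbinom.sf(obs[nb] - 1, n, p_param)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p if np.ndim(observed) else float(p[0])


def log2_fc(patient_norm, normal_mean, pseudocount: float = 1.0):
    """Pseudocounted log2 fold change patient vs. frozen normal mean."""
    p = np.asarray(patient_norm, dtype=float)
    m = np.asarray(normal_mean, dtype=float)
    if (p < 0).any() or (m < 0).any():
        raise InvalidInputError("expression values must be non-negative")
    out = np.log2((p + pseudocount) / (m + pseudocount))
    return out if out.ndim else float(out)


def call_de(
    profile: PatientProfile,
    reference: FrozenReference,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DE table over the patient's reliable genes.

    Columns: gene, normal_mean, patient_norm, log2_fold_change, p_value,
    adj_p, significant, direction ('up'/'down'/'none'), degenerate.  Genes
    with non-positive frozen normal mean are recorded with p = 1 and flagged
    degenerate.  Rows are sorted by raw p-value (stable on gene order).
    """
    if reference.normal_mean is None:
        raise InvalidInputError("frozen reference carries no normal-tissue parameters")
    gene_index = pd.Index(reference.gene_ids)
    reliable = [g for g in reference.gene_ids if g in profile.reliable_genes]
    if not reliable:
        warnings.warn("no reliably expressed genes: DE table is empty", stacklevel=2)
        return pd.DataFrame(
            columns=["gene", "normal_mean", "patient_norm", "log2_fold_change",
                     "p_value", "adj_p", "significant", "direction", "degenerate"]
        )
    idx = gene_index.get_indexer(reliable)
    normal_mean = reference.normal_mean[idx]
    dispersion = reference.normal_dispersion[idx]
    observed = profile.counts.loc[reliable].to_numpy(dtype=float)
    patient_norm = profile.norm_counts.loc[reliable].to_numpy(dtype=float)

    expected = normal_mean * profile.size_factor
    degenerate = expected <= 0
    p = np.ones(len(reliable))
    ok = ~degenerate
    if ok.any():
        p[ok] = nb_two_sided_p(observed[ok], expected[ok], dispersion[ok])
    lfc = log2_fc(patient_norm, normal_mean, pseudocount)

    adj_p = multipletests(p, method="fdr_bh")[1]
    significant = (adj_p < alpha) & (np.abs(lfc) >= lfc_min) & ~degenerate
    direction = np.where(significant, np.where(lfc > 0, "up", "down"), "none")

    table = pd.DataFrame(
        {
            "gene": reliable,
            "normal_mean": normal_mean,
            "patient_norm": patient_norm,
            "log2_fold_change": lfc,
            "p_value": p,
            "adj_p": adj_p,
            "significant": significant,
            "direction": direction,
            "degenerate": degenerate,
        }
    )
    return table.sort_values("p_value", kind="mergesort", ignore_index=True)
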