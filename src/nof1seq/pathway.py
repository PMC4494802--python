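"""Topological pathway impact analysis over single-sample DE results.

For each pathway with a signed, weighted gene-gene topology, the observed
log2 fold changes of differentially expressed genes are propagated through
the network: the perturbation factor vector PF solves

    PF = dE + B PF,        B_ij = beta_ij / n_downstream(j)

(dE holds the fold changes, beta_ij the signed effect of gene j on gene i,
and n_downstream(j) the number of targets of j, floored at 1).  The net
accumulated perturbation is Acc = PF - dE with total tA = sum(Acc).  Two
independent p-values are combined per pathway: pNDE, the hypergeometric
over-representation of DE genes in the pathway, and pPERT, a bootstrap
probability of observing a total perturbation at least as extreme as tA
when the observed fold changes are placed on random genes of the pathway.
The combination is pG = c - c ln c with c = pNDE * pPERT, BH-adjusted over
pathways.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, InvalidInputError, UnsolvablePathwayError

DEFAULT_EDGE_WEIGHTS = {"activation": 1.0, "inhibition": -1.0, "other": 0.0}
SINGULARITY_TOL = 1e-10

__all__ = [
    "PathwayTopology",
    "load_pathways",
    "net_perturbation",
    "accumulation",
    "p_pert",
    "p_nde",
    "combine",
    "analyze_pathways",
]


@dataclass
class PathwayTopology:
    """Signed weighted topology of one pathway."""

    pathway_id: str
    genes: list[str]
    beta: np.ndarray  # (G, G); beta[i, j] = effect of gene j on gene i

    @property
    def n_downstream(self) -> np.ndarray:
        """Number of targets per gene, floored at 1 for propagation."""
        return np.maximum((self.beta != 0).sum(axis=0), 1)

    @property
    def propagation_matrix(self) -> np.ndarray:
        return self.beta / self.n_downstream[None, :]


def load_pathways(path, edge_weights: dict | None = None) -> list[PathwayTopology]:
    """Read an edge-list TSV (pathway_id, source_gene, target_gene, interaction).

    Interaction types map to signed weights (activation +1, inhibition -1,
    anything else 0 = ignored by default, configurable via ``edge_weights``).
    Pathways are returned sorted by identifier; genes are ordered by first
    appearance within each pathway's edge list.
    """
    weights = dict(DEFAULT_EDGE_WEIGHTS)
    if edge_weights:
        weights.update(edge_weights)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["pathway_id", "source_gene", "target_gene", "interaction"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    topologies = []
    for pid in sorted(df["pathway_id"].unique()):
        sub = df[df["pathway_id"] == pid]
        genes: list[str] = []
        seen = set()
        for _, row in sub.iterrows():
            for g in (row["source_gene"], row["target_gene"]):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        index = {g: i for i, g in enumerate(genes)}
        beta = np.zeros((len(genes), len(genes)))
        for _, row in sub.iterrows():
            w = weights.get(row["interaction"], 0.0)
            beta[index[row["target_gene"]], index[row["source_gene"]]] = w
        topologies.append(PathwayTopology(pathway_id=pid, genes=genes, beta=beta))
    return topologies


def net_perturbation(delta_e, topology: PathwayTopology) -> np.ndarray:
    """Solve PF = (I - B)^-1 dE; raises if (I - B) is numerically singular."""
    de = np.asarray(delta_e, dtype=float)
    if de.shape[0] != len(topology.genes):
        raise InvalidInputError("delta_e not aligned to pathway genes")
    A = np.eye(len(topology.genes)) - topology.propagation_matrix
    if np.linalg.svd(A, compute_uv=False)[-1] < SINGULARITY_TOL:
        raise UnsolvablePathwayError(topology.pathway_id)
    return np.linalg.solve(A, de)


def accumulation(pf, delta_e) -> tuple[np.ndarray, float]:
    """Per-gene net accumulation Acc = PF - dE and its total tA."""
    pf = np.asarray(pf, dtype=float)
    de = np.asarray(delta_e, dtype=float)
    if pf.shape != de.shape:
        raise InvalidInputError("PF and delta_e not aligned")
    acc = pf - de
    return acc, float(acc.sum())


def _null_ta(topology: PathwayTopology, values: np.ndarray, placements) -> np.ndarray:
    """Total perturbation for each placement of ``values`` on gene positions."""
    G = len(topology.genes)
    A = np.eye(G) - topology.propagation_matrix
    de_mat = np.zeros((G, len(placements)))
    for col, pos in enumerate(placements):
        de_mat[list(pos), col] = values
    pf = np.linalg.solve(A, de_mat)
    return (pf - de_mat).sum(axis=0)


def p_pert(
    topology: PathwayTopology,
    delta_e,
    n_boot: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> float:
    """Bootstrap p-value of the total net perturbation tA.

    The null places the observed nonzero fold changes on uniformly random
    distinct gene positions of the pathway; pPERT is the fraction of null
    draws at least as far from the null median as the observed tA, floored
    at 1/n_boot.  ``exhaustive=True`` enumerates every ordered placement
    instead of sampling (small pathways only).
    """
    de = np.asarray(delta_e, dtype=float)
    values = de[de != 0]
    if values.size == 0:
        return 1.0
    G = len(topology.genes)
    A = np.eye(G) - topology.propagation_matrix
    if np.linalg.svd(A, compute_uv=False)[-1] < SINGULARITY_TOL:
        raise UnsolvablePathwayError(topology.pathway_id)
    _, ta_obs = accumulation(net_perturbation(de, topology), de)

    if exhaustive:
        placements = list(itertools.permutations(range(G), values.size))
    else:
        if n_boot < 100:
            raise InvalidInputError("n_boot must be >= 100")
        if rng is None:
            rng = np.random.default_rng(seed)
        placements = [rng.choice(G, size=values.size, replace=False)
                      for _ in range(n_boot)]
    ta_null = _null_ta(topology, values, placements)
    med = float(np.median(ta_null))
    frac = float(np.mean(np.abs(ta_null - med) >= abs(ta_obs - med)))
    return max(frac, 1.0 / len(placements))


def p_nde(n_de_in_path: int, path_size: int, n_de_total: int, universe_size: int) -> float:
    """Hypergeometric upper tail P[X >= n_de_in_path] of DE over-representation."""
    if not (0 <= n_de_in_path <= min(path_size, n_de_total) <= universe_size):
        raise InvalidInputError(
            f"inconsistent counts: {n_de_in_path} DE in path of {path_size}, "
            f"{n_de_total} DE of {universe_size}"
        )
    if n_de_in_path == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_de_in_path - 1, universe_size, n_de_total, path_size))


def combine(pnde: float, ppert: float) -> float:
    """Fisher-product combination pG = c - c ln c with c = pNDE * pPERT."""
    if not (0 < pnde <= 1 and 0 < ppert <= 1):
        raise InvalidInputError("p-values must lie in (0, 1]")
    c = pnde * ppert
    if c >= 1.0:
        return 1.0
    return c - c * math.log(c)


def analyze_pathways(
    topologies: list[PathwayTopology],
    de_table: pd.DataFrame,
    universe,
    fdr_alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full pathway analysis over a DE table.

    ``universe`` is the set of reliably expressed genes.  Pathways with no
    gene in the universe, or with a singular topology, are skipped with a
    warning.  Returns a DataFrame sorted ascending by pG with columns
    pathway_id, n_genes, n_in_universe, n_de, tA, pNDE, pPERT, pG, pG_fdr,
    status.
    """
    universe = set(universe)
    if len(de_table):
        sig = de_table[de_table["significant"]]
        lfc_map = dict(zip(sig["gene"], sig["log2_fold_change"]))
    else:
        lfc_map = {}
    de_genes = {g for g in lfc_map if g in universe}
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(len(topologies))
    for topo, ss in zip(topologies, seeds):
        in_universe = [g for g in topo.genes if g in universe]
        if not in_universe:
            warnings.warn(
                f"pathway {topo.pathway_id}: no genes in the reliable universe; skipped",
                stacklevel=2,
            )
            continue
        de = np.array([lfc_map.get(g, 0.0) for g in topo.genes])
        n_de_in_path = sum(1 for g in in_universe if g in de_genes)
        pnde = p_nde(n_de_in_path, len(in_universe), len(de_genes), len(universe))
        try:
            pf = net_perturbation(de, topo)
            acc, ta = accumulation(pf, de)
            ppert = p_pert(topo, de, n_boot=n_boot,
                           rng=np.random.default_rng(ss))
        except UnsolvablePathwayError:
            warnings.warn(
                f"pathway {topo.pathway_id}: singular topology; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "pathway_id": topo.pathway_id,
                "n_genes": len(topo.genes),
                "n_in_universe": len(in_universe),
                "n_de": n_de_in_path,
                "tA": ta,
                "pNDE": pnde,
                "pPERT": ppert,
                "pG": combine(pnde, ppert),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway_id", "n_genes", "n_in_universe", "n_de", "tA",
                     "pNDE", "pPERT", "pG", "pG_fdr", "status"]
        )
    out = pd.DataFrame(rows)
    out["pG_fdr"] = multipletests(out["pG"].to_numpy(), method="fdr_bh")[1]
    sig_mask = out["pG_fdr"] < fdr_alpha
    out["status"] = np.where(
        sig_mask & (out["tA"] > 0), "activated",
        np.where(sig_mask & (out["tA"] < 0), "inhibited", "none"),
    )
    return out.sort_values("pG", kind="mergesort", ignore_index=True)
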