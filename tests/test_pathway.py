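"""Pathway impact engine: propagation, accumulation, bootstrap and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nof1seq.errors import InvalidInputError, UnsolvablePathwayError
from nof1seq.pathway import (
    PathwayTopology,
    accumulation,
    analyze_pathways,
    combine,
    load_pathways,
    net_perturbation,
    p_nde,
    p_pert,
)


def chain_topology(sign=1.0, n=2, pid="chain"):
    beta = np.zeros((n, n))
    for i in range(n - 1):
        beta[i + 1, i] = sign
    return PathwayTopology(pid, [f"g{i}" for i in range(n)], beta)


def fixed_point_pf(topology, delta_e, n_iter=300):
    """Iterative oracle: PF <- dE + B PF."""
    B = topology.propagation_matrix
    pf = np.zeros(len(delta_e), dtype=float)
    for _ in range(n_iter):
        pf = np.asarray(delta_e) + B @ pf
    return pf


def random_dag_topology(rng, max_genes=10):
    n = int(rng.integers(3, max_genes))
    beta = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                beta[j, i] = rng.choice([-1.0, 1.0])
    return PathwayTopology("dag", [f"g{i}" for i in range(n)], beta)


class TestNetPerturbation:
    def test_zero_de_gives_zero_pf(self):
        topo = chain_topology()
        np.testing.assert_allclose(net_perturbation([0, 0], topo), [0, 0])

    def test_activation_chain(self):
        topo = chain_topology(+1.0)
        pf = net_perturbation([1.0, 0.0], topo)
        np.testing.assert_allclose(pf, [1.0, 1.0])
        acc, ta = accumulation(pf, [1.0, 0.0])
        np.testing.assert_allclose(acc, [0.0, 1.0])
        assert ta == 1.0

    def test_inhibition_chain(self):
        topo = chain_topology(-1.0)
        pf = net_perturbation([1.0, 0.0], topo)
        np.testing.assert_allclose(pf, [1.0, -1.0])
        assert accumulation(pf, [1.0, 0.0])[1] == -1.0

    def test_singular_topology_flagged(self):
        # A <-> B with both edges +1 and single targets: B = [[0,1],[1,0]],
        # I - B is singular
        beta = np.array([[0.0, 1.0], [1.0, 0.0]])
        topo = PathwayTopology("loop", ["a", "b"], beta)
        with pytest.raises(UnsolvablePathwayError):
            net_perturbation([1.0, 0.0], topo)

    def test_matrix_solve_equals_fixed_point_on_random_dags(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            topo = random_dag_topology(rng)
            de = np.where(rng.random(len(topo.genes)) < 0.3,
                          rng.normal(0, 2, len(topo.genes)), 0.0)
            np.testing.assert_allclose(
                net_perturbation(de, topo), fixed_point_pf(topo, de), atol=1e-9
            )

    def test_ta_invariant_under_gene_relabeling(self):
        rng = np.random.default_rng(22)
        topo = random_dag_topology(rng)
        n = len(topo.genes)
        de = rng.normal(0, 1, n)
        perm = rng.permutation(n)
        topo_p = PathwayTopology("perm", [topo.genes[i] for i in perm],
                                 topo.beta[np.ix_(perm, perm)])
        _, ta = accumulation(net_perturbation(de, topo), de)
        _, ta_p = accumulation(net_perturbation(de[perm], topo_p), de[perm])
        assert ta == pytest.approx(ta_p, abs=1e-9)

    def test_leaf_floor_prevents_division_by_zero(self):
        topo = chain_topology()
        assert topo.n_downstream.tolist() == [1, 1]  # leaf g1 floored at 1


class TestPPert:
    def test_no_de_genes(self):
        topo = chain_topology()
        assert p_pert(topo, [0.0, 0.0], seed=0) == 1.0

    def test_isolated_node_degenerate(self):
        topo = PathwayTopology("iso", ["a"], np.zeros((1, 1)))
        assert p_pert(topo, [2.0], seed=0) == 1.0

    def test_exhaustive_matches_enumeration_oracle(self):
        """Five-gene line, one DE gene: exhaustive pPERT equals the direct
        enumeration over the 5 placements."""
        topo = chain_topology(n=5, pid="line")
        de = np.array([0.0, 0.0, 2.0, 0.0, 0.0])
        # oracle: place the value on each position, recompute tA
        tas = []
        for pos in range(5):
            v = np.zeros(5)
            v[pos] = 2.0
            _, ta = accumulation(net_perturbation(v, topo), v)
            tas.append(ta)
        tas = np.array(tas)
        _, ta_obs = accumulation(net_perturbation(de, topo), de)
        med = np.median(tas)
        expected = max(np.mean(np.abs(tas - med) >= abs(ta_obs - med)), 1 / 5)
        assert p_pert(topo, de, exhaustive=True) == pytest.approx(expected)

    def test_exhaustive_two_values(self):
        topo = chain_topology(n=4, pid="line4")
        de = np.array([1.0, 0.0, -2.0, 0.0])
        values = de[de != 0]
        tas = []
        for pos in itertools.permutations(range(4), 2):
            v = np.zeros(4)
            v[list(pos)] = values
            _, ta = accumulation(net_perturbation(v, topo), v)
            tas.append(ta)
        tas = np.array(tas)
        _, ta_obs = accumulation(net_perturbation(de, topo), de)
        med = np.median(tas)
        expected = max(np.mean(np.abs(tas - med) >= abs(ta_obs - med)), 1 / len(tas))
        assert p_pert(topo, de, exhaustive=True) == pytest.approx(expected)

    def test_seeded_bootstrap_is_deterministic(self):
        topo = chain_topology(n=6, pid="c6")
        de = np.array([3.0, 0, 0, -1.0, 0, 0])
        assert p_pert(topo, de, n_boot=500, seed=9) == p_pert(topo, de, n_boot=500, seed=9)


class TestPNde:
    def test_zero_observed(self):
        assert p_nde(0, 5, 5, 10) == 1.0

    def test_single_term(self):
        assert p_nde(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-9)

    def test_at_expectation_band(self):
        # observed equals expectation under independence -> mid-range p
        p = p_nde(5, 10, 50, 100)
        assert 0.5 <= p <= 1.0

    def test_inconsistent_counts(self):
        with pytest.raises(InvalidInputError):
            p_nde(6, 5, 5, 10)


class TestCombine:
    def test_unit_case(self):
        assert combine(1.0, 1.0) == 1.0

    def test_fisher_product_value(self):
        assert combine(0.1, 0.1) == pytest.approx(0.01 - 0.01 * np.log(0.01), abs=1e-10)

    def test_dominates_single_p(self):
        for p in (1e-6, 0.01, 0.3, 0.9):
            assert combine(p, 1.0) >= p

    def test_rejects_zero(self):
        with pytest.raises(InvalidInputError):
            combine(0.0, 0.5)


class TestAnalyzePathways:
    def _null_setup(self, seed=31, n_pathways=50):
        from nof1seq.simulate import simulate_pathways

        rng = np.random.default_rng(seed)
        genes = [f"G{i:04d}" for i in range(800)]
        edges, _ = simulate_pathways(genes, n_pathways=n_pathways, seed=seed)
        topologies = load_pathways_from_frame(edges)
        # random DE assignment: 40 random genes, random signs
        de_genes = rng.choice(genes, size=40, replace=False)
        de_table = pd.DataFrame(
            {
                "gene": de_genes,
                "log2_fold_change": rng.normal(0, 2, 40),
                "significant": True,
                "direction": "up",
            }
        )
        return topologies, de_table, genes

    def test_null_pg_roughly_uniform(self):
        """With random DE placement the pG < 0.05 fraction stays near 5%."""
        topologies, de_table, genes = self._null_setup()
        res = analyze_pathways(topologies, de_table, genes, n_boot=500, seed=77)
        frac = (res["pG"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_planted_pathway_ranks_first(self, ):
        from nof1seq.simulate import simulate_pathways

        genes = [f"G{i:04d}" for i in range(300)]
        planted = genes[:5]
        edges, planted_id = simulate_pathways(genes[10:], planted_genes=planted,
                                              n_pathways=10, seed=3)
        topologies = load_pathways_from_frame(edges)
        de_table = pd.DataFrame(
            {
                "gene": planted,
                "log2_fold_change": [3.0, 2.5, 3.5, 2.8, 3.2],
                "significant": True,
                "direction": "up",
            }
        )
        res = analyze_pathways(topologies, de_table, genes, n_boot=500, seed=5)
        assert res.iloc[0]["pathway_id"] == planted_id
        assert res.iloc[0]["tA"] > 0

    def test_empty_de_table_all_ones(self):
        topologies = [chain_topology(pid="c")]
        de_table = pd.DataFrame(
            columns=["gene", "log2_fold_change", "significant", "direction"]
        )
        res = analyze_pathways(topologies, de_table, ["g0", "g1"], n_boot=500, seed=0)
        assert (res["pNDE"] == 1.0).all() and (res["pPERT"] == 1.0).all()

    def test_pathway_outside_universe_skipped(self):
        topologies = [chain_topology(pid="c")]
        de_table = pd.DataFrame(
            columns=["gene", "log2_fold_change", "significant", "direction"]
        )
        with pytest.warns(UserWarning, match="no genes in the reliable universe"):
            res = analyze_pathways(topologies, de_table, ["other"], n_boot=500, seed=0)
        assert len(res) == 0

    def test_status_sign_agrees_with_ta(self):
        topologies, de_table, genes = self._null_setup(seed=55, n_pathways=20)
        res = analyze_pathways(topologies, de_table, genes, fdr_alpha=0.9,
                               n_boot=500, seed=1)
        sig = res[res["status"] != "none"]
        assert ((sig["status"] == "activated") == (sig["tA"] > 0)).all()


def load_pathways_from_frame(edges: pd.DataFrame):
    """Round edges through the TSV reader so tests exercise the real parser."""
    import io as _io

    buf = _io.StringIO()
    edges.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return load_pathways(buf)


class TestLoadPathways:
    def test_edge_weights_and_ordering(self, tmp_path):
        path = tmp_path / "edges.tsv"
        pd.DataFrame(
            [
                {"pathway_id": "P1", "source_gene": "A", "target_gene": "B",
                 "interaction": "activation"},
                {"pathway_id": "P1", "source_gene": "B", "target_gene": "C",
                 "interaction": "inhibition"},
                {"pathway_id": "P1", "source_gene": "A", "target_gene": "C",
                 "interaction": "binding"},  # unknown type -> weight 0
            ]
        ).to_csv(path, sep="\t", index=False)
        topo = load_pathways(path)[0]
        assert topo.genes == ["A", "B", "C"]
        assert topo.beta[1, 0] == 1.0
        assert topo.beta[2, 1] == -1.0
        assert topo.beta[2, 0] == 0.0

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "edges.tsv"
        pd.DataFrame([{"pathway_id": "P", "source_gene": "A"}]).to_csv(
            path, sep="\t", index=False
        )
        from nof1seq.errors import FormatError

        with pytest.raises(FormatError, match="target_gene"):
            load_pathways(path)
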