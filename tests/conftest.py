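import numpy as np
import pandas as pd
import pytest

from nof1seq.reference import FrozenReference
from nof1seq.simulate import SimulationConfig, make_fixture_dir, simulate_reference


@pytest.fixture(scope="session")
def sim_cohort():
    """Default-condition 50-sample synthetic reference cohort."""
    cfg = SimulationConfig(seed=11)
    counts_df, metadata, truth = simulate_reference(cfg)
    return counts_df, metadata, truth


@pytest.fixture(scope="session")
def frozen_sim_ref(sim_cohort):
    counts_df, metadata, _ = sim_cohort
    group = metadata.loc[counts_df.columns, "group"].to_numpy()
    return FrozenReference.build(counts_df, sample_group=group)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Complete demo input directory written by the fixture generator."""
    out = tmp_path_factory.mktemp("fixtures")
    truth = make_fixture_dir(out, seed=7)
    return out, truth


@pytest.fixture()
def tiny_ref():
    """Hand-checkable 6-gene reference with 2 background genes."""
    counts = pd.DataFrame(
        {
            "s1": [10, 20, 5, 0, 8, 0],
            "s2": [10, 20, 5, 0, 8, 0],
            "s3": [10, 20, 5, 1, 8, 0],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
    counts.index.name = "gene_id"
    return counts


# ---------------------------------------------------------------- oracles


def brute_force_size_factor(counts_col, geo_means):
    """Explicit-loop median-of-ratios oracle."""
    ratios = []
    for c, g in zip(counts_col, geo_means):
        if g > 0 and c > 0:
            ratios.append(c / g)
    return float(np.median(ratios))


def brute_force_bh(pvals):
    """Step-up Benjamini-Hochberg oracle."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def brute_force_nb_p(observed, expected, dispersion, tail_tol=1e-12):
    """Two-sided NB p by direct pmf summation (truncated at mass 1-tail_tol)."""
    from scipy import stats

    if dispersion == 0:
        dist = stats.poisson(expected)
    else:
        n = 1.0 / dispersion
        dist = stats.nbinom(n, n / (n + expected))
    k = 0
    lower = 0.0
    observed = int(observed)
    while True:
        mass = dist.pmf(k)
        if k <= observed:
            lower += mass
        if dist.cdf(k) >= 1 - tail_tol and k > observed:
            break
        k += 1
    upper = 1.0 - lower + dist.pmf(observed)
    return min(1.0, 2 * min(lower, upper))
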