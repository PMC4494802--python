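"""Synthetic data generation for every pipeline stage.

The generator emulates the statistical structure the pipeline assumes: a
reference cohort of negative-binomial gene counts (variance mu + alpha mu^2)
with per-sample sequencing-depth multipliers, a fixed fraction of genes
silent in every sample (the background set), tumor-only class structure for
classifier training, a patient sample drawn from the normal-tissue model
with spiked fold changes, signed pathway topologies with one planted
activated pathway, and hand-enumerable clinical fixtures (toy VCF,
annotation bundle, fusion and drug tables) whose filter/join/match outcomes
are known by construction.

Every function is fully determined by its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from . import io as nio

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "simulate_patient",
    "pick_spike_genes",
    "simulate_class_data",
    "simulate_pathways",
    "make_annotation_tables",
    "toy_drug_inputs",
    "make_fixture_dir",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic reference cohort.

    Defaults: a 50-sample cohort (40 tumor / 10 normal), 5000 genes of which
    a fraction 0.0312 (156 genes) form the silent background, expressed-gene
    means LogNormal(ln 100, 1), NB dispersion Uniform(0.05, 0.2), and
    lognormal depth multipliers with log-sd 0.3.
    """

    n_genes: int = 5000
    n_tumor: int = 40
    n_normal: int = 10
    background_fraction: float = 0.0312
    depth_log_sd: float = 0.3
    depth_multipliers: np.ndarray | None = None
    mean_log_mu: float = math.log(100.0)
    sd_log_mu: float = 1.0
    dispersion_range: tuple[float, float] = (0.05, 0.2)
    subtype_classes: tuple[str, ...] = ("Basal", "HER2", "LumA", "LumB")
    genes_per_subtype: int = 10
    subtype_lfc: float = 2.0
    n_er_genes: int = 10
    er_lfc: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_tumor < 0 or self.n_normal < 0:
            raise InvalidInputError("cohort dimensions must be positive")
        if not 0.0 <= self.background_fraction < 1.0:
            raise InvalidInputError("background_fraction must be in [0, 1)")
        n = self.n_tumor + self.n_normal
        if self.depth_multipliers is not None and len(self.depth_multipliers) != n:
            raise InvalidInputError("depth_multipliers length must equal n_samples")
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise InvalidInputError("dispersion_range must be positive and ordered")
        n_marker = len(self.subtype_classes) * self.genes_per_subtype + self.n_er_genes
        if n_marker >= self.n_genes * (1 - self.background_fraction):
            raise InvalidInputError("too many marker genes for n_genes")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) samples; dispersion ~ 0 falls back to Poisson."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    a = np.broadcast_to(alpha, mean.shape)[pos]
    m = mean[pos]
    tiny = a < 1e-12
    draws = np.empty(m.shape, dtype=np.int64)
    if tiny.any():
        draws[tiny] = rng.poisson(m[tiny])
    if (~tiny).any():
        n = 1.0 / a[~tiny]
        p = n / (n + m[~tiny])
        draws[~tiny] = rng.negative_binomial(n, p)
    out[pos] = draws
    return out


def simulate_reference(config: SimulationConfig):
    """Simulate a reference cohort; returns (counts_df, metadata_df, truth).

    ``truth`` carries the generating parameters needed by recovery tests:
    per-gene mean (``mu``) and dispersion (``alpha``), the background gene
    set, true depth multipliers, and the marker-gene blocks used for the
    subtype and ER class structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_tumor + config.n_normal
    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]

    mu = rng.lognormal(config.mean_log_mu, config.sd_log_mu, config.n_genes)
    lo, hi = config.dispersion_range
    alpha = rng.uniform(lo, hi, config.n_genes)
    n_bg = int(round(config.n_genes * config.background_fraction))
    bg_idx = rng.choice(config.n_genes, size=n_bg, replace=False)
    mu[bg_idx] = 0.0

    if config.depth_multipliers is not None:
        depths = np.asarray(config.depth_multipliers, dtype=float)
    else:
        depths = rng.lognormal(0.0, config.depth_log_sd, n_samples)

    sample_ids = [f"TUMOR{i:03d}" for i in range(config.n_tumor)] + [
        f"NORMAL{i:03d}" for i in range(config.n_normal)
    ]
    group = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal

    # marker blocks: disjoint, drawn from expressed genes
    expressed = np.setdiff1d(np.arange(config.n_genes), bg_idx)
    n_marker = len(config.subtype_classes) * config.genes_per_subtype + config.n_er_genes
    marker = rng.choice(expressed, size=n_marker, replace=False)
    subtype_blocks = {}
    pos = 0
    for cls in config.subtype_classes:
        subtype_blocks[cls] = marker[pos:pos + config.genes_per_subtype]
        pos += config.genes_per_subtype
    er_block = marker[pos:pos + config.n_er_genes]

    subtype = [config.subtype_classes[i % len(config.subtype_classes)]
               for i in range(config.n_tumor)]
    er_status = ["positive" if rng.random() < 0.6 else "negative"
                 for _ in range(config.n_tumor)]

    counts = np.zeros((config.n_genes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        mean_j = mu * depths[j]
        if group[j] == "tumor":
            mean_j = mean_j.copy()
            mean_j[subtype_blocks[subtype[j]]] *= 2.0 ** config.subtype_lfc
            if er_status[j] == "positive":
                mean_j[er_block] *= 2.0 ** config.er_lfc
        counts[:, j] = _nb_draw(rng, mean_j, alpha)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "subtype": subtype + [""] * config.n_normal,
            "er_status": er_status + [""] * config.n_normal,
        }
    ).set_index("sample_id")
    truth = {
        "gene_ids": gene_ids,
        "mu": mu,
        "alpha": alpha,
        "background_genes": {gene_ids[i] for i in bg_idx},
        "depths": depths,
        "subtype_blocks": {c: [gene_ids[i] for i in b] for c, b in subtype_blocks.items()},
        "er_genes": [gene_ids[i] for i in er_block],
    }
    return counts_df, metadata, truth


def pick_spike_genes(gene_ids, mu, n: int, seed: int = 0, min_mean: float = 50.0):
    """Deterministically pick ``n`` well-expressed genes to spike."""
    mu = np.asarray(mu, dtype=float)
    eligible = [g for g, m in zip(gene_ids, mu) if m >= min_mean]
    if len(eligible) < n:
        raise InvalidInputError(f"only {len(eligible)} genes with mean >= {min_mean}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


def simulate_patient(
    gene_ids,
    normal_mean,
    dispersion,
    spikes: dict[str, float] | None = None,
    depth: float = 1.0,
    seed: int = 0,
    patient_id: str = "PATIENT001",
) -> pd.Series:
    """Draw one patient sample from the normal-tissue NB model.

    ``spikes`` maps gene id -> log2 fold change applied multiplicatively to
    that gene's mean (lfc 0 leaves the gene null).
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(normal_mean, dtype=float) * depth
    alpha = np.asarray(dispersion, dtype=float)
    if spikes:
        index = {g: i for i, g in enumerate(gene_ids)}
        for gene, lfc in spikes.items():
            if gene not in index:
                raise InvalidInputError(f"spike gene {gene!r} not in gene_ids")
            mean[index[gene]] *= 2.0 ** lfc
    counts = _nb_draw(rng, mean, alpha)
    return pd.Series(counts, index=pd.Index(list(gene_ids), name="gene_id"),
                     name=patient_id)


def simulate_class_data(
    n_classes: int = 4,
    n_per_class: int = 40,
    n_genes: int = 500,
    n_shifted: int = 30,
    shift: float = 2.0,
    seed: int = 0,
):
    """Gaussian log-expression with class-mean shifts in pooled-SD units.

    ``n_shifted`` genes are assigned round-robin to classes; each carries a
    +``shift`` mean offset (pooled SD is 1) in its class.  Returns (X, y).
    """
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    X = rng.normal(0.0, 1.0, (n, n_genes))
    y = np.repeat([f"class{k}" for k in range(n_classes)], n_per_class)
    for j in range(n_shifted):
        cls = j % n_classes
        X[y == f"class{cls}", j] += shift
    return X, y


def simulate_pathways(
    gene_pool,
    planted_genes=None,
    n_pathways: int = 50,
    size_range: tuple[int, int] = (5, 15),
    edge_density: float = 0.3,
    activation_fraction: float = 0.8,
    seed: int = 0,
):
    """Random acyclic signed pathway topologies as an edge-list DataFrame.

    Each pathway is a DAG over genes sampled from ``gene_pool``: a chain
    backbone (so every gene is connected) plus random forward edges with
    probability ``edge_density``; edges are activating with probability
    ``activation_fraction``, inhibiting otherwise.  When ``planted_genes``
    is given, an extra pathway ``PW_PLANTED`` is added in which the planted
    genes (expected to carry coordinated positive fold changes) sit upstream
    of a chain of unrelated genes, so the pathway accumulates a large
    positive net perturbation.  Returns (edges_df, planted_pathway_id).
    """
    rng = np.random.default_rng(seed)
    gene_pool = list(gene_pool)
    rows = []

    def add_edge(pid, src, tgt, sign):
        rows.append({"pathway_id": pid, "source_gene": src, "target_gene": tgt,
                     "interaction": "activation" if sign > 0 else "inhibition"})

    for p in range(n_pathways):
        pid = f"PW{p:03d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        genes = [gene_pool[i] for i in rng.choice(len(gene_pool), size=size, replace=False)]
        for i in range(size - 1):  # chain backbone keeps the DAG connected
            sign = 1 if rng.random() < activation_fraction else -1
            add_edge(pid, genes[i], genes[i + 1], sign)
        for i in range(size):
            for j in range(i + 2, size):
                if rng.random() < edge_density:
                    sign = 1 if rng.random() < activation_fraction else -1
                    add_edge(pid, genes[i], genes[j], sign)

    planted_id = None
    if planted_genes:
        planted_id = "PW_PLANTED"
        downstream = [g for g in gene_pool if g not in set(planted_genes)][:5]
        for g in planted_genes:
            add_edge(planted_id, g, downstream[0], +1)
        for i in range(len(downstream) - 1):
            add_edge(planted_id, downstream[i], downstream[i + 1], +1)
    return pd.DataFrame(rows), planted_id


def _write_vcf(path, variants):
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        "##contig=<ID=2>",
        "##contig=<ID=3>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Predicted effect">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for chrom, pos, ref, alt, gene, effect in variants:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\tGENE={gene};EFFECT={effect}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_annotation_tables(out_dir, gene_a="GENE_A", gene_b="GENE_B",
                           gene_c="GENE_C", seed: int = 0) -> dict:
    """Write the hand-enumerable clinical fixtures and return expectations.

    Six variants with population MAFs (0.01, 0.2, 0.5, absent, 0.09,
    common-flagged) of which exactly three survive the filter; clinical
    tables with six entries of which exactly three attach to retained
    variants by exact allele match; variant-drug rules hitting one retained
    and one removed variant; a fusion table with p-values (0.5, 0.01,
    absent); and a five-drug table with known match outcomes.
    """
    out_dir = Path(out_dir)
    bundle_dir = out_dir / "bundle"
    bundle_dir.mkdir(parents=True, exist_ok=True)

    variants = [
        ("1", 100, "A", "T", gene_a, "missense_variant"),   # maf 0.01 -> retained
        ("1", 200, "C", "G", gene_b, "missense_variant"),   # maf 0.2  -> removed
        ("2", 300, "G", "A", "TP53", "stop_gained"),        # maf 0.5  -> removed
        ("2", 400, "T", "C", "PIK3CA", "missense_variant"), # no maf   -> retained
        ("3", 500, "A", "G", gene_c, "missense_variant"),   # maf 0.09 -> retained
        ("3", 600, "C", "T", "BRCA1", "synonymous_variant"),# common   -> removed
    ]
    _write_vcf(out_dir / "patient.vcf", variants)

    pd.DataFrame(
        [{"chrom": "3", "pos": 600, "ref": "C", "alt": "T"}]
    ).to_csv(bundle_dir / "common_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "T", "maf": 0.01},
            {"chrom": "1", "pos": 200, "ref": "C", "alt": "G", "maf": 0.2},
            {"chrom": "2", "pos": 300, "ref": "G", "alt": "A", "maf": 0.5},
            {"chrom": "3", "pos": 500, "ref": "A", "alt": "G", "maf": 0.09},
            {"chrom": "3", "pos": 600, "ref": "C", "alt": "T", "maf": 0.01},
        ]
    ).to_csv(bundle_dir / "population_maf.tsv", sep="\t", index=False)
    # 6 clinical entries; exactly 3 match a retained variant's exact allele
    pd.DataFrame(
        [
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "T",
             "cosmic_id": "COSM0001", "histology": "breast"},
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "G",
             "cosmic_id": "COSM0002", "histology": "breast"},  # wrong alt
            {"chrom": "2", "pos": 400, "ref": "T", "alt": "C",
             "cosmic_id": "COSM0003", "histology": "breast"},
        ]
    ).to_csv(bundle_dir / "cosmic.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": "3", "pos": 500, "ref": "A", "alt": "G",
             "clnsig": "pathogenic", "review": "expert"},
            {"chrom": "9", "pos": 999, "ref": "A", "alt": "T",
             "clnsig": "benign", "review": "single"},          # no such variant
            {"chrom": "2", "pos": 300, "ref": "G", "alt": "T",
             "clnsig": "uncertain", "review": "single"},       # wrong alt
        ]
    ).to_csv(bundle_dir / "clinvar.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "T", "drug_id": "D1"},
            {"chrom": "1", "pos": 200, "ref": "C", "alt": "G", "drug_id": "D2"},
        ]
    ).to_csv(bundle_dir / "variant_drug_rules.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"gene_5p": gene_a, "gene_3p": "ETV6", "description": "known",
             "oncogenic_p": 0.5, "expression_gain_loss": 1.2},
            {"gene_5p": "BCR", "gene_3p": "ABL1", "description": "known",
             "oncogenic_p": 0.01, "expression_gain_loss": 0.8},
            {"gene_5p": "ESR1", "gene_3p": "CCDC170", "description": "",
             "oncogenic_p": None, "expression_gain_loss": None},
        ]
    ).to_csv(out_dir / "fusions.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"drug_id": "D1", "name": "Alphanib", "approved": "true",
             "targets": f"{gene_a}:inhibitor", "pathway_ids": "PW_PLANTED"},
            {"drug_id": "D2", "name": "Betazumab", "approved": "true",
             "targets": f"{gene_b}:antibody", "pathway_ids": ""},
            {"drug_id": "D3", "name": "Gammagonist", "approved": "true",
             "targets": f"{gene_c}:agonist", "pathway_ids": ""},
            {"drug_id": "D4", "name": "Deltanib", "approved": "false",
             "targets": f"{gene_a}:inhibitor", "pathway_ids": ""},
            {"drug_id": "D5", "name": "Epsilonib", "approved": "true",
             "targets": f"{gene_c}:inhibitor", "pathway_ids": ""},
        ]
    ).to_csv(out_dir / "drugs.tsv", sep="\t", index=False)

    return {
        "n_variants": 6,
        "retained_keys": [("1", 100, "A", "T"), ("2", 400, "T", "C"),
                          ("3", 500, "A", "G")],
        "removal_reasons": {("1", 200, "C", "G"): "maf-above-threshold",
                            ("2", 300, "G", "A"): "maf-above-threshold",
                            ("3", 600, "C", "T"): "common-flag"},
        "n_annotation_attachments": 3,
        "fusion_order_genes_5p": ["BCR", gene_a, "ESR1"],
        "variant_drug_hits": {"D1"},
    }


def toy_drug_inputs(gene_a="GENE_A", gene_b="GENE_B", gene_c="GENE_C"):
    """In-memory fixture with a fully hand-enumerated drug-match outcome.

    Expected: Alphanib (D1) matches on expression + variant + pathway,
    Betazumab (D2) and Gammagonist (D3) on expression only; Deltanib (D4,
    not approved) and Epsilonib (D5, discordant direction) never match.
    Final ranking: D1, D2, D3.
    """
    from .annotate import VariantRecord
    from .drugs import DrugRecord

    de_table = pd.DataFrame(
        {
            "gene": [gene_a, gene_b, gene_c, "GENE_NULL"],
            "log2_fold_change": [3.1, 2.5, -2.8, 0.1],
            "p_value": [1e-8, 1e-6, 1e-7, 0.8],
            "adj_p": [4e-8, 2e-6, 2e-7, 0.8],
            "significant": [True, True, True, False],
            "direction": ["up", "up", "down", "none"],
        }
    )
    pathway_results = pd.DataFrame(
        {
            "pathway_id": ["PW_PLANTED", "PW001"],
            "tA": [12.0, 0.4],
            "pG": [1e-4, 0.6],
            "pG_fdr": [2e-4, 0.6],
            "status": ["activated", "none"],
        }
    )
    drugs = [
        DrugRecord("D1", "Alphanib", True, [(gene_a, "inhibitor")], ["PW_PLANTED"]),
        DrugRecord("D2", "Betazumab", True, [(gene_b, "antibody")], []),
        DrugRecord("D3", "Gammagonist", True, [(gene_c, "agonist")], []),
        DrugRecord("D4", "Deltanib", False, [(gene_a, "inhibitor")], []),
        DrugRecord("D5", "Epsilonib", True, [(gene_c, "inhibitor")], []),
    ]
    rules = pd.DataFrame(
        [
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "T", "drug_id": "D1"},
            {"chrom": "1", "pos": 200, "ref": "C", "alt": "G", "drug_id": "D2"},
        ]
    )
    retained_variants = [
        VariantRecord("1", 100, "A", "T", gene=gene_a),
        VariantRecord("2", 400, "T", "C", gene="PIK3CA"),
        VariantRecord("3", 500, "A", "G", gene=gene_c),
    ]
    expected = {
        "ranked_drug_ids": ["D1", "D2", "D3"],
        "evidence_counts": {"D1": 3, "D2": 1, "D3": 1},
        "evidence_types": {"D1": {"expression", "variant", "pathway"},
                           "D2": {"expression"}, "D3": {"expression"}},
    }
    return de_table, pathway_results, drugs, rules, retained_variants, expected


def make_fixture_dir(out_dir, seed: int = 0, config: SimulationConfig | None = None) -> dict:
    """Write a complete demo input directory for the whole pipeline.

    Produces cohort.tsv, samples.tsv, patient.tsv, pathways.tsv, patient.vcf,
    bundle/, fusions.tsv, drugs.tsv and truth.json; returns the ground-truth
    dictionary (also stored in truth.json).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or SimulationConfig(seed=seed)
    counts_df, metadata, truth = simulate_reference(cfg)
    nio.write_counts(counts_df, out_dir / "cohort.tsv")
    metadata.to_csv(out_dir / "samples.tsv", sep="\t")

    seeds = np.random.SeedSequence(seed).spawn(3)
    spike_up = pick_spike_genes(truth["gene_ids"], truth["mu"], 25,
                                seed=int(seeds[0].generate_state(1)[0] % 2**31))
    remaining_mu = truth["mu"].copy()
    up_set = set(spike_up)
    down_pool = [(g, m) for g, m in zip(truth["gene_ids"], remaining_mu)
                 if g not in up_set and m >= 50]
    spike_down = [g for g, _ in down_pool[:10]]
    spikes = {g: 3.0 for g in spike_up}
    spikes.update({g: -3.0 for g in spike_down})
    patient = simulate_patient(
        truth["gene_ids"], truth["mu"], truth["alpha"], spikes=spikes,
        depth=1.3, seed=int(seeds[1].generate_state(1)[0] % 2**31),
    )
    nio.write_counts(patient.to_frame(), out_dir / "patient.tsv")

    pool = [g for g, m in zip(truth["gene_ids"], truth["mu"]) if m >= 20]
    edges, planted_id = simulate_pathways(
        pool, planted_genes=spike_up[:5], n_pathways=20,
        seed=int(seeds[2].generate_state(1)[0] % 2**31),
    )
    edges.to_csv(out_dir / "pathways.tsv", sep="\t", index=False)

    gene_a, gene_b = spike_up[0], spike_up[1]
    gene_c = spike_down[0]
    expectations = make_annotation_tables(out_dir, gene_a, gene_b, gene_c, seed=seed)

    summary = {
        "seed": seed,
        "spike_up": spike_up,
        "spike_down": spike_down,
        "planted_pathway": planted_id,
        "gene_a": gene_a,
        "gene_b": gene_b,
        "gene_c": gene_c,
        "background_genes": sorted(truth["background_genes"]),
        "expectations": {k: v for k, v in expectations.items()
                         if k in ("n_variants", "n_annotation_attachments")},
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    truth.update(summary)
    return truth
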