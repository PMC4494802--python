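"""Match approved compounds to altered genes, variants and pathways.

Three evidence channels feed the drug table: significantly differentially
expressed target genes (with an action/direction concordance rule:
inhibitor, antagonist and antibody actions pair with up-regulated targets,
agonists with down-regulated ones, 'other' with either), exact-allele
variant-drug rules, and significantly dysregulated pathways the drug is
annotated to.  Matches are consolidated into one deterministically ranked
row per drug; drugs without an approved flag never enter matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError

UP_ACTIONS = frozenset({"inhibitor", "antagonist", "antibody"})
DOWN_ACTIONS = frozenset({"agonist"})

__all__ = [
    "DrugRecord",
    "DrugMatch",
    "load_drug_table",
    "match_expression",
    "match_variants",
    "match_pathways",
    "consolidate",
]


@dataclass
class DrugRecord:
    drug_id: str
    name: str
    approved: bool
    targets: list[tuple[str, str]] = field(default_factory=list)  # (gene, action)
    pathway_ids: list[str] = field(default_factory=list)
    url: str | None = None


@dataclass
class DrugMatch:
    drug_id: str
    drug_name: str
    evidence_type: str  # expression | variant | pathway
    matched_entity: str  # gene, variant key label, or pathway id
    direction_concordant: bool | None  # None = not applicable
    rationale: str


def _parse_list(cell, sep=";"):
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [p.strip() for p in str(cell).split(sep) if p.strip()]


def load_drug_table(path) -> list[DrugRecord]:
    """Read drug metadata TSV.

    Columns: drug_id, name, approved (true/false), targets
    ('GENE:action;GENE2:action'), pathway_ids (';'-separated), optional url.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drug_id", "name", "approved", "targets"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        targets = []
        for item in _parse_list(row["targets"]):
            if ":" not in item:
                raise FormatError(f"{path}: malformed target {item!r} (want GENE:action)")
            gene, action = item.rsplit(":", 1)
            targets.append((gene, action))
        records.append(
            DrugRecord(
                drug_id=row["drug_id"],
                name=row["name"],
                approved=str(row["approved"]).strip().lower() in {"true", "1", "yes"},
                targets=targets,
                pathway_ids=_parse_list(row.get("pathway_ids")),
                url=row.get("url") if "url" in df.columns else None,
            )
        )
    return records


def match_expression(
    de_table: pd.DataFrame,
    drugs: list[DrugRecord],
    require_concordance: bool = True,
) -> list[DrugMatch]:
    """Match approved drugs to significantly DE target genes.

    With ``require_concordance`` (default) inhibitor-class actions only match
    up-regulated targets and agonists only down-regulated ones; 'other'
    actions match either direction with concordance not applicable.
    """
    if len(de_table) == 0:
        return []
    sig = de_table[de_table["significant"]]
    direction = dict(zip(sig["gene"], sig["direction"]))
    matches = []
    for drug in drugs:
        if not drug.approved:
            continue
        for gene, action in drug.targets:
            if gene not in direction:
                continue
            d = direction[gene]
            if action in UP_ACTIONS:
                concordant = d == "up"
            elif action in DOWN_ACTIONS:
                concordant = d == "down"
            else:
                concordant = None
            if require_concordance and concordant is False:
                continue
            matches.append(
                DrugMatch(
                    drug_id=drug.drug_id,
                    drug_name=drug.name,
                    evidence_type="expression",
                    matched_entity=gene,
                    direction_concordant=concordant,
                    rationale=f"{drug.name} ({action}) targets {gene} ({d}-regulated)",
                )
            )
    return matches


def match_variants(
    annotated_variants,
    rules: pd.DataFrame | None,
    drugs: list[DrugRecord],
) -> list[DrugMatch]:
    """One match per (retained variant, exact-allele drug rule) pair."""
    if rules is None or len(rules) == 0 or not annotated_variants:
        return []
    if "drug_id" not in rules.columns:
        raise FormatError("variant drug rules: missing required column 'drug_id'")
    by_id = {d.drug_id: d for d in drugs if d.approved}
    rule_index: dict[tuple, list[str]] = {}
    for _, row in rules.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        rule_index.setdefault(key, []).append(row["drug_id"])
    matches = []
    for av in annotated_variants:
        v = av.variant if hasattr(av, "variant") else av
        for drug_id in rule_index.get(v.key, []):
            drug = by_id.get(drug_id)
            if drug is None:
                continue  # unknown or non-approved drug: rule ignored
            matches.append(
                DrugMatch(
                    drug_id=drug.drug_id,
                    drug_name=drug.name,
                    evidence_type="variant",
                    matched_entity=v.label,
                    direction_concordant=None,
                    rationale=f"{drug.name} linked to variant {v.label}"
                    + (f" in {v.gene}" if v.gene else ""),
                )
            )
    return matches


def match_pathways(
    pathway_results: pd.DataFrame,
    drugs: list[DrugRecord],
    fdr_alpha: float = 0.05,
) -> list[DrugMatch]:
    """Match approved drugs annotated to significantly dysregulated pathways."""
    if len(pathway_results) == 0:
        return []
    sig = pathway_results[pathway_results["pG_fdr"] < fdr_alpha]
    status = dict(zip(sig["pathway_id"], sig["status"]))
    matches = []
    for drug in drugs:
        if not drug.approved:
            continue
        for pid in drug.pathway_ids:
            if pid in status:
                matches.append(
                    DrugMatch(
                        drug_id=drug.drug_id,
                        drug_name=drug.name,
                        evidence_type="pathway",
                        matched_entity=pid,
                        direction_concordant=None,
                        rationale=f"{drug.name} acts on {status[pid]} pathway {pid}",
                    )
                )
    return matches


def consolidate(matches: list[DrugMatch]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank one row per drug; keep every evidence line as a sub-table.

    Ranking: distinct evidence types (desc), total evidence count (desc),
    drug name (asc), drug id (asc) — a deterministic total order.  Returns
    (ranked drug table, evidence table).
    """
    if not matches:
        empty_drugs = pd.DataFrame(
            columns=["rank", "drug_id", "name", "n_evidence_types",
                     "n_evidence", "evidence_types"]
        )
        empty_ev = pd.DataFrame(
            columns=["drug_id", "drug_name", "evidence_type", "matched_entity",
                     "direction_concordant", "rationale"]
        )
        return empty_drugs, empty_ev
    ev = pd.DataFrame(
        {
            "drug_id": [m.drug_id for m in matches],
            "drug_name": [m.drug_name for m in matches],
            "evidence_type": [m.evidence_type for m in matches],
            "matched_entity": [m.matched_entity for m in matches],
            "direction_concordant": [
                "" if m.direction_concordant is None else str(m.direction_concordant)
                for m in matches
            ],
            "rationale": [m.rationale for m in matches],
        }
    )
    grouped = ev.groupby("drug_id", sort=False)
    rows = []
    for drug_id, sub in grouped:
        types = sorted(sub["evidence_type"].unique())
        rows.append(
            {
                "drug_id": drug_id,
                "name": sub["drug_name"].iloc[0],
                "n_evidence_types": len(types),
                "n_evidence": len(sub),
                "evidence_types": ";".join(types),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        by=["n_evidence_types", "n_evidence", "name", "drug_id"],
        ascending=[False, False, True, True],
        kind="mergesort",
        ignore_index=True,
    )
    table.insert(0, "rank", range(1, len(table) + 1))
    order = {d: i for i, d in enumerate(table["drug_id"])}
    ev = ev.sort_values(
        by=["drug_id", "evidence_type", "matched_entity"],
        key=lambda col: col.map(order) if col.name == "drug_id" else col,
        kind="mergesort",
        ignore_index=True,
    )
    return table, ev
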