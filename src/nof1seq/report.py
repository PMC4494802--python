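"""Structured report model and HTML/CSV rendering.

Every analysis stage deposits its output into one :class:`ReportModel`;
rendering then produces a self-contained interactive HTML report (sortable
and searchable tables, no network assets), one CSV per table, a JSON dump
of the whole model, and a print-ready clinical summary page.  Sections that
were not run are rendered as explicit "not run" blocks.  Rendering is
deterministic: identical models yield byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from html import escape
from pathlib import Path

import pandas as pd

from .errors import IntegrationError
from .nsc import Prediction
from .preprocess import PatientProfile

DEFAULT_URL_TEMPLATES = {
    "gene": "https://www.ncbi.nlm.nih.gov/gene/?term={id}",
    "drug": "https://go.drugbank.com/drugs/{id}",
}

SECTION_TABLES = {
    "predictions": "Receptor status & molecular subtype",
    "de_genes": "Differentially expressed genes",
    "pathways": "Dysregulated pathways",
    "variants": "Annotated variants",
    "fusions": "Fusion gene candidates",
    "drugs": "Drug candidates",
    "drug_evidence": "Drug evidence detail",
    "qc": "Quality control (pass-through)",
}

_CSS = """
body{font-family:system-ui,Helvetica,Arial,sans-serif;margin:2em;color:#222}
h1{border-bottom:3px solid #1f5fa8}h2{color:#1f5fa8;margin-top:2em}
table{border-collapse:collapse;width:100%;font-size:0.9em}
th,td{border:1px solid #ccc;padding:4px 8px;text-align:left}
th{background:#eef3fa;cursor:pointer;user-select:none}
tr:nth-child(even){background:#fafafa}
input.filter{margin:6px 0;padding:4px;width:20em}
.up{background:#fdd}.down{background:#ddf}
.notrun{color:#888;font-style:italic;border:1px dashed #bbb;padding:8px}
.prov{font-size:0.8em;background:#f4f4f4;padding:8px}
@media print{input.filter{display:none}}
"""

_JS = """
function sortTable(t,c){const b=t.tBodies[0];const r=[...b.rows];
const asc=t.dataset.sc==c+'a';const n=r.every(x=>x.cells[c]&&(!x.cells[c].innerText.trim()||!isNaN(parseFloat(x.cells[c].innerText))));
r.sort((x,y)=>{let a=x.cells[c].innerText,d=y.cells[c].innerText;
if(n){a=parseFloat(a)||0;d=parseFloat(d)||0;return asc?d-a:a-d}
return asc?d.localeCompare(a):a.localeCompare(d)});
t.dataset.sc=asc?c+'d':c+'a';r.forEach(x=>b.appendChild(x));}
function filterTable(i,id){const q=i.value.toLowerCase();
document.querySelectorAll('#'+id+' tbody tr').forEach(r=>{
r.style.display=r.innerText.toLowerCase().includes(q)?'':'none';});}
"""


@dataclass
class ReportModel:
    """Everything the rendered report shows, in one serializable object."""

    patient_id: str
    patient_meta: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    profile_summary: dict = field(default_factory=dict)
    predictions: dict[str, Prediction] | None = None
    de_table: pd.DataFrame | None = None
    pathway_table: pd.DataFrame | None = None
    pathway_gene_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    variant_table: pd.DataFrame | None = None
    fusion_table: pd.DataFrame | None = None
    drug_table: pd.DataFrame | None = None
    drug_evidence: pd.DataFrame | None = None
    qc_table: pd.DataFrame | None = None
    url_templates: dict = field(default_factory=lambda: dict(DEFAULT_URL_TEMPLATES))

    def tables(self) -> dict[str, pd.DataFrame | None]:
        return {
            "predictions": self._predictions_frame(),
            "de_genes": self.de_table,
            "pathways": self.pathway_table,
            "variants": self.variant_table,
            "fusions": self.fusion_table,
            "drugs": self.drug_table,
            "drug_evidence": self.drug_evidence,
            "qc": self.qc_table,
        }

    def _predictions_frame(self) -> pd.DataFrame | None:
        if self.predictions is None:
            return None
        rows = []
        for name in sorted(self.predictions):
            pred = self.predictions[name]
            rows.append(
                {
                    "classifier": name,
                    "call": pred.label,
                    "probability": round(pred.probabilities[pred.label], 6),
                    "all_probabilities": "; ".join(
                        f"{c}={pred.probabilities[c]:.4f}" for c in sorted(pred.probabilities)
                    ),
                    "uninformative": pred.uninformative,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        def frame(df):
            if df is None:
                return None
            return {"columns": list(df.columns),
                    "rows": json.loads(df.to_json(orient="values"))}

        doc = {
            "patient_id": self.patient_id,
            "patient_meta": self.patient_meta,
            "provenance": self.provenance,
            "profile_summary": self.profile_summary,
        }
        for name, df in self.tables().items():
            doc[name] = frame(df)
        doc["pathway_gene_tables"] = {
            pid: frame(df) for pid, df in self.pathway_gene_tables.items()
        }
        return doc


def build_report_model(
    profile: PatientProfile,
    de_table: pd.DataFrame,
    predictions: dict[str, Prediction] | None = None,
    pathway_table: pd.DataFrame | None = None,
    pathway_gene_tables: dict[str, pd.DataFrame] | None = None,
    variant_table: pd.DataFrame | None = None,
    fusion_table: pd.DataFrame | None = None,
    drug_table: pd.DataFrame | None = None,
    drug_evidence: pd.DataFrame | None = None,
    qc_table: pd.DataFrame | None = None,
    patient_meta: dict | None = None,
    provenance: dict | None = None,
    url_templates: dict | None = None,
) -> ReportModel:
    """Assemble stage outputs; at minimum a profile and DE table are needed.

    Raises :class:`IntegrationError` when a patient_id in ``patient_meta``
    disagrees with the profile's.
    """
    patient_meta = dict(patient_meta or {})
    meta_id = patient_meta.get("patient_id")
    if meta_id is not None and str(meta_id) != profile.patient_id:
        raise IntegrationError(
            f"patient id mismatch: profile {profile.patient_id!r} vs "
            f"metadata {meta_id!r}"
        )
    prov = {
        "patient_id": profile.patient_id,
        "size_factor": profile.size_factor,
        "expression_cutoff": profile.expression_cutoff,
        "bg_quantile": profile.bg_quantile,
        "n_reliable_genes": len(profile.reliable_genes),
    }
    prov.update(provenance or {})
    templates = dict(DEFAULT_URL_TEMPLATES)
    if url_templates:
        templates.update(url_templates)
    return ReportModel(
        patient_id=profile.patient_id,
        patient_meta=patient_meta,
        provenance=prov,
        profile_summary={
            "n_genes": len(profile.gene_ids),
            "size_factor": profile.size_factor,
            "expression_cutoff": profile.expression_cutoff,
            "n_reliable_genes": len(profile.reliable_genes),
            "n_unmatched_dropped": profile.n_unmatched_dropped,
        },
        predictions=predictions,
        de_table=de_table,
        pathway_table=pathway_table,
        pathway_gene_tables=dict(pathway_gene_tables or {}),
        variant_table=variant_table,
        fusion_table=fusion_table,
        drug_table=drug_table,
        drug_evidence=drug_evidence,
        qc_table=qc_table,
        url_templates=templates,
    )


def _linkify(value, template):
    return f'<a href="{escape(template.format(id=value), quote=True)}">{escape(str(value))}</a>'


def _cell_html(col: str, value, model: ReportModel) -> str:
    if pd.isna(value):
        return ""
    if col == "gene" and isinstance(value, str) and value:
        return _linkify(value, model.url_templates["gene"])
    if col == "drug_id" and isinstance(value, str) and value:
        return _linkify(value, model.url_templates["drug"])
    if isinstance(value, float):
        return escape(f"{value:.6g}")
    return escape(str(value))


def _row_class(name: str, row: pd.Series) -> str:
    if name in {"de_genes"} and "direction" in row.index and row["direction"] in ("up", "down"):
        return f' class="{row["direction"]}"'
    return ""


def _table_html(name: str, df: pd.DataFrame, model: ReportModel) -> str:
    tid = f"tbl_{name}"
    head = "".join(
        f'<th onclick="sortTable(document.getElementById(\'{tid}\'),{i})">{escape(str(c))}</th>'
        for i, c in enumerate(df.columns)
    )
    body = []
    for _, row in df.iterrows():
        cells = "".join(f"<td>{_cell_html(c, row[c], model)}</td>" for c in df.columns)
        body.append(f"<tr{_row_class(name, row)}>{cells}</tr>")
    return (
        f'<input class="filter" placeholder="filter rows..." '
        f"oninput=\"filterTable(this,'{tid}')\">"
        f'<table id="{tid}"><thead><tr>{head}</tr></thead>'
        f'<tbody>{"".join(body)}</tbody></table>'
    )


def _lfc_span(gene: str, lfc: float) -> str:
    cls = "up" if lfc > 0 else ("down" if lfc < 0 else "")
    return f'<span class="{cls}">{escape(gene)} ({lfc:+.2f})</span>'


def render_html(model: ReportModel, out_dir) -> Path:
    """Write report.html, tables/*.csv and report_model.json into ``out_dir``."""
    out_dir = Path(out_dir)
    tables_dir = out_dir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)

    tables = model.tables()
    for name, df in tables.items():
        if df is not None:
            df.to_csv(tables_dir / f"{name}.csv", index=False)
    with open(out_dir / "report_model.json", "w") as fh:
        json.dump(model.to_json_dict(), fh, indent=1, sort_keys=True)

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>n-of-1 report: {escape(model.patient_id)}</title>",
        f"<style>{_CSS}</style><script>{_JS}</script></head><body>",
        f"<h1>n-of-1 RNA-seq report &mdash; patient {escape(model.patient_id)}</h1>",
    ]
    if model.patient_meta:
        meta = "".join(
            f"<tr><td>{escape(str(k))}</td><td>{escape(str(v))}</td></tr>"
            for k, v in sorted(model.patient_meta.items())
        )
        parts.append(f"<h2>Patient</h2><table><tbody>{meta}</tbody></table>")
    summary = "".join(
        f"<tr><td>{escape(str(k))}</td><td>{escape(str(v))}</td></tr>"
        for k, v in model.profile_summary.items()
    )
    parts.append(f"<h2>Sample processing</h2><table><tbody>{summary}</tbody></table>")

    for name, title in SECTION_TABLES.items():
        df = tables[name]
        parts.append(f"<h2>{escape(title)}</h2>")
        if df is None:
            parts.append('<div class="notrun">not run</div>')
        elif len(df) == 0:
            placeholder = "no candidates" if name in {"drugs", "drug_evidence"} else "no entries"
            parts.append(f'<div class="notrun">{placeholder}</div>')
        else:
            parts.append(_table_html(name, df, model))
        if name == "pathways" and model.pathway_gene_tables:
            for pid in sorted(model.pathway_gene_tables):
                gt = model.pathway_gene_tables[pid]
                spans = " ".join(
                    _lfc_span(g, l) for g, l in zip(gt["gene"], gt["log2_fold_change"])
                )
                parts.append(
                    f"<p><b>{escape(pid)}</b> DE genes (log2 fold change): {spans}</p>"
                )

    prov = "".join(
        f"<tr><td>{escape(str(k))}</td><td>{escape(str(v))}</td></tr>"
        for k, v in sorted(model.provenance.items())
    )
    parts.append(
        f'<h2>Provenance</h2><div class="prov"><table><tbody>{prov}</tbody></table></div>'
    )
    parts.append("</body></html>")
    out = out_dir / "report.html"
    out.write_text("".join(parts))
    return out


def render_summary(model: ReportModel, out_path) -> Path:
    """Print-ready one-page clinical summary (HTML, no scripts)."""
    out_path = Path(out_path)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Clinical summary: {escape(model.patient_id)}</title>",
        f"<style>{_CSS}</style></head><body>",
        f"<h1>Clinical summary &mdash; patient {escape(model.patient_id)}</h1>",
    ]
    if model.patient_meta:
        meta = "".join(
            f"<tr><td>{escape(str(k))}</td><td>{escape(str(v))}</td></tr>"
            for k, v in sorted(model.patient_meta.items())
        )
        parts.append(f"<h2>Patient information</h2><table><tbody>{meta}</tbody></table>")
    summary = "".join(
        f"<tr><td>{escape(str(k))}</td><td>{escape(str(v))}</td></tr>"
        for k, v in model.profile_summary.items()
    )
    parts.append(f"<h2>Sample processing</h2><table><tbody>{summary}</tbody></table>")

    preds = model._predictions_frame()
    if preds is not None and len(preds):
        parts.append("<h2>Molecular classification</h2><ul>")
        for _, row in preds.iterrows():
            parts.append(
                f"<li>{escape(row['classifier'])}: <b>{escape(row['call'])}</b> "
                f"(probability {row['probability']:.3f})</li>"
            )
        parts.append("</ul>")

    parts.append("<h2>Recommended approved drugs</h2>")
    if model.drug_table is None or len(model.drug_table) == 0:
        parts.append('<div class="notrun">no actionable findings</div>')
    else:
        parts.append("<ol>")
        for _, row in model.drug_table.iterrows():
            parts.append(
                f"<li><b>{escape(row['name'])}</b> ({escape(row['drug_id'])}) "
                f"&mdash; evidence: {escape(row['evidence_types'])} "
                f"({int(row['n_evidence'])} items)</li>"
            )
        parts.append("</ol>")

    parts.append("<h2>Appendix</h2>")
    for name in ("de_genes", "pathways", "variants", "fusions"):
        df = model.tables()[name]
        parts.append(f"<h3>{escape(SECTION_TABLES[name])}</h3>")
        if df is None:
            parts.append('<div class="notrun">not run</div>')
        elif len(df) == 0:
            parts.append('<div class="notrun">no entries</div>')
        else:
            shown = df.head(25)
            head = "".join(f"<th>{escape(str(c))}</th>" for c in shown.columns)
            rows = []
            for _, row in shown.iterrows():
                rows.append(
                    "<tr>" + "".join(
                        f"<td>{escape('' if pd.isna(row[c]) else (f'{row[c]:.4g}' if isinstance(row[c], float) else str(row[c])))}</td>"
                        for c in shown.columns
                    ) + "</tr>"
                )
            parts.append(
                f"<table><thead><tr>{head}</tr></thead><tbody>{''.join(rows)}</tbody></table>"
            )
            if len(df) > 25:
                parts.append(f"<p>... {len(df) - 25} further rows in the full report.</p>")

    prov = "".join(
        f"<tr><td>{escape(str(k))}</td><td>{escape(str(v))}</td></tr>"
        for k, v in sorted(model.provenance.items())
    )
    parts.append(
        f'<h2>Provenance</h2><div class="prov"><table><tbody>{prov}</tbody></table></div>'
    )
    parts.append("</body></html>")
    out_path.write_text("".join(parts))
    return out_path


def pathway_gene_table(topology, de_table: pd.DataFrame) -> pd.DataFrame:
    """DE genes of one pathway with their fold changes (for report coloring)."""
    if len(de_table) == 0:
        return pd.DataFrame(columns=["gene", "log2_fold_change"])
    sig = de_table[de_table["significant"]]
    sub = sig[sig["gene"].isin(topology.genes)]
    return sub[["gene", "log2_fold_change"]].reset_index(drop=True)
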