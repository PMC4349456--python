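"""Deterministic HTML and JSON reports of a neighborhood analysis.

The report keeps a fixed section order: the homolog list, one neighborhood
drawing per homolog (anchor highlighted), then the three over-representation
tables — enzymes, metabolites, pathways.  Entity ids become hyperlinks when
a ``link_base`` URL template is supplied; otherwise they render as plain
text.  In deterministic mode (the default) no timestamps are emitted, so the
same analysis always renders to identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

from jinja2 import Environment, BaseLoader, select_autoescape

from .context import (AnalysisConfig, AnalysisResult, EnzymeSummaryRow,
                      MetaboliteSummaryRow, Neighborhood, PathwaySummaryRow)
from .datastore import Gene
from .homology import HomologQuery

SCHEMA_VERSION = 1

_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Neighborhood analysis: {{ r.query.query_gene_id }}</title>
<style>
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.25em 0.6em; text-align: left; }
th { background: #eee; }
.anchor { font-weight: bold; background: #ffe9a8; }
.gene { display: inline-block; border: 1px solid #bbb; border-radius: 4px;
        padding: 0 0.3em; margin: 0 0.15em; }
.empty { color: #777; font-style: italic; }
</style>
</head>
<body>
<h1>Gene-neighborhood analysis for {{ r.query.query_gene_id }}</h1>
<p>Parameters: {{ r.query.n_homologs }} homologs,
{{ r.query.n_neighbors }} genes up- and downstream,
amino-acid identity cutoff {{ "%g" % r.query.aa_idc }}%,
pathway scoring: {{ r.config.score_mode }}.</p>
{% if timestamp %}<p>Generated: {{ timestamp }}</p>{% endif %}

<h2>Homolog ID</h2>
<table>
<tr><th>#</th><th>gene</th><th>organism</th><th>role</th></tr>
{% for gid in r.homologs %}
<tr><td>{{ loop.index }}</td><td>{{ gid }}</td>
<td>{{ gid.split(":")[0] }}</td>
<td>{{ "query" if loop.first else "homolog" }}</td></tr>
{% endfor %}
</table>

<h2>Neighborhood Representations</h2>
{% for nb in r.neighborhoods %}
<p><b>{{ nb.anchor_gene_id }}</b><br>
{% for g in nb.genes %}<span class="gene{{ ' anchor' if g.gene_id == nb.anchor_gene_id }}"
title="{{ g.product }}">{{ g.locus_tag }}{% if g.ec_numbers %}
[{{ g.ec_numbers | sort | join(", ") }}]{% endif %}</span>{% endfor %}
</p>
{% else %}
<p class="empty">no neighborhoods</p>
{% endfor %}

<h2>Over-represented Enzyme Summary</h2>
{% if r.enzyme_summary %}
<table>
<tr><th>#</th><th>EC</th><th>frequency</th><th>neighborhoods</th></tr>
{% for row in r.enzyme_summary %}
<tr><td>{{ loop.index }}</td><td>{{ link(row.ec) }}</td>
<td>{{ row.frequency }}</td>
<td>{{ row.neighborhoods | join(", ") }}</td></tr>
{% endfor %}
</table>
{% else %}<p class="empty">no enzymes found in the neighborhoods</p>{% endif %}

<h2>Over-represented Metabolite Summary</h2>
{% if r.metabolite_summary %}
<table>
<tr><th>#</th><th>compound</th><th>frequency</th></tr>
{% for row in r.metabolite_summary %}
<tr><td>{{ loop.index }}</td><td>{{ link(row.compound_id) }}</td>
<td>{{ row.frequency }}</td></tr>
{% endfor %}
</table>
{% else %}<p class="empty">no metabolites mapped</p>{% endif %}

<h2>Over-represented Pathway Summary</h2>
{% if r.pathway_summary %}
<table>
<tr><th>#</th><th>pathway</th><th>hits</th><th>enzymes</th><th>compounds</th></tr>
{% for row in r.pathway_summary %}
<tr><td>{{ loop.index }}</td><td>{{ link(row.pathway_id) }}</td>
<td>{{ row.hits }}</td>
<td>{{ row.ecs | join(", ") }}</td>
<td>{{ row.compounds | join(", ") }}</td></tr>
{% endfor %}
</table>
{% else %}<p class="empty">no pathway mapping available</p>{% endif %}
</body>
</html>
"""


def _make_link(link_base: str | None):
    from markupsafe import Markup, escape

    def link(entity_id: str):
        if link_base is None:
            return entity_id
        href = link_base.format(id=entity_id)
        return Markup(f'<a href="{escape(href)}">{escape(entity_id)}</a>')

    return link


def render_html(result: AnalysisResult, out: str | Path,
                link_base: str | None = None,
                deterministic: bool = True) -> None:
    """Write the self-contained HTML report.

    ``link_base`` is a URL template with an ``{id}`` placeholder applied to
    every EC, compound and pathway id.
    """
    env = Environment(loader=BaseLoader(),
                      autoescape=select_autoescape(["html"]))
    template = env.from_string(_TEMPLATE)
    timestamp = (None if deterministic
                 else datetime.now(timezone.utc).isoformat())
    html = template.render(r=result, link=_make_link(link_base),
                           timestamp=timestamp)
    Path(out).write_text(html)


# ---------------------------------------------------------------------------
# JSON

def _result_to_doc(result: AnalysisResult) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "query": asdict(result.query),
        "config": {"score_mode": result.config.score_mode,
                   "exclude_compounds": sorted(result.config.exclude_compounds)},
        "homologs": list(result.homologs),
        "neighborhoods": [
            {"anchor_gene_id": nb.anchor_gene_id,
             "genes": [{**asdict(g), "ec_numbers": sorted(g.ec_numbers)}
                       for g in nb.genes]}
            for nb in result.neighborhoods],
        "enzyme_summary": [
            {"ec": r.ec, "frequency": r.frequency,
             "neighborhoods": list(r.neighborhoods)}
            for r in result.enzyme_summary],
        "metabolite_summary": [
            {"compound_id": r.compound_id, "frequency": r.frequency,
             "neighborhoods": list(r.neighborhoods)}
            for r in result.metabolite_summary],
        "pathway_summary": [
            {"pathway_id": r.pathway_id, "hits": r.hits,
             "ecs": list(r.ecs), "compounds": list(r.compounds)}
            for r in result.pathway_summary],
    }


def render_json(result: AnalysisResult, out: str | Path) -> None:
    """Lossless, schema-versioned serialization of the full result."""
    Path(out).write_text(
        json.dumps(_result_to_doc(result), indent=1, sort_keys=True) + "\n")


def load_json(path: str | Path) -> AnalysisResult:
    """Inverse of :func:`render_json`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version "
                         f"{doc.get('schema_version')!r}")
    neighborhoods = [
        Neighborhood(
            anchor_gene_id=nb["anchor_gene_id"],
            genes=tuple(Gene(**{**g, "ec_numbers": frozenset(g["ec_numbers"])})
                        for g in nb["genes"]))
        for nb in doc["neighborhoods"]]
    return AnalysisResult(
        query=HomologQuery(**doc["query"]),
        homologs=list(doc["homologs"]),
        neighborhoods=neighborhoods,
        enzyme_summary=[EnzymeSummaryRow(r["ec"], r["frequency"],
                                         tuple(r["neighborhoods"]))
                        for r in doc["enzyme_summary"]],
        metabolite_summary=[MetaboliteSummaryRow(r["compound_id"],
                                                 r["frequency"],
                                                 tuple(r["neighborhoods"]))
                            for r in doc["metabolite_summary"]],
        pathway_summary=[PathwaySummaryRow(r["pathway_id"], r["hits"],
                                           tuple(r["ecs"]),
                                           tuple(r["compounds"]))
                         for r in doc["pathway_summary"]],
        config=AnalysisConfig(
            score_mode=doc["config"]["score_mode"],
            exclude_compounds=frozenset(doc["config"]["exclude_compounds"])),
    )
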