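"""Gene-neighborhood extraction and over-representation summaries.

This is the heart of the function-prediction pipeline.  Given the homologs of
a query transcriptional regulator, each homolog anchors a window of genes
upstream and downstream on its own replicon (a *neighborhood*).  Enzymes
found in those windows are ranked by the number of distinct neighborhoods
they occur in; the compounds their reactions involve, and the pathways those
enzymes and compounds map to, are ranked the same way.  A pathway that keeps
co-occurring with the regulator across many genomes is a strong candidate
for the metabolic area the regulator controls.

Frequencies use presence/absence per neighborhood rather than raw gene
counts, so a tandem duplication within one window cannot inflate a rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datastore import Datastore, Gene, GenomeAnnotation, MetabolicReference
from .homology import HomologQuery, select_homologs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Neighborhood:
    """A window of genes around an anchor on one replicon."""

    anchor_gene_id: str
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        if self.anchor_gene_id not in {g.gene_id for g in self.genes}:
            raise ValueError("anchor missing from its own neighborhood")

    @property
    def ec_numbers(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.genes:
            out |= g.ec_numbers
        return frozenset(out)


@dataclass(frozen=True)
class EnzymeSummaryRow:
    ec: str
    frequency: int
    neighborhoods: tuple[str, ...]      # anchor gene ids where the EC occurs


@dataclass(frozen=True)
class MetaboliteSummaryRow:
    compound_id: str
    frequency: int
    neighborhoods: tuple[str, ...]


@dataclass(frozen=True)
class PathwaySummaryRow:
    pathway_id: str
    hits: int
    ecs: tuple[str, ...]                # summary ECs mapped to this pathway
    compounds: tuple[str, ...]          # summary compounds mapped to it


@dataclass
class AnalysisConfig:
    """Tunables of the neighborhood analysis.

    ``score_mode`` chooses how pathway hits are counted: ``weighted`` sums
    the neighborhood frequencies of every mapped enzyme and compound;
    ``distinct`` counts each mapped entity once.  ``exclude_compounds`` is an
    optional currency-metabolite blacklist applied to the metabolite table.
    """

    score_mode: str = "weighted"
    exclude_compounds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.score_mode not in ("weighted", "distinct"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        self.exclude_compounds = frozenset(
            c.strip().upper() for c in self.exclude_compounds)


#: currency metabolites commonly excluded from naive compound counts;
#: applied only when explicitly configured
CURRENCY_COMPOUNDS = frozenset({
    "C00001",  # H2O
    "C00002",  # ATP
    "C00003",  # NAD+
    "C00004",  # NADH
    "C00005",  # NADPH
    "C00006",  # NADP+
    "C00008",  # ADP
    "C00009",  # orthophosphate
    "C00011",  # CO2
    "C00013",  # diphosphate
    "C00080",  # H+
})


def extract_neighborhood(genome: GenomeAnnotation, anchor: str,
                         n_neighbors: int) -> Neighborhood:
    """Window of genes with replicon index in [i-n, i+n] around the anchor.

    Linear replicons truncate at their ends; circular replicons wrap around
    without ever duplicating a gene (the window is capped at the replicon
    size).
    """
    if n_neighbors < 0:
        raise ValueError("n_neighbors must be >= 0")
    gene = genome.genes.get(anchor)
    if gene is None:
        raise KeyError(f"anchor {anchor!r} not in genome {genome.org_code}")
    rep = genome.replicon(gene.replicon_id)
    size = len(rep.gene_order)
    i = gene.index
    if rep.topology == "circular":
        # modulo wrap; the set caps the window at the replicon size
        picked = sorted({k % size for k in range(i - n_neighbors,
                                                 i + n_neighbors + 1)})
    else:
        lo, hi = max(0, i - n_neighbors), min(size - 1, i + n_neighbors)
        picked = list(range(lo, hi + 1))
    genes = tuple(genome.genes[rep.gene_order[k]] for k in picked)
    return Neighborhood(anchor_gene_id=anchor, genes=genes)


def _rank(counter: dict[str, set[str]]) -> list[tuple[str, int, tuple[str, ...]]]:
    rows = [(key, len(anchors), tuple(sorted(anchors)))
            for key, anchors in counter.items()]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows


def summarize_enzymes(neighborhoods: list[Neighborhood]
                      ) -> list[EnzymeSummaryRow]:
    """Rank ECs by the number of distinct neighborhoods containing them."""
    counter: dict[str, set[str]] = {}
    for nb in neighborhoods:
        for ec in nb.ec_numbers:
            counter.setdefault(ec, set()).add(nb.anchor_gene_id)
    return [EnzymeSummaryRow(ec, freq, anchors)
            for ec, freq, anchors in _rank(counter)]


def summarize_metabolites(enzyme_summary: list[EnzymeSummaryRow],
                          neighborhoods: list[Neighborhood],
                          ref: MetabolicReference,
                          config: AnalysisConfig | None = None
                          ) -> list[MetaboliteSummaryRow]:
    """Rank the substrates/products of the summary enzymes by the number of
    distinct neighborhoods whose enzymes involve them."""
    if config is None:
        config = AnalysisConfig()
    compounds_of: dict[str, frozenset[str]] = {}
    for row in enzyme_summary:
        cpds = ref.compounds_of_ec(row.ec)
        if not ref.ec_to_reactions.get(row.ec):
            logger.info("EC %s has no reactions in the reference", row.ec)
        compounds_of[row.ec] = cpds
    counter: dict[str, set[str]] = {}
    for nb in neighborhoods:
        for ec in nb.ec_numbers:
            for cpd in compounds_of.get(ec, ()):
                if cpd in config.exclude_compounds:
                    continue
                counter.setdefault(cpd, set()).add(nb.anchor_gene_id)
    return [MetaboliteSummaryRow(cpd, freq, anchors)
            for cpd, freq, anchors in _rank(counter)]


def summarize_pathways(enzyme_summary: list[EnzymeSummaryRow],
                       metabolite_summary: list[MetaboliteSummaryRow],
                       ref: MetabolicReference,
                       config: AnalysisConfig | None = None
                       ) -> list[PathwaySummaryRow]:
    """Merge the enzyme and metabolite tables into a pathway ranking.

    In ``weighted`` mode (default) a pathway's hit count is the sum of the
    neighborhood frequencies of every summary EC and compound mapped to it;
    in ``distinct`` mode each mapped entity counts once.  Entities with no
    pathway mapping contribute nothing, so an empty table is a legal outcome
    even when the enzyme table is populated.
    """
    if config is None:
        config = AnalysisConfig()
    hits: dict[str, int] = {}
    ecs_of: dict[str, set[str]] = {}
    cpds_of: dict[str, set[str]] = {}
    for row in enzyme_summary:
        for pw in ref.ec_to_pathways.get(row.ec, ()):
            weight = row.frequency if config.score_mode == "weighted" else 1
            hits[pw] = hits.get(pw, 0) + weight
            ecs_of.setdefault(pw, set()).add(row.ec)
    for row in metabolite_summary:
        for pw in ref.compound_to_pathways.get(row.compound_id, ()):
            weight = row.frequency if config.score_mode == "weighted" else 1
            hits[pw] = hits.get(pw, 0) + weight
            cpds_of.setdefault(pw, set()).add(row.compound_id)
    rows = [PathwaySummaryRow(pw, n, tuple(sorted(ecs_of.get(pw, ()))),
                              tuple(sorted(cpds_of.get(pw, ()))))
            for pw, n in hits.items()]
    rows.sort(key=lambda r: (-r.hits, r.pathway_id))
    return rows


@dataclass
class AnalysisResult:
    """Everything one pipeline run produces, in report order."""

    query: HomologQuery
    homologs: list[str]
    neighborhoods: list[Neighborhood]
    enzyme_summary: list[EnzymeSummaryRow]
    metabolite_summary: list[MetaboliteSummaryRow]
    pathway_summary: list[PathwaySummaryRow]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    @property
    def top_pathway(self) -> str | None:
        return self.pathway_summary[0].pathway_id if self.pathway_summary else None


def run_analysis(query: HomologQuery, store: Datastore,
                 ref: MetabolicReference | None = None,
                 config: AnalysisConfig | None = None) -> AnalysisResult:
    """Full pipeline: homolog selection → neighborhoods → three summaries.

    Deterministic: identical inputs and configuration yield identical
    rankings (all sorts are stable with lexicographic tie-breaks).
    """
    if ref is None:
        ref = store.reference
    if config is None:
        config = AnalysisConfig()
    store.find_gene(query.query_gene_id)        # fail early if absent
    homologs = select_homologs(query, store.similarity)
    neighborhoods = []
    for gid in homologs:
        genome, _ = store.find_gene(gid)
        neighborhoods.append(
            extract_neighborhood(genome, gid, query.n_neighbors))
    enzymes = summarize_enzymes(neighborhoods)
    metabolites = summarize_metabolites(enzymes, neighborhoods, ref, config)
    pathways = summarize_pathways(enzymes, metabolites, ref, config)
    return AnalysisResult(query=query, homologs=homologs,
                          neighborhoods=neighborhoods,
                          enzyme_summary=enzymes,
                          metabolite_summary=metabolites,
                          pathway_summary=pathways, config=config)
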