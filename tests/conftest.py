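"""Shared builders: hand-made micro-datastores and a session-scoped
synthetic pangenome small enough for exhaustive recounts."""

from __future__ import annotations

import pytest

from funcdisc.datastore import (Datastore, Gene, GenomeAnnotation,
                                MetabolicReference, Replicon)
from funcdisc.fixtures import FixtureConfig, generate_pangenome


def make_genome(org: str, loci: list[dict], topology: str = "linear",
                replicon_id: str | None = None) -> GenomeAnnotation:
    """Build a genome from a list of gene descriptions (in gene order).

    Each entry may carry ``ec`` (list of EC strings), ``seq`` and ``product``.
    Coordinates are synthesized from the order.
    """
    rep_id = replicon_id or f"{org}_chr"
    genome = GenomeAnnotation(org_code=org)
    rep = Replicon(rep_id, topology)
    for i, spec in enumerate(loci):
        locus = spec.get("locus", f"b{i + 1:04d}")
        gid = f"{org}:{locus}"
        gene = Gene(gene_id=gid, replicon_id=rep_id, index=i,
                    start=i * 200, end=i * 200 + 150,
                    strand=spec.get("strand", "+"),
                    product=spec.get("product", ""),
                    ec_numbers=frozenset(spec.get("ec", ())))
        genome.genes[gid] = gene
        genome.proteome[gid] = spec.get("seq", "")
        rep.gene_order.append(gid)
    genome.replicons.append(rep)
    return genome


def make_reference(ec_reactions: dict[str, dict[str, tuple[list, list]]],
                   ec_pathways: dict[str, list[str]] | None = None,
                   compound_pathways: dict[str, list[str]] | None = None
                   ) -> MetabolicReference:
    """Reference from {ec: {reaction_id: (substrates, products)}} plus
    pathway link maps."""
    ref = MetabolicReference()
    for ec, rxns in ec_reactions.items():
        ref.ec_to_reactions[ec] = frozenset(rxns)
        for rid, (subs, prods) in rxns.items():
            ref.reactions[rid] = {"substrates": frozenset(subs),
                                  "products": frozenset(prods)}
    for ec, pws in (ec_pathways or {}).items():
        ref.ec_to_pathways[ec] = frozenset(pws)
    for cpd, pws in (compound_pathways or {}).items():
        ref.compound_to_pathways[cpd] = frozenset(pws)
    ref.validate()
    return ref


SMALL_CFG = FixtureConfig(n_genomes=6, genes_per_genome=30, cluster_size=3,
                          decoy_ec_count=6, conservation_prob=0.8,
                          rearrangement_rate=0.1, indel_rate=0.05, seed=7)


@pytest.fixture(scope="session")
def small_pangenome():
    """A 6-genome pangenome with honest BBH similarity; ~1 s to build."""
    return generate_pangenome(SMALL_CFG)


@pytest.fixture(scope="session")
def small_store(small_pangenome):
    return small_pangenome.as_datastore()
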