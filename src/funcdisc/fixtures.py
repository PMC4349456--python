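"""Seeded synthetic pangenomes with a planted TR-adjacent gene cluster.

The generator emulates the situation the pipeline is built for: a
transcriptional regulator (TR) whose orthologs recur across many genomes,
usually sitting next to a conserved cluster of enzyme genes that belong to
one metabolic pathway.  Real pangenomes are messy — gene clusters get
rearranged, deleted, and surrounded by unrelated genes — so the generator
perturbs the planted cluster per genome: with probability
``conservation_prob`` it stays intact next to the TR ortholog, otherwise it
is relocated to a random spot on the replicon or deleted outright, in
proportion to ``rearrangement_rate`` and ``indel_rate``.

Ortholog sequences are produced by mutating a shared ancestor at a per-site
substitution probability low enough that planted orthologs clear any
identity cutoff up to 90%; decoy genes get independent random sequences,
which stay far below the score floor of the similarity table.  Decoy EC
numbers, grouped into decoy pathways of the same size as the planted
cluster, are scattered uniformly so that a vanishing conservation
probability makes the planted pathway statistically indistinguishable from
the decoys.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datastore import (Datastore, Gene, GenomeAnnotation, MetabolicReference,
                        Replicon, SimilarityRecord)
from .homology import ScoringScheme, best_best_hits

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic pangenome.

    ``conservation_prob`` is the per-genome probability that the planted
    cluster sits intact immediately next to the TR ortholog; otherwise the
    cluster is relocated or deleted with odds ``rearrangement_rate`` :
    ``indel_rate``.  ``protein_length`` and ``substitution_prob`` control
    ortholog divergence (~3% substitutions keeps identity near 97%).
    """

    n_genomes: int = 20
    genes_per_genome: int = 45
    cluster_size: int = 4
    conservation_prob: float = 0.8
    rearrangement_rate: float = 0.1
    indel_rate: float = 0.05
    planted_pathway_id: str = "PWY_PLANTED"
    decoy_ec_count: int = 8
    seed: int = 0
    protein_length: int = 50
    substitution_prob: float = 0.03
    topology: str = "circular"

    def __post_init__(self) -> None:
        for name in ("conservation_prob", "rearrangement_rate", "indel_rate",
                     "substitution_prob"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.cluster_size >= self.genes_per_genome:
            raise ValueError("cluster does not fit in the genome")
        if self.n_genomes < 1 or self.genes_per_genome < 2:
            raise ValueError("need at least one genome of at least two genes")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class SyntheticPangenome:
    """A generated pangenome plus the ground truth planted into it."""

    config: FixtureConfig
    genomes: list[GenomeAnnotation]
    similarity: list[SimilarityRecord]
    reference: MetabolicReference
    query_gene_id: str                      # TR gene of the first genome
    tr_genes: dict[str, str]                # org -> TR gene id
    cluster_fate: dict[str, str]            # org -> conserved|relocated|deleted
    planted_ecs: tuple[str, ...]
    decoy_ecs: tuple[str, ...] = ()

    @property
    def planted_pathway_id(self) -> str:
        return self.config.planted_pathway_id

    def as_datastore(self) -> Datastore:
        store = Datastore(reference=self.reference, similarity=self.similarity)
        for genome in self.genomes:
            store.add_genome(genome)
        return store


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def _mutate(seq: str, prob: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < prob:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _build_reference(cfg: FixtureConfig,
                     planted_ecs: list[str],
                     decoy_ecs: list[str]) -> MetabolicReference:
    ref = MetabolicReference()

    def add(ec: str, tag: str, pathway: str) -> None:
        rid = f"R{tag}"
        sub, prod = f"C{tag}S", f"C{tag}P"
        ref.ec_to_reactions[ec] = frozenset({rid})
        ref.reactions[rid] = {"substrates": frozenset({sub}),
                              "products": frozenset({prod})}
        ref.ec_to_pathways[ec] = frozenset({pathway})
        for cpd in (sub, prod):
            ref.compound_to_pathways[cpd] = frozenset({pathway})

    pw = cfg.planted_pathway_id.upper()
    ref.names[pw] = "planted pathway"
    for j, ec in enumerate(planted_ecs):
        add(ec, f"P{j:02d}", pw)
    # decoy pathways hold the same number of ECs as the planted cluster so
    # that, absent conservation, no pathway is structurally favored
    for k, ec in enumerate(decoy_ecs):
        dpw = f"PWY_DECOY{k // cfg.cluster_size}"
        ref.names.setdefault(dpw, "decoy pathway")
        add(ec, f"D{k:02d}", dpw)
    return ref


def _place_cluster(rng: np.random.Generator, cfg: FixtureConfig,
                   tr_slot: int) -> tuple[str, list[int]]:
    """Decide the cluster's fate and slots for one genome."""
    n, c = cfg.genes_per_genome, cfg.cluster_size
    if rng.random() < cfg.conservation_prob:
        if cfg.topology == "circular":
            slots = [(tr_slot + 1 + j) % n for j in range(c)]
        elif tr_slot + c < n:
            slots = [tr_slot + 1 + j for j in range(c)]
        else:
            slots = [tr_slot - c + j for j in range(c)]
        return "conserved", slots
    total = cfg.rearrangement_rate + cfg.indel_rate
    p_delete = cfg.indel_rate / total if total > 0 else 0.0
    if rng.random() < p_delete:
        return "deleted", []
    # relocate: contiguous block anywhere that avoids the TR slot
    for _ in range(200):
        s = int(rng.integers(0, n))
        slots = [(s + j) % n if cfg.topology == "circular"
                 else min(s, n - c) + j for j in range(c)]
        if tr_slot not in slots:
            return "relocated", slots
    return "deleted", []    # degenerate genome: nowhere to relocate to


def generate_pangenome(cfg: FixtureConfig,
                       scoring: ScoringScheme | None = None
                       ) -> SyntheticPangenome:
    """Generate genomes, the similarity table, and the metabolic reference.

    The similarity table is computed honestly, by running bidirectional
    best-hit Smith-Waterman over the generated proteomes with the default
    scoring scheme.
    """
    rng = np.random.default_rng(cfg.seed)
    if scoring is None:
        scoring = ScoringScheme()

    planted_ecs = [f"1.1.1.{101 + j}" for j in range(cfg.cluster_size)]
    decoy_ecs = [f"9.9.9.{1 + k}" for k in range(cfg.decoy_ec_count)]
    ref = _build_reference(cfg, planted_ecs, decoy_ecs)

    tr_ancestor = _random_protein(rng, cfg.protein_length)
    cluster_ancestors = [_random_protein(rng, cfg.protein_length)
                         for _ in range(cfg.cluster_size)]

    genomes: list[GenomeAnnotation] = []
    tr_genes: dict[str, str] = {}
    cluster_fate: dict[str, str] = {}
    n, L = cfg.genes_per_genome, cfg.protein_length
    for g in range(cfg.n_genomes):
        org = f"g{g:02d}"
        tr_slot = int(rng.integers(0, n))
        fate, cluster_slots = _place_cluster(rng, cfg, tr_slot)
        cluster_fate[org] = fate

        role: dict[int, tuple[str, str, str | None]] = {}
        role[tr_slot] = ("trreg", "transcriptional regulator, TetR family", None)
        for j, slot in enumerate(cluster_slots):
            role[slot] = (f"clu{j}", f"planted cluster enzyme {j}",
                          planted_ecs[j])
        decoy_slots = [s for s in range(n) if s not in role]
        # scatter each decoy EC onto one decoy gene per genome
        chosen = rng.choice(len(decoy_slots), size=min(len(decoy_slots),
                                                       cfg.decoy_ec_count),
                            replace=False)
        decoy_ec_at = {decoy_slots[int(c)]: decoy_ecs[k]
                       for k, c in enumerate(chosen)}

        genome = GenomeAnnotation(org_code=org)
        rep = Replicon(f"{org}_chr", cfg.topology)
        for slot in range(n):
            locus = f"b{slot + 1:04d}"
            gid = f"{org}:{locus}"
            kind, product, ec = role.get(
                slot, ("decoy", "hypothetical protein", decoy_ec_at.get(slot)))
            if kind == "trreg":
                seq = _mutate(tr_ancestor, cfg.substitution_prob, rng)
                tr_genes[org] = gid
            elif kind.startswith("clu"):
                j = int(kind[3:])
                seq = _mutate(cluster_ancestors[j], cfg.substitution_prob, rng)
            else:
                seq = _random_protein(rng, L)
            start0 = slot * (3 * L + 50)
            gene = Gene(gene_id=gid, replicon_id=rep.replicon_id, index=slot,
                        start=start0, end=start0 + 3 * L,
                        strand="+" if rng.random() < 0.5 else "-",
                        product=product,
                        ec_numbers=frozenset({ec} if ec else ()))
            genome.genes[gid] = gene
            genome.proteome[gid] = seq
            rep.gene_order.append(gid)
        genome.replicons.append(rep)
        genomes.append(genome)

    similarity = (best_best_hits(genomes, scoring)
                  if cfg.n_genomes >= 2 else [])
    return SyntheticPangenome(
        config=cfg, genomes=genomes, similarity=similarity, reference=ref,
        query_gene_id=tr_genes["g00"], tr_genes=tr_genes,
        cluster_fate=cluster_fate, planted_ecs=tuple(planted_ecs),
        decoy_ecs=tuple(decoy_ecs))


def write_fixture(cfg: FixtureConfig, out_dir: str | Path,
                  scoring: ScoringScheme | None = None) -> SyntheticPangenome:
    """Generate a pangenome and write it in the exact formats the datastore
    reads (GFF3 + FASTA per genome, similarity TSV, reference JSON)."""
    pan = generate_pangenome(cfg, scoring)
    pan.as_datastore().write_directory(out_dir)
    meta = Path(out_dir) / "fixture.txt"
    meta.write_text(
        "synthetic pangenome fixture\n"
        f"query_gene_id\t{pan.query_gene_id}\n"
        f"planted_pathway_id\t{pan.planted_pathway_id.upper()}\n"
        f"seed\t{cfg.seed}\n")
    return pan
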