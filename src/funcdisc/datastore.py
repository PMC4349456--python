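"""Data model and on-disk formats for the genome-context datastore.

The pipeline never talks to a live database: everything it needs — per-genome
gene annotations, protein sequences, a pairwise similarity table, and a
metabolic reference linking EC numbers to reactions, compounds and pathways —
is read from local files.  Genome annotations are accepted either as GFF3
(CDS features with ``locus_tag``, optional ``eC_number`` and ``product``
attributes) or as a simple tabular dialect; both go through one validator.

Coordinates are 1-based inclusive on disk (the GFF3 convention) and stored
0-based half-open in memory.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: minimum Smith-Waterman score for a pair to be kept in the similarity table
SW_SCORE_FLOOR = 100


class DatastoreError(ValueError):
    """Raised for malformed or inconsistent datastore inputs."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene positioned on a replicon.

    ``start``/``end`` are 0-based half-open; ``index`` is the rank of the
    gene along its replicon in start-coordinate order.
    """

    gene_id: str            # "org:locus_tag"
    replicon_id: str
    index: int
    start: int
    end: int
    strand: str             # "+" or "-"
    product: str = ""
    ec_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DatastoreError(
                f"{self.gene_id}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise DatastoreError(f"{self.gene_id}: bad strand {self.strand!r}")
        for ec in self.ec_numbers:
            if not EC_PATTERN.match(ec):
                raise DatastoreError(f"{self.gene_id}: malformed EC {ec!r}")

    @property
    def locus_tag(self) -> str:
        return self.gene_id.split(":", 1)[1]


@dataclass
class Replicon:
    """A chromosome or plasmid; topology matters for neighborhood windows."""

    replicon_id: str
    topology: str = "linear"      # "linear" | "circular"
    gene_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise DatastoreError(f"unknown topology {self.topology!r}")


@dataclass
class GenomeAnnotation:
    """One genome: ordered genes on replicons plus the proteome."""

    org_code: str
    replicons: list[Replicon] = field(default_factory=list)
    genes: dict[str, Gene] = field(default_factory=dict)
    proteome: dict[str, str] = field(default_factory=dict)

    def replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.replicon_id == replicon_id:
                return rep
        raise KeyError(replicon_id)

    def sequence(self, gene_id: str) -> str:
        return self.proteome.get(gene_id, "")


@dataclass(frozen=True)
class SimilarityRecord:
    """A scored protein pair between two genomes.

    The pair is unordered: it is canonicalized so gene_a < gene_b
    lexicographically, mirroring a similarity database that stores one entry
    per gene pair with symmetric semantics.
    """

    gene_a: str
    gene_b: str
    sw_score: int
    pct_identity: float
    best_best: bool

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DatastoreError(f"self-pair {self.gene_a}")
        if self.gene_a.split(":", 1)[0] == self.gene_b.split(":", 1)[0]:
            raise DatastoreError(
                f"pair within one genome: {self.gene_a}, {self.gene_b}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)
        if self.sw_score < 0:
            raise DatastoreError(f"negative score for {self.gene_a}/{self.gene_b}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise DatastoreError(
                f"pct_identity {self.pct_identity} outside [0, 100]")

    def partner_of(self, gene_id: str) -> str | None:
        if gene_id == self.gene_a:
            return self.gene_b
        if gene_id == self.gene_b:
            return self.gene_a
        return None


@dataclass
class MetabolicReference:
    """Local EC → reaction → compound → pathway link tables.

    A faithful stand-in for the slice of a metabolic database the pipeline
    needs: which reactions an enzyme catalyzes, which compounds those
    reactions consume and produce, and which pathways enzymes and compounds
    belong to.  An EC may legitimately be absent from ``ec_to_pathways``
    (transport ATPases are a classic case), in which case it can never
    contribute to a pathway ranking.
    """

    ec_to_reactions: dict[str, frozenset[str]] = field(default_factory=dict)
    reactions: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    ec_to_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    compound_to_pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def compounds_of_ec(self, ec: str) -> frozenset[str]:
        """Union of substrates and products over all reactions of ``ec``."""
        out: set[str] = set()
        for rid in self.ec_to_reactions.get(ec, ()):
            rxn = self.reactions.get(rid)
            if rxn is None:
                continue
            out |= rxn["substrates"] | rxn["products"]
        return frozenset(out)

    def validate(self) -> None:
        for ec, rids in self.ec_to_reactions.items():
            for rid in rids:
                if rid not in self.reactions:
                    raise DatastoreError(
                        f"EC {ec} references unknown reaction {rid}")


# ---------------------------------------------------------------------------
# genome readers

def _norm_strand(raw: str) -> str:
    return "-" if raw in ("-", "−") else "+"


def _validated_gene_rows(rows: Iterable[dict], org_code: str) -> list[dict]:
    """Shared validator for both annotation dialects.

    Rows carry 1-based inclusive coordinates; conversion to half-open happens
    here.  A row with a malformed EC string is skipped with a warning; a
    duplicate locus_tag is a hard error.
    """
    seen: set[str] = set()
    out: list[dict] = []
    for row in rows:
        locus = row["locus_tag"].strip()
        if not locus:
            raise DatastoreError("CDS without locus_tag")
        if locus in seen:
            raise DatastoreError(f"duplicate locus_tag {locus!r}")
        seen.add(locus)
        ecs = {e.strip() for e in row.get("ec_numbers", ()) if e.strip()}
        bad = [e for e in ecs if not EC_PATTERN.match(e)]
        if bad:
            logger.warning("%s: malformed EC %s — record skipped", locus, bad)
            continue
        start1, end1 = int(row["start"]), int(row["end"])
        if start1 > end1:      # tolerate swapped coordinates on input
            start1, end1 = end1, start1
        out.append(dict(
            locus_tag=locus,
            replicon_id=row["replicon_id"],
            start=start1 - 1,
            end=end1,
            strand=_norm_strand(row.get("strand", "+")),
            product=row.get("product", ""),
            ec_numbers=frozenset(ecs),
        ))
    return out


def _assemble(org_code: str, rows: list[dict],
              topologies: Mapping[str, str],
              proteome_path: str | Path | None) -> GenomeAnnotation:
    proteome_raw: dict[str, str] = {}
    if proteome_path is not None:
        for rec in SeqIO.parse(str(proteome_path), "fasta"):
            seq = str(rec.seq).upper()
            unknown = set(seq) - AA_ALPHABET
            if unknown:
                seq = "".join(c if c in AA_ALPHABET else "X" for c in seq)
            proteome_raw[rec.id] = seq

    genome = GenomeAnnotation(org_code=org_code)
    by_rep: dict[str, list[dict]] = {}
    for row in rows:
        by_rep.setdefault(row["replicon_id"], []).append(row)
    for rep_id in sorted(by_rep):
        rep_rows = sorted(by_rep[rep_id], key=lambda r: (r["start"], r["locus_tag"]))
        rep = Replicon(rep_id, topologies.get(rep_id, "linear"))
        for idx, row in enumerate(rep_rows):
            gene_id = f"{org_code}:{row['locus_tag']}"
            gene = Gene(gene_id=gene_id, replicon_id=rep_id, index=idx,
                        start=row["start"], end=row["end"],
                        strand=row["strand"], product=row["product"],
                        ec_numbers=row["ec_numbers"])
            genome.genes[gene_id] = gene
            rep.gene_order.append(gene_id)
            seq = proteome_raw.get(row["locus_tag"], "")
            if proteome_path is not None and not seq:
                logger.warning("%s: no protein sequence in proteome, kept empty",
                               gene_id)
            genome.proteome[gene_id] = seq
        genome.replicons.append(rep)
    return genome


_TOPOLOGY_PRAGMA = re.compile(r"^##sequence-topology\s+(\S+)\s+(linear|circular)")


def _parse_gff3(path: Path) -> tuple[list[dict], dict[str, str]]:
    rows: list[dict] = []
    topologies: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                m = _TOPOLOGY_PRAGMA.match(line)
                if m:
                    topologies[m.group(1)] = m.group(2)
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DatastoreError(f"malformed GFF3 line: {line[:60]!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            attr = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                key, _, val = item.partition("=")
                # GFF3: commas separate multiple values; literal ';,=%' in a
                # value are percent-encoded
                attr.setdefault(key, []).extend(
                    unquote(v) for v in val.split(","))
            if "Is_circular" in attr and attr["Is_circular"][0] == "true":
                topologies[seqid] = "circular"
            rows.append(dict(
                replicon_id=seqid,
                locus_tag=(attr.get("locus_tag") or [""])[0],
                start=start, end=end, strand=strand,
                product=(attr.get("product") or [""])[0],
                ec_numbers=attr.get("eC_number", []),
            ))
    return rows, topologies


_TSV_COLUMNS = ["replicon_id", "locus_tag", "start", "end",
                "strand", "product", "ec_numbers"]


def _parse_gene_tsv(path: Path) -> tuple[list[dict], dict[str, str]]:
    topologies: dict[str, str] = {}
    with open(path) as fh:
        body = []
        for line in fh:
            m = _TOPOLOGY_PRAGMA.match(line)
            if m:
                topologies[m.group(1)] = m.group(2)
            elif line.strip() and not line.startswith("#"):
                body.append(line)
    df = pd.read_csv(pd.io.common.StringIO("".join(body)), sep="\t",
                     dtype=str, keep_default_na=False)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise DatastoreError(f"gene table missing columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        rec["ec_numbers"] = [e for e in rec["ec_numbers"].split(";") if e]
        rows.append(rec)
    return rows, topologies


def load_genome(annotation_path: str | Path,
                proteome_path: str | Path | None = None,
                org_code: str | None = None) -> GenomeAnnotation:
    """Load one genome from GFF3 or the tabular dialect plus a FASTA proteome.

    ``org_code`` defaults to the annotation file stem.  Genes are ordered by
    start coordinate within each replicon regardless of input row order, and
    ``Gene.index`` is assigned from that order.  Genes lacking a protein
    sequence are retained with an empty sequence (a warning is logged).
    """
    annotation_path = Path(annotation_path)
    if org_code is None:
        org_code = annotation_path.stem.split(".")[0]
    suffix = annotation_path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        rows, topologies = _parse_gff3(annotation_path)
    else:
        rows, topologies = _parse_gene_tsv(annotation_path)
    rows = _validated_gene_rows(rows, org_code)
    return _assemble(org_code, rows, topologies, proteome_path)


def write_genome(genome: GenomeAnnotation, annotation_path: str | Path,
                 proteome_path: str | Path | None = None) -> None:
    """Write a genome back to GFF3 (+FASTA proteome), deterministically."""
    lines = ["##gff-version 3"]
    for rep in genome.replicons:
        lines.append(f"##sequence-topology {rep.replicon_id} {rep.topology}")
    for rep in genome.replicons:
        for gid in rep.gene_order:
            g = genome.genes[gid]
            attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
            if g.product:
                attrs.append(f"product={quote(g.product, safe=' .:_()/-')}")
            for ec in sorted(g.ec_numbers):
                attrs.append(f"eC_number={ec}")
            lines.append("\t".join([
                rep.replicon_id, "funcdisc", "CDS",
                str(g.start + 1), str(g.end), ".", g.strand, "0",
                ";".join(attrs)]))
    Path(annotation_path).write_text("\n".join(lines) + "\n")
    if proteome_path is not None:
        with open(proteome_path, "w") as fh:
            for rep in genome.replicons:
                for gid in rep.gene_order:
                    seq = genome.proteome.get(gid, "")
                    if seq:
                        fh.write(f">{genome.genes[gid].locus_tag}\n{seq}\n")


# ---------------------------------------------------------------------------
# metabolic reference

def _norm_id(raw: str) -> str:
    return raw.strip().upper()


def _as_id_set(values: Iterable[str]) -> frozenset[str]:
    out = frozenset(_norm_id(v) for v in values if v.strip())
    if any(not v for v in out):
        raise DatastoreError("empty id in reference table")
    return out


def load_reference(path: str | Path) -> MetabolicReference:
    """Load the metabolic reference from JSON (or the TSV link-table dialect).

    Ids are normalized (uppercased, whitespace stripped).  An EC present in
    the reaction map but absent from the pathway map loads cleanly: the
    pathway tables simply lack the key.  A reaction with neither substrates
    nor products is retained with a warning.
    """
    path = Path(path)
    text = path.read_text()
    ref = MetabolicReference()
    if not text.strip():
        return ref
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        doc = json.loads(text)
        for ec, rids in doc.get("ec_to_reactions", {}).items():
            ref.ec_to_reactions[_norm_id(ec)] = _as_id_set(rids)
        for rid, rxn in doc.get("reactions", {}).items():
            ref.reactions[_norm_id(rid)] = {
                "substrates": _as_id_set(rxn.get("substrates", [])),
                "products": _as_id_set(rxn.get("products", [])),
            }
        for ec, pids in doc.get("ec_to_pathways", {}).items():
            ref.ec_to_pathways[_norm_id(ec)] = _as_id_set(pids)
        for cid, pids in doc.get("compound_to_pathways", {}).items():
            ref.compound_to_pathways[_norm_id(cid)] = _as_id_set(pids)
        for key, name in doc.get("names", {}).items():
            ref.names[_norm_id(key)] = str(name)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         comment="#")
        acc: dict[str, dict[str, set[str]]] = {
            "ec_reaction": {}, "ec_pathway": {}, "compound_pathway": {}}
        rxn_acc: dict[str, dict[str, set[str]]] = {}
        for rec in df.to_dict("records"):
            kind = rec["link_type"]
            src, dst = _norm_id(rec["source"]), rec["target"].strip()
            if kind == "name":
                ref.names[src] = dst
            elif kind == "reaction_compound":
                role = rec.get("role", "").strip()
                if role not in ("substrate", "product"):
                    raise DatastoreError(f"bad role {role!r} for {src}")
                rxn_acc.setdefault(src, {"substrate": set(), "product": set()})
                rxn_acc[src][role].add(_norm_id(dst))
            elif kind in acc:
                acc[kind].setdefault(src, set()).add(_norm_id(dst))
            else:
                raise DatastoreError(f"unknown link_type {kind!r}")
        ref.ec_to_reactions = {k: frozenset(v) for k, v in acc["ec_reaction"].items()}
        ref.ec_to_pathways = {k: frozenset(v) for k, v in acc["ec_pathway"].items()}
        ref.compound_to_pathways = {
            k: frozenset(v) for k, v in acc["compound_pathway"].items()}
        ref.reactions = {
            rid: {"substrates": frozenset(d["substrate"]),
                  "products": frozenset(d["product"])}
            for rid, d in rxn_acc.items()}
    for rid, rxn in ref.reactions.items():
        if not rxn["substrates"] and not rxn["products"]:
            logger.warning("reaction %s has no substrates and no products", rid)
    ref.validate()
    return ref


def write_reference(ref: MetabolicReference, path: str | Path) -> None:
    doc = {
        "ec_to_reactions": {k: sorted(v) for k, v in sorted(ref.ec_to_reactions.items())},
        "reactions": {k: {"substrates": sorted(v["substrates"]),
                          "products": sorted(v["products"])}
                      for k, v in sorted(ref.reactions.items())},
        "ec_to_pathways": {k: sorted(v) for k, v in sorted(ref.ec_to_pathways.items())},
        "compound_to_pathways": {k: sorted(v)
                                 for k, v in sorted(ref.compound_to_pathways.items())},
        "names": dict(sorted(ref.names.items())),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# similarity table

_SIM_COLUMNS = ["gene_a", "gene_b", "sw_score", "pct_identity", "best_best"]


def write_similarity_table(records: Iterable[SimilarityRecord],
                           path: str | Path) -> None:
    rows = sorted((r.gene_a, r.gene_b, r.sw_score, f"{r.pct_identity:.4f}",
                   int(r.best_best)) for r in records)
    df = pd.DataFrame(rows, columns=_SIM_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def load_similarity_table(path: str | Path) -> list[SimilarityRecord]:
    """Load the similarity table; pairs scoring below the floor of 100 are
    dropped with a warning, mirroring a database that only stores pairs with
    a Smith-Waterman score of at least 100."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = set(_SIM_COLUMNS) - set(df.columns)
    if missing:
        raise DatastoreError(f"similarity table missing columns {sorted(missing)}")
    out: list[SimilarityRecord] = []
    seen: set[tuple[str, str]] = set()
    for rec in df.to_dict("records"):
        score = int(rec["sw_score"])
        if score < SW_SCORE_FLOOR:
            logger.warning("dropping %s/%s: score %d below floor %d",
                           rec["gene_a"], rec["gene_b"], score, SW_SCORE_FLOOR)
            continue
        record = SimilarityRecord(rec["gene_a"], rec["gene_b"], score,
                                  float(rec["pct_identity"]),
                                  bool(int(rec["best_best"])))
        key = (record.gene_a, record.gene_b)
        if key in seen:
            raise DatastoreError(f"duplicate pair {key}")
        seen.add(key)
        out.append(record)
    return out


# ---------------------------------------------------------------------------
# directory-level datastore

@dataclass
class Datastore:
    """A directory of genomes plus similarity table and metabolic reference."""

    genomes: dict[str, GenomeAnnotation] = field(default_factory=dict)
    similarity: list[SimilarityRecord] = field(default_factory=list)
    reference: MetabolicReference = field(default_factory=MetabolicReference)

    def add_genome(self, genome: GenomeAnnotation) -> None:
        if genome.org_code in self.genomes:
            raise DatastoreError(f"duplicate org code {genome.org_code}")
        self.genomes[genome.org_code] = genome

    def find_gene(self, gene_id: str) -> tuple[GenomeAnnotation, Gene]:
        org = gene_id.split(":", 1)[0]
        genome = self.genomes.get(org)
        if genome is None or gene_id not in genome.genes:
            raise KeyError(f"gene {gene_id!r} not in datastore")
        return genome, genome.genes[gene_id]

    @classmethod
    def load_directory(cls, directory: str | Path) -> "Datastore":
        """Read ``<org>.gff3`` + ``<org>.faa`` pairs, ``similarity.tsv`` and
        ``reference.json`` from one directory."""
        directory = Path(directory)
        store = cls()
        for gff in sorted(directory.glob("*.gff3")):
            faa = gff.with_suffix(".faa")
            store.add_genome(load_genome(gff, faa if faa.exists() else None))
        sim = directory / "similarity.tsv"
        if sim.exists():
            store.similarity = load_similarity_table(sim)
        refp = directory / "reference.json"
        if refp.exists():
            store.reference = load_reference(refp)
        return store

    def write_directory(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for org, genome in sorted(self.genomes.items()):
            write_genome(genome, directory / f"{org}.gff3",
                         directory / f"{org}.faa")
        write_similarity_table(self.similarity, directory / "similarity.tsv")
        write_reference(self.reference, directory / "reference.json")
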