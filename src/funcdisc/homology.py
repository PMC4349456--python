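"""Protein similarity, bidirectional best hits, and homolog selection.

The homolog set for a query regulator is built the way classic sequence
similarity databases build theirs: all-vs-all Smith-Waterman local alignment
between genome pairs, retention of pairs scoring at least 100, and
bidirectional-best-hit (BBH) flags as the orthology proxy.  Selecting the
homologs of a query then amounts to taking its BBH partners that pass an
amino-acid identity cutoff (aa-IDc), at most one per genome.

Alignment itself is delegated to Biopython's ``PairwiseAligner`` (Gotoh
affine-gap local alignment).  Gap costs follow the BLAST convention: a gap of
length *k* costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .datastore import (AA_ALPHABET, GenomeAnnotation, SimilarityRecord,
                        SW_SCORE_FLOOR)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix and affine gap penalties for local alignment.

    Defaults are BLOSUM62 with gap open 11, extend 1 — the de facto standard
    for protein database search.  ``sw_floor`` is the minimum score a pair
    must reach to enter the similarity table.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    sw_floor: int = SW_SCORE_FLOOR
    _matrix_path: str | None = None
    _matrix_obj: object | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "ScoringScheme":
        """Use a substitution matrix in NCBI text format from ``path``."""
        return cls(matrix_name=Path(path).stem, _matrix_path=str(path), **kwargs)

    @classmethod
    def simple(cls, match: float, mismatch: float,
               gap_open: int, gap_extend: int, **kwargs) -> "ScoringScheme":
        """Uniform match/mismatch matrix over the amino-acid alphabet."""
        alphabet = "".join(sorted(AA_ALPHABET))
        arr = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                arr[a, b] = match if a == b else mismatch
        return cls(matrix_name=f"simple({match},{mismatch})",
                   gap_open=gap_open, gap_extend=gap_extend,
                   _matrix_obj=arr, **kwargs)

    @cached_property
    def matrix(self):
        if self._matrix_obj is not None:
            return self._matrix_obj
        if self._matrix_path is not None:
            return substitution_matrices.read(self._matrix_path)
        return substitution_matrices.load(self.matrix_name)

    @cached_property
    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # Biopython charges open_gap_score for the first gap position and
        # extend_gap_score for each subsequent one; shift so that a length-k
        # gap costs gap_open + k * gap_extend (BLAST convention).
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def sanitize(self, seq: str) -> str:
        alphabet = set(str(self.matrix.alphabet))
        return "".join(c if c in alphabet else "X" for c in seq.upper())

    def column_score(self, a: str, b: str) -> float:
        """Score of one alignment column (used to re-check tracebacks)."""
        return float(self.matrix[a, b])


@dataclass(frozen=True)
class AlignmentResult:
    """An optimal local alignment with its traceback."""

    score: int
    aligned_a: str
    aligned_b: str
    pct_identity: float
    start_a: int
    end_a: int
    start_b: int
    end_b: int

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class HomologQuery:
    """Parameters of a homolog search: how many genes, how wide a window,
    how strict an identity cutoff."""

    query_gene_id: str
    n_homologs: int = 100
    aa_idc: float = 40.0
    n_neighbors: int = 10

    def __post_init__(self) -> None:
        if self.n_homologs < 1:
            raise ValueError("n_homologs must be positive")
        if not 0.0 < self.aa_idc <= 100.0:
            raise ValueError("aa_idc must be in (0, 100]")
        if self.n_neighbors < 0:
            raise ValueError("n_neighbors must be >= 0")


def _percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical columns over full alignment length (gap columns count in
    the denominator), times 100."""
    if not aligned_a:
        return 0.0
    same = sum(1 for x, y in zip(aligned_a, aligned_b)
               if x == y and x != "-")
    return 100.0 * same / len(aligned_a)


def smith_waterman(seq_a: str, seq_b: str,
                   scoring: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal affine-gap local alignment of two protein sequences.

    Residues outside the matrix alphabet are scored via its X column.  Ties
    among optimal tracebacks are broken by taking the aligner's first
    reported alignment; the score is unique regardless.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    sa, sb = scoring.sanitize(seq_a), scoring.sanitize(seq_b)
    alignments = scoring.aligner.align(sa, sb)
    aln = alignments[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    return AlignmentResult(
        score=int(round(aln.score)),
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        pct_identity=_percent_identity(aligned_a, aligned_b),
        start_a=int(coords[0][0]), end_a=int(coords[0][-1]),
        start_b=int(coords[1][0]), end_b=int(coords[1][-1]),
    )


def sw_score(seq_a: str, seq_b: str, scoring: ScoringScheme) -> int:
    """Alignment score only — much faster than a full traceback."""
    return int(round(scoring.aligner.score(scoring.sanitize(seq_a),
                                           scoring.sanitize(seq_b))))


def best_best_hits(genomes: list[GenomeAnnotation],
                   scoring: ScoringScheme | None = None
                   ) -> list[SimilarityRecord]:
    """All-vs-all best hits between every genome pair, with BBH flags.

    For each ordered genome pair (A, B) and each gene *a* in A, the
    best-scoring partner *b* in B is recorded (ties broken by gene id); the
    record is flagged ``best_best`` iff *a* is also *b*'s best in A.  Only
    pairs reaching ``scoring.sw_floor`` are retained.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if len(genomes) < 2:
        raise ValueError("best_best_hits needs at least two genomes")
    records: dict[tuple[str, str], SimilarityRecord] = {}
    prepped = []
    for genome in genomes:
        seqs = [(gid, scoring.sanitize(seq))
                for gid, seq in sorted(genome.proteome.items()) if seq]
        if not seqs:
            logger.warning("genome %s has an empty proteome; skipped",
                           genome.org_code)
            continue
        prepped.append((genome.org_code, seqs))

    aligner = scoring.aligner
    for i in range(len(prepped)):
        for j in range(i + 1, len(prepped)):
            _, seqs_a = prepped[i]
            _, seqs_b = prepped[j]
            scores = [[aligner.score(sa, sb) for _, sb in seqs_b]
                      for _, sa in seqs_a]
            # directional best hits; ties -> lexicographically first gene id
            best_in_b = [min(range(len(seqs_b)),
                             key=lambda k: (-scores[ai][k], seqs_b[k][0]))
                         for ai in range(len(seqs_a))]
            best_in_a = [min(range(len(seqs_a)),
                             key=lambda k: (-scores[k][bi], seqs_a[k][0]))
                         for bi in range(len(seqs_b))]
            pairs = {(ai, best_in_b[ai]) for ai in range(len(seqs_a))}
            pairs |= {(best_in_a[bi], bi) for bi in range(len(seqs_b))}
            for ai, bi in sorted(pairs):
                score = int(round(scores[ai][bi]))
                if score < scoring.sw_floor:
                    continue
                gid_a, seq_a = seqs_a[ai]
                gid_b, seq_b = seqs_b[bi]
                mutual = best_in_b[ai] == bi and best_in_a[bi] == ai
                aln = smith_waterman(seq_a, seq_b, scoring)
                rec = SimilarityRecord(gid_a, gid_b, score,
                                       aln.pct_identity, mutual)
                records[(rec.gene_a, rec.gene_b)] = rec
    return [records[k] for k in sorted(records)]


def select_homologs(query: HomologQuery,
                    records: list[SimilarityRecord]) -> list[str]:
    """Pick the homolog set for a query gene from a similarity table.

    Candidates are the query's bidirectional best hits with percent identity
    at or above the aa-IDc, at most one per genome; they are ranked by score
    (descending, ties by gene id) and truncated to ``n_homologs``.  The query
    itself heads the list — its own neighborhood is always analyzed — so the
    result can legitimately be shorter than ``n_homologs + 1`` when few genes
    pass the cutoff.
    """
    qid = query.query_gene_id
    per_org: dict[str, tuple[int, str]] = {}
    for rec in records:
        partner = rec.partner_of(qid)
        if partner is None or not rec.best_best:
            continue
        if rec.pct_identity < query.aa_idc:
            continue
        org = partner.split(":", 1)[0]
        cand = (-rec.sw_score, partner)
        if org not in per_org or cand < per_org[org]:
            per_org[org] = cand
    ranked = [gid for _, gid in sorted(per_org.values())]
    return [qid] + ranked[: query.n_homologs]
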