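"""Independent reference implementations used only to check the package.

These are deliberately written from first principles — plain-Python dynamic
programming, brute-force recounts, grid searches — and never share code with
the implementation they verify.
"""

from __future__ import annotations

import numpy as np


def sw_score_oracle(seq_a: str, seq_b: str, score_fn,
                    gap_open: float, gap_extend: float) -> float:
    """Exhaustive affine-gap local-alignment DP (Gotoh three-state).

    A gap of length k costs ``gap_open + k * gap_extend``.  Returns the
    optimal local score; an optimal local alignment never ends in a gap, so
    maximizing over match-state cells is sufficient.
    """
    n, m = len(seq_a), len(seq_b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in seq_b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in seq_a
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = diag + score_fn(seq_a[i - 1], seq_b[j - 1])
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return best


def neighborhood_members_oracle(size: int, anchor_index: int, n_neighbors: int,
                                circular: bool) -> set[int]:
    """Window membership by distance, checked gene by gene."""
    members = set()
    for j in range(size):
        if circular:
            d = min(abs(j - anchor_index), size - abs(j - anchor_index))
        else:
            d = abs(j - anchor_index)
        if d <= n_neighbors:
            members.add(j)
    return members


def recount_tables_oracle(neighborhoods, ref, score_mode="weighted",
                          exclude=frozenset()):
    """Brute-force recount of the three summary tables.

    Walks every gene of every neighborhood with nested loops and plain
    dictionaries, then sorts by (count desc, id asc).
    Returns ({ec: freq}, {compound: freq}, {pathway: hits}).
    """
    ec_anchors: dict[str, set] = {}
    cpd_anchors: dict[str, set] = {}
    for nb in neighborhoods:
        for gene in nb.genes:
            for ec in gene.ec_numbers:
                ec_anchors.setdefault(ec, set()).add(nb.anchor_gene_id)
                for rid in ref.ec_to_reactions.get(ec, ()):
                    rxn = ref.reactions[rid]
                    for cpd in list(rxn["substrates"]) + list(rxn["products"]):
                        if cpd in exclude:
                            continue
                        cpd_anchors.setdefault(cpd, set()).add(nb.anchor_gene_id)
    ec_freq = {ec: len(s) for ec, s in ec_anchors.items()}
    cpd_freq = {c: len(s) for c, s in cpd_anchors.items()}
    pw_hits: dict[str, int] = {}
    for ec, freq in ec_freq.items():
        for pw in ref.ec_to_pathways.get(ec, ()):
            pw_hits[pw] = pw_hits.get(pw, 0) + (freq if score_mode == "weighted" else 1)
    for cpd, freq in cpd_freq.items():
        for pw in ref.compound_to_pathways.get(cpd, ()):
            pw_hits[pw] = pw_hits.get(pw, 0) + (freq if score_mode == "weighted" else 1)
    return ec_freq, cpd_freq, pw_hits


def ranked_ids(freqs: dict[str, int]) -> list[str]:
    return [k for k in sorted(freqs, key=lambda k: (-freqs[k], k))]


def hill_grid_oracle(E: np.ndarray, dA: np.ndarray,
                     kd_grid: np.ndarray, h_grid: np.ndarray):
    """Dense grid search over (K_d, H); ΔA_T solved in closed form.

    For fixed K_d and H the model is linear in ΔA_T, so the least-squares
    ΔA_T is  Σ f·y / Σ f²  with  f = E^H / (K_d^H + E^H).
    Returns (kd, h, da_t, sse) at the grid optimum.
    """
    best = (None, None, None, float("inf"))
    for kd in kd_grid:
        for h in h_grid:
            f = E ** h / (kd ** h + E ** h)
            denom = float(np.sum(f * f))
            if denom == 0:
                continue
            da_t = float(np.sum(f * dA) / denom)
            sse = float(np.sum((da_t * f - dA) ** 2))
            if sse < best[3]:
                best = (float(kd), float(h), da_t, sse)
    return best
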