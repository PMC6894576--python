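"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or explicit
loops, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices


def brute_force_rscu(sequences: list[str], families: dict[str, tuple[str, ...]]):
    """RSCU by explicit loops over triplets (independent of codon_stats)."""
    counts: dict[str, int] = {}
    for seq in sequences:
        for i in range(0, len(seq), 3):
            triplet = seq[i : i + 3]
            counts[triplet] = counts.get(triplet, 0) + 1
    rscu: dict[str, float | None] = {}
    for codons in families.values():
        total = 0
        for c in codons:
            total += counts.get(c, 0)
        for c in codons:
            if total == 0:
                rscu[c] = None
            else:
                rscu[c] = counts.get(c, 0) * len(codons) / total
    return counts, rscu


def enumerate_global_alignment_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal global alignment score by exhaustive path enumeration.

    Recurses over every possible move sequence (match/mismatch, gap in
    b, gap in a) with affine gap costs accumulated incrementally; the
    maximum over all complete paths is returned.  Exponential: only for
    short sequences.
    """
    mat = substitution_matrices.load(matrix_name)
    best = [float("-inf")]

    def rec(i: int, j: int, state: str, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + float(mat[a[i], b[j]]))
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open
            rec(i + 1, j, "X", score - cost)
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open
            rec(i, j + 1, "Y", score - cost)

    rec(0, 0, "start", 0.0)
    return best[0]


def enumerate_max_fold_score(
    seq: str,
    min_loop: int = 3,
    pair_weights: dict[str, float] | None = None,
) -> float:
    """Best weighted nested pairing by exhaustive structure enumeration.

    Plain recursion with no memoization: every nested structure on
    ``seq[i..j]`` is visited (position i unpaired, or paired with each
    admissible k), so the result is a true enumeration maximum.
    """
    if pair_weights is None:
        pair_weights = {"GC": 3, "AT": 2, "GT": 1}
    w: dict[tuple[str, str], float] = {}
    for pair, weight in pair_weights.items():
        w[(pair[0], pair[1])] = weight
        w[(pair[1], pair[0])] = weight

    def rec(i: int, j: int) -> float:
        if j - i < min_loop + 1:
            return 0.0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            pw = w.get((seq[i], seq[k]))
            if pw is None:
                continue
            cand = pw + rec(i + 1, k - 1) + rec(k + 1, j)
            if cand > best:
                best = cand
        return best

    return rec(0, len(seq) - 1)
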