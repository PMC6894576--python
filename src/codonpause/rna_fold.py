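"""mRNA window extraction and a weighted maximum-pairing structure screen.

Synonymous substitutions can alter mRNA secondary structure around the
start codon and thereby translation initiation.  The screen here
extracts the window spanning 100 nt upstream of the ATG through 250 nt
downstream (configurable) and folds wild type and variant with a
Nussinov-style dynamic programme maximizing a weighted count of nested
base pairs (GC:3, AU:2, GU:1 by default).  The score is a heuristic
stacking-free proxy for structure content, not a free energy in
kcal/mol; what the screen reports is whether a synonymous change
re-arranges the predicted pairing, the decision the prediction is used
for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetic_code import normalize_sequence

DEFAULT_PAIR_WEIGHTS = {"GC": 3, "AT": 2, "GT": 1}


def _weight_table(pair_weights: dict[str, float]) -> dict[tuple[str, str], float]:
    table: dict[tuple[str, str], float] = {}
    for pair, w in pair_weights.items():
        p = normalize_sequence(pair)
        if len(p) != 2:
            raise ValueError(f"bad pair key {pair!r}")
        table[(p[0], p[1])] = w
        table[(p[1], p[0])] = w
    return table


@dataclass(frozen=True)
class FoldWindow:
    """A start-codon-centred mRNA window."""

    gene_id: str
    sequence: str
    atg_offset: int  # 0-based index of the A of ATG within the window
    upstream_len: int
    downstream_len: int
    truncated_upstream: bool = False
    truncated_downstream: bool = False

    def __post_init__(self) -> None:
        if self.sequence[self.atg_offset : self.atg_offset + 3] != "ATG":
            raise ValueError(
                f"{self.gene_id}: no ATG at window offset {self.atg_offset}"
            )


@dataclass(frozen=True)
class FoldResult:
    """A nested secondary structure: pair set, score and dot-bracket."""

    pairs: frozenset[tuple[int, int]]  # 0-based, i < j
    score: float
    dot_bracket: str


@dataclass(frozen=True)
class VariantComparison:
    gene_id: str
    score_wt: float
    score_variant: float
    delta_score: float
    bp_distance: int  # |pairs_wt symmetric-difference pairs_variant|
    substitutions: tuple[int, ...]  # 0-based window positions that differ


def extract_window(
    sequence: str,
    atg_position: int,
    upstream: int = 100,
    downstream: int = 250,
    gene_id: str = "",
) -> FoldWindow:
    """Cut the [ATG - upstream, ATG + 3 + downstream) window.

    ``atg_position`` is the 1-based position of the A of the annotated
    start codon.  Windows truncated by the sequence ends are flagged.
    """
    seq = normalize_sequence(sequence)
    i = atg_position - 1
    if not 0 <= i <= len(seq) - 3:
        raise ValueError(f"{gene_id}: ATG position {atg_position} out of range")
    if seq[i : i + 3] != "ATG":
        raise ValueError(
            f"{gene_id}: annotated start at {atg_position} is {seq[i:i + 3]}, not ATG"
        )
    lo = max(0, i - upstream)
    hi = min(len(seq), i + 3 + downstream)
    return FoldWindow(
        gene_id=gene_id,
        sequence=seq[lo:hi],
        atg_offset=i - lo,
        upstream_len=i - lo,
        downstream_len=hi - (i + 3),
        truncated_upstream=i - lo < upstream,
        truncated_downstream=hi - (i + 3) < downstream,
    )


def pairs_to_dot_bracket(pairs: frozenset[tuple[int, int]], n: int) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def dot_bracket_to_pairs(structure: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket string")
    return frozenset(pairs)


def fold_max_pairs(
    seq: str,
    min_loop: int = 3,
    pair_weights: dict[str, float] | None = None,
) -> FoldResult:
    """Weighted maximum nested pairing (Nussinov-style DP).

    ``W(i, j) = max( W(i+1, j),  max_k w(i,k) + W(i+1,k-1) + W(k+1,j) )``
    over partners ``k`` with ``k - i - 1 >= min_loop`` and (seq[i],
    seq[k]) in the allowed pair set.  Traceback is deterministic: at
    each subproblem the smallest admissible partner k achieving the
    optimum is paired, else i is left unpaired.
    """
    seq = normalize_sequence(seq)
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    w = _weight_table(pair_weights if pair_weights is not None else DEFAULT_PAIR_WEIGHTS)

    W = [[0.0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                pw = w.get((seq[i], seq[k]))
                if pw is None:
                    continue
                inner = W[i + 1][k - 1] if k - 1 > i + 1 else 0.0
                right = W[k + 1][j] if k + 1 < j else 0.0
                cand = pw + inner + right
                if cand > best:
                    best = cand
            W[i][j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_loop + 1:
            continue
        target = W[i][j]
        chosen = None
        # pairing i is preferred over leaving it unpaired whenever it
        # achieves the optimum; the smallest admissible partner wins ties
        for k in range(i + min_loop + 1, j + 1):
            pw = w.get((seq[i], seq[k]))
            if pw is None:
                continue
            inner = W[i + 1][k - 1] if k - 1 > i + 1 else 0.0
            right = W[k + 1][j] if k + 1 < j else 0.0
            if abs(pw + inner + right - target) < 1e-9:
                chosen = k
                break
        if chosen is not None and target > 0:
            pairs.add((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    score = sum(w[(seq[i], seq[j])] for i, j in pairs)
    return FoldResult(
        pairs=frozenset(pairs),
        score=score,
        dot_bracket=pairs_to_dot_bracket(frozenset(pairs), n),
    )


def apply_substitutions(window: FoldWindow, edits: dict[int, str]) -> FoldWindow:
    """Return a copy of the window with 0-based position -> base edits."""
    seq = list(window.sequence)
    for pos, base in edits.items():
        if not 0 <= pos < len(seq):
            raise IndexError(f"edit position {pos} outside window")
        seq[pos] = normalize_sequence(base)
    return FoldWindow(
        gene_id=window.gene_id + "_variant",
        sequence="".join(seq),
        atg_offset=window.atg_offset,
        upstream_len=window.upstream_len,
        downstream_len=window.downstream_len,
        truncated_upstream=window.truncated_upstream,
        truncated_downstream=window.truncated_downstream,
    )


def compare_variants(
    wt: FoldWindow,
    variant: FoldWindow,
    min_loop: int = 3,
    pair_weights: dict[str, float] | None = None,
) -> VariantComparison:
    """Fold wild type and variant windows and report structural change.

    Reports both the score difference and the base-pair distance (size
    of the symmetric difference of the two pair sets), plus the window
    positions where the sequences differ.
    """
    if len(wt.sequence) != len(variant.sequence):
        raise ValueError(
            f"window lengths differ: {len(wt.sequence)} vs {len(variant.sequence)}"
        )
    subs = tuple(
        i for i, (x, y) in enumerate(zip(wt.sequence, variant.sequence)) if x != y
    )
    fw = fold_max_pairs(wt.sequence, min_loop=min_loop, pair_weights=pair_weights)
    fv = fold_max_pairs(variant.sequence, min_loop=min_loop, pair_weights=pair_weights)
    return VariantComparison(
        gene_id=wt.gene_id,
        score_wt=fw.score,
        score_variant=fv.score,
        delta_score=fv.score - fw.score,
        bp_distance=len(fw.pairs.symmetric_difference(fv.pairs)),
        substitutions=subs,
    )
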