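"""CDS validation, translation, codon-aware back-translation, alignment.

Back-translation turns a protein multiple sequence alignment into a
codon alignment: each aligned residue is replaced by the codon that
encodes it in the species' coding sequence, and each residue gap by a
triplet gap ``---``.  This reproduces the semantics of EMBOSS
``tranalign``.  A small global (Needleman-Wunsch, affine-gap) star
aligner is included so that fixture-scale pipelines need no external
alignment tool; externally computed alignments (FASTA or Clustal) are
first-class input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

from .genetic_code import GeneticCode, normalize_sequence, standard_code

GAP_CELL = "---"

NEG_INF = float("-inf")


class CDSValidationError(ValueError):
    """A coding sequence failed structural validation."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; ``alphabet`` is ``"protein"`` or ``"dna"``."""

    id: str
    sequence: str
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of record {self.id!r} is empty")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")


@dataclass(frozen=True)
class ValidatedCDS:
    """A CDS that passed validation (length % 3 == 0, no internal stop)."""

    id: str
    sequence: str  # coding sequence WITHOUT the terminal stop codon
    has_terminal_stop: bool
    terminal_stop: str | None = None
    code: GeneticCode = field(default_factory=standard_code, repr=False)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]


def validate_cds(record, code: GeneticCode | None = None) -> ValidatedCDS:
    """Validate a nucleotide CDS: frame, internal stops, terminal stop.

    Accepts a :class:`SequenceRecord`, a ``(id, sequence)`` pair, or a
    Bio.SeqRecord.  The returned record stores the sequence with the
    terminal stop codon (if any) stripped.
    """
    code = code or standard_code()
    if isinstance(record, SequenceRecord):
        rid, seq = record.id, record.sequence
    elif isinstance(record, tuple):
        rid, seq = record
    else:  # Bio.SeqRecord
        rid, seq = record.id, str(record.seq)
    seq = normalize_sequence(seq)
    if len(seq) % 3 != 0:
        raise CDSValidationError(f"{rid}: length {len(seq)} not divisible by 3")
    bad = set(seq) - set("ACGT")
    if bad:
        raise CDSValidationError(f"{rid}: non-nucleotide characters {sorted(bad)}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons[:-1], start=1):
        if code.is_stop(codon):
            raise CDSValidationError(f"{rid}: internal stop at codon {i}")
    has_stop = bool(codons) and code.is_stop(codons[-1])
    coding = seq[:-3] if has_stop else seq
    if not coding:
        raise CDSValidationError(f"{rid}: no coding codons")
    return ValidatedCDS(
        id=rid,
        sequence=coding,
        has_terminal_stop=has_stop,
        terminal_stop=codons[-1] if has_stop else None,
        code=code,
    )


def translate(cds: ValidatedCDS, code: GeneticCode | None = None) -> str:
    """Translate a validated CDS; the terminal stop is already stripped."""
    code = code or cds.code
    return "".join(code.translate_codon(c) for c in cds.codons())


@dataclass(frozen=True)
class ProteinMSA:
    """A protein multiple sequence alignment (rows may contain ``-``)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"MSA rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in MSA")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def row(self, rid: str) -> str:
        for r in self.records:
            if r.id == rid:
                return r.sequence
        raise KeyError(f"no MSA row for {rid!r}")

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


@dataclass(frozen=True)
class CodonMSA:
    """Species x columns matrix of codon cells (triplet or ``---``)."""

    ids: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    reference_species: str

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("codon MSA rows have unequal column counts")
        if self.reference_species not in self.ids:
            raise ValueError(f"reference species {self.reference_species!r} not in MSA")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> tuple[str, ...]:
        return self.rows[self.ids.index(rid)]

    def column(self, col: int) -> dict[str, str]:
        """1-based column -> {species: cell}."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} out of range 1..{self.n_columns}")
        return {rid: row[col - 1] for rid, row in zip(self.ids, self.rows)}

    def ungapped_cds(self, rid: str) -> str:
        return "".join(c for c in self.row(rid) if c != GAP_CELL)


def backtranslate_alignment(
    pmsa: ProteinMSA,
    cds_by_id: Mapping[str, ValidatedCDS],
    code: GeneticCode | None = None,
    reference_species: str | None = None,
) -> CodonMSA:
    """Back-translate a protein MSA into a codon MSA.

    Every MSA row id must have a CDS whose translation equals the row's
    ungapped protein; a mismatch is reported with the offending id and
    the first differing residue position (1-based).
    """
    code = code or standard_code()
    rows: list[tuple[str, ...]] = []
    for rec in pmsa.records:
        if rec.id not in cds_by_id:
            raise KeyError(f"no CDS supplied for MSA record {rec.id!r}")
        cds = cds_by_id[rec.id]
        protein = translate(cds, code)
        ungapped = rec.sequence.replace("-", "")
        if protein != ungapped:
            n = min(len(protein), len(ungapped))
            pos = next(
                (i + 1 for i in range(n) if protein[i] != ungapped[i]), n + 1
            )
            raise ValueError(
                f"{rec.id}: CDS translation does not match aligned protein "
                f"(first mismatch at residue {pos})"
            )
        codons = iter(cds.codons())
        rows.append(
            tuple(GAP_CELL if aa == "-" else next(codons) for aa in rec.sequence)
        )
    ref = reference_species or pmsa.records[0].id
    return CodonMSA(ids=pmsa.ids, rows=tuple(rows), reference_species=ref)


def column_to_reference_position(cmsa: CodonMSA, species: str, column: int) -> int | None:
    """Map a 1-based alignment column to a 1-based codon position.

    Returns the count of non-gap cells in the species' row up to and
    including the column, or ``None`` if the cell itself is a gap.
    """
    if species not in cmsa.ids:
        raise KeyError(f"unknown species {species!r}")
    row = cmsa.row(species)
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} out of range 1..{len(row)}")
    if row[column - 1] == GAP_CELL:
        return None
    return sum(1 for cell in row[:column] if cell != GAP_CELL)


# ---------------------------------------------------------------------------
# Global pairwise alignment (Gotoh affine gaps) and star merging
# ---------------------------------------------------------------------------


def _load_matrix(name: str):
    return substitution_matrices.load(name)


def needleman_wunsch(
    a: str,
    b: str,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[float, str, str]:
    """Optimal global alignment of two protein sequences.

    Affine gap cost: a gap of length k costs ``gap_open + (k-1) *
    gap_extend``.  Traceback ties are broken deterministically: diagonal
    (match state) over up (gap in ``b``) over left (gap in ``a``).
    Returns ``(score, aligned_a, aligned_b)``.
    """
    mat = _load_matrix(substitution_table) if isinstance(substitution_table, str) else substitution_table
    n, m = len(a), len(b)

    def s(x: str, y: str) -> float:
        return float(mat[x, y])

    # M: ends in aligned pair; X: ends with a[i] against gap; Y: b[j] against gap
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = s(a[i - 1], b[j - 1]) + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend, Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)

    # traceback; state preference order implements diagonal > up > left
    by_state = {"M": M, "X": X, "Y": Y}
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: (by_state[st][i][j], st == "M", st == "X"))
    score = by_state[state][i][j]
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = s(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            target = by_state["M"][i + 1][j + 1] - prev
            state = next(
                st for st in ("M", "X", "Y") if abs(by_state[st][i][j] - target) < 1e-9
            )
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            cur = X[i][j]
            i -= 1
            if abs(M[i][j] - gap_open - cur) < 1e-9:
                state = "M"
            elif abs(X[i][j] - gap_extend - cur) < 1e-9:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            cur = Y[i][j]
            j -= 1
            if abs(M[i][j] - gap_open - cur) < 1e-9:
                state = "M"
            elif abs(X[i][j] - gap_open - cur) < 1e-9:
                state = "X"
            else:
                state = "Y"
            if i == 0 and j == 0:
                break
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def align_proteins_star(
    records: Sequence[SequenceRecord],
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> ProteinMSA:
    """Star multiple alignment: pairwise-align everything to a centre.

    The centre is the longest record (first on ties).  Pairwise
    alignments are merged on the centre's coordinate system with the
    usual once-a-gap-always-a-gap rule; insertions relative to the
    centre are left-aligned within their slot.  Deterministic for fixed
    input order.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("star alignment needs at least two sequences")
    centre_idx = max(range(len(records)), key=lambda k: (len(records[k].sequence), -k))
    centre = records[centre_idx]
    c = centre.sequence
    others = [r for k, r in enumerate(records) if k != centre_idx]

    # per pairwise alignment: insertions[i] = residues of the other sequence
    # placed before centre residue i (i in 0..len(c), len(c) = after last)
    pair_data = []
    for rec in others:
        _, c_aln, s_aln = needleman_wunsch(
            c, rec.sequence, substitution_table, gap_open, gap_extend
        )
        ins: list[str] = [""] * (len(c) + 1)
        aligned_to: list[str] = []  # char of s aligned to each centre residue
        ci = 0
        for ca, sa in zip(c_aln, s_aln):
            if ca == "-":
                ins[ci] += sa
            else:
                aligned_to.append(sa)
                ci += 1
        pair_data.append((rec, ins, aligned_to))

    master = [0] * (len(c) + 1)
    for _, ins, _ in pair_data:
        for i, block in enumerate(ins):
            master[i] = max(master[i], len(block))

    def build_row(ins: list[str], aligned: list[str]) -> str:
        parts: list[str] = []
        for i in range(len(c)):
            parts.append(ins[i].ljust(master[i], "-"))
            parts.append(aligned[i])
        parts.append(ins[len(c)].ljust(master[len(c)], "-"))
        return "".join(parts)

    rows: dict[str, str] = {}
    rows[centre.id] = build_row([""] * (len(c) + 1), list(c))
    for rec, ins, aligned_to in pair_data:
        rows[rec.id] = build_row(ins, aligned_to)
    out = [SequenceRecord(r.id, rows[r.id], "protein") for r in records]
    return ProteinMSA(records=tuple(out))


# ---------------------------------------------------------------------------
# IO helpers
# ---------------------------------------------------------------------------


def read_fasta(path, alphabet: str = "dna") -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq), alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_alignment(path, fmt: str | None = None) -> ProteinMSA:
    """Read a protein MSA in FASTA or Clustal format (auto-detected)."""
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()
        fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return ProteinMSA(
        records=tuple(
            SequenceRecord(rec.id, str(rec.seq).upper(), "protein") for rec in aln
        )
    )


def write_codon_msa(path, cmsa: CodonMSA, width: int = 60) -> None:
    """Write a codon MSA as gapped nucleotide FASTA (3 chars per cell)."""
    write_fasta(
        path,
        [SequenceRecord(rid, "".join(row), "dna") for rid, row in zip(cmsa.ids, cmsa.rows)],
        width=width,
    )
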