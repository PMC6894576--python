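"""Codon counting, RSCU, optimal/non-optimal classification, substitutions.

Relative synonymous codon usage (RSCU) of a codon is its observed count
divided by the count expected if every synonym of the amino acid were
used equally: for codon ``c`` in family ``F``,

    RSCU(c) = count(c) / (sum_F count / |F|)

so the RSCU values of a family always average to 1.  RSCU measured on a
set of highly expressed genes (HEGs) is the classifier used throughout
this package: values above 1 mark translationally optimal codons, values
below 1 mark non-optimal (avoided) codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .genetic_code import GeneticCode, normalize_codon, standard_code

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts and (optionally) RSCU values over a gene set.

    ``rscu`` maps codons to floats, or ``None`` for codons of a family
    with zero total observations (undefined rather than 0/0).  Stop
    codons carry counts but never RSCU.
    """

    counts: dict[str, int]
    rscu: dict[str, float | None] = field(default_factory=dict)
    gene_set_label: str = ""
    n_genes: int = 0
    code: GeneticCode = field(default_factory=standard_code)

    def total_codons(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class CodonClassification:
    """Optimal / non-optimal / rare status of every sense codon.

    Single-codon families (ATG, TGG) are never optimal, non-optimal or
    rare: RSCU is uninformative there (always 1).  For multi-codon
    families: non-optimal iff RSCU_HEG < 1; rare iff RSCU_HEG <=
    ``rare_threshold``; the optimal codon is the unique family member
    with RSCU_HEG > 1 and maximal RSCU_HEG (none on ties).
    """

    rscu_heg: dict[str, float]
    non_optimal: dict[str, bool]
    rare: dict[str, bool]
    optimal: dict[str, bool]
    rare_threshold: float = 0.5
    rscu_total: dict[str, float] | None = None
    code: GeneticCode = field(default_factory=standard_code)

    def is_non_optimal(self, codon: str) -> bool:
        return self.non_optimal.get(normalize_codon(codon), False)

    def is_rare(self, codon: str) -> bool:
        return self.rare.get(normalize_codon(codon), False)

    def is_optimal(self, codon: str) -> bool:
        return self.optimal.get(normalize_codon(codon), False)


@dataclass(frozen=True)
class SubstitutionRecord:
    """A validated synonymous codon substitution."""

    source: str
    target: str
    amino_acid: str
    direction: str  # "optimizing" | "deoptimizing" | "neutral" | "unclassified"


def count_codons(
    cds_set: Iterable,
    code: GeneticCode | None = None,
    gene_set_label: str = "",
) -> CodonUsageTable:
    """Count codon occurrences over a collection of validated CDS.

    Accepts :class:`~codonpause.codon_alignment.ValidatedCDS` records or
    raw nucleotide strings (validated on the fly).  Terminal stop codons
    are counted under their stop triplet; they never enter RSCU family
    totals because stop codons have no synonymous family.
    """
    from .codon_alignment import ValidatedCDS, validate_cds

    code = code or standard_code()
    items = list(cds_set)
    if not items:
        raise ValueError("empty gene set: cannot count codons over zero CDS")
    counts: dict[str, int] = {}
    n = 0
    for i, item in enumerate(items):
        if isinstance(item, ValidatedCDS):
            v = item
        elif isinstance(item, str):
            v = validate_cds((f"record_{i + 1}", item), code)
        else:
            v = validate_cds(item, code)
        for j in range(0, len(v.sequence), 3):
            codon = v.sequence[j : j + 3]
            counts[codon] = counts.get(codon, 0) + 1
        if v.has_terminal_stop:
            counts[v.terminal_stop] = counts.get(v.terminal_stop, 0) + 1
        n += 1
    return CodonUsageTable(counts=counts, gene_set_label=gene_set_label, n_genes=n, code=code)


def compute_rscu(table: CodonUsageTable, pseudocount: float = 0.0) -> CodonUsageTable:
    """Fill in RSCU values from counts.

    ``pseudocount`` is added to every sense codon count before
    normalization (useful for small gene sets; default 0 keeps the
    estimator unbiased and leaves empty families undefined).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    rscu: dict[str, float | None] = {}
    for codons in table.code.families.values():
        obs = {c: table.counts.get(c, 0) + pseudocount for c in codons}
        total = sum(obs.values())
        if total == 0:
            for c in codons:
                rscu[c] = None
        else:
            expected = total / len(codons)
            for c in codons:
                rscu[c] = obs[c] / expected
    return replace(table, rscu=rscu)


def _as_rscu_mapping(source) -> Mapping[str, float | None]:
    if isinstance(source, CodonUsageTable):
        if not source.rscu:
            raise ValueError("usage table has no RSCU values; run compute_rscu first")
        return source.rscu
    return source


def classify_codons(
    rscu_heg,
    rscu_total=None,
    rare_threshold: float = 0.5,
    code: GeneticCode | None = None,
) -> CodonClassification:
    """Classify sense codons from HEG RSCU values.

    ``rscu_heg`` may be a :class:`CodonUsageTable` (with RSCU computed)
    or a plain mapping codon -> RSCU.  Every multi-codon-family sense
    codon must have a defined RSCU; single-codon families default to 1.
    """
    code = code or standard_code()
    heg = {normalize_codon(c): v for c, v in _as_rscu_mapping(rscu_heg).items()}
    full: dict[str, float] = {}
    for codons in code.families.values():
        for c in codons:
            v = heg.get(c)
            if v is None:
                if len(codons) == 1:
                    v = 1.0
                else:
                    raise ValueError(
                        f"RSCU undefined for codon {c}; supply a table covering all "
                        "multi-codon families or recompute with a pseudocount"
                    )
            full[c] = float(v)

    non_optimal: dict[str, bool] = {}
    rare: dict[str, bool] = {}
    optimal: dict[str, bool] = {}
    for codons in code.families.values():
        multi = len(codons) > 1
        for c in codons:
            non_optimal[c] = multi and full[c] < 1.0
            rare[c] = multi and full[c] <= rare_threshold
            optimal[c] = False
        if multi:
            best = max(full[c] for c in codons)
            winners = [c for c in codons if full[c] == best]
            if best > 1.0 and len(winners) == 1:
                optimal[winners[0]] = True

    total = None
    if rscu_total is not None:
        total = {
            normalize_codon(c): float(v)
            for c, v in _as_rscu_mapping(rscu_total).items()
            if v is not None
        }
    return CodonClassification(
        rscu_heg=full,
        non_optimal=non_optimal,
        rare=rare,
        optimal=optimal,
        rare_threshold=rare_threshold,
        rscu_total=total,
        code=code,
    )


def synonymous_substitution(
    codon: str,
    target: str,
    code: GeneticCode | None = None,
    classification: CodonClassification | None = None,
) -> SubstitutionRecord:
    """Validate a synonymous substitution (e.g. CAA -> CAG for Gln).

    The direction is judged against a supplied classification: a move to
    strictly higher RSCU_HEG is "optimizing", to lower "deoptimizing".
    """
    code = code or standard_code()
    src, tgt = normalize_codon(codon), normalize_codon(target)
    aa_src, aa_tgt = code.translate_codon(src), code.translate_codon(tgt)
    if "*" in (aa_src, aa_tgt):
        raise ValueError(f"substitution involves a stop codon: {src}->{tgt}")
    if aa_src != aa_tgt:
        raise ValueError(f"not synonymous: {aa_src} ({src}) vs {aa_tgt} ({tgt})")
    direction = "unclassified"
    if classification is not None:
        a, b = classification.rscu_heg[src], classification.rscu_heg[tgt]
        direction = "optimizing" if b > a else "deoptimizing" if b < a else "neutral"
    return SubstitutionRecord(source=src, target=tgt, amino_acid=aa_src, direction=direction)


def load_rscu_table(path) -> dict[str, float]:
    """Read an RSCU table from TSV (columns: codon, rscu; extras ignored).

    Codons are upper-cased and U is normalized to T.  Duplicate codons
    and negative RSCU values are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "codon" in cols and "rscu" in cols:
        codon_col, rscu_col = cols["codon"], cols["rscu"]
    else:
        # headerless two-column file: the first row was eaten as a header
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 2:
            raise ValueError("RSCU table needs at least two columns (codon, rscu)")
        codon_col, rscu_col = df.columns[0], df.columns[1]
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        codon = normalize_codon(str(row[codon_col]))
        value = float(row[rscu_col])
        if codon in out:
            raise ValueError(f"duplicate codon row in RSCU table: {codon}")
        if value < 0:
            raise ValueError(f"negative RSCU for {codon}: {value}")
        out[codon] = value
    return out


def write_usage_table(
    path,
    table: CodonUsageTable,
    classification: CodonClassification | None = None,
) -> None:
    """Write a codon usage TSV: codon, aa, count, rscu, flags.

    Rows are sorted by amino acid then codon so output is byte-stable.
    """
    rows = []
    for aa in sorted(table.code.families):
        for codon in table.code.families[aa]:
            r = table.rscu.get(codon)
            rows.append(
                {
                    "codon": codon,
                    "aa": aa,
                    "count": table.counts.get(codon, 0),
                    "rscu": "" if r is None else f"{r:.4f}",
                    "non_optimal": classification.is_non_optimal(codon) if classification else "",
                    "rare": classification.is_rare(codon) if classification else "",
                    "optimal": classification.is_optimal(codon) if classification else "",
                }
            )
    for codon in sorted(table.code.stop_codons):
        rows.append(
            {
                "codon": codon,
                "aa": "*",
                "count": table.counts.get(codon, 0),
                "rscu": "",
                "non_optimal": "",
                "rare": "",
                "optimal": "",
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# codon usage: {table.gene_set_label or 'unnamed gene set'}; n_genes={table.n_genes}\n")
        df.to_csv(fh, sep="\t", index=False)
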