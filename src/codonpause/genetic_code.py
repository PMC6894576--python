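"""Genetic code tables and codon normalization.

Only the standard nuclear code is shipped (appropriate for *Aspergillus*
nuclear genes), but :class:`GeneticCode` is table-driven so alternative
codes can be constructed from any :mod:`Bio.Data.CodonTable` entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

STOP = "*"

_DNA = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _DNA for b in _DNA for c in _DNA)


def normalize_codon(codon: str) -> str:
    """Upper-case a triplet and map RNA U to DNA T."""
    c = codon.strip().upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise ValueError(f"not a DNA/RNA triplet: {codon!r}")
    return c


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide sequence and map U to T (gaps preserved)."""
    return seq.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 DNA triplets to amino acids or stop.

    Attributes
    ----------
    name:
        Identifier of the code (e.g. ``"standard"``).
    codon_to_aa:
        Maps every one of the 64 codons to a one-letter amino acid or
        ``"*"`` for stop.
    families:
        Maps each amino acid to the ordered tuple of its synonymous
        codons.  The families partition the sense codons.
    """

    name: str
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon_to_aa must map exactly the 64 DNA triplets")
        if not self.families:
            fams: dict[str, list[str]] = {}
            for codon in ALL_CODONS:
                aa = self.codon_to_aa[codon]
                if aa != STOP:
                    fams.setdefault(aa, []).append(codon)
            object.__setattr__(
                self, "families", {aa: tuple(sorted(cs)) for aa, cs in fams.items()}
            )
        for aa, codons in self.families.items():
            for codon in codons:
                if self.codon_to_aa[codon] != aa:
                    raise ValueError(f"family {aa} contains non-synonymous codon {codon}")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != STOP)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == STOP)

    def family_of(self, codon: str) -> tuple[str, ...]:
        """Synonymous family of a sense codon."""
        aa = self.codon_to_aa[normalize_codon(codon)]
        if aa == STOP:
            raise ValueError(f"{codon} is a stop codon; it has no synonymous family")
        return self.families[aa]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[normalize_codon(codon)] == STOP

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code, built from biopython's table 1."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = {c: STOP for c in table.stop_codons}
    mapping.update(table.forward_table)
    return GeneticCode(name="standard", codon_to_aa=dict(mapping))
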