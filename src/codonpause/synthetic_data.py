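"""Synthetic orthologue families with planted conserved rare-codon sites.

The generator emulates the study design the screen targets: N
orthologous coding sequences sharing one protein with a single
hydrophobic (transmembrane-like) segment, per-amino-acid codon choice
drawn from a biased usage model with a highly-expressed-gene (HEG)
regime and a background regime, and a planted run of conserved
non-optimal codons at a configurable offset upstream of the segment.
Every artifact is deterministic for a fixed seed, and the emitted
:class:`SyntheticTruth` records exactly what was planted so recovery
can be scored.

Draw order (stable across runs): shared protein residues first, then
per-species codons in species order and position order (divergence
re-draws consumed inline), then per-species indel positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_alignment import (
    ProteinMSA,
    SequenceRecord,
    ValidatedCDS,
    validate_cds,
    write_fasta,
)
from .genetic_code import GeneticCode, normalize_codon, standard_code

HYDROPHOBIC_POOL = "FILV"  # Kyte-Doolittle >= 2.8
HYDROPHILIC_POOL = "DEKNQR"  # Kyte-Doolittle <= -3.5


@dataclass(frozen=True)
class UsageModel:
    """Within-family codon probabilities for two usage regimes.

    ``heg_like`` emulates highly expressed genes: one elevated codon per
    family gets probability ``bias + (1-bias)/k`` (all of the mass at
    bias 1, uniform at bias 0).  ``background`` emulates ordinary genes,
    which in biased genomes still lean toward the optimal codon but only
    about half as strongly (elevated weight ``bias/2``).
    """

    heg_like: dict[str, dict[str, float]]  # aa -> codon -> probability
    background: dict[str, dict[str, float]]
    elevated: dict[str, str]  # aa -> elevated codon (multi-codon families)
    bias_strength: float
    code: GeneticCode = field(default_factory=standard_code)

    def implied_rscu(self, regime: str = "heg_like") -> dict[str, float]:
        """RSCU values implied by the regime's probabilities."""
        probs = getattr(self, regime)
        out: dict[str, float] = {}
        for aa, fam in probs.items():
            k = len(fam)
            for codon, p in fam.items():
                out[codon] = p * k
        return out


def _mix(codons: tuple[str, ...], elevated: str, w: float) -> dict[str, float]:
    k = len(codons)
    return {c: w * (c == elevated) + (1 - w) / k for c in codons}


def sample_usage_model(
    seed: int,
    bias_strength: float = 0.8,
    code: GeneticCode | None = None,
    elevated_overrides: dict[str, str] | None = None,
) -> UsageModel:
    """Draw a usage model: one elevated codon per multi-codon family.

    ``elevated_overrides`` pins the elevated codon of chosen families
    (amino acid -> codon), e.g. to reproduce the known optima of a
    particular organism; other families stay seed-random.
    """
    if not 0.0 <= bias_strength <= 1.0:
        raise ValueError("bias_strength must be in [0, 1]")
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    heg: dict[str, dict[str, float]] = {}
    bg: dict[str, dict[str, float]] = {}
    elevated: dict[str, str] = {}
    overrides = dict(elevated_overrides or {})
    for aa in sorted(code.families):
        codons = code.families[aa]
        if len(codons) == 1:
            heg[aa] = {codons[0]: 1.0}
            bg[aa] = {codons[0]: 1.0}
            continue
        if aa in overrides:
            elev = normalize_codon(overrides[aa])
            if elev not in codons:
                raise ValueError(f"override {elev} does not encode {aa}")
        else:
            elev = codons[int(rng.integers(len(codons)))]
        elevated[aa] = elev
        heg[aa] = _mix(codons, elev, bias_strength)
        bg[aa] = _mix(codons, elev, bias_strength / 2.0)
    return UsageModel(
        heg_like=heg,
        background=bg,
        elevated=elevated,
        bias_strength=bias_strength,
        code=code,
    )


@dataclass(frozen=True)
class FamilyConfig:
    """Parameters of one synthetic orthologue family."""

    n_species: int = 8
    protein_length: int = 120
    tm_start: int = 26
    tm_end: int = 46
    planted_codons: dict[int, str] = field(default_factory=dict)  # 1-based pos -> codon
    divergence: float = 0.0  # per planted site, per species redraw probability
    divergence_redraw: str = "background"  # or "optimal"
    indel_rate: float = 0.0  # per eligible position, per non-reference species
    protein_sequence: str | None = None  # optional fixed protein
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 1 <= self.tm_start <= self.tm_end <= self.protein_length:
            raise ValueError("TM segment must lie within the protein")
        if self.divergence_redraw not in ("background", "optimal"):
            raise ValueError("divergence_redraw must be 'background' or 'optimal'")

    @property
    def planted_columns(self) -> tuple[int, ...]:
        return tuple(sorted(self.planted_codons))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated family."""

    planted_columns: tuple[int, ...]
    planted_codons: dict[int, str]
    tm_start: int
    tm_end: int
    species_ids: tuple[str, ...]
    reference_species: str
    bias_strength: float
    divergence: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "planted_columns": list(self.planted_columns),
            "planted_codons": {str(k): v for k, v in self.planted_codons.items()},
            "tm_start": self.tm_start,
            "tm_end": self.tm_end,
            "species_ids": list(self.species_ids),
            "reference_species": self.reference_species,
            "bias_strength": self.bias_strength,
            "divergence": self.divergence,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class FamilyBundle:
    config: FamilyConfig
    shared_protein: str
    cds_by_id: dict[str, ValidatedCDS]
    protein_msa: ProteinMSA
    truth: SyntheticTruth


def default_usage_model(seed: int = 0, bias_strength: float = 0.8) -> UsageModel:
    """The study-condition usage model.

    Gln and Gly elevation is pinned to CAG and GGT, the optimal codons
    of the organism the screen models, so the canonical planted codons
    CAA and GGG are non-optimal (and rare) under the HEG regime.
    """
    return sample_usage_model(
        seed,
        bias_strength=bias_strength,
        elevated_overrides={"Q": "CAG", "G": "GGT"},
    )


def default_family_config(seed: int = 7) -> FamilyConfig:
    """The canonical fixture: 8 species, TM [26, 46], CAA/GGG at 24-25."""
    return FamilyConfig(
        n_species=8,
        protein_length=120,
        tm_start=26,
        tm_end=46,
        planted_codons={24: "CAA", 25: "GGG"},
        divergence=0.0,
        seed=seed,
    )


def _draw_codon(rng: np.random.Generator, fam: dict[str, float]) -> str:
    codons = list(fam)
    probs = np.array([fam[c] for c in codons])
    return codons[int(rng.choice(len(codons), p=probs))]


def generate_family(config: FamilyConfig, model: UsageModel) -> FamilyBundle:
    """Generate one orthologue family with planted non-optimal codons.

    All species share one protein (hydrophobic F/I/L/V inside the TM
    block, strongly hydrophilic residues elsewhere).  Codons are drawn
    independently per species from the background regime, except planted
    positions which carry the planted codon (re-drawn per species with
    probability ``divergence``).  The first species is the reference and
    never receives indels, so alignment columns equal its codon
    positions.
    """
    code = model.code
    rng = np.random.default_rng(config.seed)
    L = config.protein_length

    # planted codons: validate and derive their residues
    planted: dict[int, str] = {}
    planted_aa: dict[int, str] = {}
    for pos, codon in config.planted_codons.items():
        c = normalize_codon(codon)
        if not 1 <= pos <= L:
            raise ValueError(f"planted position {pos} outside protein 1..{L}")
        aa = code.translate_codon(c)
        if aa == "*":
            raise ValueError(f"planted codon {c} is a stop codon")
        planted[pos] = c
        planted_aa[pos] = aa

    # shared protein (stream 1)
    if config.protein_sequence is not None:
        protein = list(config.protein_sequence.upper())
        if len(protein) != L:
            raise ValueError("protein_sequence length disagrees with protein_length")
        for pos, aa in planted_aa.items():
            if protein[pos - 1] != aa:
                raise ValueError(
                    f"planted codon {planted[pos]} not synonymous with residue "
                    f"{protein[pos - 1]} at position {pos}"
                )
    else:
        protein = []
        for pos in range(1, L + 1):
            if pos in planted_aa:
                protein.append(planted_aa[pos])
            elif pos == 1:
                protein.append("M")  # real CDS start with an ATG initiator
            elif config.tm_start <= pos <= config.tm_end:
                protein.append(HYDROPHOBIC_POOL[int(rng.integers(len(HYDROPHOBIC_POOL)))])
            else:
                protein.append(HYDROPHILIC_POOL[int(rng.integers(len(HYDROPHILIC_POOL)))])
    protein_str = "".join(protein)

    species_ids = tuple(f"sp{i:02d}" for i in range(1, config.n_species + 1))
    reference = species_ids[0]

    # per-species codons (stream 2; divergence redraws consumed inline)
    codon_rows: dict[str, list[str]] = {}
    for sp in species_ids:
        row: list[str] = []
        for pos in range(1, L + 1):
            aa = protein_str[pos - 1]
            fam = model.background[aa]
            if pos in planted:
                codon = planted[pos]
                if config.divergence > 0 and rng.random() < config.divergence:
                    if config.divergence_redraw == "optimal":
                        codon = model.elevated.get(aa, codon)
                    else:
                        codon = _draw_codon(rng, fam)
            else:
                codon = _draw_codon(rng, fam)
            row.append(codon)
        codon_rows[sp] = row

    # per-species indels (stream 3): deletions outside TM and planted context
    deleted: dict[str, set[int]] = {sp: set() for sp in species_ids}
    if config.indel_rate > 0:
        protected = set(range(config.tm_start - 2, config.tm_end + 3))
        for pos in planted:
            protected.update({pos - 1, pos, pos + 1})
        protected.add(1)
        eligible = [p for p in range(1, L + 1) if p not in protected]
        for sp in species_ids[1:]:
            mask = rng.random(len(eligible)) < config.indel_rate
            deleted[sp] = {p for p, m in zip(eligible, mask) if m}

    cds_by_id: dict[str, ValidatedCDS] = {}
    msa_rows: list[SequenceRecord] = []
    for sp in species_ids:
        keep = [p for p in range(1, L + 1) if p not in deleted[sp]]
        cds_seq = "".join(codon_rows[sp][p - 1] for p in keep) + "TAA"
        cds_by_id[sp] = validate_cds((sp, cds_seq), code)
        msa_rows.append(
            SequenceRecord(
                sp,
                "".join(
                    "-" if p in deleted[sp] else protein_str[p - 1]
                    for p in range(1, L + 1)
                ),
                "protein",
            )
        )

    truth = SyntheticTruth(
        planted_columns=config.planted_columns,
        planted_codons=dict(planted),
        tm_start=config.tm_start,
        tm_end=config.tm_end,
        species_ids=species_ids,
        reference_species=reference,
        bias_strength=model.bias_strength,
        divergence=config.divergence,
        seed=config.seed,
    )
    return FamilyBundle(
        config=config,
        shared_protein=protein_str,
        cds_by_id=cds_by_id,
        protein_msa=ProteinMSA(records=tuple(msa_rows)),
        truth=truth,
    )


def generate_heg_set(
    model: UsageModel,
    n_genes: int = 200,
    mean_length: int = 300,
    seed: int = 0,
) -> list[ValidatedCDS]:
    """Generate a synthetic highly-expressed gene set.

    Residues are uniform over the 20 amino acids (first residue Met),
    codons drawn from the HEG regime; each gene ends with TAA.  RSCU
    estimated on the output converges to the model's implied HEG RSCU.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    aas = sorted(model.code.families)
    out: list[ValidatedCDS] = []
    for g in range(n_genes):
        length = max(10, int(rng.poisson(mean_length)))
        residues = ["M"] + [aas[i] for i in rng.integers(len(aas), size=length - 1)]
        codons: list[str] = [""] * length
        res_arr = np.array(residues)
        for aa in aas:
            idx = np.where(res_arr == aa)[0]
            if idx.size == 0:
                continue
            fam = model.heg_like[aa]
            fam_codons = list(fam)
            probs = np.array([fam[c] for c in fam_codons])
            draws = rng.choice(len(fam_codons), size=idx.size, p=probs)
            for i, d in zip(idx, draws):
                codons[i] = fam_codons[d]
        out.append(validate_cds((f"heg_{g + 1:04d}", "".join(codons) + "TAA"), model.code))
    return out


def write_family(bundle: FamilyBundle, out_dir) -> dict[str, Path]:
    """Write a family to disk: CDS FASTA per species, MSA, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cds_dir = out / "cds"
    cds_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    for sp, cds in bundle.cds_by_id.items():
        p = cds_dir / f"{sp}.fasta"
        write_fasta(p, [SequenceRecord(sp, cds.sequence + "TAA", "dna")])
        paths[f"cds:{sp}"] = p
    msa_path = out / "protein_msa.fasta"
    write_fasta(msa_path, bundle.protein_msa.records)
    paths["msa"] = msa_path
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth.to_dict(), indent=2) + "\n")
    paths["truth"] = truth_path
    return paths
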