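"""Cross-species RSCU profiles and conserved non-optimal site detection.

The central screen of this package: along a codon alignment of
orthologues, plot the HEG-referenced RSCU of the codon each species uses
at every column, and flag columns where *every* species uses a
non-optimal codon (RSCU_HEG < 1).  Such 100%-conserved non-optimal
sites, when they sit just upstream of the first transmembrane segment,
are candidate programmed translational pauses in membrane-protein
biogenesis.  Also provided: adjacency grouping into runs, offsets to
the first TMS, an nnGGnn codon-pair junction screen, and a batch scanner
over many gene families.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .codon_alignment import (
    GAP_CELL,
    CodonMSA,
    ProteinMSA,
    SequenceRecord,
    ValidatedCDS,
    align_proteins_star,
    backtranslate_alignment,
    column_to_reference_position,
    translate,
)
from .codon_stats import CodonClassification
from .genetic_code import normalize_codon, standard_code
from .topology import TopologyAnnotation, offset_to_first_tms, predict_topology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteProfile:
    """Per-column codon/RSCU profile across species.

    ``per_species`` maps species -> (codon or None for gap, RSCU_HEG or
    None).  Mean and SD (population SD, i.e. divide by n) are over
    non-gap species only; both are None for an all-gap column.
    ``reference_position`` is the 1-based codon position in the
    reference species, or None if the reference is gapped here.
    """

    column: int
    per_species: dict[str, tuple[str | None, float | None]]
    mean_rscu: float | None
    sd_rscu: float | None
    reference_position: int | None

    @property
    def gap_free(self) -> bool:
        return all(codon is not None for codon, _ in self.per_species.values())


@dataclass(frozen=True)
class ConservedNonOptimalSite:
    """An alignment column where all (non-gap) species use non-optimal codons."""

    column: int
    reference_position: int | None
    per_species_codons: dict[str, str | None]
    all_rare: bool
    mean_rscu: float | None
    sd_rscu: float | None
    tms_offset: int | None = None


@dataclass(frozen=True)
class Run:
    """A maximal block of adjacent conserved sites."""

    start_column: int
    end_column: int
    sites: tuple[ConservedNonOptimalSite, ...]

    @property
    def length(self) -> int:
        return self.end_column - self.start_column + 1


@dataclass(frozen=True)
class ScanReport:
    gene_family_id: str
    sites: tuple[ConservedNonOptimalSite, ...]
    runs: tuple[Run, ...]
    parameters: dict = field(default_factory=dict)


def _classification_for(
    species: str,
    classification_by_species: Mapping[str, CodonClassification] | CodonClassification,
) -> CodonClassification:
    if isinstance(classification_by_species, CodonClassification):
        return classification_by_species
    if species not in classification_by_species:
        raise KeyError(f"no codon classification for species {species!r}")
    return classification_by_species[species]


def rscu_profile(
    cmsa: CodonMSA,
    classification_by_species: Mapping[str, CodonClassification] | CodonClassification,
) -> list[SiteProfile]:
    """One profile per alignment column.

    A single shared classification may be supplied (applied to every
    species), or a per-species mapping; per-species tables are the
    faithful mode when each genome's own HEG usage is available.
    """
    profiles: list[SiteProfile] = []
    for col in range(1, cmsa.n_columns + 1):
        cells = cmsa.column(col)
        per_species: dict[str, tuple[str | None, float | None]] = {}
        vals: list[float] = []
        for sp, cell in cells.items():
            if cell == GAP_CELL:
                per_species[sp] = (None, None)
            else:
                cls = _classification_for(sp, classification_by_species)
                r = cls.rscu_heg[normalize_codon(cell)]
                per_species[sp] = (cell, r)
                vals.append(r)
        mean = sum(vals) / len(vals) if vals else None
        sd = statistics.pstdev(vals) if vals else None
        profiles.append(
            SiteProfile(
                column=col,
                per_species=per_species,
                mean_rscu=mean,
                sd_rscu=sd,
                reference_position=column_to_reference_position(
                    cmsa, cmsa.reference_species, col
                ),
            )
        )
    return profiles


def detect_conserved_nonoptimal(
    profiles: Sequence[SiteProfile],
    require_gap_free: bool = True,
    require_rare: bool = False,
    rare_threshold: float = 0.5,
    min_fraction: float = 1.0,
) -> list[ConservedNonOptimalSite]:
    """Columns where the species-wide codon choice is non-optimal.

    Non-optimality is read off the stored RSCU_HEG values (< 1).  With
    the default ``min_fraction`` of 1.0 the rule is the strict 100%
    one; lower values relax it to a fraction of the non-gap species.
    ``require_rare`` further demands RSCU_HEG <= rare_threshold in every
    species.
    """
    sites: list[ConservedNonOptimalSite] = []
    for p in profiles:
        pairs = [(c, r) for c, r in p.per_species.values() if c is not None]
        if not pairs:
            continue
        if require_gap_free and not p.gap_free:
            continue
        n_nonopt = sum(1 for _, r in pairs if r is not None and r < 1.0)
        if n_nonopt / len(pairs) < min_fraction or n_nonopt == 0:
            continue
        all_rare = all(r is not None and r <= rare_threshold for _, r in pairs)
        if require_rare and not all_rare:
            continue
        sites.append(
            ConservedNonOptimalSite(
                column=p.column,
                reference_position=p.reference_position,
                per_species_codons={sp: c for sp, (c, _) in p.per_species.items()},
                all_rare=all_rare,
                mean_rscu=p.mean_rscu,
                sd_rscu=p.sd_rscu,
            )
        )
    return sites


def group_adjacent(sites: Iterable[ConservedNonOptimalSite]) -> list[Run]:
    """Group sites into maximal runs of consecutive alignment columns."""
    ordered = sorted(sites, key=lambda s: s.column)
    runs: list[list[ConservedNonOptimalSite]] = []
    for site in ordered:
        if runs and site.column == runs[-1][-1].column + 1:
            runs[-1].append(site)
        else:
            runs.append([site])
    return [
        Run(start_column=r[0].column, end_column=r[-1].column, sites=tuple(r))
        for r in runs
    ]


def make_report(
    gene_family_id: str,
    sites: Iterable[ConservedNonOptimalSite],
    parameters: dict | None = None,
) -> ScanReport:
    sites = tuple(sorted(sites, key=lambda s: s.column))
    return ScanReport(
        gene_family_id=gene_family_id,
        sites=sites,
        runs=tuple(group_adjacent(sites)),
        parameters=dict(parameters or {}),
    )


def annotate_with_topology(
    report: ScanReport,
    annotations: Mapping[str, TopologyAnnotation],
    reference_species: str,
) -> ScanReport:
    """Attach offsets to the first TMS of the reference species.

    The offset is measured in reference-protein residue coordinates
    (site residue position minus first-TMS start; negative = N-terminal
    of the TMS).  Missing reference annotation leaves offsets None with
    a warning.
    """
    ann = annotations.get(reference_species)
    if ann is None:
        logger.warning(
            "no topology annotation for reference species %s; offsets left unset",
            reference_species,
        )
        return report
    new_sites = tuple(
        replace(
            s,
            tms_offset=(
                offset_to_first_tms(s.reference_position, ann)
                if s.reference_position is not None
                else None
            ),
        )
        for s in report.sites
    )
    return make_report(report.gene_family_id, new_sites, report.parameters)


def codon_pair_gg_junction(codon1: str, codon2: str) -> bool:
    """True iff the codon pair matches the avoided nnGGnn pattern.

    The dipeptide junction reads G|G when the first codon ends with G
    and the second starts with G; such pairs are under-represented
    genome-wide, which is one proposed reason a non-optimal codon (e.g.
    CAA rather than CAG before a GGN glycine codon) is retained.
    """
    code = standard_code()
    c1, c2 = normalize_codon(codon1), normalize_codon(codon2)
    for c in (c1, c2):
        if code.is_stop(c):
            raise ValueError(f"{c} is a stop codon, not a sense codon")
    return c1[2] == "G" and c2[0] == "G"


@dataclass(frozen=True)
class GeneFamily:
    """Inputs for one orthologue family scan."""

    family_id: str
    cds_by_id: dict[str, ValidatedCDS]
    protein_msa: ProteinMSA | None = None  # None -> auto-align with star aligner
    reference_species: str | None = None

    @property
    def reference(self) -> str:
        return self.reference_species or next(iter(self.cds_by_id))


@dataclass(frozen=True)
class FamilyCandidate:
    family_id: str
    report: ScanReport  # filtered to sites inside the TMS-offset window
    first_tms_start: int


@dataclass(frozen=True)
class BatchScanResult:
    candidates: tuple[FamilyCandidate, ...]
    skipped: dict[str, str]  # family_id -> reason


def scan_family(
    family: GeneFamily,
    classification: Mapping[str, CodonClassification] | CodonClassification,
    annotations: Mapping[str, TopologyAnnotation] | None = None,
    require_gap_free: bool = True,
    require_rare: bool = False,
    rare_threshold: float = 0.5,
    min_fraction: float = 1.0,
    predict_tm: bool = True,
) -> tuple[ScanReport, list[SiteProfile], TopologyAnnotation | None]:
    """Full single-family scan: align, back-translate, profile, detect.

    Returns the TMS-annotated report, the per-column profiles and the
    reference topology annotation used (None when unavailable).
    """
    pmsa = family.protein_msa
    if pmsa is None:
        prots = [
            SequenceRecord(cid, translate(cds), "protein")
            for cid, cds in family.cds_by_id.items()
        ]
        pmsa = align_proteins_star(prots)
    cmsa = backtranslate_alignment(
        pmsa, family.cds_by_id, reference_species=family.reference
    )
    profiles = rscu_profile(cmsa, classification)
    sites = detect_conserved_nonoptimal(
        profiles,
        require_gap_free=require_gap_free,
        require_rare=require_rare,
        rare_threshold=rare_threshold,
        min_fraction=min_fraction,
    )
    params = {
        "require_gap_free": require_gap_free,
        "require_rare": require_rare,
        "rare_threshold": rare_threshold,
        "min_fraction": min_fraction,
        "reference_species": family.reference,
    }
    report = make_report(family.family_id, sites, params)
    ref_ann = None
    if annotations and family.reference in annotations:
        ref_ann = annotations[family.reference]
    elif predict_tm:
        ref_protein = translate(family.cds_by_id[family.reference])
        try:
            ref_ann = predict_topology(ref_protein, protein_id=family.reference)
        except ValueError as exc:  # e.g. protein shorter than the window
            logger.warning("%s: topology prediction failed: %s", family.family_id, exc)
    if ref_ann is not None:
        report = annotate_with_topology(report, {family.reference: ref_ann}, family.reference)
    return report, profiles, ref_ann


def scan_gene_families(
    families: Iterable[GeneFamily],
    classification: Mapping[str, CodonClassification] | CodonClassification,
    annotations: Mapping[str, TopologyAnnotation] | None = None,
    window: tuple[int, int] = (-10, 5),
    **scan_kwargs,
) -> BatchScanResult:
    """Scan many families, keeping sites near the first TMS.

    Per family: run :func:`scan_family`, then keep only sites whose
    offset to the reference first TMS lies in ``[window[0], window[1]]``
    (closed).  Families with no predicted/annotated first TMS are
    skipped with a logged reason; per-family errors are collected as
    skip reasons so one bad family does not abort the batch.
    """
    lo, hi = window
    candidates: list[FamilyCandidate] = []
    skipped: dict[str, str] = {}
    for family in families:
        try:
            report, _, ref_ann = scan_family(
                family, classification, annotations=annotations, **scan_kwargs
            )
        except Exception as exc:  # noqa: BLE001 - collected per family
            skipped[family.family_id] = f"error: {exc}"
            logger.warning("family %s skipped: %s", family.family_id, exc)
            continue
        if ref_ann is None or ref_ann.first_tms is None:
            skipped[family.family_id] = "no TMS"
            logger.info("family %s skipped: no first TMS", family.family_id)
            continue
        kept = [
            s for s in report.sites if s.tms_offset is not None and lo <= s.tms_offset <= hi
        ]
        if kept:
            candidates.append(
                FamilyCandidate(
                    family_id=family.family_id,
                    report=make_report(family.family_id, kept, report.parameters),
                    first_tms_start=ref_ann.first_tms.start,
                )
            )
    return BatchScanResult(candidates=tuple(candidates), skipped=skipped)
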