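"""End-to-end scan orchestration, configuration and reporting.

``run_full_scan`` wires the stages together: read per-species CDS, read
or build the protein alignment, derive the codon classification from an
RSCU table or a HEG CDS set, back-translate, profile, detect conserved
non-optimal sites, annotate offsets to the first TMS, and write the
sites/runs TSVs, a JSON summary and (optionally) the per-column RSCU
profile plot.  Outputs are deterministic for fixed inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml

from . import __version__
from .codon_alignment import read_alignment, read_fasta, validate_cds
from .codon_stats import classify_codons, compute_rscu, count_codons, load_rscu_table
from .conservation_scan import (
    GeneFamily,
    ScanReport,
    SiteProfile,
    scan_family,
)
from .topology import TopologyAnnotation, load_topology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full scan.

    Exactly one of ``rscu_table``/``heg_fasta`` must be given; topology
    comes from ``topology_table`` or hydropathy prediction
    (``predict_tm``).
    """

    cds_dir: str
    out_prefix: str
    msa: str | None = None
    rscu_table: str | None = None
    heg_fasta: str | None = None
    topology_table: str | None = None
    predict_tm: bool = True
    reference_species: str | None = None
    rare_threshold: float = 0.5
    require_rare: bool = False
    require_gap_free: bool = True
    min_fraction: float = 1.0
    window: tuple[int, int] = (-10, 5)
    plot: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.rscu_table is None) == (self.heg_fasta is None):
            raise ValueError("exactly one of rscu_table or heg_fasta is required")
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be in (0, 1]")
        lo, hi = self.window
        if lo > hi:
            raise ValueError(f"window lower bound {lo} exceeds upper bound {hi}")


def config_from_yaml(path) -> PipelineConfig:
    """Load a config YAML, rejecting unknown keys before any compute."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "window" in raw:
        raw["window"] = tuple(raw["window"])
    return PipelineConfig(**raw)


def _write_sites_tsv(path, report: ScanReport, species: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# codonpause {__version__} conserved non-optimal sites\n")
        fh.write(f"# family={report.gene_family_id}\n")
        for k in sorted(report.parameters):
            fh.write(f"# {k}={report.parameters[k]}\n")
        cols = ["column", "reference_position", "tms_offset", "all_rare", "mean_rscu", "sd_rscu"]
        cols += [f"codon_{sp}" for sp in species]
        fh.write("\t".join(cols) + "\n")
        for s in report.sites:
            row = [
                str(s.column),
                "" if s.reference_position is None else str(s.reference_position),
                "" if s.tms_offset is None else str(s.tms_offset),
                str(s.all_rare),
                "" if s.mean_rscu is None else f"{s.mean_rscu:.4f}",
                "" if s.sd_rscu is None else f"{s.sd_rscu:.4f}",
            ]
            row += [s.per_species_codons.get(sp) or "---" for sp in species]
            fh.write("\t".join(row) + "\n")


def _write_runs_tsv(path, report: ScanReport) -> None:
    with open(path, "w") as fh:
        fh.write(f"# codonpause {__version__} adjacent-site runs\n")
        fh.write("start_column\tend_column\tlength\ttms_offsets\n")
        for r in report.runs:
            offsets = ",".join(
                "NA" if s.tms_offset is None else str(s.tms_offset) for s in r.sites
            )
            fh.write(f"{r.start_column}\t{r.end_column}\t{r.length}\t{offsets}\n")


def render_profile_plot(
    profiles: list[SiteProfile],
    tms: TopologyAnnotation | None,
    highlight: list[int],
    out_path,
    reference_species: str | None = None,
) -> Path:
    """Per-column RSCU profile figure.

    Reference-species RSCU as a solid line, cross-species mean as a
    dashed line with a +-SD band, the first-TMS extent as a black box
    below the axis, and highlighted columns shaded grey.
    """
    if not profiles:
        raise ValueError("cannot plot an empty profile list")
    cols = [p.column for p in profiles]
    ref = reference_species
    if ref is None:
        ref = next(iter(profiles[0].per_species))
    ref_vals = [p.per_species.get(ref, (None, None))[1] for p in profiles]
    means = [p.mean_rscu for p in profiles]
    sds = [p.sd_rscu for p in profiles]

    fig, ax = plt.subplots(figsize=(max(6.0, len(cols) / 12), 3.5))
    for col in highlight:
        if cols[0] <= col <= cols[-1]:
            ax.axvspan(col - 0.5, col + 0.5, color="0.85", zorder=0)
        else:
            logger.warning("highlight column %d outside profile range", col)
    ax.plot(cols, ref_vals, "-", lw=1.2, color="tab:blue", label=f"RSCU_HEG ({ref})")
    mean_arr = [m if m is not None else float("nan") for m in means]
    sd_arr = [s if s is not None else 0.0 for s in sds]
    ax.plot(cols, mean_arr, "--", lw=1.0, color="tab:red", label="cross-species mean")
    ax.fill_between(
        cols,
        [m - s for m, s in zip(mean_arr, sd_arr)],
        [m + s for m, s in zip(mean_arr, sd_arr)],
        color="tab:red",
        alpha=0.15,
        label="+-SD (population)",
    )
    ax.axhline(1.0, color="0.5", lw=0.8, ls=":")
    if tms is not None and tms.first_tms is not None:
        seg = tms.first_tms
        y0 = ax.get_ylim()[0]
        ax.plot([seg.start, seg.end], [y0, y0], color="black", lw=6, solid_capstyle="butt",
                label="first TMS")
    ax.set_xlabel("alignment column (codon)")
    ax.set_ylabel("RSCU (HEG reference)")
    ax.set_xlim(cols[0] - 0.5, cols[-1] + 0.5)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def run_full_scan(config: PipelineConfig) -> ScanReport:
    """Run the whole screen on one gene family and write artifacts.

    Writes ``<out_prefix>.sites.tsv``, ``<out_prefix>.runs.tsv``,
    ``<out_prefix>.summary.json`` and, with ``plot=True``,
    ``<out_prefix>.profile.png``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    def stage(name: str):
        logger.info("stage: %s", name)

    stage("load CDS")
    cds_dir = Path(config.cds_dir)
    cds_by_id = {}
    fasta_files = sorted(cds_dir.glob("*.fasta")) + sorted(cds_dir.glob("*.fa"))
    if not fasta_files:
        raise FileNotFoundError(f"no FASTA files in {cds_dir}")
    for f in fasta_files:
        for rec in read_fasta(f, "dna"):
            cds_by_id[rec.id] = validate_cds(rec)

    stage("classification")
    if config.rscu_table is not None:
        rscu = load_rscu_table(config.rscu_table)
    else:
        heg = [validate_cds(r) for r in read_fasta(config.heg_fasta, "dna")]
        rscu = compute_rscu(count_codons(heg, gene_set_label="HEG set")).rscu
    classification = classify_codons(rscu, rare_threshold=config.rare_threshold)

    stage("alignment")
    pmsa = read_alignment(config.msa) if config.msa else None
    reference = config.reference_species or sorted(cds_by_id)[0]
    family = GeneFamily(
        family_id=Path(config.out_prefix).name,
        cds_by_id=dict(sorted(cds_by_id.items())),
        protein_msa=pmsa,
        reference_species=reference,
    )

    annotations = None
    if config.topology_table:
        stage("topology (external)")
        annotations = load_topology(config.topology_table)

    stage("scan")
    report, profiles, ref_ann = scan_family(
        family,
        classification,
        annotations=annotations,
        require_gap_free=config.require_gap_free,
        require_rare=config.require_rare,
        rare_threshold=config.rare_threshold,
        min_fraction=config.min_fraction,
        predict_tm=config.predict_tm,
    )

    stage("write outputs")
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    species = sorted(cds_by_id)
    _write_sites_tsv(f"{prefix}.sites.tsv", report, species)
    _write_runs_tsv(f"{prefix}.runs.tsv", report)
    summary = {
        "version": __version__,
        "parameters": {
            **report.parameters,
            "window": list(config.window),
            "predict_tm": config.predict_tm,
        },
        "family": report.gene_family_id,
        "n_species": len(species),
        "n_columns": len(profiles),
        "n_sites": len(report.sites),
        "n_runs": len(report.runs),
        "sites": [
            {
                "column": s.column,
                "reference_position": s.reference_position,
                "tms_offset": s.tms_offset,
                "all_rare": s.all_rare,
            }
            for s in report.sites
        ],
        "first_tms": (
            None
            if ref_ann is None or ref_ann.first_tms is None
            else {"start": ref_ann.first_tms.start, "end": ref_ann.first_tms.end}
        ),
    }
    Path(f"{prefix}.summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if config.plot:
        render_profile_plot(
            profiles,
            ref_ann,
            highlight=[s.column for s in report.sites],
            out_path=f"{prefix}.profile.png",
            reference_species=reference,
        )
    return report
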