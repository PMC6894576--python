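"""Transmembrane segment prediction from hydropathy, and annotation IO.

A sliding Kyte-Doolittle hydropathy window is the classic desk method
for locating candidate transmembrane segments (TMS).  Residues whose
windowed mean exceeds a threshold seed a segment; seeds are extended
outward while the raw per-residue hydropathy stays above the threshold
(window smoothing systematically erodes segment ends by up to half a
window, so the raw-value extension restores physical boundaries), then
nearby runs are merged and short runs discarded.  Externally computed
topology (e.g. from a dedicated HMM predictor) can be loaded from TSV
instead and used interchangeably downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

logger = logging.getLogger(__name__)

SCALES = {"kyte_doolittle": KYTE_DOOLITTLE}


@dataclass(frozen=True)
class TMSegment:
    """One transmembrane segment, 1-based inclusive residue coordinates."""

    start: int
    end: int
    mean_hydropathy: float = math.nan

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid segment [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered, non-overlapping TM segments of one protein."""

    protein_id: str
    segments: tuple[TMSegment, ...]
    source: str = "hydropathy"  # "hydropathy" | "external"

    def __post_init__(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError(
                    f"{self.protein_id}: segments overlap or are unsorted at [{seg.start}, {seg.end}]"
                )
            prev_end = seg.end

    @property
    def first_tms(self) -> TMSegment | None:
        return self.segments[0] if self.segments else None


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed hydropathy values plus the raw per-residue scale values."""

    protein_id: str
    values: np.ndarray  # windowed means; NaN where the window overhangs
    raw: np.ndarray  # per-residue scale values
    window: int
    scale: str = "kyte_doolittle"

    def __len__(self) -> int:
        return len(self.values)


def hydropathy_profile(
    protein: str,
    window: int = 19,
    scale: str = "kyte_doolittle",
    protein_id: str = "",
) -> HydropathyProfile:
    """Centred moving-average hydropathy along a protein.

    Positions closer than ``window // 2`` to either end have no fully
    contained window and get NaN.  Non-standard residues score 0 with a
    logged warning.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown hydropathy scale {scale!r}")
    table = SCALES[scale]
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > len(protein):
        raise ValueError(
            f"window {window} exceeds protein length {len(protein)}"
        )
    seq = protein.upper()
    unknown = sorted(set(seq) - set(table))
    if unknown:
        logger.warning("non-standard residues scored 0: %s", ",".join(unknown))
    raw = np.array([table.get(a, 0.0) for a in seq], dtype=float)
    half = window // 2
    values = np.full(len(seq), np.nan)
    means = np.convolve(raw, np.ones(window) / window, mode="valid")
    values[half : len(seq) - half] = means
    return HydropathyProfile(
        protein_id=protein_id, values=values, raw=raw, window=window, scale=scale
    )


def predict_tm_segments(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_length: int = 15,
    merge_gap: int = 3,
) -> TopologyAnnotation:
    """Call TM segments from a hydropathy profile.

    Seeds = maximal runs where the windowed mean >= threshold; each seed
    is extended outward while the raw residue value >= threshold; runs
    separated by <= merge_gap residues are merged; merged runs shorter
    than min_length are discarded.
    """
    vals = profile.values
    raw = profile.raw
    n = len(vals)
    above = np.where(np.nan_to_num(vals, nan=-np.inf) >= threshold)[0]
    runs: list[list[int]] = []
    for idx in above:
        if runs and idx == runs[-1][1] + 1:
            runs[-1][1] = idx
        else:
            runs.append([idx, idx])
    # extend by raw hydropathy
    for run in runs:
        while run[0] > 0 and raw[run[0] - 1] >= threshold:
            run[0] -= 1
        while run[1] < n - 1 and raw[run[1] + 1] >= threshold:
            run[1] += 1
    # merge overlapping/nearby runs
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = max(merged[-1][1], run[1])
        else:
            merged.append(run)
    segments = tuple(
        TMSegment(
            start=int(s) + 1,
            end=int(e) + 1,
            mean_hydropathy=float(np.mean(raw[s : e + 1])),
        )
        for s, e in merged
        if e - s + 1 >= min_length
    )
    return TopologyAnnotation(
        protein_id=profile.protein_id, segments=segments, source="hydropathy"
    )


def predict_topology(
    protein: str,
    protein_id: str = "",
    window: int = 19,
    scale: str = "kyte_doolittle",
    threshold: float = 1.6,
    min_length: int = 15,
    merge_gap: int = 3,
) -> TopologyAnnotation:
    """Convenience wrapper: profile + segment calling in one step."""
    prof = hydropathy_profile(protein, window=window, scale=scale, protein_id=protein_id)
    return predict_tm_segments(prof, threshold=threshold, min_length=min_length, merge_gap=merge_gap)


def offset_to_first_tms(position: int, annotation: TopologyAnnotation) -> int | None:
    """Signed residue offset of a position to the first TMS start.

    Negative = upstream (N-terminal side) of the first TMS; 0 = the
    first TMS residue itself.  ``None`` when no segment is annotated.
    """
    first = annotation.first_tms
    if first is None:
        return None
    return position - first.start


def load_topology(path) -> dict[str, TopologyAnnotation]:
    """Load external topology annotations from a TSV.

    Expected columns: protein_id, start, end (1-based inclusive).
    Segments per protein are sorted; overlaps and start > end rejected.
    An empty file yields an empty annotation set with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        logger.warning("topology file %s is empty", path)
        return {}
    if df.empty:
        logger.warning("topology file %s has no rows", path)
        return {}
    required = {"protein_id", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"topology TSV must have columns {sorted(required)}")
    out: dict[str, TopologyAnnotation] = {}
    for pid, group in df.groupby("protein_id", sort=True):
        segs = sorted(
            (int(r.start), int(r.end)) for r in group.itertuples()
        )
        for s, e in segs:
            if s > e:
                raise ValueError(f"{pid}: segment start {s} > end {e}")
        annotation = TopologyAnnotation(
            protein_id=str(pid),
            segments=tuple(TMSegment(s, e) for s, e in segs),
            source="external",
        )
        out[str(pid)] = annotation
    return out


def write_topology(path, annotations: Sequence[TopologyAnnotation] | dict) -> None:
    if isinstance(annotations, dict):
        annotations = [annotations[k] for k in sorted(annotations)]
    rows = [
        {"protein_id": a.protein_id, "start": seg.start, "end": seg.end}
        for a in annotations
        for seg in a.segments
    ]
    pd.DataFrame(rows, columns=["protein_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )
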