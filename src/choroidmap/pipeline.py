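"""End-to-end study pipeline: generate → motion-correct → segment → map
→ tabulate.

`analyze_volume` runs the measurement chain on one volume; `run_study`
generates a synthetic cohort and produces the cohort table, pairwise
comparisons and per-diopter reduction rates, applying the dual-analysis
15% exclusion rule (the second "operator" is the same segmenter with a
different smoothing configuration).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import cohort_stats, iol_measurement, motion_correction, segmentation
from . import thickness_mapping as tm
from .synthetic_oct import CohortEye, CohortSpec, RenderParams, generate_cohort
from .volume_io import OCTVolume

__all__ = ["EyeAnalysis", "StudyResult", "analyze_volume", "run_study"]

# second-operator segmentation configuration for the discrepancy QC
_OPERATOR_B = dict(presmooth_sigma=(1.5, 2.25), median_size=5)


@dataclasses.dataclass
class EyeAnalysis:
    ctmap: tm.ThicknessMap
    sectors: tm.SectorSummary
    profile: tm.RingProfile
    surfaces: dict[str, segmentation.SurfaceMap]
    shift_trace: motion_correction.ShiftTrace
    discrepancy: float


def analyze_volume(vol: OCTVolume, max_shift: int = 8,
                   qc_dual_operator: bool = True) -> EyeAnalysis:
    """Measure one OCT volume: motion correction, segmentation, fovea
    localisation, normal-thickness mapping, sector summary, ring profile
    and (optionally) the dual-analysis discrepancy."""
    corrected, trace = motion_correction.correct_motion(vol, max_shift=max_shift)
    surfaces = segmentation.segment_volume(corrected)
    axial_um = vol.axial_geom_um_per_px
    fovea = tm.locate_fovea(surfaces["ILM"], vol.lateral_spacing_x_mm,
                            vol.lateral_spacing_y_mm, axial_um)
    ctmap = tm.thickness_normal(
        surfaces["RPE_outer"], surfaces["CSI"],
        vol.lateral_spacing_x_mm, vol.lateral_spacing_y_mm, axial_um,
        vol.laterality, fovea_xy_mm=fovea,
    )
    sectors = tm.sector_summary(ctmap)
    profile = tm.ring_profile(ctmap)

    discrepancy = 0.0
    if qc_dual_operator:
        surfaces_b = segmentation.segment_volume(corrected, **_OPERATOR_B)
        ctmap_b = tm.thickness_normal(
            surfaces_b["RPE_outer"], surfaces_b["CSI"],
            vol.lateral_spacing_x_mm, vol.lateral_spacing_y_mm, axial_um,
            vol.laterality, fovea_xy_mm=fovea,
        )
        discrepancy = segmentation.segmentation_discrepancy(ctmap, ctmap_b)
    return EyeAnalysis(ctmap=ctmap, sectors=sectors, profile=profile,
                       surfaces=surfaces, shift_trace=trace,
                       discrepancy=discrepancy)


@dataclasses.dataclass
class StudyResult:
    records: list[cohort_stats.EyeRecord]
    table: cohort_stats.CohortTable
    analyses: dict[str, EyeAnalysis]
    eyes: list[CohortEye]


def run_study(spec: CohortSpec, seed: int,
              params: RenderParams | None = None,
              qc_dual_operator: bool = False,
              keep_volumes: bool = False) -> StudyResult:
    """Run the full synthetic study.

    Generates the cohort at ``seed``, measures every eye (volume pipeline
    plus composite-A-scan axial length), applies the 15% dual-analysis
    exclusion when ``qc_dual_operator`` is set, and tabulates the cohort.
    ``keep_volumes=False`` drops raw volumes after analysis to bound
    memory.
    """
    params = params or RenderParams()
    eyes = generate_cohort(spec, seed, params)
    records: list[cohort_stats.EyeRecord] = []
    analyses: dict[str, EyeAnalysis] = {}
    for eye in eyes:
        analysis = analyze_volume(eye.volume, qc_dual_operator=qc_dual_operator)
        iol = iol_measurement.measure_iol(eye.composite)
        excluded = analysis.discrepancy > segmentation.DISCREPANCY_LIMIT
        records.append(cohort_stats.EyeRecord(
            eye_id=eye.eye_id,
            laterality=eye.laterality,
            refractive_error_d=eye.refractive_error_d,
            group=eye.group,
            iol_mm=iol.iol_mm,
            sectors=analysis.sectors,
            profile=analysis.profile,
            discrepancy=analysis.discrepancy,
            excluded=excluded,
        ))
        analyses[eye.eye_id] = analysis
        if not keep_volumes:
            eye.volume = None  # type: ignore[assignment]
    table = cohort_stats.group_table(records)
    return StudyResult(records=records, table=table, analyses=analyses, eyes=eyes)


def cohort_sector_mean(records, group: str, sector: str) -> float:
    """Cohort mean of one sector over non-excluded eyes of a group."""
    vals = [r.sectors.mean_um[sector] for r in records
            if r.group == group and not r.excluded]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        raise ValueError(f"no valid {sector} values in group {group}")
    return float(np.mean(vals))


def cohort_ring_mean(records, group: str, offset_mm: int) -> float:
    """Cohort mean of one ring-profile bin over non-excluded eyes."""
    out = []
    for r in records:
        if r.group != group or r.excluded or r.profile is None:
            continue
        i = int(offset_mm + 5)
        v = r.profile.mean_um[i]
        if np.isfinite(v):
            out.append(v)
    if not out:
        raise ValueError(f"no valid ring bin {offset_mm} values in group {group}")
    return float(np.mean(out))
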