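"""Cohort-level statistics and rendering.

Eyes are grouped by spherical-equivalent refractive error (low myopia
|D| ≤ 3, moderate 3 < |D| < 6, high |D| ≥ 6), sector statistics are
tabulated as mean ± sample STD, groups are compared with the classical
pooled-variance Student's t-test (two-sided; Welch available by flag),
and per-diopter reduction rates are computed between adjacent group
means over a 3 D span.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import matplotlib
from scipy import stats as sps

from .thickness_mapping import RingProfile, SectorSummary, ThicknessMap, classify_sector
from .volume_io import OCTVolume, SECTOR_ORDER

__all__ = [
    "EyeRecord",
    "CohortTable",
    "assign_group",
    "group_table",
    "students_t",
    "reduction_rate",
    "render_ct_map",
    "GROUP_ORDER",
]

GROUP_ORDER = ("low", "moderate", "high")

#: Diopter span between adjacent group midpoints used for reduction rates.
DIOPTER_SPAN = 3.0


@dataclasses.dataclass
class EyeRecord:
    """One analysed eye, ready for cohort tabulation."""

    eye_id: str
    laterality: str
    refractive_error_d: float
    group: str
    iol_mm: float | None
    sectors: SectorSummary
    profile: RingProfile | None = None
    discrepancy: float | None = None
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.group != assign_group(self.refractive_error_d):
            raise ValueError(
                f"group {self.group!r} inconsistent with refractive error "
                f"{self.refractive_error_d} D"
            )


@dataclasses.dataclass
class CohortTable:
    """Per group × sector statistics plus comparisons and rates."""

    stats: pd.DataFrame          # group, sector, mean, std, n
    comparisons: pd.DataFrame    # group_a, group_b, sector, t, p
    rates: dict[str, float]      # named per-diopter reduction rates


def assign_group(refractive_error_d: float) -> str:
    """Myopia group from signed refractive error (D, ≤ 0).

    low: |D| ≤ 3; moderate: 3 < |D| < 6; high: |D| ≥ 6.
    """
    if refractive_error_d > 0:
        raise ValueError("hyperopic refractive error is out of study scope")
    m = abs(refractive_error_d)
    if m <= 3:
        return "low"
    if m < 6:
        return "moderate"
    return "high"


def students_t(sample_a, sample_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance by default).

    Returns (t, two-sided p).  Degenerate zero-variance input: equal
    means give (0, 1); unequal means give (±inf, 0).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return (0.0, 1.0) if ma == mb else (math.copysign(math.inf, ma - mb), 0.0)
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        df = na + nb - 2
        if sp2 == 0:
            return (0.0, 1.0) if ma == mb else (math.copysign(math.inf, ma - mb), 0.0)
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def reduction_rate(mean_a: float, mean_b: float,
                   diopter_span: float = DIOPTER_SPAN) -> float:
    """Per-diopter reduction (mean_a − mean_b) / span.

    Presentation precision is 2 decimals for CT (µm/D) and 3 for IOL
    (mm/D); the returned value is unrounded.
    """
    if diopter_span <= 0:
        raise ValueError("diopter span must be > 0")
    return (mean_a - mean_b) / diopter_span


def group_table(records: list[EyeRecord]) -> CohortTable:
    """Tabulate per-group per-sector mean and sample STD (n−1), compare
    groups pairwise on the subfoveal sector and IOL, and compute
    per-diopter reduction rates between adjacent groups.

    Excluded eyes are dropped before any statistic.  Empty cells are
    flagged missing (NaN), never zero.
    """
    kept = [r for r in records if not r.excluded]
    if not kept:
        raise ValueError("no non-excluded records")
    rows = []
    by_group: dict[str, list[EyeRecord]] = {g: [] for g in GROUP_ORDER}
    for r in kept:
        by_group.setdefault(r.group, []).append(r)
    for g in GROUP_ORDER:
        recs = by_group.get(g, [])
        for sector in SECTOR_ORDER:
            vals = np.array([r.sectors.mean_um[sector] for r in recs], dtype=float)
            vals = vals[np.isfinite(vals)]
            n = len(vals)
            rows.append({
                "group": g, "sector": sector, "n": n,
                "mean_um": float(vals.mean()) if n >= 1 else float("nan"),
                "std_um": float(vals.std(ddof=1)) if n >= 2 else float("nan"),
            })
        iols = np.array([r.iol_mm for r in recs if r.iol_mm is not None], dtype=float)
        rows.append({
            "group": g, "sector": "IOL_mm", "n": len(iols),
            "mean_um": float(iols.mean()) if len(iols) >= 1 else float("nan"),
            "std_um": float(iols.std(ddof=1)) if len(iols) >= 2 else float("nan"),
        })
    stats = pd.DataFrame(rows)

    comp_rows = []
    pairs = [("low", "moderate"), ("moderate", "high"), ("low", "high")]
    for ga, gb in pairs:
        for quantity in ("Fovea", "IOL_mm"):
            if quantity == "IOL_mm":
                va = [r.iol_mm for r in by_group.get(ga, []) if r.iol_mm is not None]
                vb = [r.iol_mm for r in by_group.get(gb, []) if r.iol_mm is not None]
            else:
                va = [r.sectors.mean_um[quantity] for r in by_group.get(ga, [])]
                vb = [r.sectors.mean_um[quantity] for r in by_group.get(gb, [])]
            va = [v for v in va if np.isfinite(v)]
            vb = [v for v in vb if np.isfinite(v)]
            if len(va) >= 2 and len(vb) >= 2:
                t, p = students_t(va, vb)
            else:
                t, p = float("nan"), float("nan")
            comp_rows.append({"group_a": ga, "group_b": gb,
                              "quantity": quantity, "t": t, "p": p})
    comparisons = pd.DataFrame(comp_rows)

    def _mean(g, sector):
        row = stats[(stats.group == g) & (stats.sector == sector)]
        return float(row.mean_um.iloc[0]) if len(row) else float("nan")

    rates = {
        "ct_low_to_moderate_um_per_d": reduction_rate(_mean("low", "Fovea"),
                                                      _mean("moderate", "Fovea")),
        "ct_moderate_to_high_um_per_d": reduction_rate(_mean("moderate", "Fovea"),
                                                       _mean("high", "Fovea")),
        "iol_low_to_moderate_mm_per_d": reduction_rate(_mean("moderate", "IOL_mm"),
                                                       _mean("low", "IOL_mm")),
        "iol_moderate_to_high_mm_per_d": reduction_rate(_mean("high", "IOL_mm"),
                                                        _mean("moderate", "IOL_mm")),
    }
    return CohortTable(stats=stats, comparisons=comparisons, rates=rates)


def render_ct_map(vol: OCTVolume, ctmap: ThicknessMap, summary: SectorSummary,
                  ct_scale_um: tuple[float, float] = (0.0, 400.0),
                  alpha: float = 0.55, path=None) -> np.ndarray:
    """En-face fundus image with the sector grid coloured by mean CT.

    The fundus is the per-(x, y) maximum intensity over depth; sector
    overlays use a fixed CT colour scale with a scale bar strip appended
    on the right.  Output is a deterministic uint8 RGB array; ``path``
    optionally writes a PNG.
    """
    fundus = vol.intensity.max(axis=0)  # (nx, ny)
    lo, hi = np.percentile(fundus, [1, 99])
    gray = np.clip((fundus - lo) / max(hi - lo, 1e-12), 0, 1)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)

    cmap = matplotlib.colormaps["turbo"]
    vmin, vmax = ct_scale_um
    from .thickness_mapping import _normalized_offsets  # shared geometry
    u, v = _normalized_offsets(ctmap)
    labels = classify_sector(u, v, summary.ring_diameters_mm)
    overlay = rgb.copy()
    for name in SECTOR_ORDER:
        mean = summary.mean_um.get(name, float("nan"))
        if not np.isfinite(mean):
            continue
        color = np.array(cmap((mean - vmin) / max(vmax - vmin, 1e-12))[:3])
        mask = labels == name
        overlay[mask] = (1 - alpha) * rgb[mask] + alpha * color

    # scale bar: vertical colour strip, vmax at top
    nx, ny = gray.shape
    bar_w = max(4, ny // 16)
    ramp = np.linspace(1.0, 0.0, nx)
    bar = np.array([cmap(val)[:3] for val in ramp])
    strip = np.repeat(bar[:, None, :], bar_w, axis=1)
    gap = np.ones((nx, 2, 3))
    img = np.concatenate([overlay, gap, strip], axis=1)
    img8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, img8)
    return img8
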