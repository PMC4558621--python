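"""Choroidal-thickness maps, fovea localisation and the geographic grid.

Choroidal thickness (CT) is the distance from the outer RPE surface to
the choroid–sclera interface measured **normal to the RPE curve**, in
geometric micrometres (axial air pitch divided by the tissue refractive
index).  Maps are summarised on a fovea-centred grid of three concentric
rings (1, 5, 10 mm diameters) split into quadrant sectors — Fovea, then
nasal / superior / temporal / inferior inner macula (NIM, SIM, TIM, IIM)
and outer macula (NOM, SOM, TOM, IOM) — and as a finer nasal–temporal
ring profile at 1 mm steps out to 5 mm.  For left eyes the horizontal
axis is mirrored so "nasal" always points toward the optic disc.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .segmentation import SurfaceMap
from .volume_io import SECTOR_ORDER

__all__ = [
    "ThicknessMap",
    "SectorSummary",
    "RingProfile",
    "FoveaNotFoundError",
    "locate_fovea",
    "thickness_normal",
    "sector_summary",
    "ring_profile",
    "classify_sector",
]

RING_DIAMETERS_MM = (1.0, 5.0, 10.0)


class FoveaNotFoundError(ValueError):
    """No foveal pit detectable; supply the centre manually."""


@dataclasses.dataclass
class ThicknessMap:
    """CT in µm per (x, y); NaN where invalid."""

    ct: np.ndarray                 # (n_alines, n_bscans) µm, NaN = invalid
    lateral_spacing_x_mm: float
    lateral_spacing_y_mm: float
    laterality: str
    fovea_xy_mm: tuple[float, float] | None = None  # scan frame, scan-centred

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be OD or OS")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.ct)

    def x_mm(self) -> np.ndarray:
        n = self.ct.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) * self.lateral_spacing_x_mm

    def y_mm(self) -> np.ndarray:
        n = self.ct.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.lateral_spacing_y_mm


@dataclasses.dataclass
class SectorSummary:
    """Mean CT and valid-area fraction per named sector (NaN = missing)."""

    mean_um: dict[str, float]
    valid_fraction: dict[str, float]
    ring_diameters_mm: tuple[float, float, float] = RING_DIAMETERS_MM

    def __post_init__(self) -> None:
        d = self.ring_diameters_mm
        if not (d[0] < d[1] < d[2]):
            raise ValueError("ring diameters must be strictly increasing")


@dataclasses.dataclass
class RingProfile:
    """Nasal–temporal CT profile: 11 bins at signed offsets −5…+5 mm
    (negative = nasal), 1 mm apart; NaN where a bin is empty."""

    offsets_mm: np.ndarray
    mean_um: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.offsets_mm) != 11:
            raise ValueError("ring profile must have 11 bins")


def locate_fovea(ilm: SurfaceMap, lateral_spacing_x_mm: float,
                 lateral_spacing_y_mm: float, axial_um_per_px: float,
                 central_fraction: float = 0.6,
                 smooth_sigma_mm: float = 0.25,
                 min_pit_depth_um: float = 5.0) -> tuple[float, float]:
    """Locate the foveal pit centre from the ILM surface, in mm.

    The ILM depth map is Gaussian-smoothed (σ = 0.25 mm); the pit is the
    maximum depth within the central 60% of the scan, refined by a
    centre-of-mass over the deepest 5% of pit pixels.
    """
    if ilm.valid.mean() < 0.5:
        raise ValueError("ILM surface must be at least 50% valid")
    z = ilm.z.copy()
    z[~ilm.valid] = np.nan
    # fill invalid cells from the valid neighbourhood before smoothing
    if np.isnan(z).any():
        fill = np.nanmedian(z)
        z = np.where(np.isnan(z), fill, z)
    sigma = (smooth_sigma_mm / lateral_spacing_x_mm,
             smooth_sigma_mm / lateral_spacing_y_mm)
    zs = ndimage.gaussian_filter(z, sigma)
    nx, ny = zs.shape
    mx = int(round(nx * (1 - central_fraction) / 2))
    my = int(round(ny * (1 - central_fraction) / 2))
    win = zs[mx: nx - mx, my: ny - my]
    depth_range_um = float(np.ptp(win)) * axial_um_per_px
    if depth_range_um < min_pit_depth_um:
        raise FoveaNotFoundError(
            f"no foveal pit: smoothed ILM depth range {depth_range_um:.2f} µm "
            f"< {min_pit_depth_um} µm; supply the centre manually"
        )
    thr = np.quantile(win, 0.95)  # deepest 5% of pit pixels
    mask = win >= thr
    wgt = np.where(mask, win - thr, 0.0)
    ii, jj = np.meshgrid(np.arange(win.shape[0]), np.arange(win.shape[1]),
                         indexing="ij")
    tot = wgt.sum()
    if tot <= 0:
        ci, cj = np.unravel_index(np.argmax(win), win.shape)
    else:
        ci = float((ii * wgt).sum() / tot)
        cj = float((jj * wgt).sum() / tot)
    ix = ci + mx
    iy = cj + my
    x = (ix - (nx - 1) / 2.0) * lateral_spacing_x_mm
    y = (iy - (ny - 1) / 2.0) * lateral_spacing_y_mm
    return float(x), float(y)


def thickness_normal(rpe: SurfaceMap, csi: SurfaceMap,
                     lateral_spacing_x_mm: float, lateral_spacing_y_mm: float,
                     axial_um_per_px: float, laterality: str,
                     fovea_xy_mm: tuple[float, float] | None = None,
                     rpe_smooth_sigma_mm: float = 0.2,
                     march_step_px: float = 0.25,
                     max_distance_um: float = 1000.0) -> ThicknessMap:
    """CT map measured along the local RPE normal.

    At each valid (x, y) the unit normal of the Gaussian-smoothed RPE
    surface is computed in physical units, a ray is cast from the RPE
    point along it (step 0.25 axial px), and CT is the Euclidean distance
    to the first crossing of the (bilinearly interpolated) CSI surface,
    with linear interpolation at the crossing.  Cells whose ray exits the
    grid, samples invalid CSI, or finds no crossing within 1000 µm are
    invalid (NaN).
    """
    if rpe.z.shape != csi.z.shape:
        raise ValueError("surfaces must share a grid")
    nx, ny = rpe.z.shape
    dx_um = lateral_spacing_x_mm * 1000.0
    dy_um = lateral_spacing_y_mm * 1000.0

    rpe_um = rpe.z * axial_um_per_px
    csi_um = csi.z * axial_um_per_px
    csi_um = np.where(csi.valid, csi_um, np.nan)

    sig = (rpe_smooth_sigma_mm / lateral_spacing_x_mm,
           rpe_smooth_sigma_mm / lateral_spacing_y_mm)
    rpe_s = ndimage.gaussian_filter(rpe_um, sig)
    gx, gy = np.gradient(rpe_s, dx_um, dy_um)
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    n_x, n_y, n_z = -gx / norm, -gy / norm, 1.0 / norm  # points deeper

    xi = np.arange(nx) * dx_um
    yi = np.arange(ny) * dy_um
    csi_itp = RegularGridInterpolator((xi, yi), csi_um, bounds_error=False,
                                      fill_value=np.nan)

    xx, yy = np.meshgrid(xi, yi, indexing="ij")
    valid0 = rpe.valid & csi.valid
    px = xx.ravel()
    py = yy.ravel()
    pz = rpe_um.ravel()
    vx = n_x.ravel()
    vy = n_y.ravel()
    vz = n_z.ravel()

    step_um = march_step_px * axial_um_per_px
    n_steps = int(np.ceil(max_distance_um / step_um))
    ct = np.full(nx * ny, np.nan)
    active = valid0.ravel().copy()
    prev_f = np.full(nx * ny, np.nan)
    t_prev = 0.0
    idx_all = np.arange(nx * ny)
    # f(t) = ray depth − CSI depth at the ray's lateral position; starts < 0
    for k in range(n_steps + 1):
        if not active.any():
            break
        t = k * step_um
        ids = idx_all[active]
        sx = px[ids] + t * vx[ids]
        sy = py[ids] + t * vy[ids]
        sz = pz[ids] + t * vz[ids]
        surf = csi_itp(np.column_stack([sx, sy]))
        f = sz - surf
        bad = ~np.isfinite(f)
        crossed = np.zeros_like(f, dtype=bool)
        if k > 0:
            fp = prev_f[ids]
            crossed = np.isfinite(f) & np.isfinite(fp) & (fp < 0) & (f >= 0)
            if crossed.any():
                fp_c = fp[crossed]
                f_c = f[crossed]
                frac = np.where(f_c > fp_c, -fp_c / (f_c - fp_c), 1.0)
                ct[ids[crossed]] = t_prev + frac * (t - t_prev)
        prev_f[ids] = f
        done = ids[crossed | bad]
        active[done] = False
        t_prev = t

    ct = ct.reshape(nx, ny)
    ct[~valid0] = np.nan
    ct[ct <= 0] = np.nan
    return ThicknessMap(
        ct=ct,
        lateral_spacing_x_mm=lateral_spacing_x_mm,
        lateral_spacing_y_mm=lateral_spacing_y_mm,
        laterality=laterality,
        fovea_xy_mm=fovea_xy_mm,
    )


def _normalized_offsets(ctmap: ThicknessMap):
    """(u, v): horizontal offset (temporal positive) and vertical offset
    (superior positive) from the fovea, in mm, laterality-normalized."""
    if ctmap.fovea_xy_mm is None:
        raise ValueError("fovea_xy must be set before geographic summaries")
    xf, yf = ctmap.fovea_xy_mm
    x = ctmap.x_mm()
    y = ctmap.y_mm()
    if not (x.min() <= xf <= x.max() and y.min() <= yf <= y.max()):
        raise ValueError("fovea lies outside the scan grid")
    dx = x[:, None] - xf
    dy = y[None, :] - yf
    u = dx if ctmap.laterality == "OD" else -dx
    u, v = np.broadcast_arrays(u, dy)
    return u, v


def classify_sector(u: np.ndarray, v: np.ndarray,
                    diameters=RING_DIAMETERS_MM) -> np.ndarray:
    """Sector name per pixel from laterality-normalized offsets (mm).

    Rings are half-open (Fovea r < 0.5; inner 0.5 ≤ r < 2.5; outer
    2.5 ≤ r < 5.0); quadrants split at the 45° diagonals, with pixels
    exactly on a diagonal assigned to the horizontal (nasal/temporal)
    quadrants.  Returns '' outside the 10-mm disk.
    """
    r0, r1, r2 = (d / 2.0 for d in diameters)
    r = np.hypot(u, v)
    horiz = np.abs(u) >= np.abs(v)
    quad = np.where(horiz, np.where(u >= 0, "T", "N"),
                    np.where(v >= 0, "S", "I"))
    out = np.full(u.shape, "", dtype=object)
    out[r < r0] = "Fovea"
    inner = (r >= r0) & (r < r1)
    outer = (r >= r1) & (r < r2)
    for q in ("N", "S", "T", "I"):
        out[inner & (quad == q)] = f"{q}IM"
        out[outer & (quad == q)] = f"{q}OM"
    return out.astype(str)


def sector_summary(ctmap: ThicknessMap, diameters=RING_DIAMETERS_MM,
                   min_valid_fraction: float = 0.25) -> SectorSummary:
    """Mean CT over valid pixels in each of the nine named sectors.

    Sectors whose in-grid area is less than 25% valid are flagged
    missing (NaN mean).
    """
    u, v = _normalized_offsets(ctmap)
    labels = classify_sector(u, v, diameters)
    ct = ctmap.ct
    means: dict[str, float] = {}
    fracs: dict[str, float] = {}
    for name in SECTOR_ORDER:
        in_sector = labels == name
        n_total = int(in_sector.sum())
        if n_total == 0:
            means[name] = float("nan")
            fracs[name] = 0.0
            continue
        vals = ct[in_sector]
        ok = np.isfinite(vals)
        frac = float(ok.mean())
        fracs[name] = frac
        means[name] = float(vals[ok].mean()) if frac >= min_valid_fraction else float("nan")
    return SectorSummary(mean_um=means, valid_fraction=fracs,
                         ring_diameters_mm=tuple(diameters))


def ring_profile(ctmap: ThicknessMap) -> RingProfile:
    """Nasal–temporal CT profile at 1 mm ring intervals out to 5 mm.

    Bin 0 is the central fovea disk (r < 0.5 mm).  Bin −k (nasal) /
    +k (temporal) averages valid pixels with k−1 ≤ r < k mm inside the
    90° wedge centred on the horizontal meridian on that side.  Empty
    bins are NaN with count 0.
    """
    u, v = _normalized_offsets(ctmap)
    r = np.hypot(u, v)
    wedge = np.abs(v) <= np.abs(u)  # within 45° of horizontal
    ct = ctmap.ct
    ok = np.isfinite(ct)
    offsets = np.arange(-5, 6)
    mean = np.full(11, np.nan)
    counts = np.zeros(11, dtype=int)
    for i, k in enumerate(offsets):
        if k == 0:
            sel = (r < 0.5) & ok
        else:
            ring = (r >= abs(k) - 1) & (r < abs(k))
            side = (u < 0) if k < 0 else (u > 0)
            sel = ring & wedge & side & ok
        counts[i] = int(sel.sum())
        if counts[i] > 0:
            mean[i] = float(ct[sel].mean())
    return RingProfile(offsets_mm=offsets.astype(float), mean_um=mean, counts=counts)
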