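"""Synthetic eyes, OCT volumes and composite A-scans with known truth.

The generator emulates the study conditions the pipeline is meant for:
a posterior-pole raster of 512 A-lines x 256 B-scans over ~10 x 5 mm
(scaled down to 256 x 64 by default), a layered retina/choroid geometry
with a foveal pit, group-dependent choroidal-thickness (CT) fields
parameterised by per-sector means and SDs for low / moderate / high
myopia, fully developed speckle, spectrometer sensitivity roll-off
(6 dB at ~3 mm), per-B-scan axial motion, and the dual-reference-arm
composite A-scan geometry used for simultaneous axial-length measurement.

Every random quantity is driven by an explicit integer seed; there is no
hidden global random state.  Ground truth (`EyeTruth`) is retained so
that each downstream stage can be tested by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from typing import Callable

import numpy as np
import yaml
from scipy.special import erf

from .iol_measurement import CompositeAScan, DELTA_L_REF_MM, GROUP_INDEX
from .volume_io import OCTVolume, SECTOR_ORDER

__all__ = [
    "EyeTruth",
    "RenderParams",
    "GroupParams",
    "CohortSpec",
    "CohortEye",
    "make_eye_truth",
    "render_volume",
    "render_composite_ascan",
    "generate_cohort",
    "default_cohort_spec",
    "SECTOR_ORDER",
]

GROUPS = ("low", "moderate", "high")

# CT-field blend geometry: erf transitions between per-sector plateaus.
# Both radial transitions are shifted off the 0.5 / 2.5 mm ring radii into
# the (large, compensated) inner-ring sectors so that the fovea disk and
# the outer ring — including the 5-mm profile bins — sit on-plateau;
# widths keep surface slopes within what the segmenter can track.
_R_IN_CENTER_MM = 0.68
_R_IN_WIDTH_MM = 0.12
_R_OUT_CENTER_MM = 2.3
_R_OUT_WIDTH_MM = 0.15
_ANGULAR_BLEND_DEG = 16.0
_CT_FLOOR_UM = 20.0
_QUAD_ANGLES = {"T": 0.0, "S": 90.0, "N": 180.0, "I": 270.0}


@dataclasses.dataclass
class GroupParams:
    """Sampling distribution for one myopia group."""

    ct_mean_sd_um: dict[str, tuple[float, float]]  # sector -> (mean, SD)
    iol_mean_sd_mm: tuple[float, float]
    refractive_range_d: tuple[float, float]  # (most myopic, least myopic)

    def __post_init__(self) -> None:
        for sector, (m, s) in self.ct_mean_sd_um.items():
            if m <= 0:
                raise ValueError(f"sector {sector}: CT mean must be positive")
            if s < 0:
                raise ValueError(f"sector {sector}: SD must be >= 0")
        if self.iol_mean_sd_mm[1] < 0:
            raise ValueError("IOL SD must be >= 0")


@dataclasses.dataclass
class CohortSpec:
    """Per-group eye counts and sampling parameters for a synthetic study."""

    groups: dict[str, GroupParams]
    n_eyes: dict[str, int]

    def __post_init__(self) -> None:
        for g, n in self.n_eyes.items():
            if g not in self.groups:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("n_eyes must be >= 0")

    @classmethod
    def from_yaml(cls, path_or_text) -> "CohortSpec":
        if hasattr(path_or_text, "read"):
            raw = yaml.safe_load(path_or_text)
        else:
            text = str(path_or_text)
            raw = yaml.safe_load(text if "\n" in text else open(text))
        groups = {}
        for name, entry in raw["groups"].items():
            groups[name] = GroupParams(
                ct_mean_sd_um={s: tuple(v) for s, v in entry["ct_um"].items()},
                iol_mean_sd_mm=tuple(entry["iol_mm"]),
                refractive_range_d=tuple(entry["refractive_range_d"]),
            )
        return cls(groups=groups, n_eyes={g: int(n) for g, n in raw["n_eyes"].items()})


def default_cohort_spec() -> CohortSpec:
    """The shipped study defaults (myopia-group CT/IOL statistics)."""
    ref = importlib.resources.files("choroidmap").joinpath("data/cohort_defaults.yaml")
    return CohortSpec.from_yaml(ref.read_text())


@dataclasses.dataclass
class RenderParams:
    """Rendering geometry and noise model for synthetic volumes.

    Defaults are a desk-scale version of the acquisition protocol:
    256 axial samples x 256 A-lines x 64 B-scans over 10 x 5 mm, 10 um
    axial pitch in air, 6 dB sensitivity roll-off at 3 mm depth.  The
    full 512 x 256 raster is available by configuration.
    """

    dims: tuple[int, int, int] = (256, 256, 64)  # (n_axial, n_alines, n_bscans)
    axial_spacing_air_um: float = 10.0
    tissue_index: float = 1.38  # air-path -> geometric tissue distance
    scan_extent_mm: tuple[float, float] = (10.0, 5.0)
    # reflectivity plateau amplitudes
    level_retina: float = 0.25
    level_rpe: float = 1.0
    level_choroid: float = 0.08
    level_sclera: float = 0.45
    level_deep: float = 0.02
    rpe_band_um: float = 25.0     # geometric thickness of the RPE band
    sclera_band_um: float = 250.0
    psf_sigma_px: float = 0.45    # axial point-spread blur (~10 um resolution)
    speckle_on: bool = True
    rolloff_6db_depth_mm: float = 3.0
    noise_floor: float = 0.02
    apply_motion: bool = True

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        if self.axial_spacing_air_um <= 0:
            raise ValueError("axial spacing must be > 0")
        if self.rolloff_6db_depth_mm <= 0:
            raise ValueError("roll-off depth must be > 0")
        if any(e <= 0 for e in self.scan_extent_mm):
            raise ValueError("scan extent must be positive")

    @property
    def lateral_spacing_x_mm(self) -> float:
        return self.scan_extent_mm[0] / self.dims[1]

    @property
    def lateral_spacing_y_mm(self) -> float:
        return self.scan_extent_mm[1] / self.dims[2]

    def um_to_px(self, z_um) -> np.ndarray:
        """Geometric tissue depth (um) -> axial sample index (float)."""
        return np.asarray(z_um) * self.tissue_index / self.axial_spacing_air_um


def _smoothstep(t, width):
    return 0.5 * (1.0 + erf(np.asarray(t, dtype=float) / width))


@dataclasses.dataclass
class EyeTruth:
    """Analytic ground truth for one synthetic eye.

    Surfaces are height fields z(x, y) in geometric micrometres of depth;
    (x, y) are millimetres in the scanner frame, centred on the scan.
    ``ct_um`` is measured along the local RPE normal, so the
    choroid-sclera interface is placed at that distance along the normal.
    """

    sector_ct_um: dict[str, float]
    plateau_um: dict[str, float]
    fovea_xy_mm: tuple[float, float]
    pit_depth_um: float
    pit_sigma_mm: float
    retina_thickness_um: float
    rpe_center_depth_um: float
    curvature_um_per_mm2: float
    tilt_um_per_mm: tuple[float, float]
    iol_true_mm: float
    refractive_error_d: float
    laterality: str
    motion_trace: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        self.motion_trace = np.asarray(self.motion_trace, dtype=int)
        if not (20.0 <= self.iol_true_mm <= 30.0):
            raise ValueError("iol_true must lie in [20, 30] mm")
        if any(v <= 0 for v in self.sector_ct_um.values()):
            raise ValueError("sector CT values must be positive")

    # -- geometry -----------------------------------------------------------

    def _temporal_offset(self, x_mm):
        """Signed horizontal offset from the fovea, temporal positive."""
        dx = np.asarray(x_mm, dtype=float) - self.fovea_xy_mm[0]
        return dx if self.laterality == "OD" else -dx

    def ct_basis(self, x_mm, y_mm) -> dict[str, np.ndarray]:
        """The nine smooth blend-basis fields (partition of unity).

        The CT field is the plateau-weighted sum of these: a central
        plateau inside the fovea disk, and per-quadrant inner/outer-ring
        plateaus with erf transitions in radius and polar angle.
        """
        u = self._temporal_offset(x_mm)
        v = np.asarray(y_mm, dtype=float) - self.fovea_xy_mm[1]
        u, v = np.broadcast_arrays(u, v)
        r = np.hypot(u, v)
        theta = np.degrees(np.arctan2(v, u))  # 0 = temporal, 90 = superior
        b_in = _smoothstep(r - _R_IN_CENTER_MM, _R_IN_WIDTH_MM)
        b_out = _smoothstep(r - _R_OUT_CENTER_MM, _R_OUT_WIDTH_MM)
        basis = {"Fovea": 1.0 - b_in}
        wsum = np.zeros_like(r)
        wq = {}
        for q, ang in _QUAD_ANGLES.items():
            d = (theta - ang + 180.0) % 360.0 - 180.0
            w = 0.5 * (
                erf((d + 45.0) / _ANGULAR_BLEND_DEG)
                - erf((d - 45.0) / _ANGULAR_BLEND_DEG)
            )
            wq[q] = w
            wsum += w
        for q in wq:
            w = wq[q] / np.maximum(wsum, 1e-12)
            basis[f"{q}IM"] = w * (b_in - b_out)
            basis[f"{q}OM"] = w * b_out
        return basis

    def ct_um(self, x_mm, y_mm) -> np.ndarray:
        """Choroidal-thickness field in µm, measured along the RPE normal.

        A smooth plateau blend whose plateau parameters are solved so the
        drawn per-sector targets are the field's exact sector means on
        the scan area; clamped to ≥ 20 µm.  At the pit centre the field
        equals the drawn Fovea value (the central basis is 1 there)."""
        basis = self.ct_basis(x_mm, y_mm)
        ct = sum(self.plateau_um[s] * basis[s] for s in basis)
        return np.maximum(ct, _CT_FLOOR_UM)

    def rpe_um(self, x_mm, y_mm) -> np.ndarray:
        """Outer-RPE surface: shallow bowl (periphery toward zero delay)
        plus a small per-eye tilt."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        r2 = (x - self.fovea_xy_mm[0]) ** 2 + (y - self.fovea_xy_mm[1]) ** 2
        tx, ty = self.tilt_um_per_mm
        return self.rpe_center_depth_um - self.curvature_um_per_mm2 * r2 + tx * x + ty * y

    def ilm_um(self, x_mm, y_mm) -> np.ndarray:
        """Inner limiting membrane: RPE minus retinal thickness, with a
        Gaussian foveal pit deepening the ILM at the fovea."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        rho2 = (x - self.fovea_xy_mm[0]) ** 2 + (y - self.fovea_xy_mm[1]) ** 2
        pit = self.pit_depth_um * np.exp(-rho2 / (2.0 * self.pit_sigma_mm**2))
        return self.rpe_um(x, y) - self.retina_thickness_um + pit

    def _rpe_normal(self, x_mm, y_mm):
        """Unit normal of the RPE surface pointing deeper, physical units
        (lateral mm converted to um)."""
        eps = 1e-3  # mm
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        dzdx = (self.rpe_um(x + eps, y) - self.rpe_um(x - eps, y)) / (2 * eps * 1000.0)
        dzdy = (self.rpe_um(x, y + eps) - self.rpe_um(x, y - eps)) / (2 * eps * 1000.0)
        norm = np.sqrt(dzdx**2 + dzdy**2 + 1.0)
        return -dzdx / norm, -dzdy / norm, 1.0 / norm  # (per-um lateral, axial)

    def csi_um(self, x_mm, y_mm) -> np.ndarray:
        """Choroid-sclera interface: the surface lying ``ct_um`` along the
        local RPE normal.  Solved by a short fixed-point iteration for the
        normal's foot point (slopes are small, two iterations suffice)."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        x, y = np.broadcast_arrays(x, y)
        x0, y0 = x.astype(float).copy(), y.astype(float).copy()
        for _ in range(3):
            nx, ny, nz = self._rpe_normal(x0, y0)
            ct = self.ct_um(x0, y0)
            # lateral displacement of the normal ray, um -> mm
            x0 = x - ct * nx / 1000.0
            y0 = y - ct * ny / 1000.0
        nx, ny, nz = self._rpe_normal(x0, y0)
        ct = self.ct_um(x0, y0)
        return self.rpe_um(x0, y0) + ct * nz

    def sample_grids(self, params: RenderParams):
        """Truth surfaces in axial pixels on the render grid (nx, ny)."""
        x = (np.arange(params.dims[1]) - (params.dims[1] - 1) / 2) * params.lateral_spacing_x_mm
        y = (np.arange(params.dims[2]) - (params.dims[2] - 1) / 2) * params.lateral_spacing_y_mm
        xx, yy = np.meshgrid(x, y, indexing="ij")
        return {
            "ILM": params.um_to_px(self.ilm_um(xx, yy)),
            "RPE_outer": params.um_to_px(self.rpe_um(xx, yy)),
            "CSI": params.um_to_px(self.csi_um(xx, yy)),
        }


def make_eye_truth(group_params: GroupParams, laterality: str, seed: int,
                   n_bscans: int = 64, motion_amplitude_px: int = 4) -> EyeTruth:
    """Draw one eye's ground truth from a group's sampling distribution.

    Sector CT targets are drawn independently from the configured normals
    and clamped at a 20 um floor.  The field's plateau parameters are then
    solved from a 9x9 linear system so that the drawn targets are the
    field's exact per-sector means over the scan area (the smooth blend
    zones mix neighbouring plateaus, which the solve compensates).
    Deterministic per seed.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    for sector in SECTOR_ORDER:
        if sector not in group_params.ct_mean_sd_um:
            raise ValueError(f"group params missing sector {sector!r}")
    rng = np.random.default_rng(seed)
    sector_ct = {}
    for sector in SECTOR_ORDER:
        m, s = group_params.ct_mean_sd_um[sector]
        sector_ct[sector] = float(max(rng.normal(m, s), _CT_FLOOR_UM))
    iol_m, iol_s = group_params.iol_mean_sd_mm
    iol = float(rng.normal(iol_m, iol_s))
    lo, hi = group_params.refractive_range_d
    refr = float(rng.uniform(min(lo, hi), max(lo, hi)))
    fovea = (float(rng.uniform(-0.15, 0.15)), float(rng.uniform(-0.15, 0.15)))
    motion = rng.integers(-motion_amplitude_px, motion_amplitude_px + 1, size=n_bscans)
    motion[0] = 0
    truth = EyeTruth(
        sector_ct_um=sector_ct,
        plateau_um=dict(sector_ct),  # provisional; compensated below
        fovea_xy_mm=fovea,
        pit_depth_um=float(rng.uniform(100.0, 140.0)),
        pit_sigma_mm=float(rng.uniform(0.35, 0.45)),
        retina_thickness_um=float(rng.uniform(280.0, 320.0)),
        rpe_center_depth_um=float(rng.uniform(850.0, 950.0)),
        curvature_um_per_mm2=float(rng.uniform(3.0, 5.0)),
        tilt_um_per_mm=(float(rng.uniform(-8.0, 8.0)), float(rng.uniform(-8.0, 8.0))),
        iol_true_mm=iol,
        refractive_error_d=refr,
        laterality=laterality,
        motion_trace=motion,
        seed=int(seed),
    )
    truth.plateau_um = _solve_plateaus(truth)
    return truth


def _solve_plateaus(truth: EyeTruth,
                    scan_extent_mm: tuple[float, float] = (10.0, 5.0),
                    n_ref: tuple[int, int] = (200, 100)) -> dict[str, float]:
    """Plateau parameters making the drawn targets exact sector means.

    Evaluates the nine blend-basis fields on a reference grid over the
    scan area, averages each basis over each sector of the geographic
    partition, and solves the resulting 9x9 system (least squares,
    floored at 1 um).
    """
    from .thickness_mapping import classify_sector  # local: avoids cycle at import time
    from .volume_io import SECTOR_ORDER as order

    x = np.linspace(-scan_extent_mm[0] / 2, scan_extent_mm[0] / 2, n_ref[0])
    y = np.linspace(-scan_extent_mm[1] / 2, scan_extent_mm[1] / 2, n_ref[1])
    xx, yy = np.meshgrid(x, y, indexing="ij")
    basis = truth.ct_basis(xx, yy)
    u = truth._temporal_offset(xx)
    v = yy - truth.fovea_xy_mm[1]
    labels = classify_sector(u, v)
    m = np.zeros((len(order), len(order)))
    for i, t in enumerate(order):
        in_t = labels == t
        if in_t.any():
            for j, s in enumerate(order):
                m[i, j] = float(basis[s][in_t].mean())
    # Sectors mostly outside the scan (the superior/inferior outer sectors
    # of a 10 x 5 mm raster) make the system ill-conditioned; pin their
    # plateaus to the targets and solve only the well-supported sectors.
    for i in range(len(order)):
        if m[i, i] < 0.55:
            m[i, :] = 0.0
            m[i, i] = 1.0
    targets = np.array([truth.sector_ct_um[s] for s in order])
    p = np.linalg.solve(m, targets)
    p = np.maximum(p, _CT_FLOOR_UM)
    return {s: float(p[j]) for j, s in enumerate(order)}


def render_volume(truth: EyeTruth, params: RenderParams | None = None,
                  seed: int = 0) -> tuple[OCTVolume, np.ndarray]:
    """Render a B-scan stack from ground truth.

    The axial reflectivity profile of each A-line is a sum of erf-smoothed
    plateaus (vitreous 0 -> retina -> bright RPE band -> dim choroid ->
    scleral band), so every boundary the segmenter looks for is a step
    edge at exactly the truth position.  Amplitude is attenuated with
    depth (half amplitude at the 6 dB roll-off depth), multiplied by
    unit-mean exponential speckle when enabled, and each B-scan is rolled
    axially by its integer motion-trace entry with vacated rows set to
    the noise floor.

    Returns the volume and the motion trace actually applied.
    """
    params = params or RenderParams()
    nz, nx, ny = params.dims
    if len(truth.motion_trace) != ny:
        raise ValueError(
            f"motion trace length {len(truth.motion_trace)} != n_bscans {ny}"
        )
    surf = truth.sample_grids(params)
    ilm, rpe, csi = surf["ILM"], surf["RPE_outer"], surf["CSI"]

    rpe_band_px = params.um_to_px(params.rpe_band_um)
    sclera_band_px = params.um_to_px(params.sclera_band_um)
    motion = truth.motion_trace if params.apply_motion else np.zeros(ny, dtype=int)
    max_shift = int(np.max(np.abs(motion))) if len(motion) else 0
    deepest = float(np.max(csi)) + float(sclera_band_px) + max_shift
    if deepest >= nz - 2 or float(np.min(ilm)) - max_shift <= 2:
        bad = int(np.argmax(csi.max(axis=0)))
        raise ValueError(
            f"truth surfaces do not fit the axial window (B-scan {bad}): "
            f"deepest sample {deepest:.1f} of {nz}"
        )

    z = np.arange(nz, dtype=float)[:, None, None]
    w = np.sqrt(2.0) * params.psf_sigma_px

    def step(edge_px):
        return 0.5 * (1.0 + erf((z - edge_px[None, :, :]) / w))

    p = params
    refl = (
        p.level_retina * step(ilm)
        + (p.level_rpe - p.level_retina) * step(rpe - rpe_band_px)
        + (p.level_choroid - p.level_rpe) * step(rpe)
        + (p.level_sclera - p.level_choroid) * step(csi)
        + (p.level_deep - p.level_sclera) * step(csi + sclera_band_px)
    )
    depth_mm = z * p.axial_spacing_air_um / 1000.0
    rolloff = 0.5 ** (depth_mm / p.rolloff_6db_depth_mm)
    intensity = p.noise_floor + rolloff * refl
    if p.speckle_on:
        rng = np.random.default_rng(seed)
        intensity = intensity * rng.exponential(1.0, size=intensity.shape)

    # per-B-scan axial motion: integer roll, vacated rows = noise floor
    out = np.empty_like(intensity)
    for iy in range(ny):
        s = int(motion[iy])
        page = intensity[:, :, iy]
        shifted = np.full_like(page, p.noise_floor)
        if s >= 0:
            shifted[s:nz, :] = page[: nz - s, :]
        else:
            shifted[: nz + s, :] = page[-s:, :]
        out[:, :, iy] = shifted

    vol = OCTVolume(
        intensity=out.astype(np.float32),
        axial_spacing_air_um=p.axial_spacing_air_um,
        lateral_spacing_x_mm=p.lateral_spacing_x_mm,
        lateral_spacing_y_mm=p.lateral_spacing_y_mm,
        tissue_index=p.tissue_index,
        laterality=truth.laterality,
        refractive_error_d=truth.refractive_error_d,
        meta={"generator": "choroidmap.synthetic_oct", "seed": int(seed),
              "truth_seed": int(truth.seed)},
    )
    return vol, motion.copy()


def render_composite_ascan(truth: EyeTruth, delta_L_ref_mm: float = DELTA_L_REF_MM,
                           n_index: float = GROUP_INDEX,
                           n_samples: int = 1024,
                           axial_spacing_air_um: float = 6.0,
                           fovea_depth_mm: float = 1.2,
                           peak_sigma_px: float = 2.0,
                           noise_floor: float = 0.01,
                           seed: int | None = None) -> CompositeAScan:
    """Render the dual-reference-arm composite A-line for one eye.

    The foveal RPE reflection sits near the zero-delay line; the corneal
    reflection appears at optical path d = delta_L_ref - n * IOL_true
    beyond it.
    """
    d_mm = delta_L_ref_mm - n_index * truth.iol_true_mm
    if d_mm <= 0:
        raise ValueError(
            f"delta_L_ref={delta_L_ref_mm} must exceed n*IOL={n_index * truth.iol_true_mm:.3f}"
        )
    px_per_mm = 1000.0 / axial_spacing_air_um
    fov_px = fovea_depth_mm * px_per_mm
    cor_px = (fovea_depth_mm + d_mm) * px_per_mm
    if cor_px >= n_samples - 4:
        raise ValueError(
            f"cornea peak at sample {cor_px:.0f} falls outside the {n_samples}-sample window"
        )
    z = np.arange(n_samples, dtype=float)
    amp = (
        noise_floor
        + 1.0 * np.exp(-0.5 * ((z - fov_px) / peak_sigma_px) ** 2)
        + 0.6 * np.exp(-0.5 * ((z - cor_px) / peak_sigma_px) ** 2)
    )
    if seed is not None:
        rng = np.random.default_rng(seed)
        amp = amp + rng.uniform(0.0, 0.3 * noise_floor, size=n_samples)
    return CompositeAScan(
        amplitude=amp,
        axial_spacing_air_um=axial_spacing_air_um,
        delta_L_ref_mm=delta_L_ref_mm,
        n_index=n_index,
    )


@dataclasses.dataclass
class CohortEye:
    eye_id: str
    group: str
    truth: EyeTruth
    volume: OCTVolume
    composite: CompositeAScan
    refractive_error_d: float
    laterality: str


def generate_cohort(spec: CohortSpec, seed: int,
                    params: RenderParams | None = None,
                    progress: Callable[[str], None] | None = None) -> list[CohortEye]:
    """Generate a full synthetic cohort, ground truths retained.

    Laterality alternates OD/OS within each group.  Deterministic per
    seed: eye-level seeds are drawn once from a master generator.
    """
    params = params or RenderParams()
    master = np.random.default_rng(seed)
    eyes: list[CohortEye] = []
    for group in GROUPS:
        n = spec.n_eyes.get(group, 0)
        gp = spec.groups.get(group)
        for k in range(n):
            eye_seed = int(master.integers(0, 2**31 - 1))
            render_seed = int(master.integers(0, 2**31 - 1))
            laterality = "OD" if k % 2 == 0 else "OS"
            truth = make_eye_truth(gp, laterality, eye_seed, n_bscans=params.dims[2])
            vol, _ = render_volume(truth, params, seed=render_seed)
            comp = render_composite_ascan(truth, seed=render_seed + 1)
            eye_id = f"{group}-{k:03d}"
            if progress is not None:
                progress(eye_id)
            eyes.append(CohortEye(
                eye_id=eye_id, group=group, truth=truth, volume=vol,
                composite=comp, refractive_error_d=truth.refractive_error_d,
                laterality=laterality,
            ))
    return eyes
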