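"""Inter-B-scan axial motion correction by cross-correlation.

Eye motion during the ~1 s raster acquisition shifts successive B-scans
axially.  Each B-scan is collapsed to its laterally averaged axial
profile (robust to speckle); adjacent profiles are registered by
normalized cross-correlation with parabolic subpixel refinement; the
chained (cumulative) shifts, referenced to the first B-scan, are negated
and applied as integer rolls so no interpolation blur is introduced.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .volume_io import OCTVolume

__all__ = ["ShiftTrace", "estimate_axial_shift", "correct_motion"]


@dataclasses.dataclass
class ShiftTrace:
    """Cumulative axial shift estimate per B-scan (pixels, float);
    first entry is 0 by convention.  ``raw_steps_px`` keeps the subpixel
    adjacent-pair estimates before integer quantisation, for audit."""

    shifts_px: np.ndarray
    raw_steps_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shifts_px = np.asarray(self.shifts_px, dtype=float)
        if self.raw_steps_px is not None:
            self.raw_steps_px = np.asarray(self.raw_steps_px, dtype=float)


def _ncc_at_lag(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Pearson correlation of a[z] against b[z + lag] on the overlap."""
    n = len(a)
    if lag >= 0:
        aw, bw = a[: n - lag], b[lag:]
    else:
        aw, bw = a[-lag:], b[: n + lag]
    if len(aw) < 2:
        return -np.inf
    aw = aw - aw.mean()
    bw = bw - bw.mean()
    denom = np.sqrt((aw**2).sum() * (bw**2).sum())
    if denom == 0:
        return -np.inf
    return float((aw * bw).sum() / denom)


def estimate_axial_shift(profile_a: np.ndarray, profile_b: np.ndarray,
                         max_shift: int = 8) -> float:
    """Axial shift of ``profile_b`` relative to ``profile_a`` in pixels.

    Positive result means b's content sits deeper than a's (b looks like
    a rolled toward larger z).  The maximizing lag of the normalized
    cross-correlation within +/- max_shift is refined to subpixel by a
    parabolic fit of the correlation peak.  Ties between correlation
    maxima resolve to the smaller absolute shift.  A zero-variance
    profile yields 0.0 with a warning.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("profiles must be equal-length 1-D arrays of length >= 3")
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant axial profile: shift set to 0", stacklevel=2)
        return 0.0
    max_shift = int(min(max_shift, len(a) - 2))
    # note: b = roll(a, +s) matches a[z] ~ b[z + s], so scan lag = shift
    lags = sorted(range(-max_shift, max_shift + 1), key=abs)
    corr = {lag: _ncc_at_lag(a, b, lag) for lag in lags}
    best = max(lags, key=lambda lag: corr[lag])  # ties -> smaller |lag| (sort order)
    c0 = corr[best]
    if c0 > 1.0 - 1e-9:  # perfect match at an integer lag
        return float(best)
    cm = corr.get(best - 1, _ncc_at_lag(a, b, best - 1))
    cp = corr.get(best + 1, _ncc_at_lag(a, b, best + 1))
    if np.isfinite(cm) and np.isfinite(cp):
        denom = cm - 2.0 * c0 + cp
        if denom < -1e-12:
            frac = 0.5 * (cm - cp) / denom
            if abs(frac) <= 1.0:
                return float(best + frac)
    return float(best)


def correct_motion(vol: OCTVolume, max_shift: int = 8) -> tuple[OCTVolume, ShiftTrace]:
    """Remove inter-B-scan axial motion from a volume.

    Adjacent-B-scan shifts are estimated on laterally averaged axial
    profiles.  Each subpixel step estimate is quantised to the nearest
    integer before chaining: saccadic motion displaces B-scans by whole
    pixels while the slow anatomical depth trend between neighbouring
    B-scans stays well below half a pixel, so quantisation removes the
    motion without flattening the anatomy.  The integer cumulative trace,
    referenced to B-scan 0, is negated and applied as a roll per B-scan;
    vacated rows are filled with the volume's noise-floor median.
    Returns the corrected volume and the trace (raw subpixel steps kept
    for audit).
    """
    ny = vol.n_bscans
    if ny < 2:
        raise ValueError("motion correction needs >= 2 B-scans")
    profiles = vol.intensity.mean(axis=1)  # (nz, ny)
    steps = np.zeros(ny)
    for iy in range(1, ny):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            steps[iy] = estimate_axial_shift(profiles[:, iy - 1], profiles[:, iy], max_shift)
    trace = np.cumsum(np.round(steps))
    trace -= trace[0]
    nz = vol.n_axial
    if np.max(np.abs(np.round(trace))) >= nz:
        raise ValueError("cumulative shift exceeds the axial extent")
    # noise-floor median from the shallow rows above the retina
    floor = float(np.median(vol.intensity[: max(3, max_shift), :, :]))
    out = np.empty_like(vol.intensity)
    for iy in range(ny):
        s = -int(np.round(trace[iy]))
        page = vol.intensity[:, :, iy]
        shifted = np.full_like(page, floor)
        if s >= 0:
            shifted[s:nz, :] = page[: nz - s, :]
        else:
            shifted[: nz + s, :] = page[-s:, :]
        out[:, :, iy] = shifted
    corrected = OCTVolume(
        intensity=out,
        axial_spacing_air_um=vol.axial_spacing_air_um,
        lateral_spacing_x_mm=vol.lateral_spacing_x_mm,
        lateral_spacing_y_mm=vol.lateral_spacing_y_mm,
        tissue_index=vol.tissue_index,
        laterality=vol.laterality,
        refractive_error_d=vol.refractive_error_d,
        meta={**vol.meta, "motion_corrected": True},
    )
    return corrected, ShiftTrace(shifts_px=trace, raw_steps_px=steps)
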