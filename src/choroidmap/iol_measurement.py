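"""Intraocular length (IOL) from a dual-reference-arm composite A-scan.

A spectrometer-based OCT system with a single reference arm cannot span a
whole eye (~24 mm) in its ~6 mm depth window.  With two reference mirrors
offset by an optical path ``delta_L_ref``, the retina appears near the
zero-delay line and the anterior corneal reflection appears further down
the same A-line.  If ``d`` is the optical-path separation between the
foveal RPE peak and the corneal peak, the axial eye length follows from

    IOL = (delta_L_ref - d) / n

with ``n`` the group refractive index of the whole eye (1.3375 by
default).  Reported IOL values are rounded to 3 decimals (mm) only at
presentation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "CompositeAScan",
    "IOLResult",
    "PeakDetectionError",
    "detect_peaks",
    "compute_iol",
    "measure_iol",
    "DELTA_L_REF_MM",
    "GROUP_INDEX",
]

#: Default reference-mirror offset, mm (optical path in air).
DELTA_L_REF_MM = 35.0
#: Default whole-eye group refractive index.
GROUP_INDEX = 1.3375


class PeakDetectionError(ValueError):
    """Raised when the composite A-scan lacks usable reflections."""


@dataclasses.dataclass
class CompositeAScan:
    """Full-depth A-line holding retina near zero delay plus the corneal
    reflection, with the geometry constants needed to invert it."""

    amplitude: np.ndarray
    axial_spacing_air_um: float
    delta_L_ref_mm: float = DELTA_L_REF_MM
    n_index: float = GROUP_INDEX

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 1:
            raise ValueError("amplitude must be 1-D")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite")
        if not self.delta_L_ref_mm > 0:
            raise ValueError("delta_L_ref must be > 0")
        if not self.n_index >= 1:
            raise ValueError("n_index must be >= 1")
        if not self.axial_spacing_air_um > 0:
            raise ValueError("axial spacing must be > 0")


@dataclasses.dataclass
class IOLResult:
    d_mm: float
    iol_mm: float
    fovea_peak_sample: float
    cornea_peak_sample: float
    quality: dict = dataclasses.field(default_factory=dict)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Subpixel peak position by parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return float(i)
    return float(i + 0.5 * (y[i - 1] - y[i + 1]) / denom)


def detect_peaks(a: CompositeAScan, retinal_fraction: float = 0.4,
                 min_separation_px: int = 5) -> tuple[float, float]:
    """Locate the foveal and corneal reflections (subpixel samples).

    The foveal peak is the strongest local maximum in the retinal portion
    of the window (first ``retinal_fraction`` of samples); the corneal
    peak is the strongest maximum beyond it.  Candidate maxima must rise
    above 5x the median amplitude.
    """
    y = a.amplitude
    thresh = 5.0 * float(np.median(y))
    idx, _ = find_peaks(y, height=thresh)
    if len(idx) < 2:
        raise PeakDetectionError(
            "no corneal signal: fewer than 2 peaks above 5x median amplitude"
        )
    n_ret = int(round(retinal_fraction * len(y)))
    retinal = idx[idx < n_ret]
    if len(retinal) == 0:
        raise PeakDetectionError("no retinal peak in the zero-delay portion")
    fov = int(retinal[np.argmax(y[retinal])])
    beyond = idx[idx >= fov + min_separation_px]
    if len(beyond) == 0:
        raise PeakDetectionError("no corneal signal beyond the retinal peak")
    cor = int(beyond[np.argmax(y[beyond])])
    return _parabolic_refine(y, fov), _parabolic_refine(y, cor)


def compute_iol(d_mm: float, delta_L_ref_mm: float = DELTA_L_REF_MM,
                n_index: float = GROUP_INDEX) -> float:
    """Axial eye length IOL = (delta_L_ref - d) / n, in mm (unrounded)."""
    if not 0 <= d_mm < delta_L_ref_mm:
        raise ValueError(
            f"peak separation d={d_mm} mm must lie in [0, delta_L_ref={delta_L_ref_mm})"
        )
    if not n_index >= 1:
        raise ValueError("n_index must be >= 1")
    return (delta_L_ref_mm - d_mm) / n_index


def measure_iol(a: CompositeAScan) -> IOLResult:
    """Full measurement: peak detection then the length formula."""
    fov, cor = detect_peaks(a)
    d_mm = (cor - fov) * a.axial_spacing_air_um / 1000.0
    iol = compute_iol(d_mm, a.delta_L_ref_mm, a.n_index)
    return IOLResult(
        d_mm=d_mm,
        iol_mm=iol,
        fovea_peak_sample=fov,
        cornea_peak_sample=cor,
        quality={"n_samples": len(a.amplitude)},
    )
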