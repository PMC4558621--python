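"""Reading and writing of OCT volumes and derived tables.

A volume on disk is a multi-page TIFF (one page per B-scan, each page a
2-D axial x A-line image) next to a JSON sidecar carrying the physical
spacings, eye laterality, refractive error and provenance.  I/O is a
faithful container: raw files stay in the scanner frame (z index 0 at the
zero-delay line, x increasing temporally for OD and nasally for OS);
laterality normalisation happens downstream in thickness mapping.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OCTVolume",
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "read_table",
    "write_table",
    "SECTOR_ORDER",
]

#: Fixed column order for sector summaries.
SECTOR_ORDER = ("Fovea", "NIM", "SIM", "TIM", "IIM", "NOM", "SOM", "TOM", "IOM")

_SIDECAR_SUFFIX = ".json"


class VolumeIOError(ValueError):
    """Raised for malformed or inconsistent on-disk volumes."""


@dataclasses.dataclass
class OCTVolume:
    """3-D OCT intensity volume with physical metadata.

    ``intensity`` is indexed ``[z, x, y]`` = [axial sample, A-line, B-scan],
    linear arbitrary units.  ``axial_spacing_air_um`` is the axial sample
    pitch in air; geometric distances inside tissue divide by
    ``tissue_index``.
    """

    intensity: np.ndarray
    axial_spacing_air_um: float
    lateral_spacing_x_mm: float
    lateral_spacing_y_mm: float
    laterality: str
    refractive_error_d: float
    tissue_index: float = 1.38
    meta: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.ndim != 3:
            raise VolumeIOError("intensity must be 3-D [z, x, y]")
        self.validate()

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_axial(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_alines(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[2]

    @property
    def axial_geom_um_per_px(self) -> float:
        """Geometric (tissue) micrometres per axial sample."""
        return self.axial_spacing_air_um / self.tissue_index

    def x_mm(self) -> np.ndarray:
        """A-line positions in mm, centred on the scan (scanner frame)."""
        n = self.n_alines
        return (np.arange(n) - (n - 1) / 2.0) * self.lateral_spacing_x_mm

    def y_mm(self) -> np.ndarray:
        n = self.n_bscans
        return (np.arange(n) - (n - 1) / 2.0) * self.lateral_spacing_y_mm

    def validate(self) -> None:
        if not (self.axial_spacing_air_um > 0):
            raise VolumeIOError("axial spacing must be > 0")
        if not (self.lateral_spacing_x_mm > 0 and self.lateral_spacing_y_mm > 0):
            raise VolumeIOError("lateral spacings must be > 0")
        if not (self.tissue_index >= 1):
            raise VolumeIOError("tissue index must be >= 1")
        if self.laterality not in ("OD", "OS"):
            raise VolumeIOError(f"laterality must be OD or OS, got {self.laterality!r}")
        if not np.all(np.isfinite(self.intensity)):
            raise VolumeIOError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise VolumeIOError("intensity must be non-negative")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(_SIDECAR_SUFFIX)


def write_volume(vol: OCTVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF + JSON sidecar; returns TIFF path."""
    path = Path(path)
    vol.validate()
    # pages iterate over B-scans; each page is (z, x)
    pages = np.moveaxis(vol.intensity, 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "schema": "choroidmap-volume-1",
        "shape_zxy": list(vol.intensity.shape),
        "axial_spacing_air_um": vol.axial_spacing_air_um,
        "lateral_spacing_x_mm": vol.lateral_spacing_x_mm,
        "lateral_spacing_y_mm": vol.lateral_spacing_y_mm,
        "tissue_index": vol.tissue_index,
        "laterality": vol.laterality,
        "refractive_error_d": vol.refractive_error_d,
        "meta": vol.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a TIFF + sidecar pair written by :func:`write_volume`."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise VolumeIOError(f"missing JSON sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise VolumeIOError(f"unreadable sidecar {sidecar_path}: {exc}") from exc
    for key in ("shape_zxy", "axial_spacing_air_um", "lateral_spacing_x_mm",
                "lateral_spacing_y_mm", "laterality", "refractive_error_d"):
        if key not in sidecar:
            raise VolumeIOError(f"sidecar missing required field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single B-scan collapses the page axis
        pages = pages[None, :, :]
    intensity = np.moveaxis(pages, 0, 2)
    expected = tuple(sidecar["shape_zxy"])
    if intensity.shape != expected:
        raise VolumeIOError(
            f"TIFF shape {intensity.shape} does not match sidecar shape {expected}"
        )
    return OCTVolume(
        intensity=intensity,
        axial_spacing_air_um=float(sidecar["axial_spacing_air_um"]),
        lateral_spacing_x_mm=float(sidecar["lateral_spacing_x_mm"]),
        lateral_spacing_y_mm=float(sidecar["lateral_spacing_y_mm"]),
        tissue_index=float(sidecar.get("tissue_index", 1.38)),
        laterality=str(sidecar["laterality"]),
        refractive_error_d=float(sidecar["refractive_error_d"]),
        meta=dict(sidecar.get("meta", {})),
    )


# -- tabular artifacts ------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a derived table (thickness map, sector summary, cohort table)
    as RFC-4180-style CSV with a header row."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise VolumeIOError(f"malformed CSV {path}: {exc}") from exc


def thickness_map_frame(ct_um: np.ndarray, x_mm: np.ndarray, y_mm: np.ndarray) -> pd.DataFrame:
    """Long-format (x_mm, y_mm, ct_um, valid) frame for a thickness grid."""
    xx, yy = np.meshgrid(x_mm, y_mm, indexing="ij")
    ct = np.asarray(ct_um, dtype=float)
    return pd.DataFrame(
        {
            "x_mm": xx.ravel(),
            "y_mm": yy.ravel(),
            "ct_um": ct.ravel(),
            "valid": np.isfinite(ct).ravel(),
        }
    )


def sector_summary_frame(rows: list[dict[str, float]]) -> pd.DataFrame:
    """One row per eye with the nine named sector columns in fixed order."""
    cols = ["eye_id", *SECTOR_ORDER]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]
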