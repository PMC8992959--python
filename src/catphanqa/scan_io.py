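"""Geometry-aware HU volumes and DICOM series loading.

Voxel convention: ``hu[k, j, i]`` is ordered (slice, row, column); voxel
centres sit at ``origin + index * spacing`` (0-based).  The in-plane
analysis frame has its origin at the centre of the pixel grid with +x along
increasing column and +y along decreasing row (i.e. "up" on a displayed
axial slice), so clock angles measured clockwise from 12 o'clock map to the
unit vector (sin a, cos a).  All distances and spatial frequencies in the
package are computed in this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ScanLoadError, ValidationError

__all__ = ["ScanVolume", "load_series", "pixel_coords", "mm_to_px", "px_to_mm"]


@dataclass
class ScanVolume:
    """A 3D HU volume with physical geometry."""

    hu: np.ndarray  # (n_slices, n_rows, n_cols), HU
    pixel_spacing: tuple[float, float]  # (row mm, column mm)
    slice_positions: np.ndarray  # mm, strictly monotone
    slice_thickness: float  # mm
    source_id: str = ""

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        self.slice_positions = np.asarray(self.slice_positions, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.hu.ndim != 3:
            raise ValidationError("hu", "must be a 3D (slice, row, column) array")
        if len(self.slice_positions) != self.hu.shape[0]:
            raise ValidationError("slice_positions", "length must match slice count")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError("pixel_spacing", "components must be > 0")
        if not np.all(np.isfinite(self.hu)):
            raise ValidationError("hu", "values must be finite")
        diffs = np.diff(self.slice_positions)
        if len(diffs):
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValidationError("slice_positions", "must be strictly monotone")
            med = np.median(np.abs(diffs))
            if np.max(np.abs(np.abs(diffs) - med)) > 0.01 * med:
                raise ValidationError("slice_positions",
                                      "spacing varies by more than 1% of the median")

    @property
    def n_slices(self) -> int:
        return self.hu.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def slice_spacing(self) -> float:
        d = np.diff(self.slice_positions)
        return float(np.median(np.abs(d))) if len(d) else self.slice_thickness

    def subvolume(self, start: int, stop: int) -> "ScanVolume":
        """A contiguous slice range as a new volume (used for truncation tests)."""
        return ScanVolume(self.hu[start:stop].copy(), self.pixel_spacing,
                          self.slice_positions[start:stop].copy(),
                          self.slice_thickness, self.source_id)


# --- in-plane frame helpers -----------------------------------------------
def pixel_coords(shape: tuple[int, int],
                 pixel_spacing: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Return (x of columns, y of rows) in mm for a (rows, cols) image."""
    n_rows, n_cols = shape
    dy, dx = pixel_spacing
    x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * dx
    y = ((n_rows - 1) / 2.0 - np.arange(n_rows)) * dy
    return x, y


def mm_to_px(xy: tuple[float, float], shape: tuple[int, int],
             pixel_spacing: tuple[float, float]) -> tuple[float, float]:
    """(x, y) mm in the analysis frame -> fractional (row, col)."""
    n_rows, n_cols = shape
    dy, dx = pixel_spacing
    col = xy[0] / dx + (n_cols - 1) / 2.0
    row = (n_rows - 1) / 2.0 - xy[1] / dy
    return row, col


def px_to_mm(rowcol: tuple[float, float], shape: tuple[int, int],
             pixel_spacing: tuple[float, float]) -> tuple[float, float]:
    """Fractional (row, col) -> (x, y) mm in the analysis frame."""
    n_rows, n_cols = shape
    dy, dx = pixel_spacing
    x = (rowcol[1] - (n_cols - 1) / 2.0) * dx
    y = ((n_rows - 1) / 2.0 - rowcol[0]) * dy
    return x, y


# --- DICOM series loading ---------------------------------------------------
def load_series(directory: str | Path) -> ScanVolume:
    """Load a single-series axial DICOM directory into a :class:`ScanVolume`.

    Slices are ordered by the projection of ImagePositionPatient onto the
    slice normal (never by filename or InstanceNumber).  Pixel values are
    mapped to HU with RescaleSlope/RescaleIntercept.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue  # non-DICOM files in the directory are ignored
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if len(datasets) < 3:
        raise ScanLoadError(f"too few slices: found {len(datasets)}, need >= 3")

    series = {str(getattr(ds, "SeriesInstanceUID", "?")) for ds in datasets}
    if len(series) > 1:
        raise ScanLoadError("mixed series in directory: " + ", ".join(sorted(series)))

    required = ["PixelSpacing", "ImagePositionPatient", "ImageOrientationPatient",
                "SliceThickness"]
    for tag in required:
        if not hasattr(datasets[0], tag):
            raise ScanLoadError(f"missing geometry tag: {tag}")

    orient = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    pos = np.array([float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))
                    for ds in datasets])
    order = np.argsort(pos)
    datasets = [datasets[i] for i in order]
    pos = pos[order]

    spacing = tuple(float(v) for v in datasets[0].PixelSpacing)
    thickness = float(datasets[0].SliceThickness)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    hu = np.stack(slices)

    diffs = np.diff(pos)
    if len(diffs):
        med = np.median(diffs)
        if med <= 0 or np.max(np.abs(diffs - med)) > 0.01 * med:
            raise ScanLoadError("non-uniform slice spacing beyond 1% of the median")

    try:
        return ScanVolume(hu, spacing, pos, thickness,
                          source_id=str(getattr(datasets[0], "StationName", "")))
    except ValidationError as exc:  # pragma: no cover - geometry errors above
        raise ScanLoadError(str(exc)) from exc
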