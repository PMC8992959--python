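"""ROI-based HU statistics: CT number accuracy, uniformity, CNR, ROI noise.

ROI membership follows a pixel-centre rule (a pixel belongs to a circular
ROI iff its centre lies inside the circle); this keeps pixel counts exactly
reproducible across runs.  Standard deviations use the n-1 (sample)
normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import MetricError
from .geometry import PhantomLayout, default_layout
from .scan_io import pixel_coords

__all__ = ["RoiStats", "UniformitySet", "CnrResult", "roi_stats", "ct_numbers",
           "uniformity", "cnr", "roi_noise"]

#: clock positions of the peripheral uniformity ROIs
UNIFORMITY_CLOCKS = (3, 6, 9, 12)

#: inserts evaluated for contrast-to-noise ratio (fat-, soft-tissue- and
#: bone-like materials)
CNR_INSERTS = ("ldpe", "polystyrene", "delrin")


@dataclass(frozen=True)
class RoiStats:
    mean: float  # HU
    sd: float  # HU
    n_pixels: int
    center: tuple[float, float]  # (x, y) mm, analysis frame
    radius: float  # mm


@dataclass
class UniformitySet:
    central: RoiStats
    peripheral: dict[int, RoiStats]  # keyed by clock position
    indices: dict[int, float]  # percent


@dataclass(frozen=True)
class CnrResult:
    signed: float
    magnitude: float
    insert: RoiStats
    background: RoiStats


def _circular_mask(shape, pixel_spacing, center_mm, radius_mm):
    x, y = pixel_coords(shape, pixel_spacing)
    dx2 = (x - center_mm[0]) ** 2
    dy2 = (y - center_mm[1]) ** 2
    return dy2[:, None] + dx2[None, :] <= radius_mm ** 2


def roi_stats(image: np.ndarray, center_mm: tuple[float, float], radius_mm: float,
              pixel_spacing: tuple[float, float]) -> RoiStats:
    """Mean/SD over pixels whose centres lie inside the circle."""
    if radius_mm <= 0:
        raise MetricError("ROI radius must be > 0")
    shape = image.shape
    x, y = pixel_coords(shape, pixel_spacing)
    if (center_mm[0] - radius_mm < x[0] or center_mm[0] + radius_mm > x[-1]
            or center_mm[1] + radius_mm > y[0] or center_mm[1] - radius_mm < y[-1]):
        raise MetricError("ROI crosses the image boundary")
    mask = _circular_mask(shape, pixel_spacing, center_mm, radius_mm)
    vals = image[mask]
    if vals.size < 9:
        raise MetricError(f"ROI too small: {vals.size} pixels")
    return RoiStats(float(vals.mean()), float(vals.std(ddof=1)), int(vals.size),
                    (float(center_mm[0]), float(center_mm[1])), float(radius_mm))


def ct_numbers(slice404: np.ndarray, insert_centers_mm: dict[str, tuple[float, float]],
               layout: PhantomLayout | None = None,
               pixel_spacing: tuple[float, float] = (1.0, 1.0),
               ) -> dict[str, RoiStats]:
    """Per-insert CT number: circular ROI of radius (insert radius - 1 mm)
    centred in each detected insert, shrunk to avoid edge fluctuations."""
    layout = layout or default_layout()
    out: dict[str, RoiStats] = {}
    for key, center in insert_centers_mm.items():
        insert = layout.insert_by_key(key)
        radius = insert.material.insert_radius - 1.0
        if radius <= 0:
            raise MetricError(f"shrunken ROI radius <= 0 for insert '{key}'")
        out[key] = roi_stats(slice404, center, radius, pixel_spacing)
    return out


def uniformity(slice486: np.ndarray, phantom_center_mm: tuple[float, float],
               module_radius_mm: float,
               pixel_spacing: tuple[float, float]) -> UniformitySet:
    """Uniformity indices U_i from one central and four peripheral ROIs.

    All five ROIs have radius 20% of the module radius; the peripheral ROIs
    sit at 3/6/9/12 o'clock with their edge 1 cm inside the module margin.
    U_i = (mean_i - mean_central) / (mean_central + 100) * 100%, the +100
    stabilising the denominator so that for a water-like centre (~0 HU) the
    index directly approximates the absolute HU deviation.
    """
    roi_radius = 0.20 * module_radius_mm
    center_dist = module_radius_mm - 10.0 - roi_radius
    central = roi_stats(slice486, phantom_center_mm, roi_radius, pixel_spacing)
    denom = central.mean + 100.0
    if abs(denom) < 1.0:
        raise MetricError("degenerate denominator: central mean + 100 below 1 HU")
    peripheral: dict[int, RoiStats] = {}
    indices: dict[int, float] = {}
    for clock in UNIFORMITY_CLOCKS:
        a = math.radians(clock * 30.0)  # clockwise from 12 o'clock
        c = (phantom_center_mm[0] + center_dist * math.sin(a),
             phantom_center_mm[1] + center_dist * math.cos(a))
        stats = roi_stats(slice486, c, roi_radius, pixel_spacing)
        peripheral[clock] = stats
        indices[clock] = (stats.mean - central.mean) / denom * 100.0
    return UniformitySet(central, peripheral, indices)


def cnr(slice404: np.ndarray, insert_centers_mm: dict[str, tuple[float, float]],
        phantom_center_mm: tuple[float, float],
        layout: PhantomLayout | None = None,
        pixel_spacing: tuple[float, float] = (1.0, 1.0),
        materials: tuple[str, ...] = CNR_INSERTS,
        background_rotation_deg: float | None = None) -> dict[str, CnrResult]:
    """Contrast-to-noise ratio per insert with a pooled-variance denominator:

        CNR = (mean_bkg - mean_insert) / sqrt((sd_bkg^2 + sd_insert^2) / 2)

    The background ROI has the same size and the same distance from the
    module centre as the insert ROI, rotated into the housing material
    between adjacent inserts (default: half the angular gap).
    """
    layout = layout or default_layout()
    out: dict[str, CnrResult] = {}
    for key in materials:
        insert = layout.insert_by_key(key)
        radius = insert.material.insert_radius - 1.0
        center = insert_centers_mm[key]
        rel = (center[0] - phantom_center_mm[0], center[1] - phantom_center_mm[1])
        dist = math.hypot(*rel)
        if background_rotation_deg is None:
            angles = sorted(p.angle_deg for p in layout.insert_positions)
            gaps = [b - a for a, b in zip(angles, angles[1:])] + \
                   [360.0 - angles[-1] + angles[0]]
            rot = min(gaps) / 2.0
        else:
            rot = background_rotation_deg
        # rotate clockwise by `rot` degrees about the phantom centre
        a = math.radians(rot)
        bx = rel[0] * math.cos(a) + rel[1] * math.sin(a)
        by = -rel[0] * math.sin(a) + rel[1] * math.cos(a)
        bkg_center = (phantom_center_mm[0] + bx, phantom_center_mm[1] + by)
        ins = roi_stats(slice404, center, radius, pixel_spacing)
        bkg = roi_stats(slice404, bkg_center, radius, pixel_spacing)
        pooled = 0.5 * (bkg.sd ** 2 + ins.sd ** 2)
        if pooled <= 0:
            raise MetricError("zero noise: pooled variance vanishes")
        signed = (bkg.mean - ins.mean) / math.sqrt(pooled)
        out[key] = CnrResult(signed, abs(signed), ins, bkg)
    return out


def roi_noise(uniformity_set: UniformitySet) -> float:
    """Scalar noise as the mean CT-number SD of the five uniformity ROIs."""
    sds = [uniformity_set.central.sd] + \
          [uniformity_set.peripheral[c].sd for c in UNIFORMITY_CLOCKS]
    if len(sds) != 5:
        raise MetricError("uniformity set incomplete")
    return float(np.mean(sds))
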