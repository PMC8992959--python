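"""Threshold-based, slice-wise localisation of the phantom and its landmarks.

Detection is fully automatic: the phantom margin is found per slice as the
largest connected component above an air/housing threshold, module slices
are identified from the nominal longitudinal layout anchored at the detected
phantom extent and confirmed by content checks, and rods, inserts and the
resolution point source are located inside small search windows around their
nominal positions.  Because every step is slice-wise and anchored at the
detected centre, small phantom translations need no explicit correction.

Default thresholds (margin -300 HU, air rods < -600 HU, Teflon > +500 HU,
uniformity-region SD < 50 HU) are implementation choices, not published
values; all are configurable through :class:`DetectionSettings`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DetectionError
from .geometry import PhantomLayout, default_layout
from .scan_io import ScanVolume, mm_to_px, pixel_coords, px_to_mm

__all__ = [
    "DetectionSettings",
    "Margins",
    "ModuleSlices",
    "Landmarks",
    "find_phantom_margins",
    "identify_module_slices",
    "locate_rods",
    "locate_inserts_and_source",
    "detect_landmarks",
]


@dataclass(frozen=True)
class DetectionSettings:
    margin_threshold_hu: float = -300.0  # air/housing boundary
    air_threshold_hu: float = -600.0
    teflon_threshold_hu: float = 500.0
    homogeneity_sd_hu: float = 50.0  # CTP486 content check
    rod_window_mm: float = 5.0  # half-width of rod search window
    source_window_mm: float = 5.0  # half-width of point-source window
    source_min_contrast_hu: float = 100.0
    module_window_mm: float = 6.0  # longitudinal content-check window
    radius_tolerance: float = 0.20  # plausible phantom radius band


@dataclass
class Margins:
    """Per-slice phantom circle: centre (x, y) mm and radius mm."""

    centers_mm: np.ndarray  # (n_slices, 2); NaN where not found
    radii_mm: np.ndarray  # (n_slices,); NaN where not found
    found: np.ndarray  # bool per slice
    phantom_radius_est: float

    def center(self, k: int) -> tuple[float, float]:
        if not self.found[k]:
            raise DetectionError(f"phantom not found on slice {k}")
        return float(self.centers_mm[k, 0]), float(self.centers_mm[k, 1])


@dataclass
class ModuleSlices:
    ctp404_center_slice: int
    ctp486_center_slice: int
    ctp528_source_slice: int


@dataclass
class RampSegment:
    """In-plane descriptor of one ramp on the CTP404 slices: a line along y
    at fixed x (analysis frame, mm)."""

    x_mm: float
    y_range_mm: tuple[float, float]


@dataclass
class Landmarks:
    margins: Margins
    modules: ModuleSlices
    rod_centers_mm: dict[int, tuple[float, float]]
    insert_centers_mm: dict[str, tuple[float, float]]
    source: tuple[int, float, float]  # (slice, x mm, y mm), sub-voxel in-plane
    ramp_segments: list[RampSegment]

    def validate(self, layout: PhantomLayout) -> None:
        if len(self.rod_centers_mm) != 4:
            raise DetectionError("expected exactly 4 labelled rods")
        if self.modules.ctp404_center_slice == self.modules.ctp486_center_slice:
            raise DetectionError("CTP404 and CTP486 identified on the same slice")


# ---------------------------------------------------------------------------
def find_phantom_margins(volume: ScanVolume, hu_threshold: float = -300.0,
                         layout: PhantomLayout | None = None,
                         radius_tolerance: float = 0.20) -> Margins:
    """Slice-wise phantom circle from the largest above-threshold component."""
    layout = layout or default_layout()
    n_slices = volume.n_slices
    shape = volume.hu.shape[1:]
    centers = np.full((n_slices, 2), np.nan)
    radii = np.full(n_slices, np.nan)
    found = np.zeros(n_slices, dtype=bool)
    px_area = volume.pixel_spacing[0] * volume.pixel_spacing[1]
    for k in range(n_slices):
        mask = volume.hu[k] > hu_threshold
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask)
        if n_lab == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n_lab + 1))
        big = int(np.argmax(sizes)) + 1
        comp = ndimage.binary_fill_holes(labels == big)
        area_mm2 = comp.sum() * px_area
        radius = math.sqrt(area_mm2 / math.pi)
        if abs(radius - layout.phantom_radius) > radius_tolerance * layout.phantom_radius:
            continue
        r_idx, c_idx = np.nonzero(comp)
        row, col = r_idx.mean(), c_idx.mean()
        centers[k] = px_to_mm((row, col), shape, volume.pixel_spacing)
        radii[k] = radius
        found[k] = True
    if not found.any():
        raise DetectionError("phantom not found")
    return Margins(centers, radii, found, float(np.nanmedian(radii)))


def _predicted_index(volume: ScanVolume, margins: Margins,
                     layout: PhantomLayout, module_key: str) -> int:
    """Expected slice index of a module plane, anchored at the detected
    longitudinal phantom extent (first slice on which the phantom appears)."""
    first = int(np.argmax(margins.found))
    z_anchor = volume.slice_positions[first]
    expected = z_anchor + (layout.module_offsets[module_key] - layout.body_z[0])
    return int(np.argmin(np.abs(volume.slice_positions - expected)))


def _window(volume: ScanVolume, center_idx: int, half_mm: float) -> range:
    half = max(2, int(round(half_mm / volume.slice_spacing)))
    return range(max(0, center_idx - half), min(volume.n_slices, center_idx + half + 1))


def _count_rods(image: np.ndarray, center: tuple[float, float],
                layout: PhantomLayout, pixel_spacing, settings: DetectionSettings) -> int:
    n_found = 0
    for rod in layout.rod_positions:
        expected = (rod.center_xy[0] + center[0], rod.center_xy[1] + center[1])
        try:
            _rod_centroid(image, expected, rod.material.nominal_hu, layout,
                          pixel_spacing, settings)
            n_found += 1
        except DetectionError:
            pass
    return n_found


def identify_module_slices(volume: ScanVolume, margins: Margins,
                           layout: PhantomLayout | None = None,
                           settings: DetectionSettings = DetectionSettings(),
                           ) -> ModuleSlices:
    """Locate the CTP404/CTP486 centre slices and the CTP528 source slice.

    Candidate indices come from the nominal module offsets anchored at the
    detected phantom extent; each is refined by a content check inside a
    longitudinal window (rod features for CTP404, in-plane homogeneity for
    CTP486, peak contrast near the nominal source position for CTP528).
    Ties are broken toward the predicted offset, then the lower index.
    """
    layout = layout or default_layout()
    shape = volume.hu.shape[1:]

    # CTP404: slices showing all four rods
    pred404 = _predicted_index(volume, margins, layout, "ctp404")
    cands = []
    for k in _window(volume, pred404, settings.module_window_mm):
        if not margins.found[k]:
            continue
        if _count_rods(volume.hu[k], margins.center(k), layout,
                       volume.pixel_spacing, settings) == 4:
            cands.append(k)
    if not cands:
        raise DetectionError("module not identified: CTP404")
    i404 = min(cands, key=lambda k: (abs(k - pred404), k))

    # CTP486: homogeneous central region
    pred486 = _predicted_index(volume, margins, layout, "ctp486")
    cands = []
    for k in _window(volume, pred486, settings.module_window_mm):
        if not margins.found[k]:
            continue
        cx, cy = margins.center(k)
        stats = _central_region_stats(volume.hu[k], (cx, cy), shape,
                                      volume.pixel_spacing,
                                      0.5 * layout.uniformity_module_radius)
        if stats[1] < settings.homogeneity_sd_hu and abs(stats[0]) < 300.0:
            cands.append(k)
    if not cands:
        raise DetectionError("module not identified: CTP486")
    i486 = min(cands, key=lambda k: (abs(k - pred486), k))

    # CTP528: slice maximising the peak near the nominal source position
    pred528 = _predicted_index(volume, margins, layout, "ctp528_source")
    best, best_peak = None, -np.inf
    for k in _window(volume, pred528, settings.module_window_mm):
        if not margins.found[k]:
            continue
        cx, cy = margins.center(k)
        sx = layout.point_source_inplane[0] + cx
        sy = layout.point_source_inplane[1] + cy
        win = _extract_window(volume.hu[k], (sx, sy), settings.source_window_mm,
                              shape, volume.pixel_spacing)
        peak = float(win.max()) - float(np.median(volume.hu[k][_central_mask(
            shape, (cx, cy), volume.pixel_spacing, 30.0)]))
        if peak > best_peak:
            best, best_peak = k, peak
    if best is None or best_peak < settings.source_min_contrast_hu:
        raise DetectionError("module not identified: CTP528 (point source not found)")
    return ModuleSlices(i404, i486, best)


# --- in-plane landmark helpers ---------------------------------------------
def _central_mask(shape, center_mm, pixel_spacing, radius_mm) -> np.ndarray:
    x, y = pixel_coords(shape, pixel_spacing)
    return (x[None, :] - center_mm[0]) ** 2 + (y[:, None] - center_mm[1]) ** 2 \
        <= radius_mm ** 2


def _central_region_stats(image, center_mm, shape, pixel_spacing, radius_mm):
    vals = image[_central_mask(shape, center_mm, pixel_spacing, radius_mm)]
    return float(vals.mean()), float(vals.std())


def _extract_window(image, center_mm, half_mm, shape, pixel_spacing):
    row, col = mm_to_px(center_mm, shape, pixel_spacing)
    hr = int(round(half_mm / pixel_spacing[0]))
    hc = int(round(half_mm / pixel_spacing[1]))
    r0, r1 = max(0, int(round(row)) - hr), min(shape[0], int(round(row)) + hr + 1)
    c0, c1 = max(0, int(round(col)) - hc), min(shape[1], int(round(col)) + hc + 1)
    if r0 >= r1 or c0 >= c1:
        raise DetectionError("search window outside image")
    return image[r0:r1, c0:c1]


def _rod_centroid(image, expected_mm, nominal_hu, layout: PhantomLayout,
                  pixel_spacing, settings: DetectionSettings) -> tuple[float, float]:
    """Sub-pixel rod centre: intensity-weighted centroid of the thresholded
    component inside a search window around the nominal position."""
    shape = image.shape
    row, col = mm_to_px(expected_mm, shape, pixel_spacing)
    hr = int(round(settings.rod_window_mm / pixel_spacing[0]))
    hc = int(round(settings.rod_window_mm / pixel_spacing[1]))
    r0, c0 = int(round(row)) - hr, int(round(col)) - hc
    r1, c1 = int(round(row)) + hr + 1, int(round(col)) + hc + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise DetectionError("rod search window outside image")
    win = image[r0:r1, c0:c1]
    if nominal_hu > 0:
        thr = settings.teflon_threshold_hu
        mask = win > thr
        weight = win - thr
    else:
        thr = settings.air_threshold_hu
        mask = win < thr
        weight = thr - win
    if not mask.any():
        raise DetectionError("rod not found")
    labels, n_lab = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_lab + 1))
    big = int(np.argmax(sizes)) + 1
    comp = labels == big
    nominal_area = math.pi * layout.rod_radius ** 2 / (pixel_spacing[0] * pixel_spacing[1])
    if comp.sum() < max(5, 0.15 * nominal_area) or comp.sum() > 4.0 * nominal_area:
        raise DetectionError("rod component of implausible area")
    w = np.where(comp, np.clip(weight, 0.0, None), 0.0)
    rr, cc = np.nonzero(comp)
    wt = w[rr, cc]
    crow = float((rr * wt).sum() / wt.sum()) + r0
    ccol = float((cc * wt).sum() / wt.sum()) + c0
    return px_to_mm((crow, ccol), shape, pixel_spacing)


def locate_rods(slice404: np.ndarray, margins_center_mm: tuple[float, float],
                layout: PhantomLayout, pixel_spacing: tuple[float, float],
                settings: DetectionSettings = DetectionSettings(),
                ) -> dict[int, tuple[float, float]]:
    """Sub-pixel centres of the Teflon and three air rods, labelled 1-4."""
    out: dict[int, tuple[float, float]] = {}
    for rod in layout.rod_positions:
        expected = (rod.center_xy[0] + margins_center_mm[0],
                    rod.center_xy[1] + margins_center_mm[1])
        try:
            out[rod.label] = _rod_centroid(slice404, expected,
                                           rod.material.nominal_hu, layout,
                                           pixel_spacing, settings)
        except DetectionError as exc:
            raise DetectionError(f"rod not found: label {rod.label} ({exc})") from exc
    return out


def locate_inserts_and_source(volume: ScanVolume, margins: Margins,
                              layout: PhantomLayout, modules: ModuleSlices,
                              settings: DetectionSettings = DetectionSettings(),
                              ) -> tuple[dict[str, tuple[float, float]],
                                         tuple[int, float, float]]:
    """Insert centres (layout angles anchored at the detected phantom centre)
    and the HU-weighted sub-voxel point-source position."""
    shape = volume.hu.shape[1:]
    cx404, cy404 = margins.center(modules.ctp404_center_slice)
    inserts = {p.key: (p.center_xy()[0] + cx404, p.center_xy()[1] + cy404)
               for p in layout.insert_positions}

    k = modules.ctp528_source_slice
    cx, cy = margins.center(k)
    sx = layout.point_source_inplane[0] + cx
    sy = layout.point_source_inplane[1] + cy
    image = volume.hu[k]
    row, col = mm_to_px((sx, sy), shape, volume.pixel_spacing)
    hr = int(round(settings.source_window_mm / volume.pixel_spacing[0]))
    hc = int(round(settings.source_window_mm / volume.pixel_spacing[1]))
    r0, c0 = int(round(row)) - hr, int(round(col)) - hc
    win = image[r0:r0 + 2 * hr + 1, c0:c0 + 2 * hc + 1]
    bg = float(np.median(image[_central_mask(shape, (cx, cy),
                                             volume.pixel_spacing, 30.0)]))
    peak = float(win.max()) - bg
    if peak < settings.source_min_contrast_hu:
        raise DetectionError("point source not found")
    w = np.clip(win - bg, 0.0, None)
    w[w < 0.05 * peak] = 0.0  # suppress the noise floor in the centroid
    rr, cc = np.indices(w.shape)
    crow = float((rr * w).sum() / w.sum()) + r0
    ccol = float((cc * w).sum() / w.sum()) + c0
    x_mm, y_mm = px_to_mm((crow, ccol), shape, volume.pixel_spacing)
    return inserts, (k, x_mm, y_mm)


def detect_landmarks(volume: ScanVolume, layout: PhantomLayout | None = None,
                     settings: DetectionSettings = DetectionSettings()) -> Landmarks:
    """Run the full detection chain and return all landmarks."""
    layout = layout or default_layout()
    margins = find_phantom_margins(volume, settings.margin_threshold_hu, layout,
                                   settings.radius_tolerance)
    modules = identify_module_slices(volume, margins, layout, settings)
    center404 = margins.center(modules.ctp404_center_slice)
    rods = locate_rods(volume.hu[modules.ctp404_center_slice], center404,
                       layout, volume.pixel_spacing, settings)
    inserts, source = locate_inserts_and_source(volume, margins, layout,
                                                modules, settings)
    ramps = [RampSegment(x_mm=ramp_x + center404[0],
                         y_range_mm=(center404[1] - layout.ramp_half_length - 7.0,
                                     center404[1] + layout.ramp_half_length + 7.0))
             for ramp_x in layout.ramp_x_offsets]
    lm = Landmarks(margins, modules, rods, inserts, source, ramps)
    lm.validate(layout)
    return lm
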