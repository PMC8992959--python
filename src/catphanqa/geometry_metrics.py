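"""Spatial linearity from rod distances and slice thickness from ramp profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detection import Landmarks, RampSegment
from .errors import MetricError
from .geometry import PhantomLayout, default_layout
from .scan_io import ScanVolume, mm_to_px

__all__ = ["LinearityResult", "SliceThicknessResult", "spatial_linearity",
           "profile_fwhm", "thickness_from_fwhms", "slice_thickness"]


@dataclass
class LinearityResult:
    """Rod-quadrilateral side and diagonal lengths in mm, keyed by rod pair."""

    sides: dict[str, float]
    diagonals: dict[str, float]

    def all_distances(self) -> dict[str, float]:
        return {**self.sides, **self.diagonals}


@dataclass
class SliceThicknessResult:
    per_ramp_fwhm: dict[float, float]  # ramp x-offset -> summed FWHM (mm)
    ramp_angle_deg: float
    n_slices: int
    thickness: float  # mm


def spatial_linearity(rod_centers_mm: dict[int, tuple[float, float]],
                      layout: PhantomLayout | None = None) -> LinearityResult:
    """Euclidean distances of the 4 sides and 2 diagonals of the rod square."""
    layout = layout or default_layout()
    pts = rod_centers_mm
    seen = {tuple(np.round(v, 9)) for v in pts.values()}
    if len(seen) != len(pts):
        raise MetricError("duplicate rod centers")

    def dist(a: int, b: int) -> float:
        (xa, ya), (xb, yb) = pts[a], pts[b]
        return math.hypot(xa - xb, ya - yb)

    sides = {f"{a}-{b}": dist(a, b) for a, b in layout.rod_sides}
    diagonals = {f"{a}-{b}": dist(a, b) for a, b in layout.rod_diagonals}
    if any(v <= 0 for v in {**sides, **diagonals}.values()):
        raise MetricError("degenerate rod distance")
    return LinearityResult(sides, diagonals)


def profile_fwhm(profile: np.ndarray, spacing: float,
                 min_contrast: float = 50.0) -> float:
    """Full width at half maximum of a single-lobe profile.

    The half-maximum level is referenced to (peak - background), with the
    background taken as the profile median (the central lobe occupies a small
    fraction of the sampled range); crossings are located by linear
    interpolation between the bracketing samples.  ``min_contrast`` (HU) is a
    plausibility floor: the wire peak is diluted roughly as 1/thickness by
    partial volume, but even at thick-slice protocols it stays well above
    50 HU, while noise excursions over the short band stay well below.
    """
    profile = np.asarray(profile, dtype=float)
    bg = float(np.median(profile))
    peak_idx = int(np.argmax(profile))
    peak = profile[peak_idx]
    if peak < bg + min_contrast:
        raise MetricError(
            f"ramp not found: profile peak below background + {min_contrast:g} HU")
    half = bg + 0.5 * (peak - bg)

    def cross(idx_range) -> float:
        prev = peak_idx
        for i in idx_range:
            if profile[i] < half:
                # interpolate between i and prev
                f = (half - profile[i]) / (profile[prev] - profile[i])
                return i + f * (prev - i)
            prev = i
        raise MetricError("FWHM bounds outside profile")

    left = cross(range(peak_idx - 1, -1, -1))
    right = cross(range(peak_idx + 1, len(profile)))
    return float((right - left) * spacing)


def thickness_from_fwhms(fwhms_mm, ramp_angle_deg: float) -> float:
    """Slice thickness = (sum of per-slice FWHMs) * tan(angle) / n_slices."""
    fwhms = list(fwhms_mm)
    if not fwhms:
        raise MetricError("no ramp profiles")
    return float(sum(fwhms) * math.tan(math.radians(ramp_angle_deg)) / len(fwhms))


def _ramp_profile(image: np.ndarray, segment: RampSegment,
                  pixel_spacing: tuple[float, float]) -> tuple[np.ndarray, float]:
    """HU profile along y: maximum-intensity ridge across a narrow band in x."""
    shape = image.shape
    r_top, c_lo = mm_to_px((segment.x_mm - 2.0, segment.y_range_mm[1]), shape,
                           pixel_spacing)
    r_bot, c_hi = mm_to_px((segment.x_mm + 2.0, segment.y_range_mm[0]), shape,
                           pixel_spacing)
    r0, r1 = int(math.floor(r_top)), int(math.ceil(r_bot)) + 1
    c0, c1 = int(math.floor(c_lo)), int(math.ceil(c_hi)) + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise MetricError("ramp profile band outside image")
    band = image[r0:r1, c0:c1]
    return band.max(axis=1), pixel_spacing[0]


def slice_thickness(volume: ScanVolume, landmarks: Landmarks,
                    layout: PhantomLayout | None = None,
                    n_slices: int = 3) -> SliceThicknessResult:
    """Reconstructed slice thickness from the inclined-ramp method.

    Each ramp maps the longitudinal sensitivity profile into an in-plane HU
    profile; the FWHM is accumulated over the module's ``n_slices`` central
    slices and converted with tan(inclination)/n_slices.  The two ramps'
    estimates are averaged.
    """
    layout = layout or default_layout()
    i404 = landmarks.modules.ctp404_center_slice
    # Module identification is only accurate to about one slice; at coarse
    # slice thickness a one-slice offset can push the outermost averaging
    # slice past the ramp's longitudinal extent.  Re-centre the window on the
    # candidate centre (within +-1 of the detected one) whose weakest window
    # slice still carries the strongest ramp signal.
    half = n_slices // 2

    def _slice_peak(k: int) -> float:
        peak = 0.0
        for seg in landmarks.ramp_segments:
            profile, _ = _ramp_profile(volume.hu[k], seg, volume.pixel_spacing)
            peak += float(profile.max() - np.median(profile))
        return peak

    best_k, best_score = i404, -math.inf
    for k in range(i404 - 1, i404 + 2):
        window = range(k - half, k - half + n_slices)
        if window[0] < 0 or window[-1] >= volume.n_slices:
            continue
        score = min(_slice_peak(j) for j in window)
        if score > best_score:
            best_k, best_score = k, score
    idx = range(best_k - half, best_k - half + n_slices)
    if idx[0] < 0 or idx[-1] >= volume.n_slices:
        raise MetricError("central CTP404 slices outside volume")
    per_ramp: dict[float, float] = {}
    estimates = []
    for seg, ramp_x in zip(landmarks.ramp_segments, layout.ramp_x_offsets):
        total = 0.0
        for k in idx:
            profile, spacing = _ramp_profile(volume.hu[k], seg, volume.pixel_spacing)
            total += profile_fwhm(profile, spacing)
        per_ramp[ramp_x] = total
        estimates.append(total * math.tan(math.radians(layout.ramp_angle_deg))
                         / n_slices)
    return SliceThicknessResult(per_ramp, layout.ramp_angle_deg, n_slices,
                                float(np.mean(estimates)))
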