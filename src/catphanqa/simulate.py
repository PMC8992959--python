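"""Synthetic CatPhan 504 scan rendering with known ground truth.

The renderer produces HU volumes containing the three analysed modules: a
sensitometry module with eight inserts, four linearity rods and two opposed
inclined wire ramps; a resolution plane with a sub-pixel point source; and a
homogeneous water-like uniformity module.  Edges are rendered with
area-weighted supersampling (partial-volume antialiasing in-plane and along
z), Gaussian blur emulates the reconstruction PSF, and white (optionally
frequency-shaped) Gaussian noise is added last.

This is a geometric emulator, not a physics simulation: there are no
sinograms, no beam hardening and no scatter.  Its purpose is to give every
detector and metric a ground truth to be tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .errors import ValidationError
from .geometry import PhantomLayout, default_layout
from .scan_io import ScanVolume, mm_to_px, pixel_coords

__all__ = ["SimulationConfig", "GroundTruth", "render_scan", "write_dicom_series"]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Rendering parameters; defaults mirror a typical validation protocol
    (512 x 512 matrix, 0.5 mm pixels, 3 mm slices, smooth kernel)."""

    pixel_size: float = 0.5  # mm, isotropic in-plane
    matrix_size: int = 512  # pixels per side
    slice_thickness: float = 3.0  # mm
    slice_count: int | None = None  # default: cover the whole phantom body
    z_start: float = -28.0  # mm, centre of the first slice (CTP404 frame)
    psf_sigma: float = 0.6  # mm Gaussian in-plane blur
    noise_sigma: float = 10.0  # HU white Gaussian noise
    noise_correlation: float | None = None  # mm isotropic correlation length
    source_contrast: float = 1000.0  # HU peak of the rendered point source
    layout: PhantomLayout = field(default_factory=default_layout)
    rng_seed: int = 0
    offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (dx, dy, dz) mm
    supersample: int = 4  # per-axis subsampling at edges

    def resolved_slice_count(self) -> int:
        if self.slice_count is not None:
            return self.slice_count
        z_end = self.layout.body_z[1] + self.offsets[2] + self.slice_thickness
        return int(math.ceil((z_end - self.z_start) / self.slice_thickness)) + 1

    def slice_positions(self) -> np.ndarray:
        n = self.resolved_slice_count()
        return self.z_start + np.arange(n) * self.slice_thickness

    def validate(self) -> None:
        if not (0.1 <= self.pixel_size <= 2.0):
            raise ValidationError("pixel_size", "must lie in [0.1, 2.0] mm")
        if self.matrix_size < 128:
            raise ValidationError("matrix_size", "must be >= 128")
        if self.psf_sigma < 0:
            raise ValidationError("psf_sigma", "must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma", "must be >= 0")
        if self.slice_thickness <= 0:
            raise ValidationError("slice_thickness", "must be > 0")
        if self.supersample < 1:
            raise ValidationError("supersample", "must be >= 1")
        lay = self.layout
        lay.validate()
        dz = self.offsets[2]
        pos = self.slice_positions()
        T = self.slice_thickness
        # all three module planes must be contained, with enough margin for
        # the three-slice ramp window and the 4x-thickness NPS partner slice
        needed = [
            lay.module_offsets["ctp404"] + dz - 1.5 * T,
            lay.module_offsets["ctp404"] + dz + 1.5 * T,
            lay.module_offsets["ctp528_source"] + dz,
            lay.module_offsets["ctp486"] + dz,
            lay.module_offsets["ctp486"] + dz + 4.0 * T,
            lay.body_z[0] + dz,
        ]
        if min(needed) < pos[0] - T / 2 or max(needed) > pos[-1] + T / 2:
            raise ValidationError("slice_count",
                                  "volume does not cover all module planes")
        if lay.phantom_radius * 2 >= self.pixel_size * self.matrix_size:
            raise ValidationError("matrix_size", "phantom does not fit in the field of view")


@dataclass
class GroundTruth:
    """Everything the renderer knows that the pipeline should recover."""

    material_hu: dict[str, float]
    insert_centers_mm: dict[str, tuple[float, float]]  # analysis frame, mm
    rod_centers_mm: dict[int, tuple[float, float]]
    rod_side_lengths: dict[str, float]
    rod_diagonal_lengths: dict[str, float]
    source_slice: int
    source_xy_mm: tuple[float, float]
    module_center_slices: dict[str, int]
    phantom_center_mm: tuple[float, float]
    slice_thickness: float
    psf_sigma: float
    noise_sigma: float
    landmark_voxels: dict[str, tuple[float, ...]]  # (slice, row, col) coordinates


# ---------------------------------------------------------------------------
def _disk_coverage(x: np.ndarray, y: np.ndarray, cx: float, cy: float,
                   radius: float, pixel: float, ss: int) -> np.ndarray:
    """Area fraction of each pixel covered by a disk (supersampled edges)."""
    r = np.hypot(x[None, :] - cx, y[:, None] - cy)
    half_diag = pixel * _SQRT2 / 2.0
    cov = (r <= radius - half_diag).astype(np.float64)
    band = np.abs(r - radius) <= half_diag + 0.5 * pixel
    if not band.any() or ss == 1:
        cov[band] = (r[band] <= radius).astype(np.float64)
        return cov
    jj, ii = np.nonzero(band)
    offs = ((np.arange(ss) + 0.5) / ss - 0.5) * pixel
    sx = x[ii][:, None, None] + offs[None, :, None]
    sy = y[jj][:, None, None] + offs[None, None, :]
    inside = (sx - cx) ** 2 + (sy - cy) ** 2 <= radius * radius
    cov[jj, ii] = inside.mean(axis=(1, 2))
    return cov


def _slab_overlap(z0: float, z1: float, lo: float, hi: float) -> float:
    """Fraction of slab [z0, z1] inside [lo, hi]."""
    return max(0.0, min(z1, hi) - max(z0, lo)) / (z1 - z0)


def _render_ramp(img: np.ndarray, x: np.ndarray, y: np.ndarray,
                 ramp_x: float, cy: float, z404: float,
                 z0: float, z1: float, layout: PhantomLayout,
                 pixel: float, ss: int) -> None:
    """Add one inclined wire ramp to a slice via 3D supersampled coverage."""
    tan_a = math.tan(math.radians(layout.ramp_angle_deg))
    rho = layout.ramp_radius
    L = layout.ramp_half_length
    # wire: p(t) = (ramp_x, cy + t, z404 + t * tan_a), |t| <= L
    t_lo = (z0 - z404) / tan_a - 2 * rho / tan_a - pixel
    t_hi = (z1 - z404) / tan_a + 2 * rho / tan_a + pixel
    t_lo, t_hi = max(t_lo, -L), min(t_hi, L)
    if t_lo >= t_hi:
        return
    xm = (np.abs(x - ramp_x) <= rho + pixel)
    ym = (y >= cy + t_lo - pixel) & (y <= cy + t_hi + pixel)
    ii = np.nonzero(xm)[0]
    jj = np.nonzero(ym)[0]
    if len(ii) == 0 or len(jj) == 0:
        return
    offs = ((np.arange(ss) + 0.5) / ss - 0.5) * pixel
    ssz = max(2 * ss, 8)
    zc = z0 + (np.arange(ssz) + 0.5) / ssz * (z1 - z0)
    # subsample grid: (ny, nx, ss_y, ss_x, ss_z)
    sx = (x[ii][None, :, None, None, None] + offs[None, None, None, :, None])
    sy = (y[jj][:, None, None, None, None] + offs[None, None, :, None, None])
    sz = zc[None, None, None, None, :]
    d = np.array([0.0, 1.0, tan_a])
    d /= np.linalg.norm(d)
    vx = sx - ramp_x
    vy = sy - cy
    vz = sz - z404
    proj = vy * d[1] + vz * d[2]
    dist2 = vx * vx + vy * vy + vz * vz - proj * proj
    inside = (dist2 <= rho * rho) & (np.abs(proj) <= L / d[1])
    cov = inside.mean(axis=(2, 3, 4))
    img[np.ix_(jj, ii)] += cov * (layout.ramp_hu - layout.background_hu)


def _pixel_avg_gaussian(x: np.ndarray, y: np.ndarray, x0: float, y0: float,
                        sigma: float, amp: float, pixel: float) -> np.ndarray:
    """Pixel-area-averaged 2D Gaussian blob of peak ``amp``."""
    s2 = sigma * _SQRT2

    def avg(u: np.ndarray, u0: float) -> np.ndarray:
        a = (u - pixel / 2 - u0) / s2
        b = (u + pixel / 2 - u0) / s2
        return sigma * math.sqrt(math.pi / 2.0) * (erf(b) - erf(a)) / pixel

    return amp * avg(y, y0)[:, None] * avg(x, x0)[None, :]


def _shaped_noise(shape: tuple[int, int], sigma: float, corr_mm: float,
                  pixel: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with isotropic Gaussian-shaped power spectrum."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0], d=pixel)
    fx = np.fft.fftfreq(shape[1], d=pixel)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    h = np.exp(-2.0 * math.pi ** 2 * corr_mm ** 2 * f2)
    shaped = np.fft.ifft2(np.fft.fft2(white) * h).real
    shaped *= sigma / shaped.std()
    return shaped


def render_scan(config: SimulationConfig) -> tuple[ScanVolume, GroundTruth]:
    """Render a synthetic scan volume and its ground truth."""
    config.validate()
    lay = config.layout
    dx_off, dy_off, dz_off = config.offsets
    px = config.pixel_size
    n = config.matrix_size
    T = config.slice_thickness
    ss = config.supersample
    positions = config.slice_positions()
    x, y = pixel_coords((n, n), (px, px))
    rng = np.random.default_rng(config.rng_seed)

    air_hu = -1000.0
    bg = lay.background_hu
    body_lo = lay.body_z[0] + dz_off
    body_hi = lay.body_z[1] + dz_off
    z404_lo, z404_hi = (v + dz_off for v in lay.module_z_extents["ctp404"])
    z404_center = lay.module_offsets["ctp404"] + dz_off
    source_z = lay.module_offsets["ctp528_source"] + dz_off
    source_xy = (lay.point_source_inplane[0] + dx_off,
                 lay.point_source_inplane[1] + dy_off)
    source_slice = int(np.argmin(np.abs(positions - source_z)))

    body_cov = _disk_coverage(x, y, dx_off, dy_off, lay.phantom_radius, px, ss)
    insert_cov = {
        p.key: (_disk_coverage(x, y, p.center_xy()[0] + dx_off,
                               p.center_xy()[1] + dy_off,
                               p.material.insert_radius, px, ss),
                p.material.nominal_hu)
        for p in lay.insert_positions
    }
    rod_cov = {
        r.label: (_disk_coverage(x, y, r.center_xy[0] + dx_off,
                                 r.center_xy[1] + dy_off, lay.rod_radius, px, ss),
                  r.material.nominal_hu)
        for r in lay.rod_positions
    }

    hu = np.empty((len(positions), n, n), dtype=np.float64)
    sigma_px = config.psf_sigma / px
    for k, z in enumerate(positions):
        z0, z1 = z - T / 2, z + T / 2
        f_body = _slab_overlap(z0, z1, body_lo, body_hi)
        img = np.full((n, n), air_hu)
        if f_body > 0:
            img += body_cov * f_body * (bg - air_hu)
            f404 = _slab_overlap(z0, z1, z404_lo, z404_hi)
            if f404 > 0:
                for cov, mat_hu in insert_cov.values():
                    img += cov * f404 * (mat_hu - bg)
                for cov, mat_hu in rod_cov.values():
                    img += cov * f404 * (mat_hu - bg)
                for ramp_x in lay.ramp_x_offsets:
                    _render_ramp(img, x, y, ramp_x + dx_off, dy_off,
                                 z404_center, z0, z1, lay, px, ss)
        if sigma_px > 0:
            img = ndimage.gaussian_filter(img, sigma_px, mode="nearest")
        if k == source_slice:
            # With no blur configured, a true point is unresolvable on the
            # pixel grid; render it at half-pixel width so it remains a
            # well-defined landmark.
            blob_sigma = config.psf_sigma if config.psf_sigma > 0 else 0.5 * px
            img += _pixel_avg_gaussian(x, y, source_xy[0], source_xy[1],
                                       blob_sigma, config.source_contrast, px)
        if config.noise_sigma > 0:
            if config.noise_correlation:
                img += _shaped_noise((n, n), config.noise_sigma,
                                     config.noise_correlation, px, rng)
            else:
                img += rng.normal(0.0, config.noise_sigma, size=(n, n))
        hu[k] = img

    volume = ScanVolume(hu, (px, px), positions, T, source_id="synthetic")

    insert_centers = {p.key: (p.center_xy()[0] + dx_off, p.center_xy()[1] + dy_off)
                      for p in lay.insert_positions}
    rod_centers = {r.label: (r.center_xy[0] + dx_off, r.center_xy[1] + dy_off)
                   for r in lay.rod_positions}
    sides = {}
    for a, b in lay.rod_sides:
        (xa, ya), (xb, yb) = rod_centers[a], rod_centers[b]
        sides[f"{a}-{b}"] = math.hypot(xa - xb, ya - yb)
    diags = {}
    for a, b in lay.rod_diagonals:
        (xa, ya), (xb, yb) = rod_centers[a], rod_centers[b]
        diags[f"{a}-{b}"] = math.hypot(xa - xb, ya - yb)
    module_slices = {
        name: int(np.argmin(np.abs(positions - (lay.module_offsets[key] + dz_off))))
        for name, key in (("ctp404", "ctp404"), ("ctp486", "ctp486"))
    }
    module_slices["ctp528_source"] = source_slice

    shape2d = (n, n)
    landmark_voxels = {"phantom_center": mm_to_px((dx_off, dy_off), shape2d, (px, px))}
    for key, c in insert_centers.items():
        landmark_voxels[f"insert/{key}"] = mm_to_px(c, shape2d, (px, px))
    for label, c in rod_centers.items():
        landmark_voxels[f"rod/{label}"] = mm_to_px(c, shape2d, (px, px))
    landmark_voxels["source"] = (source_slice,
                                 *mm_to_px(source_xy, shape2d, (px, px)))

    truth = GroundTruth(
        material_hu={p.key: p.material.nominal_hu for p in lay.insert_positions},
        insert_centers_mm=insert_centers,
        rod_centers_mm=rod_centers,
        rod_side_lengths=sides,
        rod_diagonal_lengths=diags,
        source_slice=source_slice,
        source_xy_mm=source_xy,
        module_center_slices=module_slices,
        phantom_center_mm=(dx_off, dy_off),
        slice_thickness=T,
        psf_sigma=config.psf_sigma,
        noise_sigma=config.noise_sigma,
        landmark_voxels=landmark_voxels,
    )
    return volume, truth


# ---------------------------------------------------------------------------
def write_dicom_series(volume: ScanVolume, directory: str | Path,
                       series_description: str = "catphanqa synthetic") -> list[Path]:
    """Write one minimal CT-Image-Storage-like DICOM file per slice.

    HU values are stored as signed 16-bit integers with RescaleSlope 1 and
    RescaleIntercept -1024, so a round-trip through :func:`scan_io.load_series`
    reproduces the volume to within 1 HU.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    series_uid = generate_uid()
    n_rows, n_cols = volume.hu.shape[1:]
    dy, dx = volume.pixel_spacing
    paths: list[Path] = []
    for k in range(volume.n_slices):
        stored = np.round(volume.hu[k]).astype(np.int32) + 1024
        stored = np.clip(stored, -32768, 32767).astype(np.int16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.SeriesDescription = series_description
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.Rows = n_rows
        ds.Columns = n_cols
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = volume.slice_thickness
        ds.ImagePositionPatient = [-(n_cols - 1) / 2.0 * dx,
                                   -(n_rows - 1) / 2.0 * dy,
                                   float(volume.slice_positions[k])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.PixelData = stored.tobytes()

        path = directory / f"slice_{k:04d}.dcm"
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
        paths.append(path)
    return paths
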