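"""QA-routine orchestration: run all metrics on a scan, manage per-system
baselines and tolerances, evaluate pass/fail and persist documented results.

Every run appends to a per-system JSON-lines history (never overwrites), and
optionally writes a per-run directory with the machine-readable result
record, tabulated MTF / 1D-NPS curves (CSV) and plots.

Auto-configured tolerance half-widths about a measured baseline:

    CT numbers                  +- 50 HU
    rod distances               +- 1 mm
    slice thickness             +- 0.5 mm
    uniformity indices          +- 10 percentage points
    MTF HWHM/HWTM, CNRs, noise  +- 20% of baseline

The uniformity tolerance is interpreted as +-10 percentage points about the
baseline index (the index itself is a percentage); both noise scalars (the
NPS-derived and the ROI-based one) receive the 20% rule.  Tolerance bounds
are inclusive: a value exactly on a bound passes.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import fourier_metrics as fm
from . import geometry_metrics as gm
from . import hu_metrics as hm
from .detection import DetectionSettings, Landmarks, detect_landmarks
from .errors import CatphanQaError, MetricError
from .geometry import PhantomLayout, default_layout
from .scan_io import ScanVolume

__all__ = ["SystemProfile", "QaResult", "ScanAnalysis", "analyze_scan",
           "auto_baseline", "evaluate", "run_qar", "load_profile", "save_profile"]


# --- profile -----------------------------------------------------------------
@dataclass
class MetricBand:
    baseline: float
    lower: float
    upper: float


@dataclass
class SystemProfile:
    """Per-scanner/protocol baselines and tolerance bands, keyed by metric."""

    system_id: str
    metrics: dict[str, MetricBand] = field(default_factory=dict)
    created: str = ""
    modified: str = ""

    def validate(self) -> None:
        for key, band in self.metrics.items():
            if not (band.lower <= band.baseline <= band.upper):
                raise CatphanQaError(
                    f"profile metric '{key}': lower <= baseline <= upper violated")


def save_profile(profile: SystemProfile, path: str | Path) -> None:
    profile.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {"system_id": profile.system_id, "created": profile.created,
            "modified": profile.modified,
            "metrics": {k: asdict(v) for k, v in profile.metrics.items()}}
    path.write_text(json.dumps(data, indent=2, sort_keys=True))


def load_profile(path: str | Path) -> SystemProfile:
    data = json.loads(Path(path).read_text())
    profile = SystemProfile(
        data["system_id"],
        {k: MetricBand(**v) for k, v in data["metrics"].items()},
        data.get("created", ""), data.get("modified", ""))
    profile.validate()
    return profile


# --- measurement -------------------------------------------------------------
@dataclass
class ScanAnalysis:
    """All measured quantities of one scan, plus the curves behind them."""

    metrics: dict[str, float]
    landmarks: Landmarks
    ct_stats: dict[str, hm.RoiStats]
    uniformity_set: hm.UniformitySet
    cnr_results: dict[str, hm.CnrResult]
    linearity: gm.LinearityResult
    thickness: gm.SliceThicknessResult
    psf: fm.PsfFit
    mtf: fm.SpectralCurve
    hwhm: float
    hwtm: float | None
    nps2d: fm.Nps2d
    nps_radial: fm.SpectralCurve


def analyze_scan(volume: ScanVolume, layout: PhantomLayout | None = None,
                 settings: DetectionSettings = DetectionSettings()) -> ScanAnalysis:
    """Detect landmarks and compute every quality metric of the routine."""
    layout = layout or default_layout()
    lm = detect_landmarks(volume, layout, settings)
    i404 = lm.modules.ctp404_center_slice
    i486 = lm.modules.ctp486_center_slice
    center404 = lm.margins.center(i404)
    center486 = lm.margins.center(i486)

    metrics: dict[str, float] = {}
    ct_stats = hm.ct_numbers(volume.hu[i404], lm.insert_centers_mm, layout,
                             volume.pixel_spacing)
    for key, stats in ct_stats.items():
        metrics[f"ct_number/{key}"] = stats.mean

    linearity = gm.spatial_linearity(lm.rod_centers_mm, layout)
    for pair, dist in linearity.all_distances().items():
        metrics[f"rod_distance/{pair}"] = dist

    uniformity_set = hm.uniformity(volume.hu[i486], center486,
                                   layout.uniformity_module_radius,
                                   volume.pixel_spacing)
    for clock, idx in uniformity_set.indices.items():
        metrics[f"uniformity/{clock}"] = idx

    cnr_results = hm.cnr(volume.hu[i404], lm.insert_centers_mm, center404,
                         layout, volume.pixel_spacing)
    for key, res in cnr_results.items():
        metrics[f"cnr/{key}"] = res.signed
        metrics[f"cnr_magnitude/{key}"] = res.magnitude

    psf = fm.fit_psf(volume, lm.source)
    mtf, hwhm, hwtm = fm.mtf_from_psf(psf)
    metrics["mtf_hwhm"] = hwhm
    metrics["mtf_hwtm"] = hwtm if hwtm is not None else float("nan")

    nps2d = fm.nps_2d(volume, i486, center_mm=center486)
    radial = fm.nps_radial(nps2d)
    metrics["noise_nps"] = fm.nps_scalar(radial)
    metrics["noise_rois"] = hm.roi_noise(uniformity_set)

    thickness = gm.slice_thickness(volume, lm, layout)
    metrics["slice_thickness"] = thickness.thickness

    return ScanAnalysis(metrics, lm, ct_stats, uniformity_set, cnr_results,
                        linearity, thickness, psf, mtf, hwhm, hwtm, nps2d, radial)


# --- tolerances --------------------------------------------------------------
def _tolerance_band(key: str, baseline: float) -> tuple[float, float]:
    """Auto-configured tolerance band about a measured baseline."""
    if key.startswith("ct_number/"):
        half = 50.0  # HU
    elif key.startswith("rod_distance/"):
        half = 1.0  # mm
    elif key == "slice_thickness":
        half = 0.5  # mm
    elif key.startswith("uniformity/"):
        half = 10.0  # percentage points
    elif (key.startswith(("cnr/", "cnr_magnitude/"))
          or key in ("mtf_hwhm", "mtf_hwtm", "noise_nps", "noise_rois")):
        half = 0.20 * abs(baseline)
    else:
        raise MetricError(f"no tolerance rule for metric '{key}'")
    return baseline - half, baseline + half


def auto_baseline(volume: ScanVolume, layout: PhantomLayout | None = None,
                  system_id: str = "default",
                  settings: DetectionSettings = DetectionSettings(),
                  ) -> SystemProfile:
    """Measure a scan and store the results as baselines with pre-configured
    tolerances (see module docstring)."""
    analysis = analyze_scan(volume, layout, settings)
    now = _dt.datetime.now().isoformat(timespec="seconds")
    profile = SystemProfile(system_id, created=now, modified=now)
    for key, value in analysis.metrics.items():
        if math.isnan(value):
            continue
        lower, upper = _tolerance_band(key, value)
        profile.metrics[key] = MetricBand(value, lower, upper)
    profile.validate()
    return profile


# --- evaluation & reporting ---------------------------------------------------
@dataclass
class QaResult:
    metric: str
    value: float
    baseline: float | None
    lower: float | None
    upper: float | None
    passed: bool
    status: str  # "pass", "fail", "not computed", "no tolerance"
    timestamp: str
    scan_id: str


def evaluate(measured: float, bounds: tuple[float, float]) -> tuple[bool, str]:
    """Inclusive-bound tolerance check; NaN fails with status 'not computed'."""
    lower, upper = bounds
    if lower > upper:
        raise CatphanQaError("tolerance bounds out of order")
    if math.isnan(measured):
        return False, "not computed"
    ok = lower <= measured <= upper
    return ok, "pass" if ok else "fail"


def run_qar(volume: ScanVolume, profile: SystemProfile,
            layout: PhantomLayout | None = None,
            out_dir: str | Path | None = None, scan_id: str = "",
            settings: DetectionSettings = DetectionSettings(),
            make_plots: bool = True,
            timestamp: str | None = None) -> list[QaResult]:
    """Run the full QA routine and check every metric against the profile.

    Detection failures abort (there is nothing to measure without landmarks);
    individual metric failures are recorded per metric without aborting the
    rest.  When ``out_dir`` is given, results are appended to the system's
    history and a per-run directory with the record, curve CSVs and plots is
    written.
    """
    analysis = analyze_scan(volume, layout, settings)
    ts = timestamp or _dt.datetime.now().isoformat(timespec="seconds")
    scan_id = scan_id or volume.source_id or "scan"
    results: list[QaResult] = []
    for key, value in analysis.metrics.items():
        band = profile.metrics.get(key)
        if band is None:
            results.append(QaResult(key, value, None, None, None,
                                    False, "no tolerance", ts, scan_id))
            continue
        ok, status = evaluate(value, (band.lower, band.upper))
        results.append(QaResult(key, value, band.baseline, band.lower,
                                band.upper, ok, status, ts, scan_id))
    if out_dir is not None:
        _persist(Path(out_dir), profile.system_id, ts, scan_id, analysis,
                 results, make_plots)
    return results


def _persist(out_dir: Path, system_id: str, ts: str, scan_id: str,
             analysis: ScanAnalysis, results: list[QaResult],
             make_plots: bool) -> None:
    sys_dir = out_dir / system_id
    sys_dir.mkdir(parents=True, exist_ok=True)
    record = {"timestamp": ts, "scan_id": scan_id,
              "results": [asdict(r) for r in results]}
    with (sys_dir / "history.jsonl").open("a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")

    run_dir = sys_dir / "runs" / ts.replace(":", "-")
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "results.json").write_text(json.dumps(record, indent=2,
                                                     sort_keys=True))
    np.savetxt(run_dir / "mtf.csv",
               np.column_stack([analysis.mtf.frequencies, analysis.mtf.values]),
               delimiter=",", header="frequency_cycles_per_mm,mtf", comments="")
    np.savetxt(run_dir / "nps_radial.csv",
               np.column_stack([analysis.nps_radial.frequencies,
                                analysis.nps_radial.values]),
               delimiter=",", header="frequency_cycles_per_mm,nps_hu2_mm2",
               comments="")
    if make_plots:
        _write_plots(run_dir, analysis)


def _write_plots(run_dir: Path, analysis: ScanAnalysis) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(analysis.mtf.frequencies, analysis.mtf.values)
    for level, name in ((0.5, "HWHM"), (0.1, "HWTM")):
        ax.axhline(level, color="grey", lw=0.5)
    ax.set_xlabel("spatial frequency (cycles/mm)")
    ax.set_ylabel("MTF")
    ax.set_title("Modulation transfer function")
    fig.tight_layout()
    fig.savefig(run_dir / "mtf.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    nps = np.fft.fftshift(analysis.nps2d.nps)
    fx = np.fft.fftshift(analysis.nps2d.fx)
    fy = np.fft.fftshift(analysis.nps2d.fy)
    im = ax.imshow(nps, extent=[fx[0], fx[-1], fy[0], fy[-1]], origin="lower")
    fig.colorbar(im, ax=ax, label="NPS (HU$^2$ mm$^2$)")
    ax.set_xlabel("$f_x$ (cycles/mm)")
    ax.set_ylabel("$f_y$ (cycles/mm)")
    ax.set_title("2D noise-power spectrum")
    fig.tight_layout()
    fig.savefig(run_dir / "nps_2d.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(analysis.nps_radial.frequencies, analysis.nps_radial.values)
    ax.set_xlabel("radial frequency (cycles/mm)")
    ax.set_ylabel("NPS (HU$^2$ mm$^2$)")
    ax.set_title("1D noise-power spectrum")
    fig.tight_layout()
    fig.savefig(run_dir / "nps_1d.png", dpi=120)
    plt.close(fig)
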