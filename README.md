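# catphanqa

Automated image-quality assurance for CT and cone-beam CT scanners using the
CatPhan 504 phantom.

## The problem

Routine CT quality assurance scans a standardised cylindrical phantom and
checks a battery of image-quality metrics against baselines recorded at
commissioning. Done by hand this is slow and observer-dependent: ROIs are
placed by eye, profiles are read off a viewer, and tolerance bookkeeping lives
in spreadsheets. `catphanqa` automates the whole chain — landmark detection,
metric computation, tolerance evaluation and record keeping — and ships a
physics-based synthetic scan generator so every step can be validated against
known ground truth.

## The model

The CatPhan 504 is a cylindrical phantom (100 mm radius) with three analysed
modules along its axis:

- **CTP404** (geometry and sensitometry): eight cylindrical inserts of known
  materials (air, PMP, LDPE, polystyrene, acrylic, Delrin, Teflon) on a ring,
  four small rods on a 50 mm square (one Teflon, three air) for spatial
  linearity, and two wire ramps inclined 23° to the axial plane for slice
  thickness.
- **CTP528** (resolution): a sub-pixel point source from which the point
  spread function (PSF) is fitted.
- **CTP486** (uniformity): a homogeneous disc (75 mm analysis radius) for
  uniformity, noise and the noise power spectrum (NPS).

Computed metrics and their definitions:

| Metric | Definition |
|---|---|
| CT numbers | Mean HU in a circular ROI 1 mm smaller than each insert |
| Spatial linearity | The 4 side and 2 diagonal distances of the rod square |
| Uniformity index | `U_i = (ROI_i − ROI_c) / (ROI_c + 100) · 100%` for ROIs at 3, 6, 9, 12 o'clock vs. the central ROI |
| CNR | `(mean_bkg − mean_insert) / sqrt((σ²_bkg + σ²_insert)/2)` for LDPE, polystyrene and Delrin |
| MTF HWHM / HWTM | Frequencies where the MTF (zero-order Hankel transform of the fitted radial Gaussian PSF) falls to 0.5 / 0.1 |
| Noise (NPS) | `sqrt` of the polar integral of the radial NPS, measured on the difference of two uniformity-module slices (~200 overlapping 5×5 cm ROIs, ½ correction for the differencing) |
| Noise (ROIs) | Mean standard deviation of the five uniformity ROIs |
| Slice thickness | Mean ramp-profile FWHM over 3 central slices × tan 23° |
| CTDIw / CBDIw | `DLP_c/(3C) + 2·DLP_p/(3C)` and `(DLP_c + 2·DLP_p)/300 mm` from five pencil-chamber DLP readings |

Each metric is checked against a per-scanner baseline with pre-configured
tolerances: ±50 HU (CT numbers), ±1 mm (rod distances), ±0.5 mm (slice
thickness), ±10 points (uniformity), ±20 % of baseline (HWHM/HWTM, CNR,
noise).

See [docs/methods.md](docs/methods.md) for assumptions, numerical choices and
limitations.

## Worked example

Render a synthetic scan, record baselines, and re-run the QA routine against
them:

```bash
$ catphan-qa simulate demo --seed 7 --matrix-size 256 --pixel-size 0.9 --noise-sigma 8
wrote 43 slices to demo

$ catphan-qa baseline --scan demo --system demo-ct --results-dir qa_results
stored baselines for 'demo-ct' in qa_results/profiles/demo-ct.json

$ catphan-qa run --scan demo --system demo-ct --results-dir qa_results --no-plots
ct_number/air               -989.9314           [-1040, -939.9]  PASS
ct_number/pmp               -197.7157          [-247.7, -147.7]  PASS
ct_number/ldpe               -99.5631          [-149.6, -49.56]  PASS
ct_number/polystyrene        -33.7451           [-83.75, 16.25]  PASS
ct_number/air_2             -989.7745           [-1040, -939.8]  PASS
ct_number/acrylic            119.0784            [69.08, 169.1]  PASS
ct_number/delrin             335.8235            [285.8, 385.8]  PASS
ct_number/teflon             979.5196             [929.5, 1030]  PASS
rod_distance/1-2              49.9412            [48.94, 50.94]  PASS
rod_distance/2-3              49.9687            [48.97, 50.97]  PASS
rod_distance/3-4              49.9469            [48.95, 50.95]  PASS
rod_distance/4-1              49.9323            [48.93, 50.93]  PASS
rod_distance/1-3              70.6290            [69.63, 71.63]  PASS
rod_distance/2-4              70.6432            [69.64, 71.64]  PASS
uniformity/3                  -0.1056           [-10.11, 9.894]  PASS
uniformity/6                   0.3553           [-9.645, 10.36]  PASS
uniformity/9                   0.4583           [-9.542, 10.46]  PASS
uniformity/12                  0.5503            [-9.45, 10.55]  PASS
cnr/ldpe                      12.6292             [10.1, 15.16]  PASS
cnr_magnitude/ldpe            12.6292             [10.1, 15.16]  PASS
cnr/polystyrene                4.4459            [3.557, 5.335]  PASS
cnr_magnitude/polystyrene      4.4459            [3.557, 5.335]  PASS
cnr/delrin                   -32.5257          [-39.03, -26.02]  PASS
cnr_magnitude/delrin          32.5257            [26.02, 39.03]  PASS
mtf_hwhm                       0.2895          [0.2316, 0.3474]  PASS
mtf_hwtm                       0.5288           [0.423, 0.6346]  PASS
noise_nps                      7.9790            [6.383, 9.575]  PASS
noise_rois                     8.0416             [6.433, 9.65]  PASS
slice_thickness                2.8920            [2.392, 3.392]  PASS
29/29 checks passed
```

Exit code is 0 when all checks pass, 1 if any check fails, 2 on
loading/detection errors. Dose indices from chamber readings:

```bash
$ catphan-qa dose --central 120 --peripheral 95 100 105 98 --beam-width 10
CTDIw = 10.6333 mGy
```

The same workflow is available from Python:

```python
from catphanqa import SimulationConfig, render_scan, auto_baseline, run_qar

volume, truth = render_scan(SimulationConfig(rng_seed=7))
profile = auto_baseline(volume, system_id="demo-ct")
results = run_qar(volume, profile, out_dir="qa_results")
```

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

renders seeded synthetic scans and writes the headline quantities. With
`--seed 1` (8 s on one CPU) the script reports, among others:

| Quantity | Value |
|---|---|
| `dose_oracle_exact_agreements` | 100 / 100 |
| `max_ct_number_error_noiseless_hu` | 0.0 |
| `max_rod_distance_error_noiseless_mm` | 0.0 |
| `slice_thickness_measured_mm` | 2.852 (nominal 3.0) |
| `fitted_psf_sigma_mm` | 0.6213 (effective truth 0.6172) |
| `mtf_hwhm_cycles_per_mm` | 0.3015 |
| `noise_nps_hu` | 10.046 (truth 10.0) |
| `noise_rois_hu` | 9.984 (truth 10.0) |
| `nps_noise_estimate_white_10hu` | 9.999 (truth 10.0) |
| `qa_checks_passed` | 29 / 29 |

All randomness derives from `--seed`; re-running with the same seed
reproduces the JSON bit-for-bit. The full test suite
(`python -m pytest -q tests/`, 162 tests including the end-to-end acceptance
checks) runs in about 25 s.
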