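# dtialps

Simulation and analysis pipeline for the **DTI-ALPS index** — a
diffusion-MRI proxy for glymphatic (perivascular waste-clearance)
function — built around synthetic phantoms with exact ground truth.

The package is aimed at neuroimaging methodologists who want a fully
verifiable ALPS measurement chain: every stage, from the raw
diffusion-weighted signal to the cohort-level statistics, can be run on
synthetic data whose true answer is known analytically, so correctness is
established by parameter recovery rather than by eyeballing maps.

## The measurement

At the level of the lateral ventricle body, projection fibers run along
the image z-axis, association fibers along y, and the medullary
perivascular spaces along x — perpendicular to both tracts. Water mobility
along the perivascular space therefore shows up as x-axis diffusivity in
both tracts, and the ALPS index is

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

with each term the mean of a diagonal tensor element (image coordinates)
over a 5 mm disk ROI. The package provides:

* `dtialps.phantom` — a three-fiber-tract DWI phantom whose ground-truth
  ALPS index is set exactly by analytic inversion of the formula, plus a
  Stejskal–Tanner signal simulator with Rician noise;
* `dtialps.tensor` — log-linear least-squares tensor fitting, eigensystem,
  FA and directionally encoded color maps;
* `dtialps.alps` — deterministic ROI placement, per-axis diffusivity
  extraction, and the index;
* `dtialps.cohort` — a Gaussian-copula cohort generator with configurable
  group ALPS distributions and ALPS–covariate correlations;
* `dtialps.stats` — pooled t tests (raw or from printed mean ± SD),
  Pearson correlations, chi-square, and a cohort report;
* a `dtialps` command-line tool (`simulate`, `fit`, `alps`, `stats`,
  `run-experiment`).

## Worked example

```python
import dtialps as d

spec = d.PhantomSpec()                        # 48x48x24, three tracts
gtab = d.build_gradient_table(30, 1000, 1, seed=0)
field = d.make_phantom(spec, alps_true=1.45)  # exact ground truth
dwi = d.simulate_dwi(field, gtab, s0=1000, snr=30, seed=7)
m = d.run_subject_pipeline(dwi, phantom_spec=spec)
print(f"measured ALPS = {m.alps:.3f}")
print(f"Dxx_proj = {m.dxx_proj:.2e}  Dyy_proj = {m.dyy_proj:.2e}")
```

prints

```
measured ALPS = 1.431
Dxx_proj = 5.52e-04  Dyy_proj = 3.80e-04
```

i.e. a single noisy scan at SNR 30 recovers the built-in index 1.45 to
about 0.01–0.04 (noiseless simulation recovers it to machine precision).
A full cohort experiment — 42 patients and 50 controls with prescribed
group distributions and ALPS–age/duration correlations, imaged and
measured per subject, then analysed — is one call:

```python
from dtialps.io import default_run_config
subjects, report = d.run_experiment(default_run_config(), seed=1)
print(report.summary())
```

```
ALPS index (alps_measured): CAE 1.41 +/- 0.35 (n=42) vs HC 1.64 +/- 0.31 (n=50); t(90) = 3.43, p = 0.000926
ALPS vs age (CAE): r = 0.808 (n = 42), p = 9.95e-11
ALPS vs duration (CAE): r = -0.484 (n = 42), p = 0.00117
ALPS vs frequency (CAE): r = 0.017 (n = 42), p = 0.913
ALPS vs age (HC): r = 0.759 (n = 50), p = 1.74e-10
```

or, from a shell:

```
dtialps run-experiment --out-dir results/run1 --seed 1
```

which writes `cohort.csv`, `stats_report.csv`, `summary.txt` and a copy of
the configuration; outputs depend only on (config, seed).

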