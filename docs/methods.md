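# Methods

## The ALPS index and what the package computes

Diffusion along the perivascular space (the "ALPS" approach) quantifies
glymphatic function from an ordinary diffusion-tensor acquisition. At the
level of the lateral ventricle body, three white-matter systems are locally
orthogonal: projection fibers run inferior–superior (image z), association
fibers anterior–posterior (image y), and the medullary perivascular spaces
right–left (image x), perpendicular to both tracts. Water that moves freely
along the perivascular channels raises the x-axis diffusivity of both
tracts without affecting the diffusivities perpendicular to all three
structures. The index is

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where the four quantities are means of *diagonal tensor elements in image
coordinates* (not eigenvalues) over a 5 mm disk ROI in the projection and
association tracts of the left hemisphere. An index of 1 means no
preferential perivascular mobility; healthy values are well above 1.

The package implements that measurement end to end on synthetic data with
exact ground truth, so every stage is validated by parameter recovery:

1. **Phantom** (`dtialps.phantom`): three disjoint cuboid tracts with
   axis-aligned diagonal tensors in an isotropic background. Given a target
   index `a`, the shared perivascular diffusivity is solved analytically,
   `d_pv = a * (Dyy_proj + Dzz_assoc) / 2`, so the region-mean ground-truth
   index equals `a` to machine precision. Targets requiring
   `d_pv >= d_parallel` are rejected: the tract's principal axis would no
   longer be the fiber axis and the geometry premise would collapse.
2. **Signal** (`simulate_dwi`): mono-exponential Stejskal–Tanner model
   `S_i = S0 exp(-b_i g_i^T D g_i)`, optionally with Rician noise
   (magnitude of a complex Gaussian-noised signal, sigma = S0/SNR).
3. **Fit** (`dtialps.tensor`): ordinary log-linear least squares on the
   6-component design; exact on noiseless positive signals. Eigensystem,
   FA and the directionally encoded color map are derived from the fit.
4. **ROI and index** (`dtialps.alps`): deterministic ROI placement at the
   tract centroids, voxel-center-in-disk masking, arithmetic ROI means,
   and the ratio above.
5. **Cohort** (`dtialps.cohort`, `dtialps.stats`): a Gaussian-copula
   cohort generator and the case-control statistics battery (pooled t
   tests from raw data or summary statistics, Pearson correlations,
   Pearson chi-square).

## Acquisition and phantom defaults

| parameter | default | rationale |
|---|---|---|
| directions | 30 at b = 1000 s/mm², one b = 0 | standard single-shell clinical DTI protocol |
| direction scheme | Fibonacci half-sphere + seeded rotation | deterministic, approximately uniform, reproducible across platforms (vendor tables are not) |
| grid | 48 × 48 × 24 voxels | a reduced-FOV stand-in for a 128 × 128 × 45 acquisition; ~92 simulated subjects fit in about a minute of CPU |
| voxel size | 1.72 × 1.72 × 3 mm | 220 mm-FOV/128 in-plane resolution, 3 mm slices |
| d_parallel | 1.4e-3 mm²/s | typical coherent white-matter axial diffusivity |
| d_perp | 0.4e-3 mm²/s | typical radial diffusivity |
| background | 0.8e-3 mm²/s isotropic | gray-matter-like mean diffusivity |
| S0, SNR | 1000, 30 (Rician) | routine 3 T EPI magnitude data |
| ROI | 5 mm disk, single axial slice | disk-on-a-slice mirrors manual ROI drawing on an axial color-FA map; slice thickness is carried by the single-slice convention |

With these values the index headroom is `d_parallel / d_perp = 3.5`; any
target in roughly (0.05, 3.4) is representable, which comfortably covers
both group distributions.

Tensors are axis-aligned by construction (no rotation is simulated)
because the index consumes diffusivities along image axes directly; the
rotation consistency of the simulator/fitter pair is nevertheless tested
separately.

## Cohort generator

Group marginals and correlation targets default to the emulated study:
42 patients with index ~ N(1.45, 0.36) and 50 controls ~ N(1.66, 0.30);
ages ~ N(8.31, 2.12) and N(8.44, 1.94) years truncated to [4, 12] (the
typical onset range of childhood absence epilepsy); disease duration
~ N(10.71, 4.97) months and seizure frequency ~ N(7.71, 2.00) per day,
both truncated at 0; target correlations r(ALPS, age) = 0.766 (patients)
and 0.651 (controls), r(ALPS, duration) = -0.48, r(ALPS, frequency) = 0.

Sampling uses a Gaussian copula: normal scores with the target correlation
matrix (star-shaped — ALPS against each covariate, covariates mutually
independent; validated for joint positive semi-definiteness, which for the
star structure reduces to the sum of squared correlations being at most 1)
are mapped through the inverse CDF of each truncated-normal marginal. The
inverse-CDF construction was chosen over post-hoc clipping: it reproduces
the configured marginal exactly and puts no point mass at the bounds.
Because the inverse CDF is monotone and nearly linear under this mild
truncation, the realised Pearson correlations match the normal-score
targets to well under 0.01 (tested at n = 5000); no score-matrix
adjustment is applied.

Truncation makes the realised moments those of the *truncated* normal, not
the parent: e.g. the configured age marginal N(8.31, 2.12) on [4, 12] has
theoretical SD ≈ 1.79. Tests therefore compare empirical moments against
`scipy.stats.truncnorm` theory, not the parent parameters.

## Determinism and seeding

Every random stage (gradient-table rotation, cohort draws, Rician noise)
is driven by `numpy.random.SeedSequence`. The cohort uses children of
`SeedSequence(seed)`; per-subject noise streams use children of
`SeedSequence([seed, 1])`, a separate entropy domain, so truth draws and
noise realisations never share a stream. All outputs are bit-reproducible
under a fixed (config, seed) pair.

## Numerical choices

* Signals are clamped to `1e-6 * S0` before the log so noise-driven
  nonpositive magnitudes cannot produce NaNs.
* Negative eigenvalues after a noisy fit are clamped to zero and counted in
  the log rather than rejected, mirroring common DTI tooling and keeping
  the index computable.
* FA of the zero tensor is defined as 0 (the 0/0 convention).
* ROI voxel inclusion is "voxel center within radius, inclusive"; half-in
  voxels are excluded, and the center voxel is always kept so a mask is
  never empty.
* A perfect correlation reports the smallest positive float as its p-value
  so p stays in (0, 1].
* The 2×2 test is the Pearson chi-square with df = 1 and no continuity
  correction; it equals the squared two-proportion z statistic.

## What the synthetic data does and does not show

The phantom is artifact-free and single-compartment: no motion, no eddy
currents, no crossing fibers, no CSF partial volume, and the tracts are
perfectly axis-aligned with spatially constant tensors. Passing recovery
tests therefore demonstrates the *correctness of the measurement chain*
(simulation → fit → ROI → index → statistics) and its noise behaviour at
SNR 30 — not robustness to the confounds of in-vivo data, nor anything
about patients beyond what the generator was told. Real between-subject
imaging claims are represented only through the seeded-recovery surface:
the generator imposes the group means and correlation structure, and the
pipeline is checked for recovering them.

Recovery precision at the study's sample sizes is dominated by cohort
sampling, not measurement noise: per-subject measurement scatter at SNR 30
is ≈ 0.04 in index units (bias < 0.01), while the sampling standard error
of a group mean is ≈ 0.056 (n = 42) or 0.042 (n = 50). A single seeded
run of the group-mean recovery therefore lands within one standard error
of the configured mean only about 70–76% of the time; the correlation
recoveries at n = 42/50 behave analogously with the sampling error of r.

## Problem sizes used in tests and the acceptance run

Unit and property tests use a 24 × 24 × 12 phantom; end-to-end recovery
and the acceptance script use the full 48 × 48 × 24 default with 30
directions, 92 subjects per cohort draw (about 0.2 s per subject), and
n = 2000 truth-value cohorts for the large-sample correlation checks.

## Known limitations

* Single-shell, single-tensor only; no multi-compartment or kurtosis
  models.
* ROIs are placed from known phantom geometry; manual-ROI mode exists for
  external data but no registration or FA-guided placement is provided.
* The statistics mirror the emulated study design (no covariate
  adjustment, no multiple-comparison correction).
* Only left-hemisphere-style single tract pairs are modelled; no bilateral
  averaging.
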