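# Methods

`alpsfw` implements a complete diffusion-MRI analysis chain for two
glymphatic-proxy measures — the DTI-ALPS index and the white-matter free-water
(FW) fraction — together with the group-statistics layer used to compare a
noise-induced-hearing-loss (NIHL) cohort against healthy controls (HC), and a
synthetic-phantom generator that makes the whole chain testable without any
patient data.

## Forward model

Every voxel's diffusion-weighted signal follows the two-compartment
(bi-tensor) model

    S(b, g) = S0 [ (1 − f) · exp(−b gᵀ D g) + f · exp(−b · d_csf) ]

with `D` the tissue diffusion tensor (mm²/s), `f ∈ [0, 1]` the free-water
volume fraction, and `d_csf = 3.0 × 10⁻³ mm²/s` the diffusivity of free water
at body temperature (fixed, not estimated). Magnitude noise is Rician:
`|S + n₁ + i·n₂|` with `n₁, n₂ ~ N(0, σ)` and `σ = S0 / SNR`.

## Tensor fitting

`fit_tensor_wls` solves the log-linearized model `log S = log S0 − b gᵀ D g`
by ordinary least squares followed by one weighted pass with weights equal to
the squared predicted signals (the first-order optimal weights for
log-transformed data). On noiseless single-compartment signals the model is
exactly linear in the log, so recovery is at machine precision — this serves
as the module's oracle. Numerical guards: signals are clamped to
`10⁻⁶ · S0` before the log; fitted eigenvalues are clipped to a floor of
`10⁻⁶ mm²/s` (keeping downstream ratios finite) via an eigendecomposition
that is skipped whenever Gershgorin bounds already certify the spectrum.
FA and MD use the standard eigenvalue formulas; an all-zero tensor is
assigned FA = 0.

## DTI-ALPS

Four spherical ROIs (5 mm diameter; membership by center-distance ≤ radius,
which yields the deterministic 81-voxel sphere on a 1-mm grid) sample the
projection fibers (principal axis z) and association fibers (principal axis
y) of each hemisphere at the level of the lateral ventricles. On the full
182×218×182 1-mm template grid the published ROI centers are used verbatim,
interpreted as 0-based voxel indices; on phantom grids the centers are scaled
from the template pattern with a guaranteed minimum spacing so the spheres
stay disjoint. With ROI-mean components (mean first, then ratio — matching
how the index formulas compose):

    ALPS_left  = mean(Dxx_proj_L, Dxx_assoc_L) / mean(Dyy_proj_L, Dzz_assoc_L)
    ALPS_right = analogous
    ALPS_mean  = (4-component numerator mean) / (4-component denominator mean)

The mean index is the 4-over-4 ratio, *not* the average of the two sides (the
two differ on asymmetric data; a test asserts the distinction). Registration
estimation is out of scope: the pipeline accepts a known rigid/affine
transform, resamples components trilinearly and reorients tensors as
`D' = R D Rᵀ` with `R` the polar-decomposition rotation factor.

## Free-water mapping

`fit_bitensor` minimizes the voxelwise squared residual of the bi-tensor
model on the normalized signal plus a spatial smoothness penalty
`λ Σ‖∇f‖²` (default `λ = 0.1` on the normalized scale), by projected
gradient descent: analytic gradients in `(f, D/d_csf)`, a backtracking step
(so the total objective is non-increasing by construction — asserted in
tests), and a projection after every step that clamps `f` to `[0, 1]` and the
tissue eigenvalues to `[10⁻⁶, d_csf]`. Initialization:
`f₀ = clamp((MD_single − 0.6×10⁻³)/(d_csf − 0.6×10⁻³), 0.05, 0.95)` from the
single-tensor MD with a white-matter tissue prior of `0.6×10⁻³ mm²/s`; the
tissue tensor is initialized from a log-linear solve of the f₀-stripped
attenuation. Convergence: relative cost change below `10⁻⁶` or 200
iterations; non-converged voxels are flagged, and voxels whose tissue
compartment collapses onto free water (tissue MD within 5 % of `d_csf`) are
flagged degenerate because `f` is unidentifiable there.

**Single-shell caveat (important).** With one nonzero shell the per-voxel
problem is ill-posed: we measured the cost valley along the (f, D)
compensation direction to be ~10⁻⁸ deep on noiseless b = 0/1000 data,
versus a noise floor of ~5×10⁻² at SNR 30. Per-voxel `f` is therefore
driven almost entirely by the MD-based initialization, and between-subject
differences in `f` are attenuated (empirical slope ≈ 0.35–0.4 through the
full pipeline). Group differences keep their sign and ordering but shrink in
magnitude — exactly the behavior the end-to-end tests assert. Two-shell
synthetic data (b = 500/1000) makes the per-voxel problem well posed and is
used for sharp recovery tests (±0.01 against a dense grid-search oracle).

## Skeleton and FW projection

A simplified tract-skeleton dialect replaces the canonical
distance-transform search: candidates are voxels with group mean FA ≥ 0.2;
a candidate stays on the skeleton iff its mean FA is ≥ both neighbors along
the rounded local FA-gradient direction (perpendicular-maximum rule,
nearest-neighbor sampling). Plateaus (zero gradient or exact ties) are kept
and flagged degenerate rather than broken arbitrarily. Projection samples
each subject's FA at integer steps within ±3 voxels along the stored
direction and copies the FW value from the subject's FA maximum (ties prefer
the nearest sample, so aligned inputs are projected in place and the
operation is idempotent). One scalar per subject — the arithmetic mean FW
over the skeleton — feeds the group statistics. Tests rely on
construction-controlled ridge phantoms, not parity with any external
implementation.

## Group statistics

* Demographics: Shapiro-Wilk per group gates a pooled two-sample t-test
  (both p ≥ 0.05) versus Mann-Whitney U (midranks; exact enumeration for
  n₁+n₂ ≤ 12 without ties). A summary-statistics variant of the t-test
  reproduces printed table values from (mean, SD, n) triples.
* ANCOVA: `y ~ intercept + group + age + education` by least squares. The
  group coefficient β equals the adjusted (least-squares) mean difference
  evaluated at the whole-sample covariate means (asserted to 10⁻¹² on every
  fit); F = t² for the single-df term; partial eta squared
  `η²p = F·df₁/(F·df₁ + df₂)`; 95 % CI from t(df₂). Residual normality and
  homoscedasticity checks (Shapiro-Wilk, Levene with mean centering by
  default, median available) are recorded alongside.
* Correlations: Spearman (Pearson on midranks) with the t-approximation for
  two-sided p.
* Multiplicity: Benjamini-Hochberg step-up within two families — the four
  ANCOVA p-values, and the full 15-cell correlation grid (9 NIHL + 6 HC
  cells; MTWV is undefined for HC). These family definitions are the ones
  under which the published survival pattern is internally consistent.
  Censored "<0.001" entries are represented by any stand-in below 0.001; the
  rejection boundary in the 15-test family sits between 0.004 and 0.031, so
  the pattern is insensitive to the stand-in (tested).

All tests are two-sided at α = 0.05.

## Synthetic cohorts

The phantom is a piecewise-constant grid (default 48×48×12 voxels at 1 mm):
projection-fiber slabs (eigenvalues (1.4, 0.6, 0.4)×10⁻³ on axes z, x, y),
association-fiber slabs (same eigenvalues on axes y, x, z), and isotropic
background (0.8×10⁻³, free-water fraction 0.30 to emulate periventricular
CSF partial volume). The perivascular axis is x.

The cohort generator encodes the study conditions:

* 48 NIHL / 40 HC; covariates drawn with the observed group moments (age
  46.04 ± 7.18 vs 47.10 ± 8.05 y; education 11.60 ± 2.08 vs 12.45 ± 3.21 y;
  HAMA 6.42 ± 3.89 vs 3.60 ± 0.95; MTWV 43.45 ± 13.31 dB, truncated at the
  26 dB diagnostic floor; HC MTWV stored as missing-with-flag).
* Group-mean ALPS targets per hemisphere (HC 1.409/1.440, NIHL 1.331/1.374,
  i.e. means ≈ 1.423 vs 1.352) are hit by 1-D root-finding on the
  ground-truth Dxx scale, where the objective is the ALPS value a
  single-tensor fit of the clean two-compartment signal yields
  ("noiseless-implied" ALPS). The ledger records both this value — which a
  noiseless pipeline run reproduces to ≤10⁻⁶ relative error — and the raw
  tensor-ratio ground truth.
* The subject's Dxx multiplier applies inside boxes around the four ALPS ROI
  centers (the hemisphere-specific perivascular effect), while the
  white-matter FW offset (NIHL +0.018 over the HC 0.108) applies to the full
  fiber slabs. Keeping the Dxx effect local mirrors the fact that the index
  is an ROI measurement and prevents an artificial tissue-MD shift across
  the entire skeleton.
* A latent severity `s ~ N(0,1)` within NIHL couples the Dxx multiplier
  (−0.063 s), FW (+0.014 s), HAMA (+2.3 s) and MTWV (+6.5 s), with
  idiosyncratic SDs chosen so that, at large n, the ALPS/FW dispersions and
  the NIHL correlation magnitudes match the observed table values
  (Spearman ≈ −0.50 with FW, −0.43 with HAMA, −0.32 with MTWV). Controls
  carry no coupling; their weak negative ALPS-FW association emerges
  mechanically from free-water contamination of the single-tensor fit, as
  it plausibly does in vivo.
* Acquisition: 1 b0 + 50 directions at b = 1000 s/mm² from a deterministic
  Fibonacci spherical spiral (the scanner's proprietary direction set is
  unpublished); a two-shell override exists for well-posed FW tests.
  SNR 30 Rician noise by default; `snr=None` gives noiseless data.
* Reproducibility: per-subject parameter and noise streams are derived from
  the master seed with counter-based spawn keys, so identical seeds are
  bit-identical and adding a subject never perturbs the others.

What the generator does *not* emulate: scanner artifacts (motion, eddy
currents, Gibbs ringing, bias fields — their correction is out of scope),
anatomical heterogeneity within regions, crossing fibers, registration
error (phantoms are generated in template space; the pipeline applies
identity transforms), and partial-volume gradients at region borders.
Passing tests therefore demonstrate the correctness and calibration of the
estimators and statistics under the stated model, not robustness to real
acquisition artifacts.

## Problem sizes

Cohort-level tests and the acceptance script run the full 88-subject
pipeline on a 24×24×10 phantom grid with the free-water fit capped at 40
iterations — small enough for quick iteration while keeping every stage
(tensor fit, ALPS extraction, FW fit, skeletonization, statistics)
end-to-end real. The library defaults remain 48×48×12 and 200 iterations.
Sharp oracle tests (tensor recovery, two-shell FW recovery) use dedicated
small fixtures.

## Known limitations

* Single-shell FW magnitudes are initialization-dominated (see above);
  between-group FW differences are sign-faithful but attenuated.
* The skeleton dialect is not voxel-compatible with the canonical
  distance-transform implementation; only construction-controlled phantom
  behavior is guaranteed.
* The ANCOVA assumes homoscedastic Gaussian residuals; the report records
  the assumption checks but does not switch models automatically.
* Exact numeric parity with the original study's toolboxes is not claimed
  anywhere; the estimator choices (log-linear WLS, projected-gradient
  bi-tensor fit) are documented alternatives.
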