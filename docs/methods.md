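# Methods

This note documents the models implemented in `brainfuel`, the
assumptions behind them, the parameter defaults and why they were
chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results.

## Patlak graphical analysis

For a tracer with an effectively irreversible tissue compartment, the
ratio of tissue to plasma activity becomes linear in normalized time
θ(t) = ∫₀ᵗ Cp dτ / Cp(t) once the exchangeable pools have
equilibrated; the slope of that line is the net influx constant K. The
implementation:

- evaluates each frame at its **arithmetic midpoint** (standard for
  frame-averaged data);
- interpolates the sampled input function **linearly** and integrates
  it **trapezoidally**; points where Cp ≤ 0 are flagged undefined and
  excluded from fits rather than propagated;
- fits the retained (θ, ratio) points by least squares, either
  unweighted (default) or weighted by frame duration;
- requires ≥ 3 usable frames past `t_star` and positive spread in θ,
  raising `PatlakFitError` otherwise;
- **retains negative slope estimates** (flagged, never clamped) so
  that downstream group statistics remain unbiased.

`t_star` marks the start of the assumed-linear phase. Defaults: 10 min
for the 60-min FDG protocol (the conventional choice) and 3 min for the
10-min acetoacetate protocol (the short scan leaves only the late
frames once the fast bolus has cleared). Both are configuration
parameters because the linear-phase onset of real data depends on
kinetics that vary between tissues and subjects.

On noiseless irreversible two-tissue-compartment data
(K1 = 0.102, k2 = 0.13, k3 = 0.062 min⁻¹, FDG schedule), the estimate
at t* = 10 min lands within 0.9% of the closed-form
Ki = K1·k3/(k2+k3); sweeping t* from 5 to 20 min the estimates decrease
monotonically onto a late-window value offset ~1.3% below Ki. That
residual offset is a discretization effect of frame-averaged sampling
(frame means divided by midpoint plasma values), not an unconverged
transient; it is well inside the noise floor of real data.

### Metabolic rates

CMR = 100 · K · Cp / (LC · ρ) in µmol/100 g/min, with lumped constants
0.8 (glucose) and 1.0 (acetoacetate) and density ρ = 1 g/mL. As
commonly printed, the conversion omits the density/percent scaling; the
explicit 100/ρ factor here is a documented convention that lands the
result in µmol/100 g/min with mL ≡ g. `Cp` in this formula is the
**cold metabolite concentration** (µmol/mL plasma — mM for glucose and
acetoacetate), not the tracer activity; the two are deliberately
distinct fields of `PlasmaInputFunction` because conflating them is a
common source of unit errors.

## Partial-volume correction (Müller-Gärtner)

corrected(v) = (pet(v) − WMref · smooth(wm)(v)) / smooth(gm)(v), at
voxels with grey-matter probability ≥ `gm_threshold`; everything else
is NaN ("missing"), and so are retained voxels where the smoothed GM
map vanishes. CSF is assumed activity-free (the classic formulation).
Parameters:

- `fwhm` (mm, isotropic, default 6): scanner point-spread width,
  typical for whole-body TOF PET; kernel SD = fwhm/2.3548 per axis.
- `gm_threshold` (default 0.3): the usual mask cutoff for MG
  corrections; exposed because published workflows vary.
- `wm_reference`: `auto` estimates the white-matter activity as the
  mean PET value over deep WM — the wm ≥ 0.95 region eroded once with
  a ball of radius two kernel SDs (at least one voxel). Sizing the
  erosion to the PSF keeps the retained voxels beyond grey-matter
  spill-in; with a one-voxel erosion at 6-mm FWHM the estimate was
  biased ~10% high on phantoms, versus < 0.5% with the PSF-sized
  radius.

Convolution uses edge-value padding; phantom tests keep structures away
from grid edges, where padding would otherwise distort mass
conservation. On a 6-mm-blurred digital phantom the corrected GM mean
recovers the true GM activity to < 0.1% while the uncorrected mean is
~12% low, and the correction is strictly closer than no correction at
4, 6 and 8 mm.

The pipeline applies PVC to each dynamic frame before TAC extraction by
default (`pvc_before_tac`); correcting the parametric K image instead
is available because which order the original tool chain used is not
derivable from published descriptions.

## Longitudinal mixed models

Per region: outcome = β₀ + β₁·(age − mean age) + u_subject + ε with a
random intercept only — three visits at N ≤ 25 barely identify random
slopes. Estimation uses **REML** (statsmodels `MixedLM`); the slope
test refers β₁/SE to a **t distribution with n_subjects − 1 df** by
default. Both choices were calibrated empirically: over 900 simulated
null cohorts with the study's design (25/25/16 visits, between-subject
SD 0.006, residual SD 0.004 min⁻¹), REML with the t reference rejects
at 5.7% ± 0.8% at α = 0.05, whereas the normal (Wald) reference and ML
estimation each inflate the rate to ~6.5–7%. The normal reference
remains available (`inference="wald_normal"`), as does ML
(`reml=False`).

Robustness: the profiled likelihood of a random-intercept model can
have a singular Hessian at the optimum for unlucky samples (~7% of
null replicates at this design size). The fit is retried with
derivative-free optimizers (powell, Nelder–Mead, CG), which rescued
every such case in 900 replicates; the last-resort fallback is OLS with
by-subject cluster-robust standard errors, flagged `converged=False`.
Plain OLS was rejected as a fallback because it ignores within-subject
correlation and rejected at ~25% under the null on exactly the
pathological samples that trigger it.

The **pooled SEM** column of the regional report is
sqrt((τ̂² + σ̂²)/n̄), the model-based standard error of a visit mean
with n̄ the mean number of subjects per visit — a definition chosen
here since the original tables do not state theirs.

**FDR**: the 43 regions of one tracer form one Benjamini–Hochberg
family at q = 0.05; the two tracers are corrected separately, mirroring
their separate reporting. The report prints raw p-values plus the FDR
flag, since whether published tables show raw or adjusted values is
ambiguous. The FDR calibration study simulates per-region slope
estimates and their Wald p-values directly (null z ~ N(0,1), non-null
shifted) rather than refitting thousands of mixed models; this isolates
the step-up procedure, whose empirical FDR over 300 simulated
43-region families with 10 true effects is ~0.04 at q = 0.05.

## Associations

HOMA-IR = glucose (mM) · insulin (µU/mL) / 22.5. Cognitive composite
z-scores are the mean over a domain's tests of (scaled − 10)/3 — the
fixed population-norm conversion; the original normative tables are not
reproducible, so the scaled scores themselves are taken as given.
Correlations are Pearson r on per-subject averages across all available
visits (pairwise-complete for missing data, effective n reported), with
the two-sided t-test on n − 2 df. Since simple linear regression and
Pearson r are equivalent for the reported statistic, one operation
serves both and also emits slope and intercept.

## What the synthetic data emulate — and what they do not

The generator reproduces the *study conditions*: the two frame
schedules (12×10 s + 8×30 s + 1×4 min = 10 min; 12×10 s + 8×30 s +
6×4 min + 6×5 min = 60 min), irreversible-uptake glucose-tracer
kinetics and fast ketone-tracer kinetics, a 43-region parcellation, and
a three-visit cohort of 25/25/16 participants whose per-region baseline
means and annual slopes default to the bundled reference tables
(glucose and acetoacetate variants), with baseline age ~ N(70.9, 5)
truncated to [60, 85].

Deliberate idealizations, and hence what passing tests do *not* show
about real data:

- the **input function** is an analytic Feng-type curve
  ((A1·t − A2 − A3)e^(−λ1·t) + A2·e^(−λ2·t) + A3·e^(−λ3·t)), exact and
  noise-free; real studies calibrate plasma curves against discrete
  blood samples with their own error;
- **frame noise** is zero-mean Gaussian with SD ∝ value/√(frame
  duration) — the standard count-statistics heuristic — not a full
  Poisson/reconstruction noise model; all activities are assumed
  decay-corrected, so isotope decay is omitted;
- the **phantom** is an ellipsoidal shell with crisp (binary) tissue
  maps and Voronoi-parcellated grey matter; it has no gyral anatomy,
  no segmentation error, and no subject motion, so PVC results bound
  the method's best case. Region-to-region spill between adjacent GM
  regions is present and is the main residual error of the exemplar
  regional K tables (small regions recover worse than large ones);
- **dropout at year 4 is random** (seeded, nested), not informative;
- **covariate couplings** (insulin negatively, cognition positively
  tied to the subject-level uptake factor; ketones negatively tied to
  insulin) are single-latent-factor constructions that reproduce
  observed association *directions*, not their magnitudes;
- plasma levels, cognitive scaled scores and their dispersions are set
  to round, physiologically typical values (glucose 5.1 ± 0.5 mM,
  insulin ~5 ± 2 µU/mL, scaled scores ~10 ± 3 clipped to [1, 19]).

## Numerical choices

- Tissue curves solve dC1/dt = K1·Cp − (k2+k3)·C1, dC2/dt = k3·C1 with
  an integrating-factor scheme on a 0.0025-min grid whose knots include
  every frame boundary, chunked so the exponential growth factor stays
  well-conditioned; frame values are trapezoidal time-averages. Against
  an independent stiff ODE solve (LSODA, rtol 1e-9) the frame means
  agree to < 0.01%.
- The input-function amplitude A1 is solved in closed form from the
  stationarity condition Cp′(peak_time) = 0 (linear in A1), then all
  amplitudes are rescaled to hit the requested peak; the sampled curve
  is validated to be non-negative with a single maximum at the
  requested location.
- Headline decline percentages round half-away-from-zero to the
  nearest integer; annualized values divide by the 4-year follow-up
  and round to one decimal. These conventions reproduce printed ranges
  exactly and are fixed, not tunable.
- All tables are written with fixed float formatting (`%.6g`) and a
  config-hash header line, making repeated runs byte-identical.
- Study sizes used by the test-suite simulations (200 cohorts for
  slope recovery, 500 for type-I calibration, 300 families for FDR,
  900 for the inference calibration reported above, 15 cohorts for
  sign recovery across all 43 regions) were chosen to give Monte-Carlo
  standard errors comfortably below the margins being asserted.

## Known limitations

- No full nonlinear compartment fitting, no Logan (reversible-tracer)
  analysis, no image reconstruction, registration or motion
  correction; volumes are assumed voxel-aligned.
- PVC implements Müller-Gärtner only (no GTM or iterative
  deconvolution variants).
- Brain-volume change is segmentation-volume arithmetic
  (100·(V1−V0)/V0, atrophy = negative change); registration-based
  longitudinal streams are out of scope, so PBVC here is a
  methodological substitution for those tools.
- The exemplar voxel pipeline synthesizes one scan per tracer; the
  cohort statistics operate on regionally simulated rate constants,
  not on 66 full voxel-level scans — an explicit problem-size choice
  that leaves the statistical layer exercised at the study's actual
  design size.
- Which acetoacetate frames enter the Patlak fit in commercial
  pipelines is not standardized; `t_star` exposes the choice, and the
  10-min protocol tolerates larger estimation bias than the 60-min
  protocol (reported by the simulations, not asserted).
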