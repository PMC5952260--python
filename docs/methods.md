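# Methods

## Signal models

Two forward models are implemented, both evaluated in linear intensity
space (fits act on signal intensities, not log-signals):

- **IVIM**: `S(b) = S0 [ f e^(−b D*) + (1 − f) e^(−b D) ]`. Any overall TE
  weighting of a single-TE acquisition is absorbed into `S0`.
- **T2-IVIM**: `S(b, TE) = S0 [ f e^(−b D*) e^(−TE/T2p) +
  (1 − f) e^(−b D) e^(−TE/T2t) ]`, where `S0` is free of both diffusion and
  T2 weighting. The model assumes TR is long enough that T1 saturation is
  negligible, and ignores diffusion-time/gradient-profile effects and water
  exchange between compartments.

Units are fixed and never auto-detected: b in s mm⁻², `D`/`D*` in mm² s⁻¹,
TE and T2 in ms.

For fixed TE the T2-IVIM curve is *exactly* an IVIM curve whose fraction is
the apparent fraction
`f_app(TE) = f e^(−TE/T2p) / [f e^(−TE/T2p) + (1 − f) e^(−TE/T2t)]`
and whose scale is `S0 [f e^(−TE/T2p) + (1 − f) e^(−TE/T2t)]`. This identity
is the package's central oracle: a single-TE IVIM fit of noiseless two-
compartment-T2 data must return `f_app`, and with T2p > T2t the apparent
fraction rises monotonically with TE. `f_app` short-circuits at f ∈ {0, 1}
to avoid 0/0.

## Acquisition schemes

Schemes are ordered (b, TE, n_averages) tables; row order is the sole
mapping from 4-D volume frames to (b, TE), because image headers do not
carry per-frame TE reliably. Three liver protocols are built in: the full
6 × 5 exploratory grid (b 0–250 s mm⁻², TE 62–102 ms, 5 averages), the
clinical-style scheme (nine b-values 0–800 at TE 62 ms plus b ∈ {0, 10, 50}
at TE 80 and 100 ms, 12 averages, 15 rows), and its reduced variant that
drops (b=10, TE=80/100) and keeps six averages. Repeats may be stored
pre-averaged (one frame per row) or as individual frames; averaging is the
arithmetic mean of magnitudes.

## Fitting

**Initialization (segmented).** `D` comes from a log-linear fit to points
with b > 150 s mm⁻² (configurable), where the pseudo-diffusion term is
negligible (< e⁻² even for D* = 0.015 at b = 150, and usually ≪ that).
Back-projecting that line to b = 0 gives the tissue-only intercept; the
excess of the measured minimum-b signal over it, as a fraction, seeds `f`
(clamped to [0.01, 0.95]). `D*` has no data-driven seed and starts at 10 D.
For the six-parameter model, `T2t` is seeded by a log-linear fit of signal
vs TE at b = 50 s mm⁻², where the flow compartment is essentially
suppressed; on two-compartment data this seed is biased high by the
residual fast signal (tests bound the bias at 15% for liver-like
parameters). `T2p` has no initialization rule in the field; it starts at
2 × the `T2t` seed (clipped to bounds), refined by optimization and,
optionally, seeded multiplicative-jitter restarts (`FitConfig.n_starts`,
jitter drawn from a `FitConfig.seed`-keyed generator; best cost wins).

**Optimizer.** `scipy.optimize.least_squares` (trust-region reflective)
with box bounds: f ∈ [0, 1], D ∈ [1e-5, 5e-3], D* ∈ [5e-3, 0.5] mm² s⁻¹,
T2p, T2t ∈ [10, 1000] ms. The disjoint D/D* boxes enforce D* > D and remove
label-switching between the exponentials. The objective is unweighted
Gaussian least squares on intensities; no Rician-bias correction is applied
to the likelihood. Signals are normalized by their maximum before fitting
and `S0` rescaled afterwards — a pure conditioning device. Tolerances:
ftol = xtol = gtol = 1e-10, at most 500 iterations' worth of function
evaluations. Degenerate inputs (e.g. a flat series) fall back to a generic
start and report `converged` honestly rather than raising.

**Uncertainty.** Asymptotic standard errors from the Jacobian at the
optimum, `cov = (JᵀJ)⁻¹ · RSS/(n − p)` (pseudo-inverse for near-singular
JᵀJ); `FitResult.ci95` exposes the ±1.96 SE interval.

**Voxel-wise maps.** Each masked voxel of a 4-D volume is fitted
independently; failed or non-converged voxels become NaN and are counted,
never fatal — whole-liver ROIs legitimately contain vessels where the fit
is unstable. Output maps include `f·D*` (the compound perfusion-related
parameter) and, for the extended model, an apparent-`f` map evaluated at a
reference TE (default: the scheme's minimum).

## Phantom generator

The generator emulates a free-breathing multi-b/multi-TE liver acquisition
at the level of voxel signal statistics. Defaults are liver-parenchyma-like:
f = 0.18, D = 1.07e-3 mm² s⁻¹, D* = 0.15 mm² s⁻¹, T2p = 77.6 ms,
T2t = 42.1 ms, with vessel-like regions (default f = 0.6) and an optional
linear `f` ramp. Noise is Rician — the magnitude of two independent
Gaussian channels — because magnitude DWI at high b/TE sits on a positive
noise floor; Gaussian noise would allow negative signals and miss the
floor-induced bias. `n_averages` draws per scheme row are averaged in the
magnitude domain, as repeated magnitude images are in practice. SNR is
defined as `S0/σ` relative to the diffusion- and T2-free scale `S0`, so the
realized image SNR at (b = 0, minimum TE) is lower by the compartmental T2
weighting; the default SNR = 50 keeps signals in the exploratory-protocol
range well above the floor. Each voxel consumes an independent child stream
spawned from the spec seed, so adding a vessel never perturbs background
noise and results are bit-reproducible per seed.

What the phantom does **not** emulate: respiratory motion, partial-volume
mixing beyond binary vessel/background, EPI distortion, spatially
correlated (parallel-imaging) noise. Passing phantom tests therefore shows
correctness of the estimator under the stated noise model, not robustness
to scanner artefacts.

## Statistics

- `percent_error_f` = 100 (f_apparent − f_reference)/f_reference.
- `cohort_summary` = arithmetic mean and (n−1) standard deviation.
- `cov_repeated`: the geometric CoV for repeated measures. Values are
  natural-log transformed; the within-subject variance σ²_w is the mean
  over subjects of the per-subject sample variance of log values; then
  CoV(%) = 100 √(exp(σ²_w) − 1). The log-scale form is invariant to
  rescaling any subject's values by a positive constant and is the natural
  estimator when repeat measurements scatter multiplicatively. Balanced
  designs (equal visit counts ≥ 2, all values > 0) are required.
- `te_dependence_table`: per-TE single-TE IVIM `f`, the all-data T2-IVIM
  `f`, and the percent bias of the minimum-TE fit relative to it, laid out
  longest-TE-first. Failed cells become NaN rather than aborting the table.

ANOVA between visits/models is out of scope; only descriptive summaries
and the CoV are provided.

## Problem sizes and numerical choices in the test suite

Noiseless recovery is exercised with 50 random parameter draws per
protocol, sampled from identifiable physiologic sub-ranges of the fit box
(f ∈ [0.05, 0.5], D ∈ [0.3, 3]·10⁻³ mm² s⁻¹, D* ∈ [0.03, 0.3] mm² s⁻¹,
T2p ∈ [40, 300] ms, T2t ∈ [25, 80] ms). Draws spanning the *full* box are
deliberately avoided: at f → 0 the fast-compartment parameters are
unidentifiable, at D* ≈ D the bi-exponential collapses, and T2 near
1000 ms is flat over a 62–102 ms TE window — failures there reflect model
degeneracy, not estimator defects. The noisy-recovery experiment uses a
32 × 32 single-slice phantom with a two-voxel-wide vessel stripe, the
clinical scheme, SNR 40 and five seeds (≈ 5000 voxel fits, about half a
minute); medians over background voxels are compared with ground truth.
The Monte-Carlo CoV check uses 10 000 two-visit subjects with σ_w = 0.2.

## Known limitations

- `D*` is weakly determined at clinical SNR (its fit bounds span two
  decades); the package reports it but, like any IVIM tool, its voxel-wise
  values should be interpreted cautiously.
- The unweighted Gaussian objective ignores the Rician noise floor, which
  biases high-b/long-TE fits slightly at low SNR (visible as the ≈ +0.02
  median f offset in the SNR-40 phantom experiment).
- `f` and `T2p` are strongly covariant when the TE range is short; standard
  errors from the Jacobian reflect this but no reparameterization is
  attempted.
- Image registration, ROI drawing and scanner metadata parsing are out of
  scope; inputs are assumed aligned, with the scheme CSV as the frame map.
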