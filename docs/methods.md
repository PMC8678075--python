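# Methods

## Kinetic model

The voxel is modelled as three label pools in series. Label arrives through
the arterial input `c(t) = α·exp(−t/T1b)` for `ATT ≤ t < ATT + τ_eff`
(boxcar bolus of nominal width τ; `τ_eff = τ·(1 + bolus_extension_frac)`
when an artificial extension is used to soften the no-partial-delivery
structure of Hadamard TIs). A cohort arriving in the voxel at time `u`

1. sits in the arterial tree (`s_bl1`) until its intra-voxel transit time
   ITT elapses, decaying with blood T1;
2. then occupies the capillary pool (`s_bl2`) with weight
   `r_blex = exp(−t_x/Texch)` and the extravascular pool (`s_ex`) with
   weight `1 − r_blex`, decaying with blood and tissue T1 respectively.

All times are milliseconds; perfusion `f` (ml/100 g/min) is converted to
s⁻¹ by /6000 at the model boundary, and the signal is scaled by `2·M0·f·α`.
The two-compartment model is the exact `ITT = 0` restriction; the two
implementations share one code path, so their equivalence at `ITT = 0` is
structural, not numerical.

### Exchange-clock conventions

The exchange elapsed time `t_x` for a cohort arriving at `u` is a genuinely
open convention and both variants ship:

- `exchange_clock="voxel_arrival"` (default): `t_x = TI − u` — exchange
  accrues from voxel entry, i.e. during the intra-voxel transit as well.
  This is the extended model exactly as its equations are written, and it is
  the convention under which the worked-example numbers (two-compartment
  Texch ≈ 249 ms for a true 150 ms) are produced.
- `exchange_clock="capillary_arrival"`: `t_x = TI − u − ITT` — exchange
  starts only at the capillary, consistent with exchange-free arterioles.
  Under this variant the two-compartment model overestimates Texch for the
  whole grid with an identity-line offset close to the simulated ITT, and
  its perfusion estimate is biased high on average; the sensitivity tests
  document both behaviours.

The two conventions make distinct, testable predictions for the
two-compartment bias; the default follows the extended-model equations as
written and produces the worked-example values, while the capillary variant
is exercised as a sensitivity analysis.

### Echo-time decay

At readout the excitation is local to the voxel, so only label already in
the voxel contributes. The three components decay over TE with blood T2
(`s_bl1`, `s_bl2`) and tissue T2 (`s_ex`). With
`exchange_during_te = True`, capillary spins may still exchange during the
echo: the staying fraction decays as `exp(−TE/T2b)·exp(−TE/Texch)` and the
transferred fraction carries blood T2 before and tissue T2 after the
transfer (closed-form two-exponential convolution; when `T2b = T2t` the
split becomes invisible, which the tests verify). The default is
`exchange_during_te = False` — each spin keeps the T2 of the compartment it
occupied at excitation — the convention under which the package
produces its reference worked-example values; the on-variant is retained and shifts
the two-compartment estimate upward by roughly 25 %.

### Numerics

Because the input is a boxcar and all relaxation/exchange kernels are
mono-exponential, every delivery integral has an exact piecewise
antiderivative with breakpoints at `{ATT, ATT+ITT, ATT+τ_eff, ATT+ITT+τ_eff,
TI}`. The implementation evaluates these closed forms with exponents
combined before exponentiation (numerically stable down to Texch = 10 ms)
and `expm1`-based forms near vanishing rate differences. The test suite
checks them against an independent brute-force 1 ms discrete-time label
bookkeeping simulator to < 0.5 % over a parameter grid, and against exact
limits (no-exchange, full-delivery, equal-T2) analytically.

## Default constants

3 T literature values, all overridable from a YAML/JSON `constants:` block:
T1 blood 1650 ms, T1 tissue 1330 ms, T2 blood 150 ms, T2 tissue 90 ms,
partition coefficient λ = 0.9 ml/g, labelling efficiency α = 0.85.

## Acquisition and encoding

`TI_k = PLD + k·SBD` (k = 1…order−1); the decoded bolus width per TI equals
the sub-bolus duration. The Hadamard matrix is Sylvester-type with the
constant column dropped (+1 = control, −1 = label; any valid scheme can be
supplied). The earliest-played sub-bolus has the longest TI; per-frame
(TI, TE) metadata is always stored explicitly, in milliseconds, in a JSON
sidecar next to the NIfTI volume — frames are never interpreted by position
alone. Decoding is the orthogonal linear inverse; white per-frame noise
variance is multiplied by 4/order (verified by Monte-Carlo).

The six printed TIs of the first study protocol follow the arithmetic
`200 + 400·k` (600…3000 ms); the second protocol gives 1600/2600/3600 ms.

## Synthetic experiments

The default phantom spans ATT 500–2,500 ms (axis 0) × Texch 10–1,000 ms
(axis 1) linearly, with ITT fixed at 200 ms or spanning 100–500 ms across
slices, perfusion fixed at 60 ml/100 g/min and unit M0. Generation is
noise-free by default — the error-surface studies are deterministic — and
an SNR option adds white Gaussian noise with per-frame
σ = (mean positive noise-free signal)/SNR, seeded and reproducible. The
simulator shares the kinetic closed forms exactly (asserted in tests).

What the phantom does **not** emulate: partial-volume mixtures, dispersion
beyond the fractional bolus extension, motion, physiological noise,
background-suppression efficiency, or spatial correlation. Passing the
recovery tests therefore demonstrates correctness of the estimator under the
model's own assumptions, not in-vivo accuracy.

## Voxel-wise estimation

Bounded MAP by trust-region nonlinear least squares (`scipy`'s `trf`): the
residual vector stacks the frame misfit scaled by a per-voxel noise σ with
Gaussian prior pull-backs, so the summed squares equal twice the negative
log posterior. Priors: f ~ N(50, 50²) ml/100 g/min, ATT ~ N(1300, 600²) ms,
Texch ~ N(300, 300²) ms, ITT ~ N(250, 200²) ms; bounds f ∈ [0, 500],
ATT ∈ [100, 3500], Texch ∈ [10, 2000], ITT ∈ [0, 1000].

- **Noise scale.** σ starts at 5 % of the data RMS, is re-estimated from the
  residual RMS of the best candidate and the fit repeated once; on
  noise-free data σ → 0 and the priors vanish, making recovery unbiased.
- **Multi-start.** Deterministic grid of initial points
  f ∈ {30, 60} × ATT ∈ {400, 700, 1500} × Texch ∈ {100, 400} × ITT ∈ {0, 300}
  (ITT axis dropped for the two-compartment model). The 400 ms ATT start is
  required: the objective has a kink where ATT crosses the first TI and
  trust-region steps from above stall on it. All starts are screened at
  loose tolerance and the three leading candidates are polished at full
  tolerance (ftol 1e-8, xtol 1e-10, ≤ 2000 function evaluations); ties break
  toward the smaller Texch.
- **Amplitude convention.** The labelling efficiency is not identifiable per
  voxel, so fits run with α = 1 and the model is referred internally to the
  data's own scale (it is linear in f·M0); the raw fitted amplitude
  therefore carries `α·M0·f`. `quantify_cbf` divides it out:
  `CBF = f_raw·λ/(α·M0_tissue)` with the M0 image understood as the
  tissue-equivalent equilibrium magnetization (λ × arterial M0), which makes
  simulator data round-trip exactly.
- **Model comparison.** Laplace approximation around the MAP point with the
  Gauss–Newton Hessian of the stacked weighted residuals. The reported free
  energy is the negative log evidence (lower = better); the Occam component
  (prior penalty + ½ log det H − (d/2) log 2π) is exposed separately, since
  on uninformative data the net evidence of an unconstrained extra dimension
  is close to free while its complexity term is strictly positive.
- **Degenerate inputs.** All-zero voxels return a flagged non-fit rather
  than raising; optimizer failure is reported as `converged = False`; maps
  mark unfit voxels with a sentinel (−10⁶), never silent zeros.

Volume fits are embarrassingly parallel (joblib); results are independent of
worker count and execution order.

## Post-processing and statistics

Post-hoc smoothing is a normalized masked Gaussian convolution with per-axis
FWHM = factor × voxel size (default factor 2; σ = FWHM/2.3548); sentinel and
out-of-mask voxels are excluded and mean preservation on constant fields is
tested. Probabilistic masks threshold at 0.5 by default.

Test-retest metrics operate on per-subject session means: ICC(2,1)
(two-way, absolute agreement, single measure; switchable to consistency
form), reported as computed even when negative; within-subject CoV
`100·sqrt(Σd²/2n)/grand mean` (a mean-of-per-subject-CV variant is
available); Bland–Altman mean difference ± 1.96 SD. Back-to-back repeats are
averaged on the *encoded* series before decoding. The bootstrap interval for
the wsCoV resamples subjects and is formed on the log scale by the basic
(reflected-percentile) construction at level 0.99: for a right-skewed
positive scale statistic at n ≈ 10, the plain 95 % percentile interval is
badly anti-conservative, and this construction is the one whose observed
coverage meets the suite's ≥ 90 % check.

## Problem sizes

The shipped studies run at desk scale by choice: the worked example uses a
31-TI × 8-TE noise-free curve (seconds), the error-surface study a
20 × 20 × 1 grid with three ITT variants (minutes on one CPU), and the
reliability study 10 subjects × 2 sessions × 200 Monte-Carlo replicates.
Grid sizes are parameters everywhere and can be raised freely.

## Known limitations

- The two-compartment bias pattern depends on the exchange-clock
  convention (overestimation magnitude, identity-line offset, perfusion
  bias sign); the dependence is documented in the sensitivity tests rather
  than hidden in a tuned default.
- Under the default (printed-equation) clock, the two-compartment perfusion
  estimate is *not* systematically inflated on the full parameter grid (the
  bias is slightly negative at very fast exchange and late arrival); the
  positive perfusion bias appears under the capillary-arrival variant.
- The estimator is MAP + Laplace, not full variational Bayes or MCMC: the
  evidence surrogate is asymptotic and per-parameter SDs are local
  curvatures.
- No dispersion kernels beyond the fractional bolus extension, no
  partial-volume or macrovascular modelling, no spatial regularization
  (smoothing is post hoc, matching the processing pipeline it emulates).
- ATT is only weakly identified between adjacent TIs when the bolus exactly
  abuts them (no partial delivery); the optional ~15 % bolus extension
  mitigates but does not remove this.
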