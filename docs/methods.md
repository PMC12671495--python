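# Methods

`psiikin` analyzes chlorophyll-fluorescence kinetics of Photosystem II
(PSII) antenna mutants: fluorescence induction under DCMU, PAM
quench/yield decomposition, xanthophyll-cycle kinetics, photoinhibition
decay, and ECS light-saturation.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
generator does and does not emulate.

## Connected-units induction model

Excitonic connectivity between PSII units makes variable fluorescence V a
hyperbolic function of the closed-center fraction C:

    V(C) = (1 − p) C / (1 − p C),      p = J/(1 + J),

where p is the inter-unit transfer probability and J the connectivity
parameter.  J = 0 recovers independent units (V = C, exponential
induction); J ≈ 2 gives the strongly sigmoidal rise typical of wild-type
leaves.  We expose both parameterizations (J and p) because the
literature uses either curvature parameter for the same hyperbola; the
magnitudes recovered for wild-type material (J ≈ 2) are consistent with
J = p/(1 − p).

Under DCMU, closure is a single photochemical turnover:

    dC/dt = k_ph (1 − C)/(1 − p C),     C(0) = 0,

with k_ph (s⁻¹) proportional to optical cross-section × irradiance.  The
closure ODE has the implicit solution k_ph·t = pC − (1−p)·ln(1−C), which
is inverted per time point by vectorized guarded bisection on [0, 1): the
left side is strictly increasing and convex, so 80 halvings bracket C far
below 1e-14 with no convergence failures possible for valid inputs.  A
property test keeps this closed-form path within 1e-6 of a brute-force
high-order ODE integration.

**Fitting.** `fit_dcmu_induction` estimates (J, k_ph, F0, Fv) by
Levenberg–Marquardt least squares (lmfit).  Initialization is derived
from the curve itself: F0/Fm from the trace extremes, J from the
initial-slope/max-slope sigmoidicity ratio (1 for an exponential, smaller
for sigmoidal curves), and k_ph from the observed two-thirds time.
Bounds: J ∈ [0, 10], rates > 0.  Starting values are kept strictly inside
bounds; MINPACK's `leastsq` can stall when a parameter starts pinned on a
bound transform.  A fitted-Fm shortfall (trace max < F0 + 0.95·Fv) raises
a "truncated induction" warning rather than an error.

The instrument-style fit arguments sometimes quoted for this model (a
baseline term and a PSII quantum-yield factor) are absorbed into F0 and
k_ph respectively; they are not separately estimable from a single curve.

**Antenna size.** t_2/3 is the earliest time at which the normalized rise
crosses 2/3, linearly interpolated between bracketing samples (earliest
crossing on ties); 1/t_2/3 is the classical functional-antenna-size
measure.  The wild-type preset is calibrated so that 1/t_2/3 =
5.76 s⁻¹ (= 5.76 × 10⁻³ ms⁻¹) exactly.

**Cross-section rescaling.**  For the normalized DCMU curve the
complementary area ∫(1 − V) dt equals 1/k_ph *exactly and independently
of J* (substituting dt from the closure ODE reduces the integrand to
dC/k_ph).  Equalizing complementary areas between a test and a reference
curve therefore rescales time by exactly k_test/k_ref, the relative
optical cross-section.  This equal-area criterion is primary; the ratio
of times at the V = 0.6 crossing is reported as a diagnostic only,
because the two criteria disagree slightly when the curves' J differ — in
that case a shape-discrepancy score (max |ΔV| after rescaling, threshold
0.05) is flagged but the factor is still returned.  Finite traces
truncate the area integral; traces used for rescaling should extend to
k_ph·t ≳ 10 (the generator's 6-s grids keep the truncation error well
below 1%).

## No-DCMU rise and the PQ pool

Without DCMU the rise mainly reflects reduction of the plastoquinone (PQ)
pool.  We use a deliberately minimal two-pool model:

    dC/dt = k_ph (1 − C)/(1 − p C) − k_ox C q,
    dq/dt = − k_ox C q / n_pq,               q(0) = 1,

with q the oxidized-PQ fraction, n_pq the pool size in electron
equivalents per active reaction center, and k_ox the Q_A⁻ → PQ
reoxidation rate.  No PSI re-oxidation, no domain heterogeneity.  In the
pool-limited regime the time to any fixed V level scales as n_pq/k_ph, so
the slowdown of a mutant rise relative to a reference, multiplied by the
cross-section ratio, estimates the PQ-per-RC fold change.  Defaults
n_pq = 12 (≈6 PQ molecules/RC) and k_ox = 150 s⁻¹ are literature-scale
choices; the asymptotic slowdown for a preset encoding a 6-fold pool at
1.9-fold cross-section is 6/1.9 ≈ 3.16, emerging as ≈3.14 at these
defaults (the published estimate for this comparison is ≈3.2, within the
model's reach only asymptotically).  Alongside the raw product
σ_ratio × slowdown, a rounded-convention product (slowdown rounded
half-to-even to an integer first) mirrors how such fold-changes are
usually quoted.

## PAM quenching and yield partition

Level extraction (robust to ±50 ms pulse-timing jitter): F0 = median of
the pre-actinic baseline excluding pulse windows; Fm = max within the
first (dark-adapted) pulse window; per pulse Fm′ = max within
[t−0.5 s, t+1 s] and Fs = median of [t−1.5 s, t−0.5 s].  NPQ uses the
Stern–Volmer form (Fm − Fm′)/Fm′.  Yields default to the simple
complementary partition Φ_II = (Fm′−Fs)/Fm′, Φ_NPQ = Fs/Fm′ − Fs/Fm,
Φ_NO = Fs/Fm, which sums to 1 identically; the lake-model variant is
available behind `lake_model=True`.  F0′, when not measured, uses the
Oxborough–Baker estimate F0/(Fv/Fm + F0/Fm′).  Fm′ excursions ≤2% above
Fm are warned about, not rejected (measurement noise).

qE/qI are split operationally: npq_max at the last pulse of the first
light period, qI at the final pulse of the following dark window,
qE = npq_max − qI.  With an 8-min dark window and a ~1-min qE relaxation
time this endpoint split recovers the fast component to <0.1%;
single-exponential unmixing of the dark relaxation is available as
`method="unmix"`.  NPQ definite integrals are raw trapezoids over the
stated window; baseline subtraction is off by default and exposed as a
flag, since published integrals do not state the convention.

## Xanthophyll cycle

V ⇄ A ⇄ Z is a first-order sequential chain with light-gated forward
rates (k_vd, k_az off in darkness) and a common reverse epoxidation rate
k_ep that is always active.  Within each constant-light segment the
propagator is the matrix exponential of the rate matrix, whose columns
sum to zero — pool conservation is therefore exact to machine precision
(<1e-12 is asserted).  DI = (Z + 0.5·A)/(V+A+Z) by default (A counts
half, one of two rings de-epoxidized); `formula="z_only"` preserves the
stricter reading.  Rate fitting runs in log-space (positivity without
active bounds) against the normalized fractions.

Preset rates: k_ep = 4e-4 s⁻¹ (≈30 min epoxidation half-time) and k_az
(3e-3 s⁻¹ wild-type-like; 6e-3 s⁻¹ for the antenna-less line, whose
lipid-phase violaxanthin converts faster) were fixed a priori; k_vd was
then calibrated once per preset so the de-epoxidation index at the end of
the 8-min light phase equals the published steady states (0.30 wild-type
and trimer-less lines, 0.50 antenna-less), and frozen.

## Photoinhibition

Fv/Fm decline under photoinhibitory treatment (550 µmol photons m⁻² s⁻¹,
4 °C emulated) is a single exponential toward a plateau,
y(t) = y_p + (y_i − y_p)e^(−kt); biphasic fits are out of scope.
t_half = ln2/k is defined on the init→plateau span, making it invariant
to the plateau choice ("halfway to zero" is computable from the fit if
preferred).  A nonparametric halfway-crossing time is reported as a
cross-check; on noiseless long courses the two agree within a sampling
interval.  Mutant presets encode published half-times (1.4 h / 1.9 h /
1.1 h) with plateau 0; the wild-type rate is set so the 6-h endpoint is
80% of the initial 0.82 (implying t_half ≈ 18.6 h).  Chl-photobleaching
courses reuse the identical fit.

## ECS / pmf saturation

The ECS_t amplitude vs irradiance is fitted with a rectangular hyperbola
amp_max·I/(I + I_half) (exponential saturation behind a flag, with its
half-saturation reported on the same scale).  The fit is
scale-equivariant, so relative amp_max values across genotypes are
meaningful regardless of instrument units.  Presets: I_half = 100 µmol
photons m⁻² s⁻¹ for every genotype; amp_max relative 1.0/0.80/0.65
(wild type / trimer-less / antenna-less).

## Synthetic generator and what passing tests show

The generator produces every pipeline input from the genotype presets
(WT, npq4, NoM, koLHCII, koLhcb, lowLHCII).  Published values are encoded
as preset fields with per-field provenance strings; unconstrained
parameters are tagged `assumed` (notably the NPQ rise/relaxation time
constants τ_fast = 30 s, τ_slow = 180 s, τ_relax = 60 s, known only
graphically, and excluded from recovery targets).  The antenna-less
line's qE/qI amplitudes (0.45/0.15) were calibrated once so its maximal
NPQ is 22% of wild type, encoding the published relative amplitude.

Generator and analyzers share no code paths: generation integrates
explicit ODEs (`solve_ivp`, tight tolerances) and inline formulas,
whereas analysis inverts implicit closed forms, uses matrix exponentials,
and fits by least squares.  An architectural test enforces that no
analysis module imports the generator.  Noise is multiplicative Gaussian
clipped at zero (fluorescence noise scales with signal), fully seeded.

Default problem sizes: DCMU induction 0–2 s at 1 ms (6 s grids for
area-based rescaling); no-DCMU rises at 2 ms out to 4·n_pq/k_ph; PAM
sessions sampled at 0.5 s with 0.6-s saturating pulses — the two-period
NPQ protocol is 1-min dark baseline + 2 × (8 min light at 1000 µmol +
8 min dark), pulses every 30 s; the light-response session steps through
9 intensities (25–1000 µmol, 120 s each); pigment courses sampled every
30 s; Fv/Fm courses every 15 min over 6 h; ECS curves at 8 irradiances
(25–1000 µmol).

What the generator does **not** emulate: instrument detector response and
single-turnover flash photophysics, OJIP intermediate steps, PSI
cross-talk/spill-over, state transitions (qT), domain-heterogeneous PQ
diffusion, and actinic-spectrum effects.  Recovery tests therefore
demonstrate correctness and identifiability of the analysis chain under
the stated models — not robustness to real-instrument artifacts beyond
the jitter and multiplicative-noise cases covered explicitly.

## Degenerate inputs and tie-breaks

Non-monotone time bases, negative fluorescence, empty xanthophyll pools
and overlapping actinic segments are rejected at container construction
with the first offending row named.  Level crossings use the earliest
crossing; traces that never cross raise.  All-dark pigment courses are
rejected as under-determined.  Non-declining Fv/Fm courses raise ("no
photoinhibition signal").  Non-saturating dose-response data fit but
warn.
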