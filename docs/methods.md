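# Methods

`acodopt` analyzes a nine-run Taguchi screening campaign for anaerobic
codigestion of oil-refinery wastewater (ORWW) with chicken manure, and
models biogas production from digestion kinetics with a small neural
network. This note records the models, the defaults that matter, and the
choices made where the design was genuinely open.

## The screening design

Four three-level process factors — ORWW portion in the digester (A: 33, 44,
55 %), temperature (B: 36, 46, 56 °C), sonication pretreatment time (C: 15,
30, 0 min) and total-solids level (D: 6, 11, 18 %) — are screened with an
L9(3⁴) orthogonal array instead of the 3⁴ = 81-run full factorial. Level
order is the assignment order, **not** sorted: C3 is the 0-min untreated
control. The row order of the array is fixed to the campaign's run
numbering, because the factor-effect tables only line up with the published
analysis under that run→level mapping. Balance (each level three times per
column) and pairwise orthogonality (all nine ordered level pairs once per
column pair) are validated by exhaustive counting.

## Responses and signal-to-noise analysis

Three larger-the-better responses are tracked per run: biogas yield
(BGP, mL/gVS), biomethane yield (BMP, mL/gVS), and the soluble-COD
stabilization rate (%), defined as 100·(CODs,i − CODs,f)/CODs,i. The COD
rate can legitimately be negative (net accumulation of hydrolyzed organics
in an inhibited digester); negative values are preserved everywhere except
in explicit display clipping.

The per-run quality statistic is the larger-the-better S/N ratio

    S/N = −10·log10( (1/n) Σᵢ 1/yᵢ² )   [dB].

Because y enters squared, a negative response scores like its absolute
value: an inhibited digester with −263 % COD removal gets the *best* COD
S/N of the campaign. This is the literal convention of the original
analysis and is reproduced by default, but it is treated as a hazard: a
`NegativeResponseWarning` is always emitted, and `negative_policy`
(`literal` | `exclude` | `floor`) lets a user opt out.

When only replicate summaries (mean m, sd s) are available, the S/N is
reconstructed with the second-moment approximation

    S/N ≈ 20·log10(m) − 10·log10(1 + 3(s/m)²),

obtained by expanding E[1/y²] around the mean. It is accurate to about
±0.02 dB for CV ≤ 12 % and is the documented reconstruction path; it is
*not* reliable for |s/m| large or m < 0, which is why the shipped per-run
S/N table (computed from the original triplicates) is the input of record
for the factor-effects analysis.

Factor effects are level means of per-run S/N (exact for main effects under
the balanced array); factors are ranked by the range of their level means,
ties broken by factor order A<B<C<D, and the per-response optimum is the
per-factor argmax level (ties toward the lowest index). Report-facing dB
values are rounded half-up to 2 decimals; all internal computation is full
precision.

## Multiresponse optimization

The predictive surrogate over the 81-point grid is a pure additive
main-effects model on raw run means: ŷ(f) = ȳ + Σ_F (m_F(l_f) − ȳ). Each
predicted response maps to a Derringer–Suich larger-is-better desirability
d = clip((y−L)/(U−L), 0, 1)^w, combined across responses by an
importance-weighted geometric mean (zero vetoes). Defaults: w = 1, equal
importances, bounds at the observed min/max of the run means — the choice
that makes D = 1 attainable at the best candidate. The ranking is
exhaustive over all 81 formulations with deterministic lexicographic
tie-break.

The surrogate reproduces the published gas-yield predictions at the
selected optimum to within 0.1 mL/gVS but **not** the published COD
prediction, which rests on an unpublished commercial-software model and a
different (unknown) treatment of the negative COD runs; the COD prediction
is therefore documented as out of reach rather than matched.

## Process chemistry

Free ammonia nitrogen (the unionized, inhibitory fraction) follows the
ammonium equilibrium FAN = TAN · (1 + 10^(pKa−pH))^(−1) with
pKa = 0.09018 + 2729.92/T (T in Kelvin). The published equation is typeset
ambiguously; this reading is the standard equilibrium form, is bounded by
TAN, is strictly increasing in pH and T, and yields the reported ≈8–10×
FAN increase for a pH step from 7 to 8 at mesophilic temperature (computed
ratio 9.04). No ionic-strength corrections are applied.

Inhibition diagnostics are threshold rules with configurable defaults:
FAN > 250 mg/L (mesophilic, TS ≥ 10 %), FAN > 700 mg/L (thermophilic),
acetate > 800 mg/L together with propionate:acetate > 1.4 (failure signal),
TVFA > 5000 mg/L (rapid accumulation), TVFA > 12000 mg/L (pH suppression),
and a TAN band of 1700–14000 mg/L reported as undesirable. The thresholds
come from heterogeneous literature and are regime-dependent, hence config,
not code. TAN = 0 is read as "no substrate yet" and exempted from the band
note, so an all-zero record raises no flags.

## Synthetic experiment generator

The raw time series of the original campaign are unpublished, so the
package ships a generator with known ground truth. Per run, cumulative
biogas follows the modified Gompertz form
B(t) = P·exp(−exp(e·Rm/P·(λ−t)+1)); the plateau P is the run's true BGP
mean from an additive main-effect profile, the maximum rate is a
temperature-dependent fraction of P (0.07/0.10/0.13 d⁻¹ by B level), and
the lag depends on sonication (4/2.5/6 d; untreated longest). Digestion
stops once a day's production falls below 1 % of the prior cumulative
total, capped at 60 d.

Replicate noise is multiplicative lognormal (mean-preserving) for the
positive-scale gas yields, additive Gaussian for the COD rate so inhibited
runs cross zero. Default CVs (BGP 0.05, BMP 0.08, COD sd 12 points) sit in
the spread of the campaign's printed replicate summaries (CV ≈ 0.002–0.19).
Kinetic trajectories are phenomenological: TAN rises saturating to a
plateau that grows with solids, temperature and manure share; FAN is always
derived through the equilibrium (so FAN ≤ TAN holds by construction); runs
whose true COD removal is negative accumulate TVFA monotonically with a
propionate-dominated acid profile (ratio 1.5), others show a peak-and-decay
VFA transient. The default true-mean profiles are calibrated to the
campaign's observed run means (constants in `data/calibration.yaml`, not in
code); `planted_config(signal_noise)` instead plants clean orthogonal
effects with optimum A2B1C2D1 and a chosen effect-size-to-noise ratio.

What the generator does **not** emulate: mechanistic digestion (no ADM1,
no stoichiometry), inter-replicate kinetic variation, correlated noise
across responses, or measurement drift. Passing end-to-end tests therefore
demonstrates correctness of the *analysis machinery* under controlled
truth, not predictive validity on real digesters.

The ANN table samples each run's kinetics every other day starting at day
1 — at day 0 no ammonia has been released and same-temperature runs would
present identical inputs with different targets. Target observation noise
defaults to CV 0.02 for biogas yield and 0.05 for methane content,
mirroring the qualitative finding that yield is the easier target; the
asymmetry is a tested, controllable property.

## Neural predictor

A 9-h-2 perceptron (tanh hidden, linear output, both outputs trained
jointly) maps TAN, FAN, TVFA, the four acids, temperature and pH to biogas
yield and methane content. Inputs and targets are affinely normalized to
[−1, 1] per variable on the training split. Training is full-batch
Levenberg–Marquardt: Δw = (JᵀJ + μI)⁻¹Jᵀe with the analytic residual
Jacobian (checked against central finite differences), μ₀ = 10⁻³, ×10 on a
rejected step, ×0.1 on an accepted one, μ_max = 10¹⁰. Data split 70/15/15
(floor counts, remainder to train first, seed-reproducible); early stopping
after 6 consecutive validation-MSE rises, returning the best-validation
weights; at most 1000 epochs; weights initialized uniform [−0.5, 0.5] under
the run seed. μ exhaustion after at least one accepted step is a normal
stop (the optimizer has converged); a convergence-failure error is raised
only if no damped step ever reduces the error.

The hidden width is chosen by training a candidate ladder (5–30 step 5,
then 16–19, plus 50), flagging any candidate whose validation or test MSE
exceeds κ = 10 times its training MSE as overfit, and taking the best
overall correlation among the rest. On the shipped candidate-metrics table
this rule selects 19 and flags the 30- and 50-neuron runs. The original
campaign's dataset being unpublished, the network's published fit metrics
are not reproduction targets; the trainer is validated on generator data
(noiseless linear target converges below 10⁻³ MSE within 100 epochs;
zero-noise Gompertz data reach test R² ≥ 0.99 for biogas yield with h = 15
at daily sampling, ~190 samples).

## Problem sizes and numerics

Default test/verification sizes: 9 runs × 3 replicates for the Taguchi
path; ~100–200 kinetics rows for the network; 100 seeded repetitions for
the planted-optimum recovery rate (recovered 100/100 at effect size 3× the
replicate sd); 500 random tables for the level-mean oracle sweep. Linear
solves use `numpy.linalg.solve` on the damped normal equations; the
undamped step is cross-checked against `lstsq`. Degenerate inputs are
errors, not silent fixes: zero measurements in S/N, nonpositive means in
the moment path, empty series in diagnostics, fewer than 10 rows in the
splitter.

## Known limitations

- The S/N moment path cannot recover per-run S/N for high-CV or negative
  summaries; the exact path needs replicate-level data.
- The desirability surrogate is main-effects only; interactions alias into
  the estimates exactly as in any saturated L9 analysis.
- The LM trainer is full-batch and dense (Jacobian n·2 × p); it is meant
  for hundreds of samples and tens of hidden units, not large datasets.
- Diagnostics are literature threshold rules, not a calibrated classifier.
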