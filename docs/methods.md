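# Methods

## Problem setting

In vitro transcription (IVT) synthesizes mRNA from a linear DNA template
using T7 RNA polymerase, NTPs as substrate, Mg²⁺ as cofactor and several
auxiliary components (inorganic pyrophosphatase, spermidine, DTT, RNase
inhibitor) under controlled pH, temperature and reaction time. Measured
yield (g mRNA per L of reaction) is an expensive, noisy black box of 12
parameters; the package optimizes it with batch Bayesian optimization and
ships a calibrated emulator so the loop can be run and validated in silico.

## Search space and encoding

The default space has 12 parameters: one categorical (cofactor salt,
MgAcetate vs MgCl₂), six integers (RNase inhibitor 0–2000 U/mL, DNA template
10–100 nM, PPase 0–10 U/mL, T7 RNAP 1000–50000 U/mL, temperature 20–50 °C,
time 10–300 min) and five reals (cofactor 0–100 mM, DTT 0–10 mM, NTPs
1–10 mM, spermidine 0–10 mM, pH 6.5–8). Yield is the objective, stored as a
real number, not a 13th parameter.

All kernel work happens in a 13-dimensional unit cube: numeric parameters
min–max scaled (their raw ranges span four orders of magnitude, so a shared
length-scale prior is meaningless unscaled), the categorical one-hot with an
independent ARD length scale per level. Integers are relaxed to continuous
values during acquisition search and rounded at decode time; decode∘encode
is the identity on valid conditions.

## Initial design

Latin hypercube sampling with n strata per dimension, uniform placement
within each stratum (not centered), independent stratum permutations per
dimension. Categorical levels are cycled then shuffled, extending the
equal-probability idea to labels. The stratification guarantee holds on the
latent continuous design; rounding necessarily merges strata for integer
parameters whose range is narrower than n (e.g. PPase 0–10 with n = 16 —
a pigeonhole fact, not an implementation defect). A uniform-random design is
available as a baseline; at n = 16 in 12 dimensions the two behave similarly.

## Gaussian-process surrogate

ARD Matérn 5/2 kernel (twice-differentiable sample paths; the squared
exponential is unrealistically smooth for reaction surfaces), constant mean
c in g/L, observation noise σ_n². Yields are fit in raw g/L rather than
standardized so EI values and all reports stay in measurement units.
Hyperparameters are point estimates maximizing the log marginal likelihood:
L-BFGS in log-space with analytic gradients, 8 restarts drawn from
ℓ_d ∈ [0.05, 5], σ_f² ∈ [0.1, 10]·var(y), σ_n² ∈ [10⁻⁴, 1]·var(y), plus one
deterministic unit-length-scale start. A jitter of 10⁻⁸·σ_f² keeps the Gram
factor positive definite; the hard noise floor is 10⁻⁶.

**Replicate-informed noise floor.** With a single replicate per condition,
marginal-likelihood maximization reliably drives σ_n² → 0 and the GP
interpolates measurement noise as structure; the resulting overconfidence
collapses EI exploration (observed directly: cold-started campaigns stalled
under 6 g/L). IVT replicate SDs are known to be a few tenths of a g/L
(0.2–1.0 in the reference data), so the loop floors σ_n at the recorded
replicate SD of the log, defaulting to 0.5 g/L. The floor is an explicit
argument (`noise_floor_sd`) threaded through `fit_surrogate`/`step`; bare
`gp.fit` keeps the tiny default floor for users who want unconstrained ML-II.

## Acquisition and batches

Expected improvement over the best observed yield f_max, in its standard
maximization form EI = (μ−f_max)Φ(z) + sφ(z); at s = 0 it degenerates to
max(0, μ−f_max). Batches of 3–5: member 1 is the EI maximizer over a pool of
20 000 LHS candidates plus 2 000 local perturbations around the incumbent,
refined by three shrinking-radius zoom rounds (σ = 0.1, 0.04, 0.015 around
the running top-40 candidates) so the maximizer is located finer than pool
spacing. Members 2…k are random draws from base-pool points with
EI ≥ 0.5·max EI, subject to pairwise encoded distance ≥ 0.05, falling back
to next-best-EI points when the diverse set is exhausted. Diversity draws
deliberately come from the global pool only — drawing them from the zoomed
neighbourhood collapses batch spread and measurably hurts optimization. The
0.5 EI fraction and 0.05 distance are fixed, auditable constants. No
constant-liar fantasizing between batch members; the model sees only real
measurements.

## The optimization loop

Seed with 16 LHS conditions, then repeat: refit the GP on the full log,
propose a batch (default 4), measure, append. The experiment log is
append-only and round-trips through a fixed-header CSV. Stopping: total
budget (default 150 evaluations) or a plateau — best-so-far improved by less
than ε = 0.5 g/L (≈ replicate SD) over the last 30 evaluations. Replicates
enter the GP as individual rows; `replicate_sd` is carried as metadata.
The loop is bit-reproducible given (seed, configuration).

## Explanations

Shapley sampling values: for each sampled feature permutation a background
log entry is drawn; features enter in permutation order with absent features
imputed from the background row, and φ_j is the mean marginal contribution
of parameter j. Permutations are antithetic (forward + reversed, same
background row) for variance reduction; default 256 permutations; a
Monte-Carlo standard error accompanies each effect. Features are the 12 raw
reaction parameters — the categorical cofactor is imputed at label level,
never per one-hot column — and attributions explain the GP posterior mean of
the final refit model only. The background set is the full experiment log.

## Surrogate comparison

Leave-one-out cross-validation: each model trains on n−1 log entries and is
scored by absolute error on the held-out one, every observation held out
exactly once, replicated conditions kept as distinct points. Random forest
and gradient boosting are sklearn regressors behind the same fit/predict
factory contract; the GP is the in-repo model. Output is the paired
per-point error table plus median/IQR — no significance testing.

## The IVT simulator

A calibrated emulator, not a mechanistic kinetic model. Noise-free yield is
multiplicative over per-parameter unimodal responses in (0, 1]:

    yield(c) = Y_max · Π_j f_j(x_j) · g(t),   g(t) = 1 − e^(−kt)

with saturating Hill responses for monotone helpers (DTT, NTPs, DNA, PPase),
asymmetric generalized-Gaussian bells for windowed optima (cofactor
concentration, spermidine, T7 on log₁₀ scale, temperature with a flat-top
p = 6 bell, pH) and a near-flat response for the RNase inhibitor. The
cofactor salt couples to concentration: MgCl₂ shifts the usable window down
relative to MgAcetate (acetate tolerates higher Mg²⁺) with a 3 % amplitude
penalty. Each factor has a fixed floor (0.2–0.6) so no single mid-impact
parameter zeroes the reaction. There are no other interactions — the minimal
structure consistent with the anchor data, a modeling convenience rather
than a biological claim.

The shared rate k = ln(5)/120 min⁻¹ makes every reaction reach exactly 80 %
of its plateau at 120 min. Kinetic profiles use plateau
Y_kin(c) = kin_scale · Y_max Π f_j, with kin_scale calibrated so the best
reference reaction passes through 10.65 g/L at 120 min (plateau
13.31 g/L = 10.65/0.80); the endpoint surface and the kinetics experiment are
anchored to slightly inconsistent published values (12.18 g/L at 121 min vs
10.65 at 120 min), a discrepancy treated as replicate/measurement variation.
dsRNA mass fraction is 0 until ~115 min, then ramps as
ρ_∞(1 − e^(−(t−115)/40)) with ρ_∞ chosen so the ratio is exactly 0.05 mg/mg
at 300 min. Templates longer than 2000 bp get a linear amplitude attenuation
and a linear post-peak decline whose two rates follow in closed form from
the published 5299 bp anchors (9.7 g/L at 145 min, 7.1 g/L at 300 min);
the 1195 and 1864 bp templates are unaffected. Measurements add Gaussian
noise (default SD 0.5 g/L, the replicate scale of the reference data)
truncated at zero, deterministic per (seed, call index).

**Calibration.** The 24 free shape parameters are fit to the seven reference
reactions by SD-weighted least squares with a weak prior pull toward the
initial guesses. Bound constraints keep each factor's optimum inside its
reported window: cofactor 40–60 mM, spermidine 1–3 mM, T7 6000–8000 U/mL,
temperature 37–44 °C, pH 6.5–7.2, pH bell widths ≤ 0.8 (yields fall off
meaningfully above pH 7.5), and Y_max ∈ [14, 17] g/L — the campaign
converged, so the reachable ceiling sits just above the best observed
endpoint plateau (~15.2 g/L). The fit reproduces all seven yields to within
0.01 g/L (requirement: within each printed replicate SD; hard failure above
the mean replicate SD of 0.686 g/L). The result ships as a frozen JSON
fixture (`ivtbo/data/sim_params.json`); recalibration from scratch
reproduces it to within 0.05 g/L at the anchors.

## What the simulator does and does not show

Passing the in-silico loop demonstrates that the optimizer recovers
>10.7 g/L conditions within 60 evaluations on a surface that honors the
published anchors, windows and noise scale (median over seeds ~11.7–11.8 vs
~5.6–5.9 for random search). It does not demonstrate performance on real
IVT chemistry: the emulator has no parameter interactions beyond the
cofactor coupling, no batch effects, no drift, and homoscedastic noise.
Two further limitations are worth naming. First, random conditions on the
multiplicative surface are mostly low-yield (median ~0.6 g/L), likely
harsher than reality; some seeds therefore stall below the headline yield
and the headline claim holds in the median, not per run. Second, the
benchmark anchor (pH 8.0 yielding 7.64 g/L — 63 % of the best reaction)
upper-bounds how punishing the pH response can be in a multiplicative
model, so Shapley attributions rank pH mid-field (5th–7th of 12) rather
than top-ranked as wet-lab campaigns report; the qualitative test asserts
substantial pH influence rather than a top-4 rank.

## Numerical choices

Gram jitter 10⁻⁸·σ_f²; noise floor 10⁻⁶ (g/L)²; EI treated as exactly 0 when
s = 0 and μ ≤ f_max; importance ranking ties broken by parameter order;
categorical decode by block argmax (first label wins exact ties); integer
decode round-half-even then clipped. Kinetic queries outside [0, 300] min
are rejected rather than extrapolated. All loop randomness flows from a
single integer seed; GP refits inside the loop use seed + 1000·cycle.

## Problem sizes used in validation

Desk-scale throughout: closed-loop replication uses ten 60-evaluation
campaigns with 20k-candidate pools (~2 s per campaign); the surrogate
comparison and explanation checks run on 40–150-point logs; exact-Shapley
oracles enumerate up to 2⁴ coalitions on 4-feature toys; GP oracles use
dense solves on ≤ 20 points.
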