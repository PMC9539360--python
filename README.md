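# ivtbo — Bayesian optimization of mRNA in vitro transcription

`ivtbo` is a closed-loop experiment-design toolkit for maximizing mRNA yield
in cell-free in vitro transcription (IVT) reactions. IVT — the reaction at the
heart of mRNA vaccine manufacturing — depends on a dozen interacting
parameters (Mg²⁺ cofactor salt and concentration, NTPs, DNA template, T7 RNA
polymerase and pyrophosphatase activities, spermidine, DTT, RNase inhibitor,
pH, temperature, reaction time), far too many for factorial designs. The
package treats measured yield *y(x)* (g·L⁻¹) as an expensive black box over a
bounded mixed space and drives the classic Bayesian-optimization cycle:

1. **Seed** — a Latin hypercube design of 16 reaction conditions (one sample
   per equal-probability stratum in every dimension).
2. **Model** — a Gaussian-process surrogate with an ARD Matérn 5/2 kernel
   k(x,x′) = σ_f² (1 + √5 r + 5/3 r²) e^(−√5 r), r² = Σ_d (x_d−x′_d)²/ℓ_d²,
   constant mean, hyperparameters by multi-start maximization of the log
   marginal likelihood.
3. **Propose** — a batch of 3–5 conditions from expected improvement
   EI(x) = (μ−f_max)Φ(z) + sΦ′(z), z = (μ−f_max)/s: one EI maximizer plus
   diversity draws from the high-EI region.
4. **Measure, append, repeat** until the evaluation budget or a plateau rule
   stops the loop.

Around the loop it provides Shapley-sampling attributions of the surrogate
(which parameters drive predicted yield), a leave-one-out harness comparing
the GP against random-forest and gradient-boosting surrogates, and a
**calibrated synthetic IVT simulator** so the whole workflow runs and is
validated entirely in silico: the simulator reproduces seven published
reference reactions (six optimized conditions and a patent-derived benchmark),
the reported optimal parameter windows, first-order production kinetics that
reach 80 % of plateau at 2 h, the dsRNA by-product ratio, and the yield
decline seen with long (5.3 kb) DNA templates.

Intended users: bioprocess engineers exploring reaction optimization
strategies, and methods researchers who need a reproducible benchmark of
batch Bayesian optimization on a realistic mixed-variable response surface.

## Worked example

```python
from ivtbo import Simulator, run_closed_loop, best_so_far_trace

sim = Simulator(seed=1)                      # bundled calibrated IVT emulator
log = run_closed_loop(sim.measure_fn(),      # noisy yield measurements
                      budget=60, batch_size=4, n_init=16, seed=1)
best = log.best
print(f"best measured  {best.yield_gL:.2f} g/L")
print(f"noise-free     {sim.yield_mean(best.conditions):.2f} g/L")
print(best.conditions.values)
```

prints

```
best measured  13.05 g/L
noise-free     13.13 g/L
{'cofactor': 'MgAcetate', 'cofactor_mM': 48.63, 'DTT_mM': 6.18,
 'RNaseInh_UmL': 2000, 'NTPs_mM': 8.86, 'DNA_nM': 62, 'PPase_UmL': 10,
 'spermidine_mM': 3.81, 'T7_UmL': 7245, 'temperature_C': 45,
 'time_min': 291, 'pH': 6.9}
```

Sixty simulated reactions (16 LHS + 11 EI batches of 4) locate conditions in
the known good region — magnesium acetate near 50 mM, T7 RNAP ~7000 U·mL⁻¹,
mildly acidic pH — with a noise-free yield of 13.1 g·L⁻¹ against a reaction
ceiling of ~15–16 g·L⁻¹ and a benchmark reaction at 7.6 g·L⁻¹. Run-to-run
spread is real: across seeds 0–9 the median best noise-free yield is
11.8 g·L⁻¹, versus 5.9 g·L⁻¹ for random search at the same budget.

The same loop is available from the shell:

```bash
ivtbo run-sim --budget 60 --batch 4 --seed 1 --out experiments.csv
ivtbo status --log experiments.csv          # best-so-far trace + stop rule
ivtbo suggest --log experiments.csv --batch 4 --seed 2 --out next.csv
ivtbo explain --log experiments.csv --out shap.csv
ivtbo compare-surrogates --log experiments.csv --out loo.csv
```

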