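# commtrial

Bayesian adaptive design simulation for two-arm clinical trials with a
**community of priors** — skeptical, enthusiastic, and noninformative
viewpoints wired into different stopping rules of the same trial.

## The problem

Pediatric trials face ethical limits on sample size and slow accrual, yet a
new pediatric indication usually arrives after the same drug was approved in
adults, so strong prior information exists. A community-of-priors adaptive
design exploits both facts: it stops a trial **early for success** only when
even a *skeptical* prior (centered at no effect) is convinced, and **early for
futility** only when even an *enthusiastic* prior (centered at the historical
adult effect) has given up. Either way, fewer children stay on an uninformative
or harmful protocol, while the frequentist operating characteristics — one-sided
type I error, power — remain controlled.

`commtrial` is for trial statisticians who want to simulate, compare, and
calibrate such designs from Python.

## The model

Responses are continuous with a shared residual variance:

    y_di | θ_d, σ²  ~  N(θ_d, σ²),        d = control, treatment
    θ_d             ~  N(μ_d, v_d²)
    σ²              ~  Scaled-inv-χ²(σ_n, σ_μ²),   defaults σ_n = 1, σ_μ = 0.07

Each prior viewpoint is a pair of independent per-arm normals whose implied
difference prior is N(0, 0.5²) (skeptical), N(0.20, 0.10²) (enthusiastic), or
N(0, 100²) (noninformative). Monitoring is by the posterior probability of
superiority `Pr(θ_t > θ_c | data)`, computed exactly (to quadrature error) by
integrating the conjugate normal-CDF term over the σ² marginal posterior; a
Rao-Blackwellized Gibbs sampler is available as an independent cross-check.

Stopping uses constant (Haybittle–Peto-style) thresholds: early success above
0.998, early futility below 0.70, late success above 0.975, late futility
below 0.85. Six named designs are shipped — a fixed design, four Bayesian
adaptive variants differing in which prior backs which rule, and a frequentist
group-sequential comparator using one-sided pooled t-test p-values at the
corresponding levels (0.002 / 0.3 / 0.025 / 0.15).

Virtual trials enroll up to 256 subjects by a Poisson process (2/week),
randomize 1:1, and observe each endpoint 12 weeks after randomization.
Interims are scheduled by subject counts (e.g. every 37 subjects for 6 looks);
operating characteristics are estimated over thousands of replicates.

## A worked example

```python
from commtrial import (build_interim_schedule, design_preset, run_many,
                       scenario_preset, summarize)

spec = design_preset("design3")          # skeptical success / enthusiastic futility
schedule = build_interim_schedule(6)     # looks at 37/74/110/146/183/220 subjects
for label, meaning in (("null", "type I error"), ("target", "power")):
    rep = summarize(run_many(spec, scenario_preset(label),
                             schedule=schedule, n_sims=2000, seed=42))
    print(label, f"success {rep.total_success*100:.2f}% ({meaning}),",
          f"futility {rep.total_futility*100:.2f}%, mean N {rep.mean_n:.0f}")
```

prints

```
null   total success  2.20% (type I error), futility 90.85%, mean N 115, mean duration 60 wk
target total success 97.70% (power), futility  2.30%, mean N 115, mean duration 58 wk
```

Under the null the design almost always stops for futility (90.9%) and
declares success only 2.2% of the time — inside the one-sided 2.5% budget.
Under the target difference of 0.05 it finds the effect 97.7% of the time
while enrolling 115 subjects on average instead of the 256 maximum.

The `examples/` directory walks through each capability: building the prior
community, posterior monitoring at an interim, a single trial trace, operating
characteristics, a design-comparison grid, and boundary calibration. A thin
CLI mirrors the library (`commtrial simulate|grid|calibrate|presets`).

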