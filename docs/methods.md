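# Methods

## Model and monitoring quantity

Subject responses follow a two-arm normal model with a shared residual
variance: `y_di ~ N(θ_d, σ²)` with independent arm-mean priors
`θ_d ~ N(μ_d, v_d²)` and `σ² ~ Scaled-inv-χ²(σ_n, σ_μ²)`. Every decision rule
monitors `Pr(θ_t > θ_c | data)` under one of three prior communities imposed
on the treatment-minus-control difference:

| community      | per-arm priors                         | implied difference prior |
|----------------|----------------------------------------|--------------------------|
| skeptical      | both arms N(0, 0.3536²)                | N(0, 0.5²)               |
| enthusiastic   | control N(0, 0.0707²), trt N(0.2, 0.0707²) | N(0.20, 0.10²)       |
| noninformative | both arms N(0, 70.71²)                 | N(0, 100²)               |

Per-arm SDs are stored as the printed four-figure values rather than the exact
`sd/√2`, so difference-scale checks reproduce the published rounded arithmetic
(0.3536² + 0.3536² = 0.5001², within 0.03%); `make_community(...,
exact_split=True)` gives the exact split. Prior informativeness is quantified
by the variance-ratio effective sample size `σ²_data / σ²_prior`, about 0.04
subjects for the skeptical prior and 1 for the enthusiastic one — both
deliberately far below the trial's data weight.

The residual-variance prior defaults to weight `σ_n = 1` pseudo-observation at
central SD `σ_μ = 0.07`, the value that keeps the type I error near the
nominal 2.5% for this endpoint scale; the weight is the knob that strengthens
or weakens it.

## Posterior computation

Given σ² the model is conjugate, so

    Pr(θ_t > θ_c | data, σ²) = Φ( (m_t(σ²) − m_c(σ²)) / √(s_t²(σ²) + s_c²(σ²)) ),

with `m_d, s_d²` the usual precision-weighted normal updates. The marginal
probability is this quantity integrated against `p(σ² | data)`, which is known
in closed form up to normalization once θ is integrated out analytically
(`ȳ_d | σ² ~ N(μ_d, v_d² + σ²/n_d)` plus the within-arm SSE term).

The default estimator evaluates that one-dimensional integral by trapezoid
quadrature on a per-dataset log-spaced σ² grid (160 nodes, bracketed by wide
inverse-gamma quantiles of the conditional posteriors at the sample and prior
means). It is deterministic, independent of how many trials are evaluated in a
batch, vectorizes across tens of thousands of interim datasets, and its error
(~1e-6) is negligible at the 0.998 boundary. A Rao-Blackwellized Gibbs sampler
(alternating `θ | σ²` and `σ² | θ`, averaging the Φ term over σ² draws; 4,500
iterations with 500 burn-in by default) implements the same posterior by an
independent algorithm family; the test suite holds the two routes to within
0.002 of each other (observed agreement ~1e-4) and checks the conjugate
known-variance limit. A known-variance plug-in estimator (pooled sample SD)
completes the set. Only sufficient statistics `(n, mean, SSE)` per arm enter
any estimator.

Interim analyses with fewer than two observed outcomes in either arm leave the
probability undefined; the monitoring layer treats such looks as no-decision
and records them as skipped.

The frequentist comparator uses the pooled-variance (not Welch) one-sided
two-sample t-test, matching the single-σ² model the trials are simulated
under.

## Designs and stopping rules

Thresholds are constant across interim looks (Haybittle–Peto convention):
early success when the success-prior probability exceeds `s_e = 0.998`, early
futility when the futility-prior probability drops below `f_e = 0.70`; at the
final analysis `s_l = 0.975` and `f_l = 0.85`, with anything in between
inconclusive. `s_l = 0.975` is applied to all Bayesian designs, matching the
flat-prior correspondence with a one-sided p < 0.025 final test. When both
early rules could fire (possible only with contradictory priors), success is
evaluated first. The frequentist group-sequential design maps each rule to the
corresponding p-value threshold (`p < 1 − s_e`, `p > 1 − f_e`, `p < 0.025`,
`p > 0.15`).

The fixed design carries no early rules; its final analysis reuses design 3's
late rules (skeptical success, enthusiastic futility) so that the no-interim
reference answers the same question the adaptive designs do.

Boundary calibration simulates one set of null-scenario traces and replays
every candidate boundary pair against them (common random numbers), returning
the least stringent pair whose total success rate is ≤ α, ties broken toward
the lower early threshold (higher power). Futility boundaries are excluded
from the search because futility stopping can only reduce false positives.

## Trial simulation

Accrual is a homogeneous Poisson process (mean 2 subjects/week; a
deterministic option exists for variance-reduction checks), randomization is
an independent fair coin per subject (a permuted-block option exists), and
each endpoint is observed 12 weeks after randomization. No dropout process is
modeled. Maximum enrollment is 256; interim schedules are stored verbatim for
the tabulated 0–18-look configurations at max N 256 and otherwise generated by
even spacing `round(i·N/(k+1))` (which differs from the tabulated 6-look row
by one subject at two looks).

**Interim data semantics.** A look scheduled at count k fires, by default,
when the k-th *endpoint is observed* and analyzes exactly those k outcomes
(`interim_data="completed"`); subjects enrolled during the 12-week pipeline
still count toward the enrolled total if the trial stops. The alternative
(`"concurrent"`) fires when the k-th subject *enrolls* and analyzes only
complete cases. The source study does not state which convention its
simulation software applied; we measured both against its published rates and
adopted `completed` as the default because it reproduces the published
futility behavior (early futility < 3% at the target difference, futility
> 86% under the null, 100% early futility under harm, type I < 2.5%) where
`concurrent` gives ~6% early futility at the target difference. The price is
an early-success rate at the target difference of ~97.5% versus the published
93.8% — early looks see more data under this convention, so the success rule
has more power. Both semantics are first-class configuration.

Every trial is simulated to full accrual and the monitoring quantities under
*all* priors a design references are recorded at every look; stopping rules
are applied afterward to the completed traces. This mirrors the
dual-prior-join workflow of the original study, makes design comparisons on
identical streams exact (common random numbers are the default in grids, off
for headline single-design runs), and turns calibration into post-processing.
Early-stopped trials report the calendar time of the triggering look as their
duration — no pipeline follow-up is added, since the decision is made then —
and the enrolled count at that time as their sample size; completed trials
report `last enrollment + 12` weeks and 256 subjects.

Trial i of a run draws from a generator seeded by the pair `(seed, i)`, so any
replicate is reproducible in isolation; Gibbs randomness (when that estimator
is selected) is seeded per (look, prior) so traces do not depend on evaluation
order. With the default quadrature estimator entire runs are bit-reproducible
from the single run seed.

## What the generator does and does not emulate

The simulator reproduces the study conditions exactly as specified: true
differences in {−0.05, 0, 0.02, 0.05, 0.08} with per-arm SD 0.07, Poisson
accrual, constant visit delay, 1:1 allocation, no dropout, no drift. Real
trials add features deliberately out of scope here — dropout and missed
visits, accrual seasonality, covariate imbalance, endpoint non-normality, and
operational interim delays. Passing tests therefore demonstrate correctness of
the design machinery and its operating characteristics *under the stated
model*, not robustness of any particular trial to violations of it.

## Numerical choices and degenerate inputs

- Quadrature: 160 log-spaced σ² nodes, trapezoid weights, per-dataset bounds
  at inverse-gamma quantiles 1e-11 widened ×4; halving the grid changes
  probabilities by < 1e-5.
- Gibbs: 4,500 total iterations, 500 burn-in; replicate-seed spread < 0.001
  near the success boundary (batch-means check in the tests).
- Zero-variance data reject the t-test explicitly; empty arms are legal only
  for the known-variance estimator, which then returns the prior probability.
- Boundary comparisons are strict inequalities (`>` success, `<` futility), so
  a probability exactly at a threshold continues.
- Schedules collapse duplicate look counts; a look count at or above max N is
  rejected at construction.

## Problem sizes

Headline runs use 10,000 replicates per configuration (Monte-Carlo SE ≤ 0.5
percentage points for the reported rates), the same scale as the source study;
unit and property tests use 25–2,000 replicates chosen so each check's
Monte-Carlo error is small against its assertion margin. The full reproduction
script covers ten 10,000-replicate configurations in about a minute on one
CPU, which is what the vectorized quadrature posterior buys.

## Known limitations

- Neither interim-data convention reproduces every published rate at once;
  see the semantics discussion above for the residual ~4-point early-success
  gap and its cause.
- The σ²-marginal quadrature assumes independent normal priors per arm; a
  correlated-arms prior would need the 2-D integral the Gibbs path already
  handles implicitly.
- Calibration searches only the success thresholds; joint success/futility
  tuning (e.g. to a power target) is left to the caller via repeated runs.
- The frequentist comparator is exact only under equal variances; it is meant
  as the flat-prior dual, not a general Welch-style analysis.
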