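"""Virtual-trial simulation: accrual, randomization, delayed endpoints, looks.

A virtual trial enrolls up to ``max_n`` subjects by a Poisson accrual process
(mean 2/week by default), randomizes them 1:1 to control or treatment, and
draws each subject's continuous response from N(arm mean, subject_sd^2); the
response is observed ``visit_delay`` weeks (default 12) after randomization.

Interim analyses are scheduled by subject counts. Two data semantics are
supported for a look scheduled at count k:

``completed`` (default)
    The look takes place when the k-th endpoint is observed and analyzes
    exactly those k outcomes; subjects enrolled in the meantime count toward
    the enrolled total if the trial stops.
``concurrent``
    The look takes place when the k-th subject enrolls and analyzes only the
    subjects whose 12-week visit has already occurred (pipeline subjects are
    excluded from the analysis but counted as enrolled).

The engine mirrors the dual-prior monitoring workflow: every simulated trial is
carried to full accrual, posterior probabilities under every referenced prior
community (and t-test p-values for the frequentist comparator) are recorded at
every look, and stopping rules are applied afterward to the completed traces.
This makes design comparisons on identical data streams exact and turns
boundary calibration into cheap post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import designs as _designs
from .designs import Decision, DesignSpec, P_VALUE_KEY
from .inference import (
    PosteriorSettings,
    p_value_arrays,
    prob_superiority_arrays,
)
from .priors import VariancePrior, make_community

__all__ = [
    "Scenario",
    "AccrualModel",
    "InterimSchedule",
    "SubjectRecord",
    "TrialOutcome",
    "TraceTable",
    "SCENARIO_PRESETS",
    "scenario_preset",
    "build_interim_schedule",
    "simulate_accrual",
    "simulate_traces",
    "apply_design",
    "run_trial",
    "run_many",
    "DEFAULT_MAX_N",
]

DEFAULT_MAX_N = 256


@dataclass(frozen=True)
class Scenario:
    """True state of nature for virtual subject responses."""

    label: str
    control_mean: float
    treatment_mean: float
    subject_sd: float = 0.07

    def __post_init__(self) -> None:
        if not self.subject_sd > 0:
            raise ValueError(f"subject_sd must be positive, got {self.subject_sd}")

    @property
    def delta(self) -> float:
        return self.treatment_mean - self.control_mean


# Hypothetical subject-response scenarios for the trial re-design: per-arm SD
# 0.07, so the difference has SD sqrt(2) * 0.07 ~= 0.10.
SCENARIO_PRESETS: dict[str, Scenario] = {
    "null": Scenario("null", 0.0, 0.0),
    "small": Scenario("small", 0.0, 0.02),
    "target": Scenario("target", 0.0, 0.05),
    "large": Scenario("large", 0.0, 0.08),
    "harmful": Scenario("harmful", 0.0, -0.05),
}


def scenario_preset(label: str) -> Scenario:
    try:
        return SCENARIO_PRESETS[label]
    except KeyError:
        raise ValueError(
            f"unknown scenario {label!r}; expected one of {sorted(SCENARIO_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class AccrualModel:
    """Enrollment process and endpoint observation lag.

    ``kind`` is ``"poisson"`` (exponential inter-arrival gaps, the default) or
    ``"deterministic"`` (one subject every 1/mean_rate weeks, useful for
    variance-reduction checks). Dropout is not modeled; the rate field exists
    for config completeness and must be zero.
    """

    mean_rate: float = 2.0
    visit_delay: float = 12.0
    dropout_rate: float = 0.0
    kind: str = "poisson"

    def __post_init__(self) -> None:
        if not self.mean_rate > 0:
            raise ValueError(f"mean_rate must be positive, got {self.mean_rate}")
        if self.visit_delay < 0:
            raise ValueError(f"visit_delay must be nonnegative, got {self.visit_delay}")
        if self.dropout_rate != 0:
            raise NotImplementedError("dropout is not modeled; dropout_rate must be 0")
        if self.kind not in ("poisson", "deterministic"):
            raise ValueError(f"unknown accrual kind {self.kind!r}")


# Printed interim schedules for max N 256 (counts of subjects at each look).
# The 6-interim row differs from the generic even-spacing rule by one subject
# at two looks; the printed rows are authoritative for these configurations.
_SCHEDULE_TABLE: dict[int, tuple[int, ...]] = {
    0: (),
    1: (128,),
    2: (85, 170),
    3: (64, 128, 192),
    4: (51, 102, 153, 204),
    5: (43, 86, 129, 172, 215),
    6: (37, 74, 110, 146, 183, 220),
    7: (32, 64, 96, 128, 160, 192, 224),
    8: (28, 56, 84, 112, 140, 168, 196, 224),
    9: (25, 50, 75, 100, 125, 150, 175, 200, 225),
    10: (23, 46, 69, 92, 115, 138, 161, 184, 207, 230),
    12: (20, 40, 60, 80, 100, 120, 140, 160, 180, 200, 220, 240),
    14: (17, 34, 51, 68, 85, 102, 119, 136, 153, 170, 187, 204, 221, 238),
    18: (13, 26, 39, 52, 65, 78, 91, 104, 117, 130, 143, 156, 169, 182, 195, 208, 221, 234),
}


@dataclass(frozen=True)
class InterimSchedule:
    """Interim looks as strictly increasing subject counts below ``max_n``."""

    max_n: int = DEFAULT_MAX_N
    looks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.max_n <= 0:
            raise ValueError(f"max_n must be positive, got {self.max_n}")
        looks = tuple(int(x) for x in self.looks)
        object.__setattr__(self, "looks", looks)
        if any(x <= 0 for x in looks):
            raise ValueError("look counts must be positive")
        if any(b <= a for a, b in zip(looks, looks[1:])):
            raise ValueError("look counts must be strictly increasing")
        if looks and looks[-1] >= self.max_n:
            raise ValueError("all looks must be below max_n")

    @property
    def n_interims(self) -> int:
        return len(self.looks)


def build_interim_schedule(n_interims: int, max_n: int = DEFAULT_MAX_N) -> InterimSchedule:
    """Evenly spaced interims by subject count.

    For ``max_n = 256`` and the tabulated interim counts the printed schedules
    are returned verbatim; otherwise looks are placed at
    ``round(i * max_n / (n_interims + 1))`` with duplicates collapsed.
    """
    if n_interims < 0:
        raise ValueError("n_interims must be nonnegative")
    if n_interims >= max_n:
        raise ValueError(f"n_interims={n_interims} must be below max_n={max_n}")
    if max_n == DEFAULT_MAX_N and n_interims in _SCHEDULE_TABLE:
        return InterimSchedule(max_n, _SCHEDULE_TABLE[n_interims])
    step = max_n / (n_interims + 1)
    looks: list[int] = []
    for i in range(1, n_interims + 1):
        c = int(np.floor(i * step + 0.5))
        if not looks or c > looks[-1]:
            looks.append(c)
    return InterimSchedule(max_n, tuple(looks))


@dataclass(frozen=True)
class SubjectRecord:
    """One virtual subject: arm, enrollment time, outcome time, response."""

    arm: str
    enroll_time: float
    outcome_time: float
    response: float


@dataclass
class TrialOutcome:
    """Result of one simulated trial run through a design."""

    decision: Decision
    n_enrolled: int
    duration_weeks: float
    prob_trace: list[dict] = field(default_factory=list)
    skipped_looks: list[int] = field(default_factory=list)


@dataclass
class TraceTable:
    """Per-trial, per-look sufficient statistics and monitoring quantities.

    Arrays have shape (n_sims, n_looks + 1); column ``j < n_looks`` is the
    j-th interim and the last column is the final analysis. ``probs`` maps each
    prior label to its posterior-probability array; entries are NaN where an
    arm had fewer than two observed outcomes.
    """

    schedule: InterimSchedule
    scenario: Scenario
    accrual: AccrualModel
    interim_data: str
    look_counts: tuple[int, ...]
    n_c: np.ndarray
    mean_c: np.ndarray
    sse_c: np.ndarray
    n_t: np.ndarray
    mean_t: np.ndarray
    sse_t: np.ndarray
    n_enrolled: np.ndarray
    look_times: np.ndarray
    probs: dict[str, np.ndarray] = field(default_factory=dict)
    p_values: Optional[np.ndarray] = None

    @property
    def n_sims(self) -> int:
        return self.n_c.shape[0]

    @property
    def n_looks(self) -> int:
        return len(self.schedule.looks)


def simulate_accrual(
    model: AccrualModel, max_n: int, rng: np.random.Generator
) -> np.ndarray:
    """Enrollment times (weeks) for ``max_n`` subjects."""
    if max_n < 0:
        raise ValueError("max_n must be nonnegative")
    if max_n == 0:
        return np.empty(0)
    if model.kind == "deterministic":
        return np.arange(1, max_n + 1) / model.mean_rate
    gaps = rng.exponential(1.0 / model.mean_rate, size=max_n)
    return np.cumsum(gaps)


def _randomize(rng: np.random.Generator, max_n: int, scheme: str) -> np.ndarray:
    """Arm indicators (1 = treatment) for the enrollment sequence."""
    if scheme == "simple":
        return rng.integers(0, 2, size=max_n)
    if scheme == "blocked":
        n_blocks = (max_n + 1) // 2
        blocks = np.tile(np.array([0, 1]), (n_blocks, 1))
        flip = rng.integers(0, 2, size=n_blocks).astype(bool)
        blocks[flip] = blocks[flip, ::-1]
        return blocks.ravel()[:max_n]
    raise ValueError(f"unknown randomization scheme {scheme!r}")


def _generate_trial(
    rng: np.random.Generator,
    scenario: Scenario,
    accrual: AccrualModel,
    schedule: InterimSchedule,
    interim_data: str,
    randomization: str,
):
    """Simulate one trial and return per-look sufficient statistics.

    Returns arrays over the schedule's interims plus the final analysis:
    (n_c, mean_c, sse_c, n_t, mean_t, sse_t, n_enrolled, look_time).
    """
    max_n = schedule.max_n
    enroll = simulate_accrual(accrual, max_n, rng)
    arms = _randomize(rng, max_n, randomization)
    means = np.where(arms == 1, scenario.treatment_mean, scenario.control_mean)
    resp = rng.normal(means, scenario.subject_sd)

    # outcome order equals enrollment order (constant visit delay), so every
    # analysis set is a prefix of the enrollment sequence
    is_t = arms == 1
    ct = np.cumsum(is_t)
    st = np.cumsum(resp * is_t)
    qt = np.cumsum(resp**2 * is_t)
    cc = np.arange(1, max_n + 1) - ct
    sc = np.cumsum(resp) - st
    qc = np.cumsum(resp**2) - qt

    counts = list(schedule.looks)
    n_looks = len(counts)
    observed = np.empty(n_looks + 1, dtype=int)
    enrolled = np.empty(n_looks + 1, dtype=int)
    times = np.empty(n_looks + 1)
    for j, k in enumerate(counts):
        if interim_data == "completed":
            t_look = enroll[k - 1] + accrual.visit_delay
            observed[j] = k
            enrolled[j] = int(np.searchsorted(enroll, t_look, side="right"))
        else:  # concurrent
            t_look = enroll[k - 1]
            observed[j] = int(
                np.searchsorted(enroll, t_look - accrual.visit_delay, side="right")
            )
            enrolled[j] = k
        times[j] = t_look
    observed[-1] = max_n
    enrolled[-1] = max_n
    times[-1] = enroll[-1] + accrual.visit_delay

    def prefix_stats(m):
        if m == 0:
            return 0, np.nan, 0.0, 0, np.nan, 0.0
        nt = int(ct[m - 1])
        nc = int(cc[m - 1])
        mt = st[m - 1] / nt if nt else np.nan
        mc = sc[m - 1] / nc if nc else np.nan
        sset = max(qt[m - 1] - nt * mt**2, 0.0) if nt else 0.0
        ssec = max(qc[m - 1] - nc * mc**2, 0.0) if nc else 0.0
        return nc, mc, ssec, nt, mt, sset

    stats = np.array([prefix_stats(m) for m in observed], dtype=float)  # (L+1, 6)
    return stats, enrolled, times


def simulate_trial_data(
    scenario: Scenario,
    accrual: AccrualModel,
    schedule: InterimSchedule,
    n_sims: int,
    seed: int,
    interim_data: str = "completed",
    randomization: str = "simple",
) -> TraceTable:
    """Simulate ``n_sims`` independent trials and collect per-look statistics.

    Trial ``i`` draws from a generator seeded by the pair (seed, i), so any
    single trial is reproducible in isolation and streams are independent.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    if interim_data not in ("completed", "concurrent"):
        raise ValueError(f"unknown interim_data semantics {interim_data!r}")
    n_cols = len(schedule.looks) + 1
    stat_block = np.empty((n_sims, n_cols, 6))
    enrolled = np.empty((n_sims, n_cols), dtype=int)
    times = np.empty((n_sims, n_cols))
    for i in range(n_sims):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        stats, enr, t = _generate_trial(
            rng, scenario, accrual, schedule, interim_data, randomization
        )
        stat_block[i] = stats
        enrolled[i] = enr
        times[i] = t
    return TraceTable(
        schedule=schedule,
        scenario=scenario,
        accrual=accrual,
        interim_data=interim_data,
        look_counts=tuple(schedule.looks),
        n_c=stat_block[:, :, 0],
        mean_c=stat_block[:, :, 1],
        sse_c=stat_block[:, :, 2],
        n_t=stat_block[:, :, 3],
        mean_t=stat_block[:, :, 4],
        sse_t=stat_block[:, :, 5],
        n_enrolled=enrolled,
        look_times=times,
    )


def attach_probabilities(
    traces: TraceTable,
    prior_labels: Sequence[str],
    vprior: VariancePrior,
    settings: PosteriorSettings,
    seed: int = 0,
    include_p_values: bool = False,
) -> TraceTable:
    """Compute monitoring quantities at every look for every requested prior.

    Posterior probabilities for stopped-in-principle trials are still computed
    at later looks (the trace runs to full accrual); stopping is applied later
    by :func:`apply_design`. Gibbs randomness, when used, is seeded per
    (look, prior) so traces do not depend on evaluation order.
    """
    n_cols = traces.n_c.shape[1]
    for label_idx, label in enumerate(prior_labels):
        if label == P_VALUE_KEY:
            continue
        community = make_community(label)
        probs = np.empty((traces.n_sims, n_cols))
        for j in range(n_cols):
            rng = None
            if settings.estimator == "gibbs_rao_blackwell":
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(10_000 + j, label_idx))
                )
            probs[:, j] = prob_superiority_arrays(
                traces.n_c[:, j],
                traces.mean_c[:, j],
                traces.sse_c[:, j],
                traces.n_t[:, j],
                traces.mean_t[:, j],
                traces.sse_t[:, j],
                community,
                vprior,
                settings,
                rng=rng,
            )
        traces.probs[label] = probs
    if include_p_values or P_VALUE_KEY in prior_labels:
        traces.p_values = p_value_arrays(
            traces.n_c, traces.mean_c, traces.sse_c,
            traces.n_t, traces.mean_t, traces.sse_t,
        )
    return traces


def simulate_traces(
    spec: DesignSpec,
    scenario: Scenario,
    accrual: Optional[AccrualModel] = None,
    schedule: Optional[InterimSchedule] = None,
    vprior: Optional[VariancePrior] = None,
    settings: Optional[PosteriorSettings] = None,
    n_sims: int = 1000,
    seed: int = 0,
    interim_data: str = "completed",
    randomization: str = "simple",
    extra_priors: Sequence[str] = (),
) -> TraceTable:
    """Simulate trials and attach every monitoring quantity ``spec`` needs."""
    accrual = accrual or AccrualModel()
    schedule = schedule or build_interim_schedule(6)
    vprior = vprior or VariancePrior()
    settings = settings or PosteriorSettings()
    traces = simulate_trial_data(
        scenario, accrual, schedule, n_sims, seed, interim_data, randomization
    )
    labels = list(spec.prior_labels)
    for lab in extra_priors:
        if lab not in labels:
            labels.append(lab)
    return attach_probabilities(
        traces,
        labels,
        vprior,
        settings,
        seed=seed,
        include_p_values=spec.is_frequentist,
    )


def _look_probs(traces: TraceTable, i: int, j: int) -> dict[str, float]:
    probs = {label: float(arr[i, j]) for label, arr in traces.probs.items()}
    if traces.p_values is not None:
        probs[P_VALUE_KEY] = float(traces.p_values[i, j])
    return probs


def _required_values_ok(spec: DesignSpec, probs: dict[str, float], final: bool) -> bool:
    if final:
        needed = [spec.late_success_prior, spec.late_futility_prior]
    else:
        needed = [p for p in (spec.success_prior, spec.futility_prior) if p is not None]
    return all(not np.isnan(probs.get(lab, np.nan)) for lab in needed)


def apply_design(spec: DesignSpec, traces: TraceTable) -> list[TrialOutcome]:
    """Run every simulated trial in ``traces`` through the design's rules.

    Interim looks where a required quantity is undefined (fewer than two
    outcomes in an arm) are skipped and recorded. Early stops freeze the
    enrolled count and calendar time of the triggering look; trials reaching
    full accrual are decided at the final analysis.
    """
    outcomes: list[TrialOutcome] = []
    n_looks = traces.n_looks
    has_early = spec.success_prior is not None or spec.futility_prior is not None
    for i in range(traces.n_sims):
        trace_rows: list[dict] = []
        skipped: list[int] = []
        decision: Optional[Decision] = None
        if has_early:
            for j in range(n_looks):
                probs = _look_probs(traces, i, j)
                trace_rows.append({"look": j + 1, **probs})
                if not _required_values_ok(spec, probs, final=False):
                    skipped.append(j + 1)
                    continue
                d = _designs.evaluate_interim(spec, probs, look_index=j + 1)
                if d.is_terminal:
                    decision = d
                    break
        if decision is not None:
            j = decision.look_index - 1
            outcomes.append(
                TrialOutcome(
                    decision=decision,
                    n_enrolled=int(traces.n_enrolled[i, j]),
                    duration_weeks=float(traces.look_times[i, j]),
                    prob_trace=trace_rows,
                    skipped_looks=skipped,
                )
            )
            continue
        probs = _look_probs(traces, i, n_looks)
        trace_rows.append({"look": n_looks + 1, **probs})
        if _required_values_ok(spec, probs, final=True):
            d = _designs.evaluate_final(spec, probs, look_index=n_looks + 1)
        else:
            # a required quantity is undefined even at full accrual (an arm
            # with < 2 outcomes): no decision can be reached
            skipped.append(n_looks + 1)
            d = Decision("inconclusive", n_looks + 1)
        outcomes.append(
            TrialOutcome(
                decision=d,
                n_enrolled=int(traces.n_enrolled[i, n_looks]),
                duration_weeks=float(traces.look_times[i, n_looks]),
                prob_trace=trace_rows,
                skipped_looks=skipped,
            )
        )
    return outcomes


def run_many(
    spec: DesignSpec,
    scenario: Scenario,
    accrual: Optional[AccrualModel] = None,
    schedule: Optional[InterimSchedule] = None,
    vprior: Optional[VariancePrior] = None,
    settings: Optional[PosteriorSettings] = None,
    n_sims: int = 1000,
    seed: int = 0,
    interim_data: str = "completed",
    randomization: str = "simple",
) -> list[TrialOutcome]:
    """Simulate ``n_sims`` independent trials under one design and scenario."""
    traces = simulate_traces(
        spec, scenario, accrual, schedule, vprior, settings,
        n_sims=n_sims, seed=seed, interim_data=interim_data,
        randomization=randomization,
    )
    return apply_design(spec, traces)


def run_trial(
    spec: DesignSpec,
    scenario: Scenario,
    accrual: Optional[AccrualModel] = None,
    schedule: Optional[InterimSchedule] = None,
    vprior: Optional[VariancePrior] = None,
    settings: Optional[PosteriorSettings] = None,
    seed: int = 0,
    index: int = 0,
) -> TrialOutcome:
    """Simulate a single trial — replicate ``index`` of the stream ``seed``.

    Identical to element ``index`` of :func:`run_many` with the same seed up to
    sampling noise in the posterior estimator (none for the default
    deterministic quadrature estimator).
    """
    outcomes = run_many(
        spec, scenario, accrual, schedule, vprior, settings,
        n_sims=index + 1, seed=seed,
    )
    return outcomes[index]
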