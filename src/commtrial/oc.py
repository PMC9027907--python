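"""Operating characteristics: aggregating simulated trials into design summaries.

Frequentist properties of each Bayesian design are estimated by Monte Carlo:
type I error is the total (early + late) success rate under the null scenario,
power the total success rate under the target-difference scenario, futility
rate the total futility proportion, plus expected sample size and expected
trial duration in weeks. Every rate carries a binomial Monte-Carlo standard
error sqrt(p (1 - p) / n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import math

import numpy as np
import pandas as pd

from .designs import DesignSpec
from .inference import PosteriorSettings
from .priors import VariancePrior
from .simulator import (
    AccrualModel,
    InterimSchedule,
    Scenario,
    TrialOutcome,
    apply_design,
    build_interim_schedule,
    simulate_traces,
)

__all__ = ["OCReport", "summarize", "oc_grid"]

_CATEGORIES = (
    "early_success",
    "late_success",
    "early_futility",
    "late_futility",
    "inconclusive",
)


@dataclass
class OCReport:
    """Decision-category rates (with MC standard errors) and trial-cost means."""

    n_sims: int
    rates: dict[str, float]
    ses: dict[str, float]
    mean_n: float
    mean_duration_weeks: float
    scenario: str = ""
    design: str = ""
    n_interims: int = 0

    @property
    def total_success(self) -> float:
        return self.rates["early_success"] + self.rates["late_success"]

    @property
    def total_futility(self) -> float:
        return self.rates["early_futility"] + self.rates["late_futility"]

    def rate_se(self, p: float) -> float:
        return math.sqrt(p * (1.0 - p) / self.n_sims)

    def to_dict(self) -> dict:
        out = {
            "design": self.design,
            "scenario": self.scenario,
            "n_interims": self.n_interims,
            "n_sims": self.n_sims,
        }
        for cat in _CATEGORIES:
            out[cat] = self.rates[cat]
            out[f"{cat}_se"] = self.ses[cat]
        out["total_success"] = self.total_success
        out["total_futility"] = self.total_futility
        out["mean_n"] = self.mean_n
        out["mean_duration_weeks"] = self.mean_duration_weeks
        return out


def summarize(
    outcomes: Sequence[TrialOutcome],
    scenario: str = "",
    design: str = "",
    n_interims: int = 0,
) -> OCReport:
    """Aggregate replicate outcomes into one operating-characteristics report."""
    if not outcomes:
        raise ValueError("cannot summarize an empty outcome list")
    n = len(outcomes)
    counts = {cat: 0 for cat in _CATEGORIES}
    for o in outcomes:
        kind = o.decision.kind
        if kind not in counts:
            raise ValueError(f"unexpected terminal decision {kind!r}")
        counts[kind] += 1
    rates = {cat: counts[cat] / n for cat in _CATEGORIES}
    ses = {cat: math.sqrt(p * (1.0 - p) / n) for cat, p in rates.items()}
    return OCReport(
        n_sims=n,
        rates=rates,
        ses=ses,
        mean_n=float(np.mean([o.n_enrolled for o in outcomes])),
        mean_duration_weeks=float(np.mean([o.duration_weeks for o in outcomes])),
        scenario=scenario,
        design=design,
        n_interims=n_interims,
    )


def oc_grid(
    design_specs: Sequence[DesignSpec],
    scenarios: Sequence[Scenario],
    interim_counts: Sequence[int],
    n_sims: int = 1000,
    seed: int = 0,
    accrual: Optional[AccrualModel] = None,
    vprior: Optional[VariancePrior] = None,
    settings: Optional[PosteriorSettings] = None,
    max_n: Optional[int] = None,
    common_random_numbers: bool = True,
    interim_data: str = "completed",
) -> pd.DataFrame:
    """Operating characteristics over the designs x scenarios x interims grid.

    With ``common_random_numbers`` (the default) all designs within one
    (scenario, interim-count) cell are applied to the same simulated trial
    streams, sharpening between-design contrasts; otherwise each design gets an
    independent stream. Returns one tidy row per grid cell.
    """
    from .simulator import DEFAULT_MAX_N

    max_n = max_n or DEFAULT_MAX_N
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        for k_idx, n_interims in enumerate(interim_counts):
            schedule = build_interim_schedule(n_interims, max_n)
            cell_seed = _derive_seed(seed, s_idx, k_idx, 0)
            if common_random_numbers:
                # one trace computed with the union of monitored quantities
                labels: list[str] = []
                for spec in design_specs:
                    for lab in spec.prior_labels:
                        if lab not in labels:
                            labels.append(lab)
                union_spec = max(design_specs, key=lambda s: len(s.prior_labels))
                traces = simulate_traces(
                    union_spec, scenario, accrual, schedule, vprior, settings,
                    n_sims=n_sims, seed=cell_seed, interim_data=interim_data,
                    extra_priors=labels,
                )
                if any(spec.is_frequentist for spec in design_specs) and traces.p_values is None:
                    from .inference import p_value_arrays

                    traces.p_values = p_value_arrays(
                        traces.n_c, traces.mean_c, traces.sse_c,
                        traces.n_t, traces.mean_t, traces.sse_t,
                    )
                for spec in design_specs:
                    outcomes = apply_design(spec, traces)
                    rows.append(
                        summarize(outcomes, scenario.label, spec.name, n_interims).to_dict()
                    )
            else:
                for d_idx, spec in enumerate(design_specs):
                    run_seed = _derive_seed(seed, s_idx, k_idx, d_idx)
                    traces = simulate_traces(
                        spec, scenario, accrual, schedule, vprior, settings,
                        n_sims=n_sims, seed=run_seed, interim_data=interim_data,
                    )
                    outcomes = apply_design(spec, traces)
                    rows.append(
                        summarize(outcomes, scenario.label, spec.name, n_interims).to_dict()
                    )
    return pd.DataFrame(rows)


def _derive_seed(base: int, *parts: int) -> int:
    """Deterministic sub-seed below 2^31 from a base seed and index tuple."""
    ss = np.random.SeedSequence(base, spawn_key=tuple(parts))
    return int(ss.generate_state(1)[0] % (2**31))
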