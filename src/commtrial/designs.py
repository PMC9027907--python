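"""Decision rules for the fixed, Bayesian adaptive, and group-sequential designs.

Each Bayesian design monitors Pr(treatment > control | data) under one or two
prior communities and applies Haybittle-Peto-style constant thresholds:

* early success at an interim when the success-prior probability exceeds ``s_e``
  (default 0.998);
* early futility when the futility-prior probability falls below ``f_e``
  (default 0.70);
* at the final analysis, late success above ``s_l`` (default 0.975) and late
  futility below ``f_l`` (default 0.85); anything in between is inconclusive.

The five named Bayesian designs differ only in which community backs each rule:

===========  =============  =============  ============  ============
design       early success  early futility late success  late futility
===========  =============  =============  ============  ============
fixed        --             --             skeptical     enthusiastic
design1      skeptical      --             skeptical     skeptical
design2      --             enthusiastic   enthusiastic  enthusiastic
design3      skeptical      enthusiastic   skeptical     enthusiastic
design4      noninformative noninformative noninformative noninformative
===========  =============  =============  ============  ============

The frequentist group-sequential comparator replaces posterior probabilities by
one-sided pooled t-test p-values with the corresponding thresholds
(p < 1 - s_e = 0.002 / p > 1 - f_e = 0.3 at interims; p < 0.025 / p > 0.15 at
the final analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Boundaries",
    "DesignSpec",
    "Decision",
    "DEFAULT_BOUNDARIES",
    "DESIGN_PRESETS",
    "design_preset",
    "evaluate_interim",
    "evaluate_final",
    "calibrate_success_boundaries",
    "UncalibratableError",
]

P_VALUE_KEY = "p_value"


@dataclass(frozen=True)
class Boundaries:
    """Stopping thresholds on the posterior-probability scale."""

    early_success: float = 0.998
    early_futility: float = 0.70
    late_success: float = 0.975
    late_futility: float = 0.85

    def __post_init__(self) -> None:
        if not 0 < self.early_futility < self.early_success <= 1:
            raise ValueError("require 0 < early_futility < early_success <= 1")
        if not 0 < self.late_futility < self.late_success <= 1:
            raise ValueError("require 0 < late_futility < late_success <= 1")


DEFAULT_BOUNDARIES = Boundaries()


@dataclass(frozen=True)
class DesignSpec:
    """Which prior community (or p-value) backs each of the four criteria."""

    name: str
    late_success_prior: str
    late_futility_prior: str
    success_prior: Optional[str] = None
    futility_prior: Optional[str] = None
    boundaries: Boundaries = DEFAULT_BOUNDARIES

    @property
    def is_frequentist(self) -> bool:
        return self.late_success_prior == P_VALUE_KEY

    @property
    def prior_labels(self) -> tuple[str, ...]:
        """Distinct prior labels the design's rules reference (order stable)."""
        labels = []
        for lab in (
            self.success_prior,
            self.futility_prior,
            self.late_success_prior,
            self.late_futility_prior,
        ):
            if lab is not None and lab != P_VALUE_KEY and lab not in labels:
                labels.append(lab)
        return tuple(labels)

    def with_boundaries(self, boundaries: Boundaries) -> "DesignSpec":
        return replace(self, boundaries=boundaries)


@dataclass(frozen=True)
class Decision:
    """Outcome of one analysis: what was decided and at which look."""

    kind: str  # continue | early_success | early_futility | late_success | late_futility | inconclusive
    look_index: int

    @property
    def is_terminal(self) -> bool:
        return self.kind != "continue"

    @property
    def is_success(self) -> bool:
        return self.kind in ("early_success", "late_success")

    @property
    def is_futility(self) -> bool:
        return self.kind in ("early_futility", "late_futility")


DESIGN_PRESETS: dict[str, DesignSpec] = {
    "fixed": DesignSpec(
        "fixed", late_success_prior="skeptical", late_futility_prior="enthusiastic"
    ),
    "design1": DesignSpec(
        "design1",
        success_prior="skeptical",
        late_success_prior="skeptical",
        late_futility_prior="skeptical",
    ),
    "design2": DesignSpec(
        "design2",
        futility_prior="enthusiastic",
        late_success_prior="enthusiastic",
        late_futility_prior="enthusiastic",
    ),
    "design3": DesignSpec(
        "design3",
        success_prior="skeptical",
        futility_prior="enthusiastic",
        late_success_prior="skeptical",
        late_futility_prior="enthusiastic",
    ),
    "design4": DesignSpec(
        "design4",
        success_prior="noninformative",
        futility_prior="noninformative",
        late_success_prior="noninformative",
        late_futility_prior="noninformative",
    ),
    "frequentist_gsd": DesignSpec(
        "frequentist_gsd",
        success_prior=P_VALUE_KEY,
        futility_prior=P_VALUE_KEY,
        late_success_prior=P_VALUE_KEY,
        late_futility_prior=P_VALUE_KEY,
    ),
}


def design_preset(name: str) -> DesignSpec:
    """Look up one of the six named designs."""
    try:
        return DESIGN_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown design {name!r}; expected one of {sorted(DESIGN_PRESETS)}"
        ) from None


def _lookup(probs: Mapping[str, float], label: str, context: str) -> float:
    try:
        value = probs[label]
    except KeyError:
        raise ValueError(f"missing probability for {label!r} required by {context}") from None
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"probability for {label!r} in {context} is undefined")
    return float(value)


def evaluate_interim(
    spec: DesignSpec, probs: Mapping[str, float], look_index: int = 0
) -> Decision:
    """Apply the early stopping rules at one interim look.

    ``probs`` maps prior labels to posterior probabilities of superiority (and
    ``"p_value"`` to the one-sided t-test p-value for the frequentist design).
    Success is checked before futility; with sensible (non-contradictory)
    boundaries both cannot fire on the same probability.
    """
    b = spec.boundaries
    if spec.success_prior is not None:
        value = _lookup(probs, spec.success_prior, f"{spec.name} early success rule")
        fired = (value < 1 - b.early_success) if spec.is_frequentist else (value > b.early_success)
        if fired:
            return Decision("early_success", look_index)
    if spec.futility_prior is not None:
        value = _lookup(probs, spec.futility_prior, f"{spec.name} early futility rule")
        fired = (value > 1 - b.early_futility) if spec.is_frequentist else (value < b.early_futility)
        if fired:
            return Decision("early_futility", look_index)
    return Decision("continue", look_index)


def evaluate_final(
    spec: DesignSpec, probs: Mapping[str, float], look_index: int = -1
) -> Decision:
    """Apply the late success/futility rules at the final analysis."""
    b = spec.boundaries
    value = _lookup(probs, spec.late_success_prior, f"{spec.name} late success rule")
    fired = (value < 1 - b.late_success) if spec.is_frequentist else (value > b.late_success)
    if fired:
        return Decision("late_success", look_index)
    value = _lookup(probs, spec.late_futility_prior, f"{spec.name} late futility rule")
    fired = (value > 1 - b.late_futility) if spec.is_frequentist else (value < b.late_futility)
    if fired:
        return Decision("late_futility", look_index)
    return Decision("inconclusive", look_index)


class UncalibratableError(RuntimeError):
    """No candidate boundary set meets the type I error constraint."""


def calibrate_success_boundaries(
    spec: DesignSpec,
    null_scenario,
    candidate_grid: Sequence[Boundaries],
    n_sims: int = 10_000,
    alpha: float = 0.025,
    seed: int = 0,
    accrual=None,
    schedule=None,
    vprior=None,
    settings=None,
) -> Boundaries:
    """Select success boundaries controlling the one-sided type I error.

    Simulates one set of null-scenario trials (common random numbers) and
    applies every candidate boundary set to the same probability traces. Among
    candidates whose estimated total success rate is at most ``alpha``, returns
    the least stringent one — lowest late-success threshold first, ties broken
    toward a lower early-success threshold (higher power). Futility boundaries
    are left untouched: futility stopping cannot inflate type I error.
    """
    from . import simulator  # deferred: avoids a circular import at load time

    if not candidate_grid:
        raise ValueError("candidate_grid must be nonempty")
    traces = simulator.simulate_traces(
        spec,
        null_scenario,
        accrual=accrual,
        schedule=schedule,
        vprior=vprior,
        settings=settings,
        n_sims=n_sims,
        seed=seed,
    )
    admissible = []
    for bounds in candidate_grid:
        cand = spec.with_boundaries(bounds)
        outcomes = simulator.apply_design(cand, traces)
        rate = np.mean([o.decision.is_success for o in outcomes])
        if rate <= alpha:
            admissible.append((bounds.late_success, bounds.early_success, bounds))
    if not admissible:
        raise UncalibratableError(
            f"no candidate boundaries achieve total success rate <= {alpha} "
            f"under {getattr(null_scenario, 'label', null_scenario)}"
        )
    admissible.sort(key=lambda t: (t[0], t[1]))
    return admissible[0][2]
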