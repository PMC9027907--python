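"""Walk one virtual trial through design 3's stopping rules, look by look.

Design 3 stops early for success when the skeptical-prior probability exceeds
99.8% and early for futility when the enthusiastic-prior probability falls
below 70%; at the final analysis the thresholds are 97.5% and 85%.
"""

from commtrial import build_interim_schedule, design_preset, run_trial, scenario_preset

outcome = run_trial(
    design_preset("design3"),
    scenario_preset("target"),        # true difference 0.05, per-arm SD 0.07
    schedule=build_interim_schedule(6),  # looks at 37/74/110/146/183/220
    seed=3,
)

for row in outcome.prob_trace:
    look = row["look"]
    print(
        f"look {look}: P_skeptical={row['skeptical']:.4f}  "
        f"P_enthusiastic={row['enthusiastic']:.4f}"
    )
print(
    f"\ndecision: {outcome.decision.kind} at look {outcome.decision.look_index}; "
    f"{outcome.n_enrolled} subjects enrolled, {outcome.duration_weeks:.1f} weeks"
)
# With a real 0.05 benefit the skeptical probability typically crosses 0.998
# within the first few looks, stopping the trial far below the 256-subject
# maximum and well short of the ~140-week full-accrual duration.
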