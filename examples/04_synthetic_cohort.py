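"""Generate a synthetic two-arm patient cohort and recover its parameters.

Emulates a retrospective surgical cohort (100 patients per arm, uniform
accrual over 46 months, administrative censoring 87 months after accrual
start) and summarises it the way a study table would: Kaplan-Meier median
DFS/OS and mean direct cost per arm.
"""

from markovcea import CohortConfig, generate_cohort, summarize_cohort

config = CohortConfig(n_per_arm=100, seed=7)
records = generate_cohort(config)
print(f"{len(records)} patients, columns: {', '.join(records.columns)}")
print(f"censored for OS: {(~records.os_event).mean():.0%}\n")

for arm, s in summarize_cohort(records).items():
    print(
        f"{arm}: KM median DFS {s.median_dfs:.1f} mo (target "
        f"{config.median_dfs[arm]:.0f}), median OS {s.median_os:.1f} mo, "
        f"mean direct cost {s.mean_cost:,.0f} RMB (n={s.n})"
    )

print(
    "\nAt n=100 the Kaplan-Meier medians scatter around the generating"
    "\nvalues; rerun with n_per_arm=10_000 to see them recovered within a"
    "\nfew percent."
)
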