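"""Median survival times to monthly transition probabilities.

The decision model tracks three health states — disease-free survival (DFS),
progressed disease (PD) and death (D) — with a one-month cycle.  Monthly
transition probabilities are derived from median event times under a constant
(exponential) hazard: if the median time to an event is ``m`` months, the
per-month event probability is ``1 - 0.5**(1/m)``, equivalently
``1 - exp(-R)`` with monthly rate ``R = ln(2)/m``.

Progressed disease is reachable only from DFS, death is absorbing, and there
is no recovery from PD back to DFS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STATES = ("dfs", "pd", "death")

__all__ = [
    "STATES",
    "TransitionMatrix",
    "monthly_risk",
    "prob_from_rate",
    "rate_from_prob",
    "build_transition_matrix",
    "param_range",
    "probability_table",
]


def monthly_risk(median_months: float) -> float:
    """Per-cycle event probability implied by a median time-to-event.

    Under a constant hazard, half the cohort experiences the event by the
    median, so the monthly probability is ``1 - 0.5**(1/median)``.

    Parameters
    ----------
    median_months : float
        Median time to the event, in months (cycles). Must be positive.
    """
    if not math.isfinite(median_months) or median_months <= 0:
        raise ValueError(f"median must be a positive number, got {median_months!r}")
    return -math.expm1(math.log(0.5) / median_months)


def prob_from_rate(rate_per_month: float) -> float:
    """Convert a monthly event rate to a per-cycle probability, P = 1 - e^(-R)."""
    if rate_per_month < 0:
        raise ValueError(f"rate must be non-negative, got {rate_per_month!r}")
    return -math.expm1(-rate_per_month)


def rate_from_prob(probability: float) -> float:
    """Inverse of :func:`prob_from_rate`: R = -ln(1 - P) for P in [0, 1)."""
    if not 0.0 <= probability < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {probability!r}")
    return -math.log1p(-probability)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 3x3 monthly transition matrix over (DFS, PD, D).

    Only the three exit probabilities are free: DFS->PD, DFS->D and PD->D.
    Stay probabilities are the residuals, death is absorbing and PD cannot
    return to DFS (structural zeros).
    """

    p_dfs_pd: float
    p_dfs_d: float
    p_pd_d: float

    def __post_init__(self) -> None:
        for name in ("p_dfs_pd", "p_dfs_d", "p_pd_d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.p_dfs_pd + self.p_dfs_d > 1.0 + 1e-12:
            raise ValueError(
                "DFS exit probabilities exceed 1: "
                f"p_dfs_pd={self.p_dfs_pd}, p_dfs_d={self.p_dfs_d}"
            )

    @property
    def p_dfs_dfs(self) -> float:
        return 1.0 - self.p_dfs_pd - self.p_dfs_d

    @property
    def p_pd_pd(self) -> float:
        return 1.0 - self.p_pd_d

    @property
    def matrix(self) -> np.ndarray:
        """Dense 3x3 array, rows indexed (DFS, PD, D)."""
        return np.array(
            [
                [self.p_dfs_dfs, self.p_dfs_pd, self.p_dfs_d],
                [0.0, self.p_pd_pd, self.p_pd_d],
                [0.0, 0.0, 1.0],
            ]
        )


def build_transition_matrix(
    median_dfs: float,
    median_os: float,
    *,
    competing_risks: bool = False,
) -> TransitionMatrix:
    """Assemble the strategy transition matrix from two median survival times.

    ``median_dfs`` is the median disease-free survival and ``median_os`` the
    median overall survival, both in months.  The post-progression survival
    median is taken as ``median_os - median_dfs``, the unique rule consistent
    with treating each sojourn as exponential with the printed medians.

    By default the DFS->D probability uses the OS median directly,
    ``monthly_risk(median_os)``, replicating the published arithmetic even
    though it slightly double-counts the death hazard against DFS exit.  With
    ``competing_risks=True`` the total DFS exit probability is kept at
    ``monthly_risk(median_dfs)`` and split between progression and death in
    proportion to their cause-specific rates (death rate ``ln2/median_os``).
    """
    if median_dfs <= 0:
        raise ValueError(f"median_dfs must be positive, got {median_dfs!r}")
    if median_os <= median_dfs:
        raise ValueError(
            "median_os must exceed median_dfs (post-progression median is "
            f"median_os - median_dfs): got {median_os!r} <= {median_dfs!r}"
        )
    median_pps = median_os - median_dfs
    if median_pps < 0.5:
        warnings.warn(
            f"post-progression median {median_pps:.3g} months is below half a "
            "cycle; monthly discretization is coarse (PD->D probability "
            "exceeds 0.75)",
            stacklevel=2,
        )
    p_pd_d = monthly_risk(median_pps)
    if competing_risks:
        lam = math.log(2.0) / median_dfs  # total DFS-exit rate
        mu = math.log(2.0) / median_os  # cause-specific death rate
        p_exit = monthly_risk(median_dfs)
        p_dfs_d = p_exit * mu / lam
        p_dfs_pd = p_exit - p_dfs_d
    else:
        p_dfs_pd = monthly_risk(median_dfs)
        p_dfs_d = monthly_risk(median_os)
        if p_dfs_pd + p_dfs_d > 1.0:
            # the direct median-per-risk arithmetic overcounts DFS exits for
            # very short medians; the competing-risks split has no such limit
            raise ValueError(
                f"medians ({median_dfs}, {median_os}) are too short for the "
                "direct probability arithmetic (DFS exit probabilities sum "
                "beyond 1); use competing_risks=True or a shorter cycle"
            )
    return TransitionMatrix(p_dfs_pd=p_dfs_pd, p_dfs_d=p_dfs_d, p_pd_d=p_pd_d)


def param_range(
    baseline: float, fraction: float = 0.20, *, cap: float | None = None
) -> tuple[float, float]:
    """Symmetric +/-``fraction`` range around a baseline value.

    Probabilities and utilities pass ``cap=1.0`` so the upper limit never
    exceeds 1; costs are left uncapped.
    """
    if baseline < 0:
        raise ValueError(f"baseline must be non-negative, got {baseline!r}")
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction!r}")
    lower = baseline * (1.0 - fraction)
    upper = baseline * (1.0 + fraction)
    if cap is not None:
        upper = min(upper, cap)
    return lower, upper


def probability_table(
    median_dfs: float,
    median_os: float,
    fraction: float = 0.20,
    *,
    decimals: int = 3,
) -> pd.DataFrame:
    """Reporting table of transition probabilities with sensitivity bounds.

    Columns ``transition, baseline, lower, upper``.  Follows the publication
    convention for such tables: the exit probabilities are rounded to
    ``decimals`` first, stay probabilities are complements of the *rounded*
    exits, and the +/-20% bounds are computed from the rounded baselines
    (upper limits capped at 1).  Full-precision values are used everywhere
    else in the package; this rounding is display-only.
    """
    tm = build_transition_matrix(median_dfs, median_os)
    p_dfs_pd = round(tm.p_dfs_pd, decimals)
    p_dfs_d = round(tm.p_dfs_d, decimals)
    p_pd_d = round(tm.p_pd_d, decimals)
    rows = [
        ("p_dfs_dfs", round(1.0 - p_dfs_pd - p_dfs_d, decimals)),
        ("p_dfs_pd", p_dfs_pd),
        ("p_dfs_d", p_dfs_d),
        ("p_pd_pd", round(1.0 - p_pd_d, decimals)),
        ("p_pd_d", p_pd_d),
    ]
    records = []
    for name, base in rows:
        lo, hi = param_range(base, fraction, cap=1.0)
        records.append(
            {
                "transition": name,
                "baseline": base,
                "lower": round(lo, decimals),
                "upper": round(hi, decimals),
            }
        )
    return pd.DataFrame.from_records(records)
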