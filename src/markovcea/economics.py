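"""Discounted costs, QALYs and incremental cost-effectiveness statistics.

Costs accrue as a one-time initial (surgical admission) cost at cycle 0 plus
a uniform per-cycle cost while alive; health accrues as state utility
weighted person-time, divided by 12 to express quality-adjusted life *years*
from monthly cycles.  Both streams are discounted at a compound annual rate
converted to a monthly exponent, with the cycle-0 initial cost undiscounted.

The incremental cost-effectiveness ratio (ICER) between two strategies is
(C_comparator - C_reference) / (U_comparator - U_reference); a strategy is
deemed cost-effective when its ICER falls below the willingness-to-pay (WTP)
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import MarkovTrace, run_trace
from .transitions import build_transition_matrix

__all__ = [
    "StrategyParams",
    "EconResult",
    "CEResult",
    "monthly_discount_factor",
    "evaluate_strategy",
    "run_strategy",
    "icer",
    "nmb",
    "calibrate_state_costs",
]


@dataclass(frozen=True)
class StrategyParams:
    """Complete model inputs for one treatment strategy.

    Parameters
    ----------
    label : str
        Strategy name, e.g. ``"OPD"`` or ``"LPD"``.
    median_dfs, median_os : float
        Median disease-free and overall survival, months.
    u_dfs, u_pd : float
        Health-state utilities in [0, 1] for disease-free and progressed
        disease (death carries utility 0).
    initial_cost : float
        One-time cost applied at cycle 0 (2023 RMB).
    cycle_cost_alive : float
        Per-cycle cost while alive in any state (2023 RMB/month).
    annual_discount : float
        Annual discount rate applied to both costs and QALYs (default 5%).
    """

    label: str
    median_dfs: float
    median_os: float
    u_dfs: float
    u_pd: float
    initial_cost: float
    cycle_cost_alive: float
    annual_discount: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.median_dfs < self.median_os:
            raise ValueError(
                f"{self.label}: require 0 < median_dfs < median_os, got "
                f"{self.median_dfs!r}, {self.median_os!r}"
            )
        if not 0.0 <= self.u_pd <= self.u_dfs <= 1.0:
            raise ValueError(
                f"{self.label}: require 0 <= u_pd <= u_dfs <= 1, got "
                f"u_pd={self.u_pd!r}, u_dfs={self.u_dfs!r}"
            )
        if self.initial_cost < 0 or self.cycle_cost_alive < 0:
            raise ValueError(f"{self.label}: costs must be non-negative")
        if not 0.0 <= self.annual_discount < 1.0:
            raise ValueError(
                f"{self.label}: annual_discount must lie in [0, 1), got "
                f"{self.annual_discount!r}"
            )

    def transition_matrix(self, *, competing_risks: bool = False):
        return build_transition_matrix(
            self.median_dfs, self.median_os, competing_risks=competing_risks
        )


@dataclass(frozen=True)
class EconResult:
    """Discounted totals for one strategy over the model horizon."""

    label: str
    total_cost: float
    total_qalys: float
    cycle_costs: np.ndarray = field(repr=False)
    cycle_qalys: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of a comparator against a reference strategy.

    ``icer`` is None when the incremental effect is zero (undefined ratio;
    the decision then rests on the cost sign alone).  ``reversed_interpretation``
    flags the south-west quadrant (comparator cheaper *and* less effective),
    where the ratio measures savings per QALY forgone and the comparator is
    preferred when the ICER *exceeds* WTP.
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None
    decision: str
    wtp: float
    reversed_interpretation: bool = False


def monthly_discount_factor(annual_rate: float, cycle: int | np.ndarray) -> float | np.ndarray:
    """Discount factor for month ``cycle``: (1 + r)^(-cycle/12), compound."""
    if not 0.0 <= annual_rate < 1.0:
        raise ValueError(f"annual_rate must lie in [0, 1), got {annual_rate!r}")
    return (1.0 + annual_rate) ** (-np.asarray(cycle) / 12.0)


def _alive_discounted(trace: MarkovTrace, annual_discount: float) -> np.ndarray:
    disc = monthly_discount_factor(annual_discount, np.arange(1, trace.n_cycles + 1))
    return disc * (trace.occupancy[:, 0] + trace.occupancy[:, 1])


def _accrue(
    trace: MarkovTrace,
    u_dfs: float,
    u_pd: float,
    initial_cost: float,
    cycle_cost_alive: float,
    annual_discount: float,
    label: str,
) -> EconResult:
    # accrual core shared with the sensitivity analyses, which relax the
    # StrategyParams utility-ordering constraint when perturbing one-at-a-time
    disc = monthly_discount_factor(annual_discount, np.arange(1, trace.n_cycles + 1))
    occ_dfs = trace.occupancy[:, 0]
    occ_pd = trace.occupancy[:, 1]
    cycle_qalys = disc * (occ_dfs * u_dfs + occ_pd * u_pd) / 12.0
    cycle_costs = disc * (occ_dfs + occ_pd) * cycle_cost_alive
    return EconResult(
        label=label,
        total_cost=initial_cost + float(cycle_costs.sum()),
        total_qalys=float(cycle_qalys.sum()),
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
    )


def evaluate_strategy(params: StrategyParams, trace: MarkovTrace) -> EconResult:
    """Accrue discounted cost and QALY totals for one strategy over a trace.

    Per-cycle QALYs are ``disc(t) * (occ_dfs*u_dfs + occ_pd*u_pd) / 12``;
    per-cycle costs are ``disc(t) * (occ_dfs + occ_pd) * cycle_cost_alive``,
    with the initial cost added undiscounted at cycle 0.  Death contributes
    neither cost nor utility.  Totals are exactly linear in each utility and
    in the per-cycle cost.
    """
    return _accrue(
        trace,
        params.u_dfs,
        params.u_pd,
        params.initial_cost,
        params.cycle_cost_alive,
        params.annual_discount,
        params.label,
    )


def run_strategy(
    params: StrategyParams,
    n_cycles: int = 120,
    *,
    half_cycle: bool = True,
    competing_risks: bool = False,
) -> tuple[MarkovTrace, EconResult]:
    """Convenience: build the matrix, run the trace, accrue economics."""
    tm = params.transition_matrix(competing_risks=competing_risks)
    trace = run_trace(tm, n_cycles=n_cycles, half_cycle=half_cycle)
    return trace, evaluate_strategy(params, trace)


def icer(reference: EconResult, comparator: EconResult, wtp: float) -> CEResult:
    """Incremental cost-effectiveness of ``comparator`` versus ``reference``.

    Standard quadrant logic: with positive incremental cost and effect the
    ICER is compared with WTP; a cheaper-and-more-effective comparator is
    dominant, a costlier-and-less-effective one dominated; in the south-west
    quadrant the ratio is reported with a reversed interpretation flag.
    """
    if wtp < 0:
        raise ValueError(f"wtp must be non-negative, got {wtp!r}")
    dc = comparator.total_cost - reference.total_cost
    de = comparator.total_qalys - reference.total_qalys
    reversed_flag = False
    if de == 0.0:
        ratio = None
        if dc > 0:
            decision = "dominated"
        elif dc < 0:
            decision = "dominant"
        else:
            decision = "equivalent"
    else:
        ratio = dc / de
        if de > 0 and dc <= 0:
            decision = "dominant"
        elif de < 0 and dc >= 0:
            decision = "dominated"
        elif de > 0:
            decision = "cost-effective" if ratio < wtp else "not-cost-effective"
        else:  # de < 0 and dc < 0: savings per QALY forgone
            reversed_flag = True
            decision = "cost-effective" if ratio > wtp else "not-cost-effective"
    return CEResult(
        reference=reference.label,
        comparator=comparator.label,
        delta_cost=dc,
        delta_effect=de,
        icer=ratio,
        decision=decision,
        wtp=wtp,
        reversed_interpretation=reversed_flag,
    )


def nmb(result: EconResult, wtp: float) -> float:
    """Net monetary benefit, ``wtp * QALYs - cost``.

    Strategy A is preferred to B at a given WTP iff nmb(A) > nmb(B); with a
    positive incremental effect the indifference WTP equals the pairwise ICER.
    """
    if wtp < 0:
        raise ValueError(f"wtp must be non-negative, got {wtp!r}")
    return wtp * result.total_qalys - result.total_cost


def calibrate_state_costs(
    trace: MarkovTrace,
    target_total_cost: float,
    initial_cost: float,
    annual_discount: float = 0.05,
) -> float:
    """Per-cycle alive cost that makes the discounted total hit a target.

    Solves ``target = initial_cost + c * sum_t disc(t) * alive(t)`` for the
    uniform per-cycle cost ``c`` — an exact linear solve, since the total is
    linear in ``c``.  Used to reconcile per-admission direct costs with
    published cumulative cost totals whose accrual mechanism is unreported.
    """
    if target_total_cost < initial_cost:
        raise ValueError(
            f"target_total_cost {target_total_cost!r} is below initial_cost "
            f"{initial_cost!r}"
        )
    denom = float(_alive_discounted(trace, annual_discount).sum())
    if denom <= 0 or not math.isfinite(denom):
        raise ValueError("trace has no discounted alive person-time to carry costs")
    return (target_total_cost - initial_cost) / denom
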