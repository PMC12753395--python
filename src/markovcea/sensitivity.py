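"""One-way (tornado) and probabilistic sensitivity analyses.

Both analyses perturb a common parameter vector — per-strategy transition
probabilities (the row stay-probability absorbs each perturbation so rows
keep summing to 1), utilities, initial and per-cycle costs, plus the shared
discount rate — and re-run the full pipeline (matrix, trace, economics,
ICER) at the perturbed values.

The one-way analysis moves each parameter to the ends of its +/-20% range
while holding the rest at baseline, producing tornado-diagram entries sorted
by ICER span.  The probabilistic analysis samples all parameters jointly
(default: independent uniforms on the same ranges, capped at 1 for
probabilities and utilities), records per-draw incremental cost and effect,
and summarises decision uncertainty as a cost-effectiveness acceptability
curve (CEAC): the fraction of draws with positive incremental net monetary
benefit at each willingness-to-pay value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import EconResult, StrategyParams, _accrue, icer
from .engine import run_trace
from .transitions import TransitionMatrix, param_range

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CeacCurve",
    "parameter_baselines",
    "default_ranges",
    "one_way_tornado",
    "psa",
    "ceac",
    "default_wtp_grid",
]

# per-strategy parameter suffixes; probabilities/utilities get capped ranges
_PROB_UTIL = ("p_dfs_pd", "p_dfs_d", "p_pd_d", "u_dfs", "u_pd")
_COSTS = ("initial_cost", "cycle_cost_alive")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental (cost, effect) pairs plus the sampled parameters."""

    n_draws: int
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    samples: pd.DataFrame
    seed: int | None


@dataclass(frozen=True)
class CeacCurve:
    """P(comparator cost-effective) over a WTP grid; fractions of PSA draws."""

    wtp: np.ndarray
    probability: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def parameter_baselines(
    reference: StrategyParams,
    comparator: StrategyParams,
    *,
    include_discount: bool = True,
) -> dict[str, float]:
    """Full-precision baseline value of every perturbable parameter.

    Names are ``"<label>.<field>"`` for per-strategy parameters (transition
    probabilities, utilities, costs) plus the shared ``"discount"``.
    """
    out: dict[str, float] = {}
    for s in (reference, comparator):
        tm = s.transition_matrix()
        vals = {
            "p_dfs_pd": tm.p_dfs_pd,
            "p_dfs_d": tm.p_dfs_d,
            "p_pd_d": tm.p_pd_d,
            "u_dfs": s.u_dfs,
            "u_pd": s.u_pd,
            "initial_cost": s.initial_cost,
            "cycle_cost_alive": s.cycle_cost_alive,
        }
        for k, v in vals.items():
            out[f"{s.label}.{k}"] = v
    if include_discount:
        out["discount"] = reference.annual_discount
    return out


def default_ranges(
    baselines: dict[str, float], fraction: float = 0.20
) -> dict[str, tuple[float, float]]:
    """+/-``fraction`` range per parameter, capped at 1 where bounded."""
    ranges = {}
    for name, base in baselines.items():
        bounded = name == "discount" or name.rsplit(".", 1)[-1] in _PROB_UTIL
        ranges[name] = param_range(base, fraction, cap=1.0 if bounded else None)
    return ranges


def _evaluate_pair(
    reference: StrategyParams,
    comparator: StrategyParams,
    values: dict[str, float],
    wtp: float,
    n_cycles: int,
    half_cycle: bool,
) -> tuple[EconResult, EconResult]:
    """Re-run both strategies at a fully specified parameter vector.

    Validation here is structural only (probabilities in [0, 1], rows
    summing to 1 via the residual stay-probability); the utility ordering
    constraint of :class:`StrategyParams` is intentionally not imposed, so
    that independent sampling and one-at-a-time variation remain possible.
    """
    discount = values.get("discount", reference.annual_discount)
    results = []
    for s in (reference, comparator):
        tm = TransitionMatrix(  # raises if any entry leaves [0, 1]
            p_dfs_pd=values[f"{s.label}.p_dfs_pd"],
            p_dfs_d=values[f"{s.label}.p_dfs_d"],
            p_pd_d=values[f"{s.label}.p_pd_d"],
        )
        u_dfs = values[f"{s.label}.u_dfs"]
        u_pd = values[f"{s.label}.u_pd"]
        if not (0.0 <= u_dfs <= 1.0 and 0.0 <= u_pd <= 1.0):
            raise ValueError(f"{s.label}: utilities must lie in [0, 1]")
        init = values[f"{s.label}.initial_cost"]
        cyc = values[f"{s.label}.cycle_cost_alive"]
        if init < 0 or cyc < 0:
            raise ValueError(f"{s.label}: costs must be non-negative")
        trace = run_trace(tm, n_cycles=n_cycles, half_cycle=half_cycle)
        results.append(_accrue(trace, u_dfs, u_pd, init, cyc, discount, s.label))
    return results[0], results[1]


def one_way_tornado(
    reference: StrategyParams,
    comparator: StrategyParams,
    wtp: float,
    *,
    parameters: list[str] | None = None,
    fraction: float = 0.20,
    n_cycles: int = 120,
    half_cycle: bool = True,
) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER to each parameter, sorted by span.

    Each parameter in turn is set to the ends of its range (others at
    baseline) and the pipeline re-run; the recorded ICER is the signed ratio
    delta_cost / delta_effect, so a corner that crosses into dominance shows
    as a negative value rather than a gap.
    """
    baselines = parameter_baselines(reference, comparator)
    if parameters is None:
        parameters = list(baselines)
    unknown = [p for p in parameters if p not in baselines]
    if unknown:
        raise ValueError(f"unknown parameter(s): {unknown}; known: {sorted(baselines)}")
    ranges = default_ranges(baselines, fraction)

    entries = []
    for name in parameters:
        lo, hi = ranges[name]
        icers = []
        for bound in (lo, hi):
            values = dict(baselines)
            values[name] = bound
            ref_res, comp_res = _evaluate_pair(
                reference, comparator, values, wtp, n_cycles, half_cycle
            )
            ce = icer(ref_res, comp_res, wtp)
            icers.append(np.nan if ce.icer is None else ce.icer)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=lo,
                high=hi,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
            )
        )
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def psa(
    reference: StrategyParams,
    comparator: StrategyParams,
    *,
    distributions: dict[str, tuple[float, float]] | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
    fraction: float = 0.20,
    include_discount: bool = False,
    n_cycles: int = 120,
    half_cycle: bool = True,
    max_retries: int = 100,
) -> PSAResult:
    """Monte Carlo re-evaluation of the model under parameter uncertainty.

    Every parameter is sampled independently per draw — by default uniform on
    its +/-``fraction`` range (probabilities and utilities capped at 1) — the
    matrices are rebuilt with the stay-probabilities absorbing the
    perturbations, both strategies re-run, and the incremental (cost, effect)
    pair recorded.  A draw whose sampled vector is structurally invalid (a
    matrix entry outside [0, 1] after renormalisation) is resampled, with a
    hard cap of ``max_retries`` attempts per draw.  Deterministic given
    ``seed``.  The discount rate is excluded by default.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    baselines = parameter_baselines(
        reference, comparator, include_discount=include_discount
    )
    if distributions is None:
        distributions = default_ranges(baselines, fraction)
    else:
        unknown = [p for p in distributions if p not in baselines]
        if unknown:
            raise ValueError(f"unknown parameter(s) in distributions: {unknown}")
    names = list(baselines)
    rng = np.random.default_rng(seed)

    dc = np.empty(n_draws)
    de = np.empty(n_draws)
    rows = []
    for i in range(n_draws):
        for attempt in range(max_retries):
            values = dict(baselines)
            for name in names:
                if name in distributions:
                    lo, hi = distributions[name]
                    values[name] = rng.uniform(lo, hi)
            try:
                ref_res, comp_res = _evaluate_pair(
                    reference, comparator, values, 0.0, n_cycles, half_cycle
                )
            except ValueError:
                continue
            break
        else:
            raise RuntimeError(
                f"draw {i}: no valid parameter vector in {max_retries} attempts"
            )
        dc[i] = comp_res.total_cost - ref_res.total_cost
        de[i] = comp_res.total_qalys - ref_res.total_qalys
        rows.append(values)
    samples = pd.DataFrame(rows, columns=names)
    return PSAResult(n_draws=n_draws, delta_cost=dc, delta_effect=de, samples=samples, seed=seed)


def default_wtp_grid() -> np.ndarray:
    """0 to 400,000 yuan/QALY in 10,000-yuan steps."""
    return np.arange(0, 400_001, 10_000, dtype=float)


def ceac(psa_result: PSAResult, wtp_grid: np.ndarray | None = None) -> CeacCurve:
    """Cost-effectiveness acceptability curve from PSA draws.

    At each WTP the probability is the exact fraction of draws with positive
    incremental net monetary benefit, ``wtp * delta_effect - delta_cost > 0``.
    """
    if psa_result.n_draws == 0 or psa_result.delta_cost.size == 0:
        raise ValueError("PSA result has no draws")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("wtp_grid is empty")
    if np.any(grid < 0):
        raise ValueError("wtp values must be non-negative")
    inmb = grid[:, None] * psa_result.delta_effect[None, :] - psa_result.delta_cost[None, :]
    prob = (inmb > 0).mean(axis=1)
    return CeacCurve(wtp=grid, probability=prob)
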