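"""Pipeline stages tying cohort simulation, the model run and the
sensitivity analyses together, with artifact serialisation.

Each stage writes plain-text artifacts (CSV tables, a JSON summary) into an
output directory; identical configuration and seed yield identical files.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .config import AnalysisConfig
from .economics import (
    StrategyParams,
    calibrate_state_costs,
    evaluate_strategy,
    icer,
)
from .engine import run_trace, trace_frame
from .sensitivity import ceac, one_way_tornado, psa
from .transitions import probability_table

log = logging.getLogger("markovcea")

__all__ = ["resolve_strategies", "run_pipeline"]


def _pkg_version() -> str:
    try:
        return version("markovcea")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def resolve_strategies(config: AnalysisConfig) -> tuple[StrategyParams, StrategyParams]:
    """Materialise both strategies, calibrating per-cycle costs where the
    configuration gives a cumulative cost target instead of a known value."""
    resolved: dict[str, float] = {}
    for s in config.strategies:
        if s.cycle_cost_alive is None:
            from .transitions import build_transition_matrix

            tm = build_transition_matrix(
                s.median_dfs, s.median_os, competing_risks=config.competing_risks
            )
            trace = run_trace(tm, n_cycles=config.n_cycles, half_cycle=config.half_cycle)
            resolved[s.label] = calibrate_state_costs(
                trace, s.calibration_target, s.initial_cost, config.discount
            )
            log.info(
                "calibrated %s cycle cost to %.4f RMB/month (target %.2f)",
                s.label,
                resolved[s.label],
                s.calibration_target,
            )
    return config.strategy_params(resolved)


def _stage_simulate(config: AnalysisConfig, out: Path, seed: int | None) -> None:
    cc = config.cohort
    ref, comp = config.strategies
    cohort_cfg = cohort_mod.CohortConfig(
        n_per_arm=cc.n_per_arm,
        median_dfs={s.label: s.median_dfs for s in (ref, comp)},
        median_pps={s.label: s.median_os - s.median_dfs for s in (ref, comp)},
        cost_mean={s.label: s.initial_cost for s in (ref, comp)},
        cost_cv=cc.cost_cv,
        accrual_window=cc.accrual_window,
        followup_cutoff=cc.followup_cutoff,
        seed=cc.seed if seed is None else seed,
    )
    records = cohort_mod.generate_cohort(cohort_cfg)
    cohort_mod.write_cohort(records, out / "cohort.csv")
    summary = {
        arm: {
            "median_dfs": s.median_dfs,
            "median_os": s.median_os,
            "mean_cost": round(s.mean_cost, 2),
            "n": s.n,
        }
        for arm, s in cohort_mod.summarize_cohort(records).items()
    }
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    log.info("simulate: wrote %d records to %s", len(records), out / "cohort.csv")


def _stage_run(config: AnalysisConfig, out: Path) -> None:
    ref, comp = resolve_strategies(config)
    results = {}
    for s in (ref, comp):
        probability_table(s.median_dfs, s.median_os, config.sensitivity.fraction).to_csv(
            out / f"transition_probabilities_{s.label}.csv", index=False
        )
        trace = run_trace(
            s.transition_matrix(competing_risks=config.competing_risks),
            n_cycles=config.n_cycles,
            half_cycle=config.half_cycle,
        )
        trace_frame(trace).to_csv(
            out / f"trace_{s.label}.csv", index=False, float_format="%.10f"
        )
        results[s.label] = evaluate_strategy(s, trace)
    ce = icer(results[ref.label], results[comp.label], config.wtp)
    summary = {
        "version": _pkg_version(),
        "n_cycles": config.n_cycles,
        "discount": config.discount,
        "wtp": config.wtp,
        "strategies": {
            label: {
                "total_cost": round(r.total_cost, 2),
                "total_qalys": round(r.total_qalys, 4),
                "cycle_cost_alive": next(
                    s.cycle_cost_alive for s in (ref, comp) if s.label == label
                ),
            }
            for label, r in results.items()
        },
        "delta_cost": round(ce.delta_cost, 2),
        "delta_effect": round(ce.delta_effect, 4),
        "icer": None if ce.icer is None else round(ce.icer, 2),
        "decision": ce.decision,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame(
        [
            {
                "strategy": label,
                "cumulative_cost": round(r.total_cost, 2),
                "effects_qalys": round(r.total_qalys, 4),
            }
            for label, r in results.items()
        ]
    ).to_csv(out / "cost_effectiveness.csv", index=False)
    log.info("run: ICER %s, decision %s", summary["icer"], ce.decision)


def _stage_tornado(config: AnalysisConfig, out: Path) -> None:
    ref, comp = resolve_strategies(config)
    entries = one_way_tornado(
        ref,
        comp,
        config.wtp,
        fraction=config.sensitivity.fraction,
        n_cycles=config.n_cycles,
        half_cycle=config.half_cycle,
    )
    pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "span": e.span,
            }
            for e in entries
        ]
    ).to_csv(out / "tornado.csv", index=False)
    log.info("tornado: %d parameters, widest span %s", len(entries), entries[0].parameter)


def _stage_psa(config: AnalysisConfig, out: Path, seed: int | None) -> None:
    ref, comp = resolve_strategies(config)
    sens = config.sensitivity
    result = psa(
        ref,
        comp,
        n_draws=sens.n_draws,
        seed=sens.seed if seed is None else seed,
        fraction=sens.fraction,
        include_discount=sens.include_discount_in_psa,
        n_cycles=config.n_cycles,
        half_cycle=config.half_cycle,
    )
    pd.DataFrame(
        {
            "draw": np.arange(result.n_draws),
            "delta_cost": result.delta_cost,
            "delta_effect": result.delta_effect,
        }
    ).to_csv(out / "psa_draws.csv", index=False, float_format="%.6f")
    grid = np.arange(0.0, sens.wtp_grid_max + sens.wtp_grid_step, sens.wtp_grid_step)
    ceac(result, grid).frame().to_csv(out / "ceac.csv", index=False)
    log.info("psa: %d draws, seed %s", result.n_draws, result.seed)


def _stage_report(config: AnalysisConfig, out: Path) -> None:
    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"report requires a prior 'run' stage: {summary_path} not found"
        )
    report = json.loads(summary_path.read_text())
    for name in ("tornado.csv", "ceac.csv", "cohort_summary.json"):
        p = out / name
        if p.exists():
            if name.endswith(".json"):
                report[name.removesuffix(".json")] = json.loads(p.read_text())
            else:
                report[name.removesuffix(".csv") + "_top"] = (
                    pd.read_csv(p).head(5).to_dict(orient="records")
                )
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("report: collated into %s", out / "report.json")


_STAGES = {
    "simulate": lambda cfg, out, seed: _stage_simulate(cfg, out, seed),
    "run": lambda cfg, out, seed: _stage_run(cfg, out),
    "tornado": lambda cfg, out, seed: _stage_tornado(cfg, out),
    "psa": lambda cfg, out, seed: _stage_psa(cfg, out, seed),
    "report": lambda cfg, out, seed: _stage_report(cfg, out),
}


def run_pipeline(
    config: AnalysisConfig,
    command: str,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Execute one pipeline stage, writing artifacts into ``out_dir``.

    ``seed`` overrides the configured seed for the stochastic stages
    (``simulate``, ``psa``); deterministic stages ignore it.
    """
    if command not in _STAGES:
        raise ValueError(f"unknown command {command!r}; choose from {sorted(_STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage %s -> %s (markovcea %s)", command, out, _pkg_version())
    _STAGES[command](config, out, seed)
    return out
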