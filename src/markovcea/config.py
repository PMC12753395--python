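"""Analysis configuration: validated settings loaded from JSON or YAML."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .economics import StrategyParams

__all__ = [
    "StrategyConfig",
    "SensitivityConfig",
    "CohortSection",
    "AnalysisConfig",
    "load_config",
    "dump_config",
]


class StrategyConfig(BaseModel):
    """One strategy block.

    Exactly one of ``cycle_cost_alive`` (a known per-cycle cost) or
    ``calibration_target`` (a cumulative discounted cost total that the
    per-cycle cost should be solved to reproduce) must be provided.
    """

    label: str
    median_dfs: float = Field(gt=0)
    median_os: float = Field(gt=0)
    u_dfs: float = Field(ge=0, le=1)
    u_pd: float = Field(ge=0, le=1)
    initial_cost: float = Field(ge=0)
    cycle_cost_alive: float | None = Field(default=None, ge=0)
    calibration_target: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "StrategyConfig":
        if self.median_os <= self.median_dfs:
            raise ValueError(
                f"{self.label}: median_os ({self.median_os}) must exceed "
                f"median_dfs ({self.median_dfs})"
            )
        if self.u_pd > self.u_dfs:
            raise ValueError(f"{self.label}: u_pd must not exceed u_dfs")
        if (self.cycle_cost_alive is None) == (self.calibration_target is None):
            raise ValueError(
                f"{self.label}: provide exactly one of cycle_cost_alive or "
                "calibration_target"
            )
        return self


class SensitivityConfig(BaseModel):
    fraction: float = Field(default=0.20, gt=0, lt=1)
    n_draws: int = Field(default=1000, ge=1)
    seed: int = 20170301
    include_discount_in_psa: bool = False
    wtp_grid_max: float = Field(default=400_000.0, gt=0)
    wtp_grid_step: float = Field(default=10_000.0, gt=0)


class CohortSection(BaseModel):
    """Knobs for the ``simulate`` stage (synthetic cohort generation)."""

    n_per_arm: int = Field(default=100, ge=2)
    cost_cv: float = Field(default=0.3, gt=0)
    accrual_window: float = Field(default=46.0, ge=0)
    followup_cutoff: float = Field(default=87.0, gt=0)
    seed: int = 20170301


class AnalysisConfig(BaseModel):
    """Full two-strategy analysis: model horizon, WTP rule, sensitivity."""

    strategies: list[StrategyConfig]
    n_cycles: int = Field(default=120, ge=1)
    wtp: float = Field(default=268_074.00, ge=0)
    discount: float = Field(default=0.05, ge=0, lt=1)
    half_cycle: bool = True
    competing_risks: bool = False
    sensitivity: SensitivityConfig = SensitivityConfig()
    cohort: CohortSection = CohortSection()

    @model_validator(mode="after")
    def _two_strategies(self) -> "AnalysisConfig":
        if len(self.strategies) != 2:
            raise ValueError(
                f"exactly two strategy blocks required, got {len(self.strategies)}"
            )
        labels = [s.label for s in self.strategies]
        if labels[0] == labels[1]:
            raise ValueError(f"strategy labels must differ, both are {labels[0]!r}")
        return self

    def strategy_params(self, resolved_cycle_costs: dict[str, float] | None = None
                        ) -> tuple[StrategyParams, StrategyParams]:
        """Materialise :class:`StrategyParams` for both arms.

        Strategies configured with a ``calibration_target`` need their
        per-cycle cost supplied via ``resolved_cycle_costs`` (label -> value);
        see :func:`markovcea.pipeline.resolve_strategies`.
        """
        out = []
        for s in self.strategies:
            cyc = s.cycle_cost_alive
            if cyc is None:
                if resolved_cycle_costs is None or s.label not in resolved_cycle_costs:
                    raise ValueError(
                        f"{s.label}: cycle cost requires calibration; use "
                        "markovcea.pipeline.resolve_strategies"
                    )
                cyc = resolved_cycle_costs[s.label]
            out.append(
                StrategyParams(
                    label=s.label,
                    median_dfs=s.median_dfs,
                    median_os=s.median_os,
                    u_dfs=s.u_dfs,
                    u_pd=s.u_pd,
                    initial_cost=s.initial_cost,
                    cycle_cost_alive=cyc,
                    annual_discount=self.discount,
                )
            )
        return out[0], out[1]


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a JSON or YAML configuration file.

    Validation failures raise with the offending field path (pydantic).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"configuration file {path} is empty")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:  # yaml is a superset of json, so this also covers unknown suffixes
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return AnalysisConfig.model_validate(data)


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    """Serialise a configuration back to JSON or YAML (round-trips exactly)."""
    path = Path(path)
    data = config.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
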