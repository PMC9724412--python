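"""Deterministic (one-way) and probabilistic sensitivity analysis.

One-way analysis re-runs the base case with a single parameter perturbed —
relative ±5%/±10% shifts or the parameter's deterministic range bounds — and
reports the resulting incremental statistics in tornado order.  The PSA draws
all parameters simultaneously from their moment-matched distributions,
re-runs both arms per draw, and summarizes the (ΔCost, ΔQALY) cloud as a
cost-effectiveness plane and an acceptability curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import ThresholdPolicy, classify_quadrant, incremental, verdict
from .errors import DomainError
from .markov import ModelSettings, run_arm
from .parameters import (
    QUANTITY_NAMES,
    ParameterSet,
    draw_from_means,
    sample_draw,
)

log = logging.getLogger(__name__)

PERTURBATIONS = (
    "minus_10pct",
    "minus_5pct",
    "plus_5pct",
    "plus_10pct",
    "range_low",
    "range_high",
)

_RELATIVE = {
    "minus_10pct": 0.90,
    "minus_5pct": 0.95,
    "plus_5pct": 1.05,
    "plus_10pct": 1.10,
}

#: parameters exercised by the default scenario set: every cost, utility,
#: switch and complication parameter.  Single survival years are excluded
#: (perturbing one year alone usually breaks curve monotonicity) but can be
#: requested explicitly.
SCENARIO_TARGETS = tuple(
    n for n in QUANTITY_NAMES if not n.startswith(("discount_", "surv_"))
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One one-way scenario: a target parameter and how to perturb its mean."""

    target: str
    perturbation: str

    def __post_init__(self):
        if self.perturbation not in PERTURBATIONS:
            raise DomainError(f"unknown perturbation '{self.perturbation}'")

    def perturbed_mean(self, params: ParameterSet) -> float | None:
        q = params[self.target]
        if self.perturbation == "range_low":
            return q.range_low
        if self.perturbation == "range_high":
            return q.range_high
        return q.mean * _RELATIVE[self.perturbation]


@dataclass(frozen=True)
class PsaSample:
    """One Monte-Carlo draw's incremental outcomes (intervention − comparator)."""

    index: int
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class CeacCurve:
    """Probability of positive net monetary benefit along a WTP grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.wtp, "prob_cost_effective": self.probability})


def default_scenarios(params: ParameterSet) -> list[ScenarioSpec]:
    """±5%, ±10% and range-bound scenarios for every non-structural parameter."""
    specs = []
    for name in SCENARIO_TARGETS:
        q = params[name]
        for pert in ("minus_10pct", "minus_5pct", "plus_5pct", "plus_10pct"):
            specs.append(ScenarioSpec(name, pert))
        if q.range_low is not None and q.range_high is not None:
            specs.append(ScenarioSpec(name, "range_low"))
            specs.append(ScenarioSpec(name, "range_high"))
    return specs


def _incremental_at_means(params: ParameterSet, settings: ModelSettings):
    draw = draw_from_means(params)
    capd = run_arm(draw, "CAPD", settings)
    hd = run_arm(draw, "HD", settings)
    return capd, hd, incremental(capd, hd)


def run_one_way(
    params: ParameterSet,
    scenarios: list[ScenarioSpec] | None = None,
    settings: ModelSettings = ModelSettings(),
) -> pd.DataFrame:
    """Scenario table: base case first, then scenarios in tornado order.

    Probabilities and utilities are clipped to [0, 1] after perturbation
    (with a logged warning); a scenario whose perturbed parameter is
    infeasible is marked failed and the run continues.
    """
    if scenarios is None:
        scenarios = default_scenarios(params)
    policy = ThresholdPolicy.from_gdp(params.gdp_per_capita)
    _, _, base = _incremental_at_means(params, settings)
    rows = [
        {
            "scenario": "base case",
            "target": "",
            "perturbation": "",
            "value": np.nan,
            "delta_cost": base.delta_cost,
            "delta_qaly": base.delta_qaly,
            "icer": base.icer,
            "quadrant": base.quadrant,
            "verdict": verdict(base, policy),
            "failed": False,
        }
    ]
    scenario_rows = []
    from .parameters import UNIT_INTERVAL_NAMES  # local import avoids cycle noise

    for spec in scenarios:
        value = spec.perturbed_mean(params)
        row = {
            "scenario": f"{spec.target} {spec.perturbation}",
            "target": spec.target,
            "perturbation": spec.perturbation,
            "value": np.nan if value is None else value,
            "delta_cost": np.nan,
            "delta_qaly": np.nan,
            "icer": np.nan,
            "quadrant": "",
            "verdict": "",
            "failed": True,
        }
        if value is None:
            scenario_rows.append(row)
            continue
        if spec.target in UNIT_INTERVAL_NAMES and not 0.0 <= value <= 1.0:
            clipped = min(max(value, 0.0), 1.0)
            log.warning(
                "scenario %s: perturbed value %.4g clipped to %.4g",
                row["scenario"], value, clipped,
            )
            value = clipped
            row["value"] = value
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                perturbed = params.replace_mean(spec.target, value)
                perturbed.validate()
                _, _, inc = _incremental_at_means(perturbed, settings)
        except Exception as exc:  # infeasible scenario: record and continue
            log.warning("scenario %s failed: %s", row["scenario"], exc)
            scenario_rows.append(row)
            continue
        row.update(
            delta_cost=inc.delta_cost,
            delta_qaly=inc.delta_qaly,
            icer=np.nan if inc.icer is None else inc.icer,
            quadrant=inc.quadrant,
            verdict=verdict(inc, policy),
            failed=False,
        )
        scenario_rows.append(row)

    base_icer = base.icer if base.icer is not None else 0.0
    scenario_rows.sort(
        key=lambda r: (
            -abs((r["icer"] if np.isfinite(r["icer"]) else base_icer) - base_icer),
        )
    )
    return pd.DataFrame(rows + scenario_rows)


def run_psa(
    params: ParameterSet,
    iterations: int = 1000,
    seed: int | None = None,
    settings: ModelSettings = ModelSettings(),
) -> list[PsaSample]:
    """Monte-Carlo PSA: per iteration, draw all parameters and run both arms.

    Reproducible given the seed.  An iteration raising a numerical error is
    skipped (not resampled, keeping the draw stream aligned with the seed)
    and reported via logging.
    """
    if iterations < 0:
        raise DomainError("iterations must be >= 0")
    rng = np.random.default_rng(seed)
    samples: list[PsaSample] = []
    failures = 0
    for i in range(iterations):
        draw = sample_draw(params, rng, index=i, seed=seed)
        try:
            capd = run_arm(draw, "CAPD", settings)
            hd = run_arm(draw, "HD", settings)
        except Exception as exc:
            failures += 1
            log.warning("PSA iteration %d failed: %s", i, exc)
            continue
        samples.append(
            PsaSample(
                index=i,
                delta_cost=capd.total_cost_discounted - hd.total_cost_discounted,
                delta_qaly=capd.total_qaly_discounted - hd.total_qaly_discounted,
            )
        )
    if failures:
        log.warning("PSA finished with %d/%d failed iterations", failures, iterations)
    return samples


def default_wtp_grid(upper: float = 200_000_000.0, steps: int = 41) -> np.ndarray:
    """Willingness-to-pay grid, 0 to 200M IDR/QALY in 41 steps by default."""
    return np.linspace(0.0, upper, steps)


def compute_ceac(samples: list[PsaSample], wtp_grid=None) -> CeacCurve:
    """Fraction of draws with positive NMB at each willingness-to-pay value.

    An exact zero NMB counts as not cost-effective (strict inequality).
    """
    if not samples:
        raise DomainError("CEAC requires at least one PSA sample")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise DomainError("WTP grid must be strictly increasing")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    return CeacCurve(wtp=grid, probability=(nmb > 0).mean(axis=1))


def export_ce_plane(samples: list[PsaSample]) -> pd.DataFrame:
    """(ΔQALY, ΔCost) point table with quadrant labels, ready for plotting."""
    rows = [
        {
            "draw": s.index,
            "delta_qaly": s.delta_qaly,
            "delta_cost": s.delta_cost,
            "quadrant": classify_quadrant(s.delta_cost, s.delta_qaly),
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["draw", "delta_qaly", "delta_cost", "quadrant"])


def quadrant_counts(samples: list[PsaSample]) -> dict[str, int]:
    table = export_ce_plane(samples)
    if table.empty:
        return {}
    return table["quadrant"].value_counts().to_dict()
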