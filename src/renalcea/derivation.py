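"""Parameter derivation from patient-level records.

Mirrors the study's data stage: EQ-5D-3L responses are scored to utilities
with an additive country tariff, monthly expenditures are annualized by
multiplying by twelve, costs are inflated to the analysis year by a consumer
price index ratio, and per-arm means with standard errors (sample SD/√n)
are produced under the same names the model's parameter table uses — so a
derived table can feed the Markov model directly.

The Thai EQ-5D-3L tariff used by the study is not published alongside it;
the tariff is therefore a pluggable config.  A clearly labelled synthetic
("toy") tariff ships for tests and examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError
from .parameters import ARMS

EQ5D_DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

ANALYSIS_YEAR = 2020


@dataclass(frozen=True)
class ValueSetTariff:
    """Additive EQ-5D-3L tariff.

    utility = anchor − constant·[any dim > 1] − any_level3·[any dim = 3]
              − Σ decrements[dim][level].
    Scoring full health (11111) always returns the anchor.
    """

    decrements: Mapping[str, Mapping[int, float]]
    anchor: float = 1.0
    constant: float = 0.0
    any_level3: float = 0.0

    def __post_init__(self):
        for dim in EQ5D_DIMENSIONS:
            if dim not in self.decrements:
                raise ConfigError(f"tariff missing dimension '{dim}'")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ValueSetTariff":
        dec = {
            dim: {int(k): float(v) for k, v in data["decrements"][dim].items()}
            for dim in data.get("decrements", {})
        }
        return cls(
            decrements=dec,
            anchor=float(data.get("anchor", 1.0)),
            constant=float(data.get("constant", 0.0)),
            any_level3=float(data.get("any_level3", 0.0)),
        )

    @classmethod
    def load(cls, path) -> "ValueSetTariff":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def toy_tariff() -> ValueSetTariff:
    """The shipped synthetic tariff (for tests/examples; not a published value set)."""
    ref = resources.files("renalcea.data").joinpath("tariff_toy.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return ValueSetTariff.from_dict(yaml.safe_load(fh))


def score_eq5d(response, tariff: ValueSetTariff) -> float:
    """Utility of a five-digit EQ-5D-3L health state under an additive tariff."""
    digits = _parse_response(response)
    utility = tariff.anchor
    if any(d > 1 for d in digits):
        utility -= tariff.constant
    if any(d == 3 for d in digits):
        utility -= tariff.any_level3
    for dim, level in zip(EQ5D_DIMENSIONS, digits):
        if level > 1:
            utility -= tariff.decrements[dim].get(level, 0.0)
    return utility


def _parse_response(response) -> tuple[int, ...]:
    if isinstance(response, str):
        seq: Sequence = [c for c in response]
    else:
        seq = list(response)
    if len(seq) != 5:
        raise DomainError(f"EQ-5D-3L response must have 5 digits, got {response!r}")
    digits = []
    for dim, raw in zip(EQ5D_DIMENSIONS, seq):
        try:
            level = int(raw)
        except (TypeError, ValueError):
            level = -1
        if level not in (1, 2, 3):
            raise DomainError(f"invalid level {raw!r} for dimension '{dim}'")
        digits.append(level)
    return tuple(digits)


@dataclass(frozen=True)
class PatientRecord:
    """One interviewed/billed patient, as the derivation stage consumes it."""

    id: str
    arm: str
    age: float
    gender: str
    distance_km: float
    monthly_dmc: float
    monthly_dnmc: float
    monthly_indirect: float
    setup_cost: float
    had_complication: bool
    complication_cost: float
    eq5d_response: str
    observation_year: int = 2015

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise DomainError(f"record {self.id}: arm must be one of {ARMS}")
        for name in ("monthly_dmc", "monthly_dnmc", "monthly_indirect",
                     "setup_cost", "complication_cost"):
            if getattr(self, name) < 0:
                raise DomainError(f"record {self.id}: negative {name}")
        _parse_response(self.eq5d_response)


RECORD_COLUMNS = (
    "id", "arm", "age", "gender", "distance_km", "monthly_dmc", "monthly_dnmc",
    "monthly_indirect", "setup_cost", "had_complication", "complication_cost",
    "eq5d_response", "observation_year",
)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)


def write_records(records: Iterable[PatientRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"eq5d_response": str})
    records = []
    for row in df.itertuples(index=False):
        rec = PatientRecord(
            id=str(row.id), arm=str(row.arm), age=float(row.age),
            gender=str(row.gender), distance_km=float(row.distance_km),
            monthly_dmc=float(row.monthly_dmc), monthly_dnmc=float(row.monthly_dnmc),
            monthly_indirect=float(row.monthly_indirect),
            setup_cost=float(row.setup_cost),
            had_complication=bool(row.had_complication),
            complication_cost=float(row.complication_cost),
            eq5d_response=str(row.eq5d_response),
            observation_year=int(row.observation_year),
        )
        rec.validate()
        records.append(rec)
    return records


def annualize_cost(monthly: float) -> float:
    """Annual cost from a monthly expenditure (×12)."""
    if monthly < 0:
        raise DomainError(f"monthly cost must be >= 0, got {monthly}")
    return monthly * 12.0


def inflate_to_year(value: float, from_year: int, to_year: int,
                    index_table: Mapping[int, float]) -> float:
    """Rescale a cost by the price-index ratio between two years."""
    for year in (from_year, to_year):
        if year not in index_table:
            raise DomainError(f"year {year} missing from the price index table")
    return value * index_table[to_year] / index_table[from_year]


def identity_cpi(years=range(2010, 2031)) -> dict[int, float]:
    """Default no-op price index (inputs already at analysis-year prices)."""
    return {int(y): 1.0 for y in years}


@dataclass(frozen=True)
class SummaryStatistic:
    name: str
    mean: float
    se: float
    n: int


def _mean_se(values: np.ndarray, name: str) -> SummaryStatistic:
    n = len(values)
    se = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return SummaryStatistic(name=name, mean=float(np.mean(values)), se=se, n=n)


def summarize_arm(
    records: Sequence[PatientRecord],
    tariff: ValueSetTariff,
    cpi: Mapping[int, float] | None = None,
    to_year: int = ANALYSIS_YEAR,
) -> list[SummaryStatistic]:
    """Per-arm mean/SE statistics keyed by the model's parameter names.

    Costs are annualized (×12 for monthly components), inflated to
    ``to_year``, and summarized as mean with SE = sample SD/√n.  Complication
    costs are averaged among patients with a complication.  Utilities are
    tariff-scored EQ-5D-3L responses.
    """
    cpi = identity_cpi() if cpi is None else cpi
    stats: list[SummaryStatistic] = []
    for arm in ARMS:
        arm_records = [r for r in records if r.arm == arm]
        if len(arm_records) < 2:
            raise DomainError(
                f"need at least 2 records in arm {arm} to estimate a standard error"
            )
        key = arm.lower()

        def infl(value, rec):
            return inflate_to_year(value, rec.observation_year, to_year, cpi)

        stats.append(_mean_se(np.array(
            [infl(annualize_cost(r.monthly_dmc), r) for r in arm_records]
        ), f"dmc_{key}"))
        stats.append(_mean_se(np.array(
            [infl(annualize_cost(r.monthly_dnmc), r) for r in arm_records]
        ), f"dnmc_{key}"))
        stats.append(_mean_se(np.array(
            [infl(annualize_cost(r.monthly_indirect), r) for r in arm_records]
        ), f"id_{key}"))
        stats.append(_mean_se(np.array(
            [infl(r.setup_cost, r) for r in arm_records]
        ), f"setup_{key}"))

        cases = [r for r in arm_records if r.had_complication]
        if len(cases) >= 2:
            stats.append(_mean_se(np.array(
                [infl(r.complication_cost, r) for r in cases]
            ), f"cc_{key}"))
        comp_name = "p_peritonitis" if arm == "CAPD" else "p_vascular"
        stats.append(_mean_se(
            np.array([float(r.had_complication) for r in arm_records]), comp_name
        ))
        stats.append(_mean_se(np.array(
            [score_eq5d(r.eq5d_response, tariff) for r in arm_records]
        ), f"u_{key}"))
    return stats


def summaries_to_parameter_patch(stats: Sequence[SummaryStatistic]) -> dict:
    """Summary statistics as a parameter-config fragment (mean/se/family)."""
    patch = {}
    for s in stats:
        family = "beta" if (s.name.startswith(("u_", "p_"))) else "gamma"
        patch[s.name] = {"mean": s.mean, "se": s.se, "family": family}
    return {"parameters": patch}
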