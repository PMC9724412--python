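"""Model parameters and their uncertainty distributions.

Every model input is an :class:`UncertainQuantity` — a mean with a standard
error, a deterministic range for scenario analysis, and a distribution family
(Beta for probabilities and utilities, Gamma for costs, or fixed).  Beta and
Gamma shapes are recovered from the printed mean/SE by the method of moments,
so each matched distribution reproduces those two moments exactly.

A :class:`ParameterSet` bundles the full input table (switch probabilities,
five-year survival per modality, annual cost components, utilities, discount
rates) together with run-level scalars (horizon, start age, the GDP-per-capita
willingness-to-pay anchor).  Probabilistic sensitivity analysis draws one
realized value per quantity, independently, via :func:`sample_draw`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigError, DomainError, InfeasibleMomentsError, ValidationError

ARMS = ("CAPD", "HD")

#: canonical quantity names, in the fixed order used for sampling
QUANTITY_NAMES = (
    "p_capd_to_hd",
    "p_hd_to_capd",
    "p_peritonitis",
    "p_vascular",
    "surv_capd_1", "surv_capd_2", "surv_capd_3", "surv_capd_4", "surv_capd_5",
    "surv_hd_1", "surv_hd_2", "surv_hd_3", "surv_hd_4", "surv_hd_5",
    "setup_capd", "setup_hd",
    "dmc_capd", "dmc_hd",
    "cc_capd", "cc_hd",
    "dnmc_capd", "dnmc_hd",
    "id_capd", "id_hd",
    "u_capd", "u_hd", "u_capd_com", "u_hd_com",
    "discount_cost", "discount_effect",
)

#: names whose values live on [0, 1]
UNIT_INTERVAL_NAMES = frozenset(
    n for n in QUANTITY_NAMES
    if n.startswith(("p_", "surv_", "u_", "discount_"))
)

FAMILIES = ("beta", "gamma", "fixed")


class ParameterWarning(UserWarning):
    """Non-fatal oddity in a parameter table (e.g. a reversed range)."""


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) shape parameters with the given mean and SD.

    Method of moments: ``nu = mean*(1-mean)/se**2 - 1`` is the effective
    sample size, split between the shapes in proportion to the mean.

    Raises
    ------
    DomainError
        if ``mean`` is 0 or 1 (degenerate; use family ``fixed`` instead).
    InfeasibleMomentsError
        if ``se**2 >= mean*(1-mean)``, which no Beta can achieve.
    """
    if not 0.0 < mean < 1.0:
        raise DomainError(f"beta mean must lie strictly inside (0, 1), got {mean}")
    if se <= 0.0:
        raise DomainError(f"beta se must be positive, got {se}")
    limit = mean * (1.0 - mean)
    if se * se >= limit:
        raise InfeasibleMomentsError(
            f"se^2={se*se:.6g} >= mean*(1-mean)={limit:.6g}: "
            "no Beta distribution has these moments"
        )
    nu = limit / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and SD.

    shape = mean^2/se^2, scale = se^2/mean.
    """
    if mean <= 0.0 or se <= 0.0:
        raise DomainError(f"gamma moments must be positive, got mean={mean}, se={se}")
    return mean * mean / (se * se), se * se / mean


@dataclass(frozen=True)
class UncertainQuantity:
    """One model input: mean, SE, deterministic range and distribution family."""

    name: str
    mean: float
    se: float = 0.0
    range_low: float | None = None
    range_high: float | None = None
    family: str = "fixed"

    def problems(self) -> tuple[list[str], list[str]]:
        """Return (errors, warnings) describing invariant violations."""
        errors: list[str] = []
        warns: list[str] = []
        if self.family not in FAMILIES:
            errors.append(f"{self.name}: unknown family '{self.family}'")
            return errors, warns
        if self.se < 0.0:
            errors.append(f"{self.name}: negative se {self.se}")
        if self.name in UNIT_INTERVAL_NAMES and not 0.0 <= self.mean <= 1.0:
            errors.append(f"{self.name}: mean {self.mean} outside [0, 1]")
        if self.family == "beta":
            if not 0.0 < self.mean < 1.0:
                errors.append(f"{self.name}: beta mean {self.mean} not in (0, 1)")
            elif self.se <= 0.0:
                errors.append(f"{self.name}: beta family requires se > 0")
            elif self.se ** 2 >= self.mean * (1.0 - self.mean):
                errors.append(
                    f"{self.name}: se^2 >= mean*(1-mean), Beta moments infeasible"
                )
        elif self.family == "gamma":
            if self.mean <= 0.0:
                errors.append(f"{self.name}: gamma mean {self.mean} must be > 0")
            elif self.se <= 0.0:
                errors.append(f"{self.name}: gamma family requires se > 0")
        if self.range_low is not None and self.range_high is not None:
            if not self.range_low <= self.mean <= self.range_high:
                warns.append(
                    f"{self.name}: mean {self.mean} outside range "
                    f"[{self.range_low}, {self.range_high}] (shipped as printed)"
                )
        return errors, warns

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one realization from the moment-matched distribution."""
        if self.family == "fixed":
            return self.mean
        if self.family == "beta":
            a, b = beta_from_moments(self.mean, self.se)
            return float(rng.beta(a, b))
        shape, scale = gamma_from_moments(self.mean, self.se)
        return float(rng.gamma(shape, scale))


@dataclass(frozen=True)
class ParameterSet:
    """All model inputs plus run-level scalars."""

    quantities: Mapping[str, UncertainQuantity]
    horizon_years: int = 40
    start_age: float = 55.0
    gdp_per_capita: float = 54_600_000.0
    exchange_rate_idr_per_usd: float = 14_121.0

    def __getitem__(self, name: str) -> UncertainQuantity:
        return self.quantities[name]

    def survival(self, arm: str) -> list[UncertainQuantity]:
        key = arm.lower()
        return [self.quantities[f"surv_{key}_{y}"] for y in range(1, 6)]

    @property
    def discount_cost(self) -> float:
        return self.quantities["discount_cost"].mean

    @property
    def discount_effect(self) -> float:
        return self.quantities["discount_effect"].mean

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every violated invariant."""
        errors: list[str] = []
        warns: list[str] = []
        missing = [n for n in QUANTITY_NAMES if n not in self.quantities]
        if missing:
            errors.append("missing parameters: " + ", ".join(missing))
        for name, q in self.quantities.items():
            if name != q.name:
                errors.append(f"key '{name}' does not match quantity name '{q.name}'")
            e, w = q.problems()
            errors.extend(e)
            warns.extend(w)
        if not missing:
            for arm in ARMS:
                means = [q.mean for q in self.survival(arm)]
                if any(b > a for a, b in zip(means, means[1:])):
                    errors.append(
                        f"surv_{arm.lower()}: cumulative survival must be "
                        f"non-increasing, got {means}"
                    )
        if self.horizon_years < 5:
            errors.append(f"horizon_years must be >= 5, got {self.horizon_years}")
        if self.gdp_per_capita <= 0:
            errors.append("gdp_per_capita must be positive")
        for msg in warns:
            warnings.warn(msg, ParameterWarning, stacklevel=2)
        if errors:
            raise ValidationError(errors)

    def replace_mean(self, name: str, mean: float) -> "ParameterSet":
        """New ParameterSet with one quantity's mean replaced (for DSA)."""
        if name not in self.quantities:
            raise KeyError(name)
        quantities = dict(self.quantities)
        quantities[name] = replace(quantities[name], mean=mean)
        return replace(self, quantities=quantities)

    def to_dict(self) -> dict:
        params = {}
        for name in QUANTITY_NAMES:
            q = self.quantities[name]
            entry: dict = {"mean": q.mean, "se": q.se, "family": q.family}
            if q.range_low is not None or q.range_high is not None:
                entry["range"] = [q.range_low, q.range_high]
            params[name] = entry
        return {
            "parameters": params,
            "settings": {
                "horizon_years": self.horizon_years,
                "start_age": self.start_age,
                "gdp_per_capita": self.gdp_per_capita,
                "exchange_rate_idr_per_usd": self.exchange_rate_idr_per_usd,
            },
        }


@dataclass(frozen=True)
class ParameterDraw:
    """One realized value per quantity, with provenance of the draw."""

    values: Mapping[str, float]
    index: int = 0
    seed: int | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def survival(self, arm: str) -> np.ndarray:
        key = arm.lower()
        return np.array([self.values[f"surv_{key}_{y}"] for y in range(1, 6)])

    def p_switch(self, arm: str) -> float:
        return self.values["p_capd_to_hd" if arm == "CAPD" else "p_hd_to_capd"]

    def p_complication(self, arm: str) -> float:
        return self.values["p_peritonitis" if arm == "CAPD" else "p_vascular"]

    def cost(self, component: str, arm: str) -> float:
        return self.values[f"{component}_{arm.lower()}"]

    def utility(self, arm: str, complicated: bool = False) -> float:
        suffix = "_com" if complicated else ""
        return self.values[f"u_{arm.lower()}{suffix}"]


def draw_from_means(params: ParameterSet) -> ParameterDraw:
    """Deterministic draw at the parameter means (the base case)."""
    return ParameterDraw(
        values={n: params.quantities[n].mean for n in QUANTITY_NAMES},
        index=0,
        seed=None,
    )


def sample_draw(
    params: ParameterSet,
    rng: np.random.Generator,
    index: int = 0,
    seed: int | None = None,
) -> ParameterDraw:
    """Independent Monte-Carlo draw of every quantity.

    Quantities are sampled in the fixed canonical order, so a given RNG state
    always yields the same draw.  Cumulative survival draws are monotonized by
    a running minimum within each arm: the per-year Betas are independent, and
    an increasing cumulative survival curve has no meaning.
    """
    values = {n: params.quantities[n].sample(rng) for n in QUANTITY_NAMES}
    for arm in ARMS:
        key = arm.lower()
        names = [f"surv_{key}_{y}" for y in range(1, 6)]
        mono = np.minimum.accumulate([values[n] for n in names])
        values.update(zip(names, mono.tolist()))
    return ParameterDraw(values=values, index=index, seed=seed)


# ---------------------------------------------------------------------------
# config I/O

def _parse_quantity(name: str, raw) -> UncertainQuantity:
    if not isinstance(raw, Mapping) or "mean" not in raw:
        raise ConfigError(f"parameter '{name}' must be a mapping with a 'mean'")
    rng = raw.get("range")
    low = high = None
    if rng is not None:
        if not isinstance(rng, (list, tuple)) or len(rng) != 2:
            raise ConfigError(f"parameter '{name}': range must be a [low, high] pair")
        low, high = (None if v is None else float(v) for v in rng)
    return UncertainQuantity(
        name=name,
        mean=float(raw["mean"]),
        se=float(raw.get("se", 0.0)),
        range_low=low,
        range_high=high,
        family=str(raw.get("family", "fixed")),
    )


def parameters_from_dict(data: Mapping) -> ParameterSet:
    """Build and validate a ParameterSet from a parsed config mapping."""
    if "parameters" not in data:
        raise ConfigError("config missing top-level 'parameters' section")
    quantities = {
        name: _parse_quantity(name, raw) for name, raw in data["parameters"].items()
    }
    settings = data.get("settings", {}) or {}
    ps = ParameterSet(
        quantities=quantities,
        horizon_years=int(settings.get("horizon_years", 40)),
        start_age=float(settings.get("start_age", 55.0)),
        gdp_per_capita=float(settings.get("gdp_per_capita", 54_600_000.0)),
        exchange_rate_idr_per_usd=float(
            settings.get("exchange_rate_idr_per_usd", 14_121.0)
        ),
    )
    ps.validate()
    return ps


def load_parameters(path) -> ParameterSet:
    """Load and validate a parameter config (YAML)."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"parameter file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path} does not contain a mapping")
    return parameters_from_dict(data)


def save_parameters(params: ParameterSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def default_parameters(corrected: bool = False) -> ParameterSet:
    """The shipped input table (optionally with the corrected switch range)."""
    name = "parameters_corrected.yaml" if corrected else "parameters_default.yaml"
    ref = resources.files("renalcea.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if corrected:
        return parameters_from_dict(data)
    with warnings.catch_warnings():
        # the default table reproduces the source verbatim, including a
        # reversed range on the HD->CAPD switch row; don't warn on every load
        warnings.simplefilter("ignore", ParameterWarning)
        return parameters_from_dict(data)
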