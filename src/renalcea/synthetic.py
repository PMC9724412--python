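"""Synthetic patient-level cohorts with the study's statistical structure.

The hospital billing and interview data behind the cost and utility inputs
are not publicly accessible, so this module generates stand-in cohorts whose
per-arm summary statistics reproduce the published parameter table: 28 CAPD
and 92 HD patients, right-skewed (Gamma) cost components whose arm means and
standard errors match the table, Bernoulli complications, and EQ-5D-3L
response profiles whose tariff-scored mean equals the published utilities
under the shipped toy tariff.

Patient-level dispersions are not published; they are back-solved from the
printed standard errors as SD = SE·√n (with n the study's arm size, or the
expected complication count for complication costs) and labelled as
assumptions.  Because the published means are themselves the sample
statistics of the closed dataset, the generator by default calibrates each
arm's cost components so the *sample* mean matches the target exactly
(multiplicative rescaling, which preserves the Gamma shape) and fixes the
complication count at its expectation; set ``calibrate_means=False`` for
plain independent sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .derivation import PatientRecord
from .errors import ConfigError
from .parameters import default_parameters
from .sensitivity import PsaSample

QUADRANT_ORDER = ("dominant", "trade-off NE", "trade-off SW", "dominated")
#: (sign of delta_cost, sign of delta_qaly) per quadrant
_QUADRANT_SIGNS = {
    "dominant": (-1.0, +1.0),
    "trade-off NE": (+1.0, +1.0),
    "trade-off SW": (-1.0, -1.0),
    "dominated": (+1.0, -1.0),
}

#: per-dimension toy-tariff decrements used to construct response profiles
_D2, _D3 = 0.10, 0.30

#: arm sizes of the emulated study; dispersion back-solving always uses these
STUDY_N = {"CAPD": 28, "HD": 92}


@dataclass(frozen=True)
class CostComponentSpec:
    """Patient-level mean/SD of one cost component (IDR/year or one-time)."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.mean < 0 or self.sd < 0:
            raise ConfigError("cost component mean and sd must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions the generator emulates.

    Defaults are back-solved from the published per-arm means and standard
    errors with the study's arm sizes (28 CAPD / 92 HD).
    """

    n_capd: int = 28
    n_hd: int = 92
    costs: dict = field(default_factory=dict)  # (component, arm) -> CostComponentSpec
    p_complication: dict = field(
        default_factory=lambda: {"CAPD": 0.200, "HD": 0.100}
    )
    target_utility: dict = field(default_factory=lambda: {"CAPD": 0.81, "HD": 0.65})
    mean_age: float = 55.0
    sd_age: float = 8.0
    observation_year: int = 2015
    seed: int = 1234
    calibrate_means: bool = True

    def __post_init__(self):
        if self.n_capd < 2 or self.n_hd < 2:
            raise ConfigError("need at least 2 patients per arm")
        for arm, p in self.p_complication.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"complication probability for {arm} not in [0,1]")
        for arm, u in self.target_utility.items():
            if not 0.0 <= u <= 1.0:
                raise ConfigError(f"target utility for {arm} not in [0,1]")
        if not self.costs:
            object.__setattr__(self, "costs", self._default_costs())

    def n_arm(self, arm: str) -> int:
        return self.n_capd if arm == "CAPD" else self.n_hd

    def _default_costs(self) -> dict:
        params = default_parameters()
        costs = {}
        for arm in ("CAPD", "HD"):
            n = STUDY_N[arm]
            key = arm.lower()
            for comp in ("dmc", "dnmc", "id", "setup"):
                q = params[f"{comp}_{key}"]
                costs[(comp, arm)] = CostComponentSpec(q.mean, q.se * np.sqrt(n))
            # complication costs are summarized among cases only, so the
            # printed SE is scaled by the expected number of cases
            q = params[f"cc_{key}"]
            n_cases = max(self.p_complication[arm] * n, 2.0)
            costs[("cc", arm)] = CostComponentSpec(q.mean, q.se * np.sqrt(n_cases))
        return costs


def _draw_costs(
    spec: CostComponentSpec, n: int, rng: np.random.Generator, calibrate: bool
) -> np.ndarray:
    """n Gamma draws with the spec's moments, optionally mean-calibrated.

    Multiplicative calibration rescales the sample so its mean equals the
    target exactly; a rescaled Gamma sample keeps its shape (skewness), only
    the scale moves.
    """
    if spec.sd == 0.0 or spec.mean == 0.0:
        return np.full(n, spec.mean)
    shape = (spec.mean / spec.sd) ** 2
    scale = spec.sd ** 2 / spec.mean
    values = rng.gamma(shape, scale, size=n)
    if calibrate and values.mean() > 0:
        values = values * (spec.mean / values.mean())
    return values


def _complication_flags(
    n: int, p: float, rng: np.random.Generator, calibrate: bool
) -> np.ndarray:
    """Bernoulli(p) complication indicators; exact count when calibrated."""
    if not calibrate:
        return rng.random(n) < p
    n_cases = int(round(p * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:n_cases]] = True
    return flags


def _response_profile(target_utility: float) -> tuple[float, float]:
    """Per-dimension level-2/level-3 probabilities hitting the target mean.

    Under the shipped toy tariff each dimension loses D2 at level 2 and D3 at
    level 3; splitting the required per-dimension decrement (1-u)/5 evenly
    between the two levels gives an expected utility of exactly ``u``.
    """
    decrement = (1.0 - target_utility) / 5.0
    q2 = decrement / (2.0 * _D2)
    q3 = decrement / (2.0 * _D3)
    if q2 + q3 > 1.0 or q2 < 0 or q3 < 0:
        raise ConfigError(
            f"target utility {target_utility} infeasible for the toy tariff profile"
        )
    return q2, q3


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> list[PatientRecord]:
    """Generate a synthetic cohort; reproducible under the config seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    calibrate = config.calibrate_means
    records: list[PatientRecord] = []
    for arm in ("CAPD", "HD"):
        n = config.n_arm(arm)
        q2, q3 = _response_profile(config.target_utility[arm])
        ages = np.clip(rng.normal(config.mean_age, config.sd_age, size=n), 18.0, 90.0)
        genders = np.where(rng.random(n) < 0.5, "F", "M")
        distances = rng.gamma(2.0, 12.0, size=n)  # km, right-skewed around ~24
        dmc = _draw_costs(config.costs[("dmc", arm)], n, rng, calibrate)
        dnmc = _draw_costs(config.costs[("dnmc", arm)], n, rng, calibrate)
        indirect = _draw_costs(config.costs[("id", arm)], n, rng, calibrate)
        setup = _draw_costs(config.costs[("setup", arm)], n, rng, calibrate)
        had_comp = _complication_flags(n, config.p_complication[arm], rng, calibrate)
        cc = np.zeros(n)
        n_cases = int(had_comp.sum())
        if n_cases:
            cc[had_comp] = _draw_costs(
                config.costs[("cc", arm)], n_cases, rng, calibrate
            )
        levels = rng.choice([1, 2, 3], size=(n, 5), p=[1.0 - q2 - q3, q2, q3])
        for k in range(n):
            rec = PatientRecord(
                id=f"{arm.lower()}-{k+1:03d}",
                arm=arm,
                age=float(ages[k]),
                gender=str(genders[k]),
                distance_km=float(distances[k]),
                monthly_dmc=float(dmc[k]) / 12.0,
                monthly_dnmc=float(dnmc[k]) / 12.0,
                monthly_indirect=float(indirect[k]) / 12.0,
                setup_cost=float(setup[k]),
                had_complication=bool(had_comp[k]),
                complication_cost=float(cc[k]),
                eq5d_response="".join(str(int(v)) for v in levels[k]),
                observation_year=config.observation_year,
            )
            rec.validate()
            records.append(rec)
    return records


def generate_psa_fixture(
    n: int,
    quadrant_weights,
    seed: int | None = None,
    cost_scale: float = 20_000_000.0,
    qaly_scale: float = 0.5,
    jitter: float = 0.5,
) -> list[PsaSample]:
    """Synthetic (ΔCost, ΔQALY) samples placed in CE-plane quadrants.

    ``quadrant_weights`` maps quadrant names (see :data:`QUADRANT_ORDER`) to
    probabilities summing to one.  Magnitudes are ``scale·(1 ± jitter/2)``;
    set ``jitter=0`` for exactly matched magnitudes across samples.
    """
    if isinstance(quadrant_weights, dict):
        weights = [float(quadrant_weights.get(q, 0.0)) for q in QUADRANT_ORDER]
    else:
        weights = [float(w) for w in quadrant_weights]
    if len(weights) != 4 or any(w < 0 for w in weights):
        raise ConfigError("quadrant_weights must give 4 non-negative weights")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigError(f"quadrant weights must sum to 1, got {sum(weights)}")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        quadrant = QUADRANT_ORDER[rng.choice(4, p=weights)]
        sc, sq = _QUADRANT_SIGNS[quadrant]
        mag_c = cost_scale * (1.0 + jitter * (rng.random() - 0.5))
        mag_q = qaly_scale * (1.0 + jitter * (rng.random() - 0.5))
        samples.append(PsaSample(index=i, delta_cost=sc * mag_c, delta_qaly=sq * mag_q))
    return samples
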