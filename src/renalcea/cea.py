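"""Incremental cost-effectiveness statistics and threshold verdicts.

Conventions: the intervention is compared against the comparator as
``delta = intervention - comparator``.  A negative ICER with lower cost and
higher effect (the dominant quadrant) is reported to humans as a saving per
QALY; machine-readable output keeps the signed value together with the
quadrant, since a negative ratio alone is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

from .markov import OutcomeSummary

QUADRANTS = ("dominant", "dominated", "trade-off NE", "trade-off SW", "indeterminate")

VERDICTS = (
    "cost-saving",
    "cost-effective at 1x GDP",
    "cost-effective at 3x GDP",
    "not cost-effective",
    "dominated",
)


def classify_quadrant(delta_cost: float, delta_qaly: float) -> str:
    """CE-plane quadrant from the signs of (ΔCost, ΔQALY)."""
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    if delta_cost > 0 and delta_qaly > 0:
        return "trade-off NE"
    if delta_cost < 0 and delta_qaly < 0:
        return "trade-off SW"
    return "indeterminate"


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    icer: float | None
    quadrant: str

    @property
    def is_cost_saving_per_qaly(self) -> bool:
        return self.quadrant == "dominant" and self.icer is not None

    def display_icer(self) -> str:
        """Human-readable ICER, mirroring parenthetical-negative style."""
        if self.icer is None:
            return "undefined (no QALY difference)"
        if self.is_cost_saving_per_qaly:
            return f"savings of {abs(self.icer):,.0f} IDR/QALY"
        if self.icer < 0:
            return f"({abs(self.icer):,.0f}) IDR/QALY [{self.quadrant}]"
        return f"{self.icer:,.0f} IDR/QALY"


@dataclass(frozen=True)
class ThresholdPolicy:
    """Willingness-to-pay thresholds at 1x and 3x GDP per capita."""

    lambda_low: float
    lambda_high: float

    def __post_init__(self):
        if not 0 < self.lambda_low <= self.lambda_high:
            raise ValueError("require 0 < lambda_low <= lambda_high")

    @classmethod
    def from_gdp(cls, gdp_per_capita: float) -> "ThresholdPolicy":
        return cls(lambda_low=gdp_per_capita, lambda_high=3.0 * gdp_per_capita)


def incremental(
    intervention: OutcomeSummary, comparator: OutcomeSummary
) -> IncrementalResult:
    """ΔCost, ΔQALY, ICER and CE-plane quadrant (discounted totals)."""
    dc = intervention.total_cost_discounted - comparator.total_cost_discounted
    dq = intervention.total_qaly_discounted - comparator.total_qaly_discounted
    icer = dc / dq if dq != 0.0 else None
    return IncrementalResult(
        delta_cost=dc, delta_qaly=dq, icer=icer, quadrant=classify_quadrant(dc, dq)
    )


def net_monetary_benefit(result: IncrementalResult, wtp: float) -> float:
    """NMB = λ·ΔQALY − ΔCost at willingness-to-pay λ (IDR/QALY)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.delta_qaly - result.delta_cost


def verdict(result: IncrementalResult, policy: ThresholdPolicy) -> str:
    """Threshold verdict; boundaries are inclusive ('not greater than')."""
    if result.quadrant == "dominant":
        return "cost-saving"
    if result.quadrant == "dominated":
        return "dominated"
    if result.quadrant == "trade-off SW":
        # cheaper but less effective: acceptable if the savings per QALY
        # forgone exceed the threshold
        assert result.icer is not None
        if abs(result.icer) >= policy.lambda_high:
            return "cost-effective at 3x GDP"
        return "not cost-effective"
    if result.icer is None:
        # no QALY difference: judged on cost alone
        if result.delta_cost < 0:
            return "cost-saving"
        return "not cost-effective" if result.delta_cost > 0 else "cost-effective at 1x GDP"
    if result.icer <= policy.lambda_low:
        return "cost-effective at 1x GDP"
    if result.icer <= policy.lambda_high:
        return "cost-effective at 3x GDP"
    return "not cost-effective"


def to_usd(value_idr: float, exchange_rate_idr_per_usd: float) -> float:
    """Display-only currency conversion; never part of the decision rule."""
    if exchange_rate_idr_per_usd <= 0:
        raise ValueError("exchange rate must be positive")
    return value_idr / exchange_rate_idr_per_usd
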