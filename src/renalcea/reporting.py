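"""Base-case orchestration, human-readable reports, and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .cea import (
    IncrementalResult,
    ThresholdPolicy,
    incremental,
    net_monetary_benefit,
    to_usd,
    verdict,
)
from .markov import ModelSettings, OutcomeSummary, run_arm
from .parameters import ParameterSet, draw_from_means

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaseCaseResult:
    capd: OutcomeSummary
    hd: OutcomeSummary
    incremental: IncrementalResult
    verdict: str
    policy: ThresholdPolicy


def run_base_case(
    params: ParameterSet, settings: ModelSettings | None = None
) -> BaseCaseResult:
    """Run both starting modalities at the parameter means and compare them."""
    if settings is None:
        settings = ModelSettings(horizon_years=params.horizon_years)
    draw = draw_from_means(params)
    capd = run_arm(draw, "CAPD", settings)
    hd = run_arm(draw, "HD", settings)
    inc = incremental(capd, hd)
    policy = ThresholdPolicy.from_gdp(params.gdp_per_capita)
    return BaseCaseResult(
        capd=capd, hd=hd, incremental=inc, verdict=verdict(inc, policy), policy=policy
    )


def _idr(value: float) -> str:
    """IDR with thousands separators; negatives in parentheses."""
    if value < 0:
        return f"({abs(value):,.0f})"
    return f"{value:,.0f}"


def format_base_case(result: BaseCaseResult, params: ParameterSet) -> str:
    """Cost / LYG / QALY / ICER summary table for the two starting modalities."""
    inc = result.incremental
    fx = params.exchange_rate_idr_per_usd
    lines = [
        "Base case (discounted totals per patient, 2020 IDR)",
        f"{'':24}{'CAPD':>18}{'HD':>18}",
        f"{'Total cost':24}{_idr(result.capd.total_cost_discounted):>18}"
        f"{_idr(result.hd.total_cost_discounted):>18}",
        f"{'Life-years gained':24}{result.capd.total_ly_discounted:>18.3f}"
        f"{result.hd.total_ly_discounted:>18.3f}",
        f"{'QALY':24}{result.capd.total_qaly_discounted:>18.2f}"
        f"{result.hd.total_qaly_discounted:>18.2f}",
        "",
        f"Incremental cost (CAPD - HD):  {_idr(inc.delta_cost)} IDR"
        f"  (USD {to_usd(inc.delta_cost, fx):,.0f}; display only)",
        f"Incremental QALY:              {inc.delta_qaly:.3f}",
        f"ICER:                          {inc.display_icer()}",
        f"CE-plane quadrant:             {inc.quadrant}",
        f"Verdict at 1-3x GDP/capita ({_idr(result.policy.lambda_low)} - "
        f"{_idr(result.policy.lambda_high)} IDR/QALY): {result.verdict}",
        f"NMB at 1x GDP: {_idr(net_monetary_benefit(inc, result.policy.lambda_low))} IDR;"
        f" at 3x GDP: {_idr(net_monetary_benefit(inc, result.policy.lambda_high))} IDR",
    ]
    return "\n".join(lines)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    config_paths: dict,
    outputs: list,
    seed: int | None = None,
    iterations: int | None = None,
) -> Path:
    """Record everything needed to re-execute a run exactly."""
    out_dir = Path(out_dir)
    missing = [str(p) for p in outputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest refers to missing outputs: {missing}")
    manifest = {
        "command": command,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "iterations": iterations,
        "configs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in config_paths.items()
            if p is not None
        },
        "outputs": [str(Path(p)) for p in outputs],
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path
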