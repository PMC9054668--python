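"""Calibration of the variant-sensitive coupling constant.

The WT and variant networks differ in a single rate constant (the
receptor/G-protein coupling step).  Peak amplitude of the simulated
transient is monotone in that constant over a wide bracket, so a target
amplitude is matched by bracketed scalar root finding; AUC and FWHM are
then predictions rather than fitted quantities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import InfeasibleTargetError, NonMonotoneBracketError
from .metrics import MetricRatios, TraceMetrics, compute_metrics, metric_ratios
from .network import (
    ReactionNetwork,
    SimulationConfig,
    StimulusProtocol,
    build_network,
    extract_ca_trace,
    simulate,
)

COUPLING_PARAM = "kf_coupling"
AMPLITUDE_RTOL = 1e-4


@dataclass(frozen=True)
class FitResult:
    fitted_value: float
    objective: float  # |amplitude(fitted) - target|
    n_evaluations: int
    bracket: tuple[float, float]
    converged: bool


@dataclass(frozen=True)
class VariantComparison:
    wt_metrics: TraceMetrics
    mut_metrics: TraceMetrics
    ratios: MetricRatios
    kf_coupling_wt: float
    kf_coupling_mut: float

    def to_dict(self) -> dict:
        return {
            "wt_metrics": asdict(self.wt_metrics),
            "mut_metrics": asdict(self.mut_metrics),
            "ratios": asdict(self.ratios),
            "kf_coupling_wt": self.kf_coupling_wt,
            "kf_coupling_mut": self.kf_coupling_mut,
        }


def simulated_amplitude(
    network: ReactionNetwork,
    stimulus: StimulusProtocol,
    config: SimulationConfig,
    kf: float | None = None,
) -> float:
    net = network if kf is None else network.with_parameter(COUPLING_PARAM, kf)
    trace = extract_ca_trace(simulate(net, stimulus, config))
    return compute_metrics(trace).amplitude


def fit_coupling(
    network: ReactionNetwork,
    stimulus: StimulusProtocol,
    config: SimulationConfig,
    target_amplitude: float,
    bracket: tuple[float, float] | None = None,
) -> FitResult:
    """Find kf_coupling whose simulated amplitude matches the target.

    The bracket defaults to [0.1x, 10x] the network's current coupling
    value.  Endpoint amplitudes are evaluated first: a target outside
    [amp(lo), amp(hi)] raises InfeasibleTargetError carrying the
    achievable interval, and a non-increasing endpoint pair raises
    NonMonotoneBracketError.
    """
    kf0 = network.parameter_value(COUPLING_PARAM)
    lo, hi = bracket if bracket is not None else (0.1 * kf0, 10.0 * kf0)
    if not (0 < lo <= hi):
        raise ValueError("bracket must satisfy 0 < lo <= hi")

    n_eval = 0

    def amp(kf: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return simulated_amplitude(network, stimulus, config, kf)

    a_lo = amp(lo)
    if hi == lo:
        ok = abs(a_lo - target_amplitude) <= AMPLITUDE_RTOL * abs(target_amplitude)
        if not ok:
            raise InfeasibleTargetError(
                f"collapsed bracket at {lo} gives amplitude {a_lo}, "
                f"target {target_amplitude} unreachable",
                achievable=(a_lo, a_lo),
            )
        return FitResult(lo, abs(a_lo - target_amplitude), n_eval, (lo, hi), True)
    a_hi = amp(hi)
    if a_hi <= a_lo:
        raise NonMonotoneBracketError(
            f"amplitude is not increasing over [{lo}, {hi}] "
            f"({a_lo} -> {a_hi}); use a narrower bracket"
        )
    if not (a_lo <= target_amplitude <= a_hi):
        raise InfeasibleTargetError(
            f"target amplitude {target_amplitude} outside achievable "
            f"interval [{a_lo}, {a_hi}] over bracket [{lo}, {hi}]",
            achievable=(a_lo, a_hi),
        )

    from scipy.optimize import brentq

    kf_fit, info = brentq(
        lambda kf: amp(kf) - target_amplitude,
        lo, hi, xtol=1e-14, rtol=1e-10, full_output=True,
    )
    resid = abs(amp(kf_fit) - target_amplitude)
    converged = bool(info.converged) and resid <= AMPLITUDE_RTOL * max(
        abs(target_amplitude), 1e-30
    )
    return FitResult(float(kf_fit), float(resid), n_eval, (lo, hi), converged)


def compare_variants(
    param_table: pd.DataFrame | None,
    stimulus: StimulusProtocol,
    config: SimulationConfig = SimulationConfig(),
) -> VariantComparison:
    """Simulate both variants under one protocol and report mutant/WT ratios."""
    nets = {v: build_network(v, param_table) for v in ("WT", "A218T")}
    metrics = {}
    for v, net in nets.items():
        trace = extract_ca_trace(simulate(net, stimulus, config))
        metrics[v] = compute_metrics(trace)
    return VariantComparison(
        wt_metrics=metrics["WT"],
        mut_metrics=metrics["A218T"],
        ratios=metric_ratios(metrics["A218T"], metrics["WT"]),
        kf_coupling_wt=nets["WT"].parameter_value(COUPLING_PARAM),
        kf_coupling_mut=nets["A218T"].parameter_value(COUPLING_PARAM),
    )


def sensitivity_scan(
    network: ReactionNetwork,
    stimulus: StimulusProtocol,
    config: SimulationConfig,
    kf_grid,
) -> pd.DataFrame:
    """Metrics of the simulated transient at each coupling value in the grid."""
    kf_grid = np.asarray(kf_grid, dtype=float)
    if kf_grid.ndim != 1 or kf_grid.size == 0:
        raise ValueError("kf_grid must be a non-empty 1-D sequence")
    if np.any(kf_grid <= 0):
        raise ValueError("kf_grid values must be positive")
    if np.any(np.diff(kf_grid) < 0):
        raise ValueError("kf_grid must be non-decreasing")
    rows = []
    for kf in kf_grid:
        net = network.with_parameter(COUPLING_PARAM, float(kf))
        m = compute_metrics(extract_ca_trace(simulate(net, stimulus, config)))
        rows.append({
            "kf": float(kf), "amplitude": m.amplitude, "auc": m.auc,
            "fwhm": m.fwhm if m.fwhm is not None else np.nan,
        })
    return pd.DataFrame(rows)


def comparison_report(
    comparison: VariantComparison,
    param_table: pd.DataFrame,
    stimulus: StimulusProtocol,
    config: SimulationConfig,
) -> dict:
    """JSON-serializable comparison with provenance (table checksum, solver)."""
    table_csv = param_table.to_csv(index=False).encode()
    return {
        **comparison.to_dict(),
        "provenance": {
            "parameter_table_sha256": hashlib.sha256(table_csv).hexdigest(),
            "stimulus": asdict(stimulus),
            "config": asdict(config),
        },
    }


def write_comparison(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
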