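"""Summary metrics for Ca2+ transients.

Works identically on ratiometric imaging traces and on simulated
concentration curves: baseline (pre-stimulus mean), amplitude (peak above
baseline), AUC (trapezoidal integral above baseline after the stimulus)
and FWHM (width at half amplitude, linearly interpolated crossings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_BASELINE_SPAN = 20.0  # s before t_stim


@dataclass
class CaTrace:
    """One Ca2+ time series (a single cell or one simulation)."""

    time: np.ndarray
    signal: np.ndarray
    signal_kind: str = "fura2_ratio"  # or "concentration_nM"
    cell_id: str = ""
    condition: dict = field(default_factory=dict)  # e.g. {"variant": "WT"}
    t_stim: float = 0.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValidationError("time and signal must be equal-length vectors")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal must be finite")
        if not (self.time[0] <= self.t_stim <= self.time[-1]):
            raise ValidationError("t_stim must lie within the sampled interval")
        if self.signal_kind not in ("fura2_ratio", "concentration_nM"):
            raise ValidationError(f"unknown signal_kind {self.signal_kind!r}")


@dataclass(frozen=True)
class TraceMetrics:
    baseline: float
    amplitude: float
    auc: float
    fwhm: float | None  # None when undefined (flat trace / no crossing)
    peak_time: float
    smoothed: bool = False

    @property
    def fwhm_defined(self) -> bool:
        return self.fwhm is not None


def moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return np.asarray(signal, dtype=float)
    half = window // 2
    out = np.empty_like(np.asarray(signal, dtype=float))
    n = len(signal)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = float(np.mean(signal[lo:hi]))
    return out


def _interp_crossing(t0, s0, t1, s1, level):
    return t0 + (level - s0) * (t1 - t0) / (s1 - s0)


def compute_metrics(
    trace: CaTrace,
    baseline_window: tuple[float, float] | None = None,
    noise_floor: float = 0.0,
    smooth_window: int | None = None,
) -> TraceMetrics:
    """Compute baseline, amplitude, AUC, FWHM and peak time for one trace.

    baseline_window defaults to the final 20 s before t_stim (clipped to
    the start of the trace) and must contain at least 3 samples.  FWHM is
    flagged undefined (None) when the amplitude does not exceed
    ``noise_floor`` or either half-maximum crossing is missing.
    """
    t, s = trace.time, trace.signal
    smoothed = False
    if smooth_window is not None and smooth_window > 1:
        s = moving_average(s, smooth_window)
        smoothed = True

    if baseline_window is None:
        baseline_window = (
            max(t[0], trace.t_stim - DEFAULT_BASELINE_SPAN),
            trace.t_stim,
        )
    w0, w1 = baseline_window
    if not (t[0] <= w0 < w1 <= trace.t_stim + 1e-12):
        raise ValueError(
            f"baseline window {baseline_window} must lie within "
            f"[{t[0]}, t_stim={trace.t_stim}]"
        )
    in_win = (t >= w0) & (t <= w1)
    if int(in_win.sum()) < 3:
        raise ValueError("baseline window contains fewer than 3 samples")
    baseline = float(np.mean(s[in_win]))

    post = t >= trace.t_stim
    t_post, s_post = t[post], s[post]
    if t_post.size == 0:
        raise ValueError("no samples at or after t_stim")
    ipk = int(np.argmax(s_post))
    amplitude = float(s_post[ipk] - baseline)
    peak_time = float(t_post[ipk])

    auc = float(np.trapezoid(np.clip(s_post - baseline, 0.0, None), t_post))

    fwhm = None
    if amplitude > max(noise_floor, 0.0):
        half = baseline + amplitude / 2.0
        t_up = t_down = None
        # first crossing below `half` walking left from the peak
        for i in range(ipk, 0, -1):
            if s_post[i - 1] < half <= s_post[i]:
                t_up = _interp_crossing(
                    t_post[i - 1], s_post[i - 1], t_post[i], s_post[i], half
                )
                break
        # first crossing below `half` walking right from the peak
        for i in range(ipk, t_post.size - 1):
            if s_post[i + 1] < half <= s_post[i]:
                t_down = _interp_crossing(
                    t_post[i], s_post[i], t_post[i + 1], s_post[i + 1], half
                )
                break
        if t_up is not None and t_down is not None and t_down > t_up:
            fwhm = float(t_down - t_up)

    return TraceMetrics(
        baseline=baseline,
        amplitude=amplitude,
        auc=auc,
        fwhm=fwhm,
        peak_time=peak_time,
        smoothed=smoothed,
    )


@dataclass(frozen=True)
class MetricStat:
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class GroupSummary:
    n: int  # number of traces in the group
    baseline: MetricStat
    amplitude: MetricStat
    auc: MetricStat
    fwhm: MetricStat  # n may be smaller when FWHM is undefined on some traces
    condition: dict = field(default_factory=dict)


def _stat(values: Sequence[float]) -> MetricStat:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    n = arr.size
    if n == 0:
        return MetricStat(0, math.nan, math.nan)
    if n == 1:
        return MetricStat(1, float(arr[0]), 0.0)  # SEM 0 by convention, n flagged
    return MetricStat(n, float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(n)))


def summarize_group(
    traces: Iterable[CaTrace],
    baseline_window: tuple[float, float] | None = None,
    **metric_kwargs,
) -> GroupSummary:
    """Mean and SEM of each metric across traces sharing one condition."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    cond = traces[0].condition
    if any(tr.condition != cond for tr in traces[1:]):
        raise ValueError("all traces in a group must share condition labels")
    ms = [compute_metrics(tr, baseline_window, **metric_kwargs) for tr in traces]
    return GroupSummary(
        n=len(traces),
        baseline=_stat([m.baseline for m in ms]),
        amplitude=_stat([m.amplitude for m in ms]),
        auc=_stat([m.auc for m in ms]),
        fwhm=_stat([m.fwhm for m in ms]),
        condition=dict(cond),
    )


@dataclass(frozen=True)
class MetricRatios:
    amplitude: float
    auc: float
    fwhm: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.amplitude, self.auc, self.fwhm)


def metric_ratios(metrics_a: TraceMetrics, metrics_b: TraceMetrics) -> MetricRatios:
    """Ratios a/b of amplitude, AUC and FWHM (b must be strictly positive)."""
    for attr in ("amplitude", "auc", "fwhm"):
        denom = getattr(metrics_b, attr)
        if denom is None or denom <= 0:
            raise ValueError(f"denominator {attr} must be strictly positive")
    if metrics_a.fwhm is None:
        raise ValueError("numerator fwhm is undefined")
    return MetricRatios(
        amplitude=metrics_a.amplitude / metrics_b.amplitude,
        auc=metrics_a.auc / metrics_b.auc,
        fwhm=metrics_a.fwhm / metrics_b.fwhm,
    )


# ---------------------------------------------------------------------------
# Tabular I/O: first column time_s, one column per cell
# ---------------------------------------------------------------------------


def read_traces(
    path,
    t_stim: float,
    signal_kind: str = "fura2_ratio",
    condition: dict | None = None,
) -> list[CaTrace]:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns[0] != "time_s":
        raise ValidationError("trace table must start with a time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    return [
        CaTrace(
            time=t,
            signal=df[col].to_numpy(dtype=float),
            signal_kind=signal_kind,
            cell_id=str(col),
            condition=dict(condition or {}),
            t_stim=t_stim,
        )
        for col in df.columns[1:]
    ]


def write_traces(path, traces: Sequence[CaTrace]) -> None:
    t0 = traces[0].time
    data = {"time_s": t0}
    for tr in traces:
        if tr.time.shape != t0.shape or not np.allclose(tr.time, t0):
            raise ValidationError("all traces must share one time grid")
        data[tr.cell_id] = tr.signal
    pd.DataFrame(data).to_csv(path, index=False)


def metrics_frame(
    traces: Sequence[CaTrace],
    baseline_window: tuple[float, float] | None = None,
    **metric_kwargs,
) -> pd.DataFrame:
    """One row per trace: id, condition labels, the four metrics, flags."""
    rows = []
    for tr in traces:
        m = compute_metrics(tr, baseline_window, **metric_kwargs)
        row = {"cell_id": tr.cell_id, **tr.condition,
               "baseline": m.baseline, "amplitude": m.amplitude, "auc": m.auc,
               "fwhm": m.fwhm if m.fwhm is not None else np.nan,
               "peak_time": m.peak_time,
               "fwhm_defined": m.fwhm_defined, "smoothed": m.smoothed}
        rows.append(row)
    return pd.DataFrame(rows)
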