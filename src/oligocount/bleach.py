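"""Copy-number estimation from photobleaching traces.

Small clusters bleach in resolvable discrete steps: the copy number is the
sum of step multiplicities, where a drop of height h contributes
``round(h / a)`` copies (a is the unit intensity of one fluorophore, so a
simultaneous double bleach counts as 2). Large clusters bleach smoothly; the
ensemble decay is exponential and the copy number is ``N = I0 / a`` with I0
the initial (pre-bleach) fluorescence above baseline.

Step localization uses a penalized piecewise-constant change-point fit:
optimal partitioning by dynamic programming on the residual sum of squares,
with a BIC-style penalty ``2 * sigma^2 * log(T)`` estimated from the
first-difference MAD, so that spurious steps smaller than
``min_step_fraction * a`` are rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._util import CalibrationError, FitError, TraceError, round_half_away

__all__ = [
    "BleachTrace",
    "StepCountResult",
    "ExponentialFit",
    "detect_steps",
    "fit_exponential_decay",
    "estimate_copy_number",
    "calibrate_unit_step",
]

log = logging.getLogger(__name__)

MIN_TRACE_FRAMES = 10


@dataclass
class BleachTrace:
    """Per-frame fluorescence of one particle during photobleaching."""

    trace_id: str
    intensity: np.ndarray
    frame_interval: float = 1.0
    baseline: Optional[float] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size < MIN_TRACE_FRAMES:
            raise TraceError(
                f"trace {self.trace_id!r}: need >= {MIN_TRACE_FRAMES} frames"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise TraceError(f"trace {self.trace_id!r}: non-finite intensities")

    def estimated_baseline(self) -> float:
        """Supplied baseline, else the median of the final 10% of frames."""
        if self.baseline is not None:
            return float(self.baseline)
        tail = max(1, self.intensity.size // 10)
        return float(np.median(self.intensity[-tail:]))


@dataclass
class StepCountResult:
    trace_id: str
    method: str  # "stepwise" | "exponential"
    copy_number_estimate: int
    unit_step: float
    initial_intensity: float
    step_positions: list[int] = field(default_factory=list)
    step_heights: list[float] = field(default_factory=list)
    fit_residual: float = 0.0


@dataclass
class ExponentialFit:
    i0: float
    rate: float
    baseline: float
    residual: float


def _segment_trace(y: np.ndarray, penalty: float) -> np.ndarray:
    """Optimal partitioning of y into piecewise-constant segments.

    Minimizes sum of per-segment squared deviations + penalty per change
    point; returns segment start indices (always starting with 0).
    """
    n = y.size
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    f = np.empty(n + 1)
    f[0] = -penalty
    last = np.zeros(n + 1, dtype=np.int64)
    for t in range(1, n + 1):
        starts = np.arange(t)
        lengths = t - starts
        cost = (s2[t] - s2[starts]) - (s1[t] - s1[starts]) ** 2 / lengths
        total = f[starts] + cost + penalty
        best = int(np.argmin(total))
        f[t] = total[best]
        last[t] = best
    # backtrack
    breaks = []
    t = n
    while t > 0:
        breaks.append(last[t])
        t = last[t]
    return np.array(sorted(breaks), dtype=int)


def _noise_sd(y: np.ndarray) -> float:
    """Robust noise scale from the MAD of first differences."""
    d = np.diff(y)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def detect_steps(
    trace: BleachTrace,
    unit_step: Optional[float] = None,
    min_step_fraction: float = 0.5,
) -> StepCountResult:
    """Count bleaching steps in one trace.

    If ``unit_step`` is not supplied it is calibrated from the trace's own
    smallest significant downward step (iteratively refined median of the
    single-step candidates). Raises :class:`TraceError` when no downward
    steps are found or the trace trends upward.
    """
    if unit_step is not None and unit_step <= 0:
        raise TraceError("unit_step must be positive")
    y = trace.intensity
    sigma = _noise_sd(y)
    penalty = max(2.0 * sigma**2 * np.log(y.size), 1e-9 * max(1.0, np.ptp(y)) ** 2)
    starts = _segment_trace(y, penalty)
    bounds = np.concatenate([starts, [y.size]])
    means = np.array(
        [y[bounds[i] : bounds[i + 1]].mean() for i in range(starts.size)]
    )
    head = y[: max(1, y.size // 10)].mean()
    tail = y[-max(1, y.size // 10) :].mean()
    if tail > head + max(3 * sigma, 1e-12):
        raise TraceError(f"trace {trace.trace_id!r}: net upward trend")

    drops = -np.diff(means)  # positive = downward step
    positions = starts[1:]
    down = drops > 0
    if not np.any(down):
        raise TraceError(f"trace {trace.trace_id!r}: no downward steps found")

    a = unit_step if unit_step is not None else _self_calibrate(drops[down])
    if not np.any(drops[down] >= min_step_fraction * a):
        raise TraceError(
            f"trace {trace.trace_id!r}: no downward steps above threshold"
        )
    baseline = trace.estimated_baseline()
    # Quantize segment levels to fluorophore counts anchored at the baseline,
    # then enforce monotone non-increasing counts (bleaching never adds
    # fluorophores): spurious noise segments collapse to zero-height steps
    # instead of miscounting. A drop of q quantized units is a q-fold
    # simultaneous bleach and contributes q to the count.
    levels = np.array([round_half_away((mu - baseline) / a) for mu in means])
    levels = np.minimum.accumulate(levels)
    multiplicity = -np.diff(levels)
    is_step = (multiplicity >= 1) & (drops >= min_step_fraction * a)
    if not np.any(is_step):
        raise TraceError(f"trace {trace.trace_id!r}: no downward steps found")
    count = int(multiplicity[is_step].sum())
    fitted = np.repeat(means, np.diff(bounds))
    residual = float(np.mean((y - fitted) ** 2))
    return StepCountResult(
        trace_id=trace.trace_id,
        method="stepwise",
        copy_number_estimate=count,
        unit_step=float(a),
        initial_intensity=float(means[0] - baseline),
        step_positions=[int(p) for p in positions[is_step]],
        step_heights=[float(h) for h in drops[is_step]],
        fit_residual=residual,
    )


def _self_calibrate(drop_heights: np.ndarray) -> float:
    """Unit step from one trace's own downward steps: start from the smallest
    step and refine as the median of heights consistent with a single step."""
    a = float(np.min(drop_heights))
    for _ in range(20):
        singles = drop_heights[(drop_heights >= 0.5 * a) & (drop_heights < 1.5 * a)]
        new_a = float(np.median(singles)) if singles.size else a
        if abs(new_a - a) < 1e-12:
            break
        a = new_a
    return a


def fit_exponential_decay(trace: BleachTrace) -> ExponentialFit:
    """Least-squares fit of ``I(t) = I0 * exp(-rate * t) + baseline``.

    Times are in seconds (``frame_interval`` per frame). A near-constant
    trace yields rate ~ 0 with a degenerate-fit warning.
    """
    y = trace.intensity
    if y.size < 20:
        raise FitError("exponential fit needs >= 20 frames")
    t = np.arange(y.size) * trace.frame_interval
    b0 = trace.estimated_baseline()
    amp0 = float(y[0] - b0)
    if np.ptp(y) <= 1e-12 * max(1.0, abs(y.mean())):
        warnings.warn(
            f"trace {trace.trace_id!r}: constant intensity, degenerate exponential fit",
            RuntimeWarning,
            stacklevel=2,
        )
        return ExponentialFit(i0=float(y.mean()), rate=0.0, baseline=0.0, residual=0.0)
    if amp0 <= 0:
        amp0 = max(np.ptp(y), 1e-9)
    # crude rate guess from the frame where the decay reaches ~1/e
    above = np.nonzero(y - b0 > amp0 / np.e)[0]
    t_e = t[above[-1]] if above.size else t[-1] / 2
    r0 = 1.0 / max(t_e, trace.frame_interval)
    try:
        popt, _ = curve_fit(
            lambda tt, i0, r, b: i0 * np.exp(-r * tt) + b,
            t,
            y,
            p0=(amp0, r0, b0),
            bounds=([1e-12, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"exponential fit failed for {trace.trace_id!r}: {exc}") from exc
    i0, rate, baseline = (float(v) for v in popt)
    resid = float(np.mean((y - (i0 * np.exp(-rate * t) + baseline)) ** 2))
    return ExponentialFit(i0=i0, rate=rate, baseline=baseline, residual=resid)


def estimate_copy_number(
    trace: BleachTrace,
    unit_step: float,
    stepwise_max: int = 6,
    min_step_fraction: float = 0.5,
) -> StepCountResult:
    """Branching copy-number estimate.

    Step counting is used when it finds at most ``stepwise_max`` copies and
    its residual is no worse than the exponential fit's; otherwise the trace
    is treated as a smooth decay and ``N = round(I0 / a)`` with I0 the
    first-frame intensity above baseline.
    """
    if unit_step <= 0:
        raise TraceError("unit_step must be positive")
    step_result: Optional[StepCountResult] = None
    step_err: Optional[Exception] = None
    try:
        step_result = detect_steps(trace, unit_step, min_step_fraction)
    except TraceError as exc:
        step_err = exc

    exp_fit: Optional[ExponentialFit] = None
    try:
        exp_fit = fit_exponential_decay(trace)
    except FitError:
        pass

    if step_result is not None and step_result.copy_number_estimate <= stepwise_max:
        if exp_fit is None or step_result.fit_residual <= exp_fit.residual:
            return step_result

    baseline = trace.estimated_baseline()
    i0 = float(trace.intensity[0] - baseline)
    if i0 <= 0:
        if step_err is not None:
            raise step_err
        raise TraceError(f"trace {trace.trace_id!r}: non-positive initial intensity")
    n = max(1, round_half_away(i0 / unit_step))
    return StepCountResult(
        trace_id=trace.trace_id,
        method="exponential",
        copy_number_estimate=n,
        unit_step=float(unit_step),
        initial_intensity=i0,
        fit_residual=exp_fit.residual if exp_fit is not None else float("nan"),
    )


def calibrate_unit_step(results: Sequence[StepCountResult]) -> float:
    """Experiment-wide unit step from the single steps of small clusters.

    Seeds a running estimate with the mode of all step heights, then takes
    the median of heights within [0.5 a0, 1.5 a0) of the running estimate,
    iterating to convergence. Heights outside the band (double or larger
    simultaneous bleaches) are excluded.
    """
    stepwise = [r for r in results if r.method == "stepwise" and r.step_heights]
    if len(stepwise) < 5:
        raise CalibrationError("need at least 5 stepwise traces for calibration")
    heights = np.concatenate([np.asarray(r.step_heights) for r in stepwise])
    if heights.size < 5:
        raise CalibrationError("too few steps for calibration")
    hist, edges = np.histogram(heights, bins="auto")
    mode_bin = int(np.argmax(hist))
    a = float((edges[mode_bin] + edges[mode_bin + 1]) / 2)
    for _ in range(50):
        singles = heights[(heights >= 0.5 * a) & (heights < 1.5 * a)]
        if singles.size == 0:
            raise CalibrationError("no single-step heights within the band")
        new_a = float(np.median(singles))
        if abs(new_a - a) < 1e-12:
            break
        a = new_a
    log.info("calibrated unit step a = %.4g from %d steps", a, heights.size)
    return a
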