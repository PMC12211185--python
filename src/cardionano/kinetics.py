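"""Per-beat kinetics of paced calcium transients and contraction traces.

Calcium metrics per beat window: diastolic level (mean of the pre-stimulus
baseline, i.e. the tail of the preceding window), systolic level (window
maximum), 10-90 % rise time of the upstroke, release rate (maximum smoothed
derivative during the upstroke) and the reuptake time constant tau from a
single-exponential fit y(t) = B + A exp(-(t - t0)/tau) to the descending
phase; the reuptake rate is 1/tau.

Contraction metrics: beating frequency (beats / acquisition duration),
per-beat amplitude, and maximal contraction / relaxation velocities from the
smoothed derivative. A motion trace can be derived from an image stack as
the mean absolute consecutive-frame difference (relative motion within the
field of view), baseline-subtracted with a rolling minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from .core import CalciumTrace, CardionanoError, ContractionTrace, FrameStack


class RatioError(CardionanoError):
    pass


class NoBeatsError(CardionanoError):
    pass


def compute_ratio(
    f340: np.ndarray,
    f380: np.ndarray,
    time: np.ndarray | None = None,
    sample_rate: float | None = None,
    pacing_hz: float | None = None,
) -> CalciumTrace:
    """Pointwise Fura-2 excitation ratio F340/F380."""
    f340 = np.asarray(f340, dtype=float)
    f380 = np.asarray(f380, dtype=float)
    if f340.shape != f380.shape:
        raise RatioError(
            f"channel length mismatch: {f340.shape} vs {f380.shape}"
        )
    bad = np.nonzero(f380 <= 0)[0]
    if len(bad):
        raise RatioError(
            f"F380 must be positive everywhere; first violation at sample {bad[0]}"
        )
    if time is None:
        if sample_rate is None:
            raise ValueError("provide either time or sample_rate")
        time = np.arange(len(f340)) / sample_rate
    return CalciumTrace(time, f340 / f380, pacing_hz)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with an odd window (window=1 is a no-op)."""
    if window <= 1:
        return values
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    return np.convolve(np.pad(values, window // 2, mode="edge"), kernel, "valid")


def _smoothed_derivative(values: np.ndarray, dt: float, window: int) -> np.ndarray:
    d = np.gradient(_smooth(values, window), dt)
    return d


def segment_beats(
    trace: CalciumTrace | ContractionTrace,
    mode: str = "paced",
    pacing_hz: float | None = None,
    min_prominence_frac: float = 0.3,
    refractory_frac: float = 0.5,
    smooth_window: int = 1,
) -> list[tuple[int, int]]:
    """Split a trace into per-beat index windows [start, stop).

    ``paced``: fixed windows [k/f, (k+1)/f) from the pacing frequency.
    ``detected``: peaks found by prominence (a fraction of the trace range)
    with a refractory spacing (a fraction of the median peak period); each
    window starts at the foot of the upstroke (the first sample of the
    monotone rise preceding the peak).
    """
    values = np.asarray(trace.values, dtype=float)
    time = np.asarray(trace.time, dtype=float)
    dt = trace.dt
    if mode == "paced":
        f = pacing_hz or getattr(trace, "pacing_hz", None)
        if f is None:
            raise ValueError("paced mode requires a pacing frequency")
        n_windows = int(np.floor(trace.duration * f + 1e-9))
        bounds = [
            int(round(k / (f * dt))) for k in range(n_windows + 1)
        ]
        bounds = [min(b, len(values)) for b in bounds]
        return [
            (bounds[k], bounds[k + 1])
            for k in range(n_windows)
            if bounds[k + 1] > bounds[k]
        ]
    if mode != "detected":
        raise ValueError("mode must be 'paced' or 'detected'")

    sm = _smooth(values, smooth_window)
    rng_v = float(np.ptp(sm))
    if rng_v <= 0:
        raise NoBeatsError("flat trace: no beats found")
    peaks, _ = signal.find_peaks(sm, prominence=min_prominence_frac * rng_v)
    if len(peaks) >= 2:
        period = float(np.median(np.diff(peaks)))
        peaks, _ = signal.find_peaks(
            sm,
            prominence=min_prominence_frac * rng_v,
            distance=max(1, int(refractory_frac * period)),
        )
    if len(peaks) == 0:
        raise NoBeatsError("no beats found above the prominence threshold")

    feet = []
    for p in peaks:
        i = int(p)
        while i > 0 and sm[i - 1] < sm[i]:
            i -= 1
        feet.append(i)
    # deduplicate feet (two close peaks can share an upstroke)
    feet = sorted(set(feet))
    windows = []
    for k, f0 in enumerate(feet):
        f1 = feet[k + 1] if k + 1 < len(feet) else len(values)
        if f1 > f0:
            windows.append((f0, f1))
    return windows


@dataclass
class ReuptakeFit:
    tau: float
    amplitude: float
    baseline: float
    r_squared: float
    flags: list[str]

    @property
    def reuptake_rate(self) -> float:
        return 1.0 / self.tau if self.tau and np.isfinite(self.tau) else np.nan


def fit_reuptake(
    time: np.ndarray, values: np.ndarray, max_tau_factor: float = 5.0
) -> ReuptakeFit:
    """Least-squares single-exponential fit to a descending-phase segment.

    Initial values come from a log-linear regression of (y - tail mean).
    Fits whose tau exceeds ``max_tau_factor`` times the segment span are
    flagged ``tau_exceeds_window`` (the decay constant is then not
    constrained by the data); non-convergence yields NaN tau and the
    ``no_convergence`` flag.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 8:
        return ReuptakeFit(np.nan, np.nan, np.nan, np.nan, ["too_few_samples"])
    t0 = t[0]
    span = t[-1] - t0
    n_tail = max(2, len(y) // 5)
    b0 = float(np.mean(y[-n_tail:]))
    a0 = float(y[0] - b0)
    resid = y - b0
    pos = resid > max(1e-12, 1e-6 * abs(a0))
    if pos.sum() >= 3 and a0 > 0:
        slope, _ = np.polyfit(t[pos] - t0, np.log(resid[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else span
    else:
        tau0 = span / 3
    tau0 = float(np.clip(tau0, 1e-6, 100 * span))

    def model(tt, b, a, tau):
        return b + a * np.exp(-(tt - t0) / tau)

    flags: list[str] = []
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[b0, a0, tau0], maxfev=10000
        )
        b, a, tau = (float(v) for v in popt)
    except (RuntimeError, ValueError):
        return ReuptakeFit(np.nan, np.nan, np.nan, np.nan, ["no_convergence"])
    pred = model(t, b, a, tau)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    if tau <= 0:
        flags.append("nonpositive_tau")
    elif tau > max_tau_factor * span:
        flags.append("tau_exceeds_window")
    return ReuptakeFit(tau, a, b, r2, flags)


@dataclass
class BeatMetrics:
    diastolic: float
    systolic: float
    amplitude: float
    rise_time: float
    release_rate: float
    tau: float
    reuptake_rate: float
    r_squared: float
    valid: bool = True
    flags: list[str] = field(default_factory=list)


def _crossing_time(
    time: np.ndarray, values: np.ndarray, level: float, start: int, stop: int
) -> float:
    """First upward crossing of `level` in [start, stop), linearly interpolated."""
    for i in range(start, stop):
        if values[i] >= level:
            if i == start:
                return float(time[i])
            v0, v1 = values[i - 1], values[i]
            frac = (level - v0) / (v1 - v0) if v1 > v0 else 0.0
            return float(time[i - 1] + frac * (time[i] - time[i - 1]))
    return float(time[stop - 1])


def beat_metrics(
    trace: CalciumTrace,
    windows: list[tuple[int, int]],
    baseline_frac: float = 0.2,
    rise_fracs: tuple[float, float] = (0.1, 0.9),
    fit_start_frac: float = 0.9,
    smooth_window: int = 1,
    min_amplitude: float | None = None,
    min_r_squared: float = 0.5,
) -> tuple[pd.DataFrame, BeatMetrics]:
    """Per-beat metrics and their average over valid beats.

    Diastolic level uses the last ``baseline_frac`` of the *preceding*
    window (pre-stimulus); the first beat falls back to its own window
    minimum. Beats whose amplitude falls below ``min_amplitude`` (default:
    5x a robust noise estimate) are flagged and excluded from the averages,
    as are beats whose reuptake fit quality is below ``min_r_squared``.
    """
    if not windows:
        raise ValueError("at least one beat window required")
    values = np.asarray(trace.values, dtype=float)
    time = np.asarray(trace.time, dtype=float)
    dt = trace.dt
    if min(stop - start for start, stop in windows) < 10:
        raise ValueError("each beat window needs at least 10 samples")
    if min_amplitude is None:
        # robust noise scale from high-frequency residuals
        noise = np.median(np.abs(np.diff(values))) * 1.4826 / np.sqrt(2)
        min_amplitude = 5.0 * noise

    deriv = _smoothed_derivative(values, dt, smooth_window)
    rows = []
    for k, (start, stop) in enumerate(windows):
        seg = values[start:stop]
        if k > 0:
            p_start, p_stop = windows[k - 1]
            n_base = max(1, int(round(baseline_frac * (p_stop - p_start))))
            dia = float(np.mean(values[p_stop - n_base : p_stop]))
        else:
            dia = float(np.min(seg))
        peak_rel = int(np.argmax(seg))
        sys_ = float(seg[peak_rel])
        amp = sys_ - dia
        flags: list[str] = []
        if amp < min_amplitude:
            rows.append(
                dict(
                    beat=k, diastolic=dia, systolic=sys_, amplitude=amp,
                    rise_time=np.nan, release_rate=np.nan, tau=np.nan,
                    reuptake_rate=np.nan, r_squared=np.nan, valid=False,
                    flags="no_upstroke",
                )
            )
            continue

        lo = dia + rise_fracs[0] * amp
        hi = dia + rise_fracs[1] * amp
        t_lo = _crossing_time(time, values, lo, start, start + peak_rel + 1)
        t_hi = _crossing_time(time, values, hi, start, start + peak_rel + 1)
        rise = max(t_hi - t_lo, dt / 2)
        release = float(np.max(deriv[start : start + peak_rel + 1]))

        fit_level = dia + fit_start_frac * amp
        fi = start + peak_rel
        while fi < stop and values[fi] > fit_level:
            fi += 1
        fit = fit_reuptake(time[fi:stop], values[fi:stop])
        flags.extend(fit.flags)
        valid = np.isfinite(fit.tau) and fit.r_squared >= min_r_squared
        if not valid and "low_r_squared" not in flags and np.isfinite(fit.tau):
            flags.append("low_r_squared")
        rows.append(
            dict(
                beat=k, diastolic=dia, systolic=sys_, amplitude=amp,
                rise_time=rise, release_rate=release, tau=fit.tau,
                reuptake_rate=fit.reuptake_rate, r_squared=fit.r_squared,
                valid=bool(valid), flags=";".join(flags),
            )
        )
    df = pd.DataFrame(rows)
    ok = df[df["valid"]]
    if len(ok):
        avg = BeatMetrics(
            diastolic=float(ok["diastolic"].mean()),
            systolic=float(ok["systolic"].mean()),
            amplitude=float(ok["amplitude"].mean()),
            rise_time=float(ok["rise_time"].mean()),
            release_rate=float(ok["release_rate"].mean()),
            tau=float(ok["tau"].mean()),
            reuptake_rate=float(ok["reuptake_rate"].mean()),
            r_squared=float(ok["r_squared"].mean()),
        )
    else:
        avg = BeatMetrics(*([np.nan] * 8), valid=False, flags=["no_valid_beats"])
    return df, avg


def motion_signal(stack: FrameStack, baseline_window_s: float = 2.0) -> ContractionTrace:
    """Motion trace from an image stack: mean |I_t - I_{t-1}| over pixels.

    The rolling minimum over ``baseline_window_s`` seconds is subtracted so
    slow drift and static texture do not offset the beats. The trace has
    T - 1 samples but keeps the full acquisition duration T * dt.
    """
    diffs = np.abs(np.diff(stack.frames, axis=0))
    s = diffs.mean(axis=(1, 2))
    w = max(3, int(round(baseline_window_s / stack.dt)))
    baseline = ndimage.minimum_filter1d(s, size=min(w, len(s)), mode="nearest")
    values = s - baseline
    time = np.arange(1, stack.n_frames) * stack.dt
    return ContractionTrace(time, values, duration=stack.n_frames * stack.dt)


@dataclass
class ContractionMetrics:
    frequency: float
    amplitude: float
    max_contraction_velocity: float
    max_relaxation_velocity: float
    n_beats: int


def contraction_metrics(
    trace: ContractionTrace,
    windows: list[tuple[int, int]] | None = None,
    smooth_window: int = 3,
    min_prominence_frac: float = 0.3,
) -> ContractionMetrics:
    """Beat frequency, amplitude and peak velocities of a contraction trace.

    Frequency = number of beats / acquisition duration. Velocities are the
    per-beat maxima of the positive (contraction) and negative (relaxation)
    smoothed derivative, reported as magnitudes and averaged over beats.
    """
    if windows is None:
        windows = segment_beats(
            trace, mode="detected", min_prominence_frac=min_prominence_frac,
            smooth_window=smooth_window,
        )
    if len(windows) < 2:
        raise NoBeatsError("contraction metrics require at least 2 beats")
    values = np.asarray(trace.values, dtype=float)
    deriv = _smoothed_derivative(values, trace.dt, smooth_window)
    amps, v_up, v_down = [], [], []
    for start, stop in windows:
        seg = values[start:stop]
        amps.append(float(seg.max() - seg.min()))
        dseg = deriv[start:stop]
        v_up.append(float(np.max(dseg)))
        v_down.append(float(np.max(-dseg)))
    return ContractionMetrics(
        frequency=len(windows) / trace.duration,
        amplitude=float(np.mean(amps)),
        max_contraction_velocity=float(np.mean(v_up)),
        max_relaxation_velocity=float(np.mean(v_down)),
        n_beats=len(windows),
    )


def average_cycles(
    frame: pd.DataFrame,
    value_columns: list[str],
    group_levels: tuple[str, ...] = ("measurement", "cell"),
    cycle_level: str = "cycle",
) -> pd.DataFrame:
    """Hierarchical averaging of per-cycle metrics.

    Cycles are averaged within each combination of ``group_levels`` (e.g.
    measurement x cell), yielding one averaged data point per group — with
    10 measurements of 10 cells this is the 100-points-per-condition scheme.
    """
    for col in (*group_levels, *value_columns):
        if col not in frame.columns:
            raise ValueError(f"missing column {col!r}")
    if len(frame) == 0:
        raise ValueError("empty input")
    out = (
        frame.groupby(list(group_levels), as_index=False)[list(value_columns)]
        .mean()
    )
    return out
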