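"""Synthetic data generation for every downstream analysis stage.

The generators emulate the statistical structure of the real assays:

* clustered 2-D localization patterns (Thomas parent-offspring process with
  ~10 nm localization jitter) and complete-spatial-randomness (CSR) nulls;
* blinking-emitter acquisition stacks (Gaussian PSF spots switching on/off
  on a per-emitter schedule, Gaussian camera background);
* 0.5 Hz field-paced ratiometric calcium transients with a linear upstroke
  and single-exponential decay;
* periodic contraction displacement traces and, optionally, a textured image
  stack that rigidly displaces following the trace.

Every generator draws all randomness from one ``numpy.random.default_rng``
seeded from the model, so identical (parameters, seed) give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CalciumTrace, ContractionTrace, FrameStack, PointPattern, Window

# ---------------------------------------------------------------------------
# Clustered / CSR point patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterModel:
    """Thomas-process model of a clustered localization pattern.

    Poisson-distributed offspring counts around uniformly placed parents,
    isotropic Gaussian offspring spread ``cluster_sigma``, uniform background
    at ``background_rate`` points/nm^2, and additive isotropic Gaussian
    localization jitter ``loc_precision_sigma`` (default 10 nm, the
    instrument's stated localization precision).
    """

    window: Window
    n_parents: int
    offspring_mean: float
    cluster_sigma: float
    background_rate: float = 0.0
    loc_precision_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 0:
            raise ValueError("n_parents must be >= 0")
        if self.offspring_mean < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.cluster_sigma < 0 or self.loc_precision_sigma < 0:
            raise ValueError("sigmas must be >= 0")


def gen_csr(n: int, window: Window, seed: int = 0) -> PointPattern:
    """Complete spatial randomness: n i.i.d. uniform points in the window."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(window.x_min, window.x_max, n)
    ys = rng.uniform(window.y_min, window.y_max, n)
    return PointPattern(np.column_stack([xs, ys]), window)


def gen_clustered(model: ClusterModel) -> PointPattern:
    """Sample a clustered pattern from the Thomas model.

    Offspring falling outside the window (after jitter) are discarded, as are
    out-of-window background points. ``labels`` records the parent index of
    each surviving point (-1 for background).
    """
    rng = np.random.default_rng(model.seed)
    w = model.window
    parents = np.column_stack(
        [
            rng.uniform(w.x_min, w.x_max, model.n_parents),
            rng.uniform(w.y_min, w.y_max, model.n_parents),
        ]
    )
    counts = rng.poisson(model.offspring_mean, model.n_parents)
    total = int(counts.sum())
    offspring = np.repeat(parents, counts, axis=0)
    offspring = offspring + rng.normal(0.0, model.cluster_sigma, (total, 2))
    offspring = offspring + rng.normal(0.0, model.loc_precision_sigma, (total, 2))
    labels = np.repeat(np.arange(model.n_parents), counts)

    n_bg = rng.poisson(model.background_rate * w.area)
    bg = np.column_stack(
        [rng.uniform(w.x_min, w.x_max, n_bg), rng.uniform(w.y_min, w.y_max, n_bg)]
    )
    pts = np.vstack([offspring, bg])
    labels = np.concatenate([labels, np.full(n_bg, -1)])
    inside = w.contains(pts)
    return PointPattern(pts[inside], w, labels[inside])


# ---------------------------------------------------------------------------
# Blinking-emitter frame stacks
# ---------------------------------------------------------------------------


@dataclass
class EmitterStackModel:
    """Acquisition model for a blinking-emitter SMLM series.

    ``blink_schedule`` maps each emitter to a list of half-open on-intervals
    ``(start_frame, stop_frame)``; if None a random schedule is drawn. While
    on, an emitter contributes ``photon_rate`` counts/frame spread over a
    Gaussian PSF of width ``psf_sigma`` (nm). Camera background is additive
    Gaussian noise with the given mean/sd.
    """

    emitters: np.ndarray
    field_shape: tuple[int, int] = (200, 200)
    pixel_size: float = 100.0
    psf_sigma: float = 120.0
    frame_count: int = 2000
    photon_rate: float = 4000.0
    blink_schedule: list[list[tuple[int, int]]] | None = None
    background_mean: float = 100.0
    background_sd: float = 8.0
    exposure: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.emitters = np.asarray(self.emitters, dtype=float).reshape(-1, 2)
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        h, w = self.field_shape
        width_nm, height_nm = w * self.pixel_size, h * self.pixel_size
        if self.emitters.size and (
            np.any(self.emitters[:, 0] < 0)
            or np.any(self.emitters[:, 0] > width_nm)
            or np.any(self.emitters[:, 1] < 0)
            or np.any(self.emitters[:, 1] > height_nm)
        ):
            raise ValueError("all emitters must lie inside the imaged field")


def _random_blink_schedule(
    rng: np.random.Generator, n_emitters: int, frame_count: int
) -> list[list[tuple[int, int]]]:
    """One to three short on-bursts per emitter, never starting at frame 0.

    Frame 0 has no predecessor in the difference-image detector, so synthetic
    schedules start at frame >= 1 and end before the final frame.
    """
    schedule: list[list[tuple[int, int]]] = []
    for _ in range(n_emitters):
        bursts = []
        n_bursts = rng.integers(1, 4)
        t = int(rng.integers(1, max(2, frame_count // 4)))
        for _ in range(n_bursts):
            length = int(rng.integers(1, 5))
            stop = min(t + length, frame_count - 1)
            if stop <= t:
                break
            bursts.append((t, stop))
            t = stop + int(rng.integers(4, max(5, frame_count // 4)))
            if t >= frame_count - 1:
                break
        if not bursts:
            bursts = [(1, 2)]
        schedule.append(bursts)
    return schedule


def _render_spot(
    frame: np.ndarray, x_nm: float, y_nm: float, sigma_nm: float,
    photons: float, pixel_size: float
) -> None:
    """Add a normalized Gaussian spot (integrated over pixel centers) in place."""
    h, w = frame.shape
    sig_px = sigma_nm / pixel_size
    cx, cy = x_nm / pixel_size - 0.5, y_nm / pixel_size - 0.5  # pixel-center coords
    r = max(2, int(np.ceil(4 * sig_px)))
    x0, x1 = max(0, int(np.floor(cx)) - r), min(w, int(np.ceil(cx)) + r + 1)
    y0, y1 = max(0, int(np.floor(cy)) - r), min(h, int(np.ceil(cy)) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    gx = np.exp(-0.5 * ((xs - cx) / sig_px) ** 2)
    gy = np.exp(-0.5 * ((ys - cy) / sig_px) ** 2)
    spot = np.outer(gy, gx)
    total = spot.sum()
    if total > 0:
        frame[y0:y1, x0:x1] += photons * spot / total


def gen_frame_stack(model: EmitterStackModel) -> tuple[FrameStack, pd.DataFrame]:
    """Render the acquisition stack and return it with the ground-truth table.

    The truth table has one row per emitter: position, first on-frame and the
    total number of on-frames, for recall/precision scoring of the detector.
    """
    rng = np.random.default_rng(model.seed)
    schedule = model.blink_schedule
    if schedule is None:
        schedule = _random_blink_schedule(rng, len(model.emitters), model.frame_count)
    if len(schedule) != len(model.emitters):
        raise ValueError("blink_schedule length must match emitter count")

    h, w = model.field_shape
    frames = rng.normal(
        model.background_mean, model.background_sd, (model.frame_count, h, w)
    )
    on_frames: list[np.ndarray] = []
    for (x, y), bursts in zip(model.emitters, schedule):
        on = []
        for start, stop in bursts:
            if not (0 <= start < stop <= model.frame_count):
                raise ValueError(f"blink interval ({start}, {stop}) out of range")
            on.extend(range(start, stop))
        on_frames.append(np.asarray(sorted(set(on)), dtype=int))
        for t in on_frames[-1]:
            _render_spot(
                frames[t], x, y, model.psf_sigma, model.photon_rate, model.pixel_size
            )
    np.clip(frames, 0, None, out=frames)
    truth = pd.DataFrame(
        {
            "emitter_id": np.arange(len(model.emitters)),
            "x_nm": model.emitters[:, 0] if model.emitters.size else [],
            "y_nm": model.emitters[:, 1] if model.emitters.size else [],
            "first_frame": [int(f[0]) if len(f) else -1 for f in on_frames],
            "n_on_frames": [len(f) for f in on_frames],
        }
    )
    return FrameStack(frames, model.pixel_size, model.exposure), truth


# ---------------------------------------------------------------------------
# Calcium transients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransientModel:
    """Paced ratiometric calcium transient: linear upstroke, exponential decay.

    Within each pacing period the ratio rises linearly from diastolic ``d``
    to systolic ``s`` over ``rise_time`` seconds, then decays as
    d + (s - d) * exp(-(t - rise_time)/tau) until the next stimulus.
    """

    pacing_hz: float = 0.5
    duration: float = 20.0
    sample_rate: float = 100.0
    diastolic: float = 1.0
    systolic: float = 1.8
    rise_time: float = 0.1
    tau: float = 0.4
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.systolic <= self.diastolic:
            raise ValueError("systolic must exceed diastolic")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not (0 < self.rise_time < 1.0 / self.pacing_hz):
            raise ValueError("rise_time must lie within one pacing period")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def transient_template(model: TransientModel, time: np.ndarray) -> np.ndarray:
    """Noise-free closed-form transient evaluated at the given times."""
    period = 1.0 / model.pacing_hz
    phase = np.mod(time, period)
    amp = model.systolic - model.diastolic
    rising = phase < model.rise_time
    out = np.empty_like(np.asarray(time, dtype=float))
    out[rising] = model.diastolic + amp * phase[rising] / model.rise_time
    out[~rising] = model.diastolic + amp * np.exp(
        -(phase[~rising] - model.rise_time) / model.tau
    )
    return out


def gen_calcium_trace(model: TransientModel) -> CalciumTrace:
    """Sample a paced calcium trace with additive Gaussian noise."""
    rng = np.random.default_rng(model.seed)
    n = int(round(model.duration * model.sample_rate))
    time = np.arange(n) / model.sample_rate
    values = transient_template(model, time)
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, n)
    onsets = np.arange(0.0, model.duration - 1e-9, 1.0 / model.pacing_hz)
    return CalciumTrace(time, values, model.pacing_hz, onsets)


# ---------------------------------------------------------------------------
# Contraction traces and stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContractionModel:
    """Periodic contraction pulses: linear up over ``t_up``, down over ``t_down``.

    ``phase`` delays the first pulse so the full upstroke is captured on
    camera. In stack mode the displacement of the textured cell is
    ``max_displacement_px * trace`` pixels along x.
    """

    beat_hz: float = 1.0
    fps: float = 50.0
    frame_count: int = 1500
    amplitude: float = 1.0
    t_up: float = 0.12
    t_down: float = 0.24
    phase: float = 0.2
    noise_sd: float = 0.0
    max_displacement_px: float = 3.0
    field_shape: tuple[int, int] = (48, 48)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_hz <= 0 or self.fps <= 0:
            raise ValueError("beat_hz and fps must be > 0")
        if self.frame_count < 2 * self.fps / self.beat_hz:
            raise ValueError("frame_count must cover at least two beats")
        if self.t_up + self.t_down + self.phase >= 1.0 / self.beat_hz:
            raise ValueError("pulse (phase + t_up + t_down) must fit in one period")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")


def contraction_template(model: ContractionModel, time: np.ndarray) -> np.ndarray:
    """Noise-free triangular pulse train evaluated at the given times."""
    period = 1.0 / model.beat_hz
    phase = np.mod(np.asarray(time, dtype=float), period) - model.phase
    out = np.zeros_like(phase)
    up = (phase >= 0) & (phase < model.t_up)
    down = (phase >= model.t_up) & (phase < model.t_up + model.t_down)
    out[up] = model.amplitude * phase[up] / model.t_up
    out[down] = model.amplitude * (1.0 - (phase[down] - model.t_up) / model.t_down)
    return out


def gen_contraction(
    model: ContractionModel, as_stack: bool = False
) -> ContractionTrace | tuple[FrameStack, ContractionTrace]:
    """Generate a contraction trace, or a textured stack following it.

    In stack mode the returned trace is the ground-truth displacement; the
    stack shows a smooth random texture rigidly shifted along x by
    ``max_displacement_px * trace`` pixels per frame, plus camera noise.
    """
    rng = np.random.default_rng(model.seed)
    time = np.arange(model.frame_count) / model.fps
    clean = contraction_template(model, time)
    truth = ContractionTrace(time, clean, duration=model.frame_count / model.fps)
    if not as_stack:
        values = clean.copy()
        if model.noise_sd > 0:
            values = values + rng.normal(0.0, model.noise_sd, len(values))
        return ContractionTrace(time, values, duration=model.frame_count / model.fps)

    h, w = model.field_shape
    texture = ndimage.gaussian_filter(rng.random((h, w)), sigma=1.5)
    texture = 200.0 + 800.0 * (texture - texture.min()) / np.ptp(texture)
    frames = np.empty((model.frame_count, h, w))
    for t in range(model.frame_count):
        shift = model.max_displacement_px * clean[t]
        frames[t] = ndimage.shift(texture, (0.0, shift), order=1, mode="nearest")
    if model.noise_sd > 0:
        frames += rng.normal(0.0, model.noise_sd, frames.shape)
    np.clip(frames, 0, None, out=frames)
    stack = FrameStack(frames, pixel_size=1000.0, dt=1.0 / model.fps)
    return stack, truth


# ---------------------------------------------------------------------------
# Condition presets (illustrative parameter sets, no biological claim)
# ---------------------------------------------------------------------------

CONDITION_PRESETS: dict[str, dict] = {
    # tight, dense clusters — the "organized control" regime
    "control": dict(n_parents=20, offspring_mean=25, cluster_sigma=20.0,
                    background_rate=5e-6),
    # looser clusters, same density — lowers the Ripley L peak
    "loose_clusters": dict(n_parents=20, offspring_mean=25, cluster_sigma=80.0,
                           background_rate=5e-6),
    # fewer, sparser clusters — wider inter-cluster spacing, larger holes
    "sparse_clusters": dict(n_parents=8, offspring_mean=25, cluster_sigma=20.0,
                            background_rate=5e-6),
}


def preset_cluster_model(name: str, window: Window, seed: int = 0) -> ClusterModel:
    """Build a ClusterModel from a named condition preset."""
    if name not in CONDITION_PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(CONDITION_PRESETS)}")
    return ClusterModel(window=window, seed=seed, **CONDITION_PRESETS[name])


# Inter-cluster spacing levels: a fixed number of compact clusters in windows
# of growing side, so the hole structure probed by persistent homology is
# dominated by the spaces *between* clusters. Mean parent spacing scales with
# the window side while cluster size stays fixed.
SPACING_PRESETS: dict[str, float] = {
    "narrow": 400.0,
    "medium": 600.0,
    "wide": 800.0,
}


def spacing_preset_model(name: str, seed: int = 0) -> ClusterModel:
    """ClusterModel for a named inter-cluster spacing level."""
    if name not in SPACING_PRESETS:
        raise KeyError(f"unknown spacing preset {name!r}; available: {sorted(SPACING_PRESETS)}")
    return ClusterModel(
        window=Window.square(SPACING_PRESETS[name]),
        n_parents=12,
        offspring_mean=3,
        cluster_sigma=3.0,
        background_rate=0.0,
        loc_precision_sigma=10.0,
        seed=seed,
    )
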