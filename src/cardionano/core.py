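"""Core data containers shared across the analysis modules.

All spatial coordinates are in nanometres, all times in seconds. The
containers are thin, validated wrappers around numpy arrays with plain-text
I/O (CSV + JSON sidecars, multi-page TIFF for image stacks) so that every
intermediate of the pipeline can be inspected and round-tripped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class CardionanoError(Exception):
    """Base class for all package errors."""


class FormatError(CardionanoError):
    """Raised when an input file or array violates the expected schema."""


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular observation window, in nm."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"window must have positive extent, got "
                f"[{self.x_min}, {self.x_max}] x [{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (N, 2) lying inside the closed window."""
        points = np.asarray(points, dtype=float)
        if points.size == 0:
            return np.zeros(0, dtype=bool)
        return (
            (points[:, 0] >= self.x_min)
            & (points[:, 0] <= self.x_max)
            & (points[:, 1] >= self.y_min)
            & (points[:, 1] <= self.y_max)
        )

    def to_dict(self) -> dict:
        return {
            "x_min_nm": self.x_min,
            "y_min_nm": self.y_min,
            "x_max_nm": self.x_max,
            "y_max_nm": self.y_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Window":
        return cls(d["x_min_nm"], d["y_min_nm"], d["x_max_nm"], d["y_max_nm"])

    @classmethod
    def square(cls, side: float) -> "Window":
        return cls(0.0, 0.0, side, side)


@dataclass
class PointPattern:
    """A 2-D point set with its observation window.

    ``labels`` optionally carries ground-truth cluster membership from the
    synthetic generator (-1 = background noise point).
    """

    points: np.ndarray
    window: Window
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise FormatError("point coordinates must be finite")
        inside = self.window.contains(self.points)
        if not bool(np.all(inside)):
            raise ValueError(
                f"{int((~inside).sum())} point(s) lie outside the window"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.points.shape[0]:
                raise ValueError("labels length must match point count")

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    def to_csv(self, path: str | Path) -> None:
        """Write points as CSV with the window in a ``.window.json`` sidecar."""
        path = Path(path)
        cols = {"x_nm": self.points[:, 0], "y_nm": self.points[:, 1]}
        if self.labels is not None:
            cols["cluster_id"] = self.labels
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".window.json")
        sidecar.write_text(json.dumps(self.window.to_dict(), sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, window: Window | None = None) -> "PointPattern":
        path = Path(path)
        df = pd.read_csv(path)
        for col in ("x_nm", "y_nm"):
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r} in {path}")
        if window is None:
            sidecar = path.with_suffix(path.suffix + ".window.json")
            if sidecar.exists():
                window = Window.from_dict(json.loads(sidecar.read_text()))
            else:
                pts = df[["x_nm", "y_nm"]].to_numpy(float)
                if len(pts) == 0:
                    raise FormatError("cannot infer a window from an empty pattern")
                window = Window(
                    float(pts[:, 0].min()), float(pts[:, 1].min()),
                    float(pts[:, 0].max()) + 1e-9, float(pts[:, 1].max()) + 1e-9,
                )
        labels = df["cluster_id"].to_numpy() if "cluster_id" in df.columns else None
        return cls(df[["x_nm", "y_nm"]].to_numpy(float), window, labels)


@dataclass
class FrameStack:
    """Acquisition image stack: frames (T, H, W), pixel size in nm, frame interval in s."""

    frames: np.ndarray
    pixel_size: float
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frame stack must be (T, H, W) with T >= 2")
        if np.any(self.frames < 0):
            raise ValueError("frame intensities must be non-negative")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def fps(self) -> float:
        return 1.0 / self.dt

    def field_extent(self) -> tuple[float, float]:
        """(width_nm, height_nm) of the imaged field."""
        t, h, w = self.frames.shape
        return w * self.pixel_size, h * self.pixel_size

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        arr = np.clip(self.frames, 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(path, arr)
        meta = {"pixel_size_nm": self.pixel_size, "dt_s": self.dt}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True)
        )

    @classmethod
    def from_tiff(
        cls, path: str | Path, pixel_size: float | None = None, dt: float | None = None
    ) -> "FrameStack":
        import tifffile

        path = Path(path)
        arr = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size = pixel_size or meta.get("pixel_size_nm")
            dt = dt or meta.get("dt_s")
        if pixel_size is None or dt is None:
            raise FormatError("pixel_size and dt required (no metadata sidecar found)")
        return cls(np.asarray(arr, dtype=float), pixel_size, dt)


def _check_uniform_time(time: np.ndarray) -> float:
    diffs = np.diff(time)
    if len(diffs) == 0:
        raise ValueError("trace needs at least two samples")
    dt = float(np.median(diffs))
    if dt <= 0 or not np.allclose(diffs, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled in time")
    return dt


@dataclass
class CalciumTrace:
    """Ratiometric (F340/F380) calcium trace, uniformly sampled."""

    time: np.ndarray
    values: np.ndarray
    pacing_hz: float | None = None
    stim_onsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have the same length")
        self.dt = _check_uniform_time(self.time)

    @property
    def duration(self) -> float:
        """Total covered time (one sample interval per sample)."""
        return len(self.time) * self.dt

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, pacing_hz: float | None = None) -> "CalciumTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "value"):
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r} in {path}")
        return cls(df["time_s"].to_numpy(float), df["value"].to_numpy(float), pacing_hz)


@dataclass
class ContractionTrace:
    """Contraction motion trace in arbitrary units, uniformly sampled.

    ``duration`` is the acquisition duration of the source recording; for a
    trace derived by frame differencing it equals frame_count / fps even
    though the trace itself has frame_count - 1 samples.
    """

    time: np.ndarray
    values: np.ndarray
    duration: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise ValueError("time and values must have the same length")
        self.dt = _check_uniform_time(self.time)
        if self.duration is None:
            self.duration = len(self.time) * self.dt

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContractionTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "value"):
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r} in {path}")
        return cls(df["time_s"].to_numpy(float), df["value"].to_numpy(float))
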