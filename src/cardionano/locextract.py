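"""Localization extraction: frame stacks -> localization table ("Orte-Matrix").

The detector works on brightness differences between consecutive frames:
positive differences mark *appearance* events (a molecule switching on),
negative differences mark *disappearance* events (switching off). The pair
delimits the frames a molecule was on. Re-appearances after a dark state of
at most ``max_gap_frames`` frames (default 2) are merged into the same
molecule; longer dark states start a new one. Each merged chain yields one
table row at the intensity-weighted barycenter of all its appearance-event
pixels, with the summed appearance intensity and the count of on-frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .core import FormatError, FrameStack

ORTE_COLUMNS = ["x_nm", "y_nm", "first_frame", "n_frames_merged", "intensity"]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_nm": pd.Series(dtype=float),
            "y_nm": pd.Series(dtype=float),
            "first_frame": pd.Series(dtype=int),
            "n_frames_merged": pd.Series(dtype=int),
            "intensity": pd.Series(dtype=float),
        }
    )


@dataclass
class _Event:
    """A thresholded connected region in one difference image."""

    frame: int
    x: float  # intensity-weighted centroid, nm
    y: float
    total: float  # summed intensity of the region
    wx: float  # intensity-weighted coordinate sums, for chain barycenters
    wy: float


@dataclass
class _Track:
    first_frame: int
    interval_start: int  # start frame of the current on-interval
    frames_on: int = 0
    intensity: float = 0.0
    wx: float = 0.0
    wy: float = 0.0
    state: str = "on"  # "on" (awaiting disappearance) or "dark"
    last_on_end: int = -1  # exclusive end frame of the last on-interval

    @property
    def x(self) -> float:
        return self.wx / self.intensity

    @property
    def y(self) -> float:
        return self.wy / self.intensity


def _find_events(
    diff: np.ndarray, frame: int, pixel_threshold: float,
    intensity_threshold: float, pixel_size: float,
) -> list[_Event]:
    mask = diff > pixel_threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    events = []
    for region in measure.regionprops(labels, intensity_image=diff):
        total = float(region.image_intensity.sum())
        if total < intensity_threshold:
            continue
        cy, cx = region.centroid_weighted  # (row, col)
        x_nm = (cx + 0.5) * pixel_size
        y_nm = (cy + 0.5) * pixel_size
        events.append(
            _Event(frame, x_nm, y_nm, total, total * x_nm, total * y_nm)
        )
    return events


def _estimate_pixel_threshold(stack: FrameStack) -> float:
    """Robust noise scale of the consecutive-frame differences (5 sigma)."""
    diffs = np.diff(stack.frames, axis=0)
    sample = diffs.ravel()
    if sample.size > 200_000:
        step = sample.size // 200_000
        sample = sample[::step]
    mad = np.median(np.abs(sample - np.median(sample)))
    sigma = 1.4826 * mad
    return max(5.0 * sigma, 1e-9)


def detect_signals(
    stack: FrameStack,
    intensity_threshold: float,
    merge_radius: float,
    max_gap_frames: int = 2,
    pixel_threshold: float | None = None,
) -> pd.DataFrame:
    """Extract the localization table from an acquisition stack.

    Parameters
    ----------
    stack : FrameStack
        T >= 2 frames of non-negative intensities.
    intensity_threshold : float
        Minimum summed region intensity (counts) for a candidate signal.
    merge_radius : float
        Maximum distance (nm) when linking events into one molecule.
    max_gap_frames : int
        Dark states of at most this many frames are bridged; longer dark
        states start a new molecule (default 2).
    pixel_threshold : float, optional
        Per-pixel difference threshold defining connected regions; estimated
        from the difference-image noise if omitted.
    """
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be > 0")
    if merge_radius <= 0:
        raise ValueError("merge_radius must be > 0")
    if pixel_threshold is None:
        pixel_threshold = _estimate_pixel_threshold(stack)

    frames = stack.frames
    open_tracks: list[_Track] = []
    done: list[_Track] = []

    def match(events: list[_Event], candidates: list[_Track]) -> dict[int, _Track]:
        """Greedy nearest-neighbor matching within merge_radius."""
        pairs: dict[int, _Track] = {}
        taken: set[int] = set()
        order = sorted(range(len(events)), key=lambda i: -events[i].total)
        for i in order:
            ev = events[i]
            best, best_d = None, merge_radius
            for j, tr in enumerate(candidates):
                if j in taken or tr.intensity == 0:
                    continue
                d = float(np.hypot(tr.x - ev.x, tr.y - ev.y))
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                taken.add(best)
                pairs[i] = candidates[best]
        return pairs

    for t in range(1, stack.n_frames):
        d = frames[t] - frames[t - 1]
        appear = _find_events(
            np.clip(d, 0, None), t, pixel_threshold, intensity_threshold,
            stack.pixel_size,
        )
        disappear = _find_events(
            np.clip(-d, 0, None), t, pixel_threshold, intensity_threshold,
            stack.pixel_size,
        )

        # disappearance at frame t: the molecule was on through frame t-1
        on_tracks = [tr for tr in open_tracks if tr.state == "on"]
        for ev_i, tr in match(disappear, on_tracks).items():
            tr.frames_on += t - tr.interval_start
            tr.state = "dark"
            tr.last_on_end = t

        # appearance at frame t: re-open a dark track within the gap, else new
        dark_tracks = [
            tr
            for tr in open_tracks
            if tr.state == "dark" and (t - tr.last_on_end) <= max_gap_frames
        ]
        matched = match(appear, dark_tracks)
        for i, ev in enumerate(appear):
            if i in matched:
                tr = matched[i]
                tr.state = "on"
                tr.interval_start = t
            else:
                tr = _Track(first_frame=t, interval_start=t)
                open_tracks.append(tr)
            tr.intensity += ev.total
            tr.wx += ev.wx
            tr.wy += ev.wy

        # dark states persisting for more than max_gap_frames close the track
        still_open = []
        for tr in open_tracks:
            if tr.state == "dark" and (t - tr.last_on_end) > max_gap_frames:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

    for tr in open_tracks:
        if tr.state == "on":  # on until the end of the acquisition
            tr.frames_on += stack.n_frames - tr.interval_start
        done.append(tr)

    rows = [
        (tr.x, tr.y, tr.first_frame, max(tr.frames_on, 1), tr.intensity)
        for tr in done
        if tr.intensity >= intensity_threshold
    ]
    rows.sort(key=lambda r: (r[2], r[0], r[1]))
    if not rows:
        return _empty_table()
    return pd.DataFrame(rows, columns=ORTE_COLUMNS)


def filter_localizations(table: pd.DataFrame, min_intensity: float) -> pd.DataFrame:
    """Keep rows with intensity >= min_intensity, preserving order."""
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    return table[table["intensity"] >= min_intensity].reset_index(drop=True)


def write_orte(table: pd.DataFrame, path) -> None:
    """Write a localization table as CSV (full float precision)."""
    missing = [c for c in ORTE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"localization table missing column(s): {missing}")
    table[ORTE_COLUMNS].to_csv(path, index=False)


def read_orte(path) -> pd.DataFrame:
    """Read a localization-table CSV, validating schema and coordinates."""
    df = pd.read_csv(path)
    for col in ORTE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if len(df) == 0:
        return _empty_table()
    for col in ("x_nm", "y_nm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.isna().idxmax())
            raise FormatError(
                f"non-numeric or NaN value in column {col!r} at row {bad}"
            )
        df[col] = vals
    df["first_frame"] = df["first_frame"].astype(int)
    df["n_frames_merged"] = df["n_frames_merged"].astype(int)
    df["intensity"] = df["intensity"].astype(float)
    return df[ORTE_COLUMNS]
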