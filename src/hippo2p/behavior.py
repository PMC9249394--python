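"""Floating circular-track behavior processing.

Converts raw tracker samples (collected faster than the imaging frame rate)
into per-imaging-frame behavioral state: circular-median position, median
speed, a movement mask, and lap structure on the annular track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrackGeometry",
    "BehaviorFrames",
    "make_track",
    "circular_median",
    "aggregate_to_frames",
    "movement_mask",
    "segment_laps",
    "process_session",
]


@dataclass(frozen=True)
class TrackGeometry:
    """Annular track geometry and spatial binning.

    The mouse runs on the annulus between an outer wall and an inner
    circle; positions are linearized along the midline circle.
    """

    outer_diameter_mm: float
    inner_diameter_mm: float
    n_bins: int
    midline_circumference_cm: float
    bin_length_cm: float
    bin_edges_cm: np.ndarray = field(repr=False)

    @property
    def midline_radius_cm(self) -> float:
        return self.midline_circumference_cm / (2.0 * np.pi)

    def position_from_angle(self, angle_rad: np.ndarray) -> np.ndarray:
        """Linearized position in cm from polar angle, wrapped to [0, C)."""
        pos = np.mod(angle_rad, 2.0 * np.pi) * self.midline_radius_cm
        # guard against pos == C from floating wrap
        return np.where(pos >= self.midline_circumference_cm, 0.0, pos)

    def bin_index(self, position_cm: np.ndarray) -> np.ndarray:
        idx = np.floor(
            np.asarray(position_cm) / self.bin_length_cm
        ).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)


@dataclass
class BehaviorFrames:
    """Per-imaging-frame behavioral state."""

    frame_times_s: np.ndarray
    angle_rad: np.ndarray
    position_cm: np.ndarray
    speed_mm_s: np.ndarray
    heading: np.ndarray
    moving: np.ndarray
    lap_id: np.ndarray
    lap_kept: np.ndarray
    interpolated: np.ndarray

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times_s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.frame_times_s,
                "angle_rad": self.angle_rad,
                "position_cm": self.position_cm,
                "speed_mm_s": self.speed_mm_s,
                "heading": self.heading,
                "moving": self.moving,
                "lap_id": self.lap_id,
            }
        )


def make_track(
    outer_diameter_mm: float = 250.0,
    inner_diameter_mm: float = 140.0,
    n_bins: int = 72,
) -> TrackGeometry:
    """Build the circular-track geometry.

    The midline circumference is pi * (outer + inner)/2; the default
    250 mm / 140 mm annulus gives 61.26 cm, divided into 72 bins of
    ~0.85 cm.
    """
    if not (outer_diameter_mm >= inner_diameter_mm > 0):
        raise ValueError("require outer_diameter >= inner_diameter > 0")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    midline_diameter_cm = (outer_diameter_mm + inner_diameter_mm) / 2.0 / 10.0
    circumference_cm = np.pi * midline_diameter_cm
    bin_length = circumference_cm / n_bins
    edges = np.linspace(0.0, circumference_cm, n_bins + 1)
    return TrackGeometry(
        outer_diameter_mm=outer_diameter_mm,
        inner_diameter_mm=inner_diameter_mm,
        n_bins=n_bins,
        midline_circumference_cm=circumference_cm,
        bin_length_cm=bin_length,
        bin_edges_cm=edges,
    )


def circular_median(angles_rad: np.ndarray) -> float:
    """Median direction of a sample of angles.

    Minimizes the mean absolute circular distance over candidate medians
    taken from the sample itself; ties are resolved by the circular mean
    of all minimizers (so {350 deg, 10 deg} -> 0 deg).
    """
    a = np.mod(np.asarray(angles_rad, dtype=float), 2.0 * np.pi)
    if a.size == 0:
        raise ValueError("empty angle sample")
    if a.size == 1:
        return float(a[0])
    d = np.abs(a[:, None] - a[None, :])
    d = np.minimum(d, 2.0 * np.pi - d)
    cost = d.sum(axis=1)
    best = cost <= cost.min() + 1e-12
    cands = a[best]
    # circular mean of the minimizing candidates
    m = np.angle(np.exp(1j * cands).mean())
    res = float(np.mod(m, 2.0 * np.pi))
    if np.isclose(res, 2.0 * np.pi):
        res = 0.0
    return res


def aggregate_to_frames(
    samples: pd.DataFrame, frame_times_s: np.ndarray
) -> pd.DataFrame:
    """Reduce tracker samples to one row per imaging frame.

    All samples with timestamp in [t_k, t_{k+1}) are grouped; the ordinary
    median is used for speed/heading/xy and the circular median for the
    polar angle. Frames with no samples carry the previous frame's values
    forward and are flagged in the ``interpolated`` column.

    Parameters
    ----------
    samples
        Columns ``time_s``, ``angle_rad``, ``speed_mm_s`` and optionally
        ``heading``, ``x_mm``, ``y_mm``.
    frame_times_s
        Monotone imaging frame-start times; the last frame extends by the
        median frame interval.
    """
    t = np.asarray(frame_times_s, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("frame_times_s must be non-empty and increasing")
    ts = samples["time_s"].to_numpy(dtype=float)
    if ts.size == 0:
        raise ValueError("no behavioral samples in session")
    dt = np.median(np.diff(t)) if t.size > 1 else 1.0
    edges = np.append(t, t[-1] + dt)
    which = np.searchsorted(edges, ts, side="right") - 1
    ok = (which >= 0) & (which < t.size)
    if not ok.any():
        raise ValueError("no behavioral samples overlap the frame grid")

    linear_cols = [
        c for c in ("speed_mm_s", "heading", "x_mm", "y_mm") if c in samples
    ]
    out = {c: np.full(t.size, np.nan) for c in linear_cols}
    out["angle_rad"] = np.full(t.size, np.nan)
    interpolated = np.ones(t.size, dtype=bool)

    sub = samples.loc[ok].copy()
    sub["_frame"] = which[ok]
    for f, grp in sub.groupby("_frame", sort=False):
        interpolated[f] = False
        out["angle_rad"][f] = circular_median(grp["angle_rad"].to_numpy())
        for c in linear_cols:
            out[c][f] = np.median(grp[c].to_numpy())

    # forward/backward fill empty frames
    df = pd.DataFrame(out, index=np.arange(t.size))
    df = df.ffill().bfill()
    df.insert(0, "time_s", t)
    df["interpolated"] = interpolated
    return df.reset_index(drop=True)


def movement_mask(
    speed_mm_s: np.ndarray,
    frame_rate_hz: float,
    threshold_mm_s: float = 20.0,
    min_dur_s: float = 1.0,
    buffer_s: float = 0.5,
    smooth: bool = True,
) -> np.ndarray:
    """Boolean mask of frames where the mouse counts as moving.

    The instantaneous speed is smoothed (0.5 s boxcar), runs of frames
    with smoothed speed above 20 mm/s lasting more than 1 s are kept, and
    each kept run is dilated by a 0.5 s buffer on both sides.
    """
    v = np.asarray(speed_mm_s, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("speed must be finite")
    if v.size == 0:
        return np.zeros(0, dtype=bool)
    if smooth:
        w = max(1, int(round(0.5 * frame_rate_hz)))
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="same")
    above = v > threshold_mm_s
    mask = np.zeros(v.size, dtype=bool)
    min_frames = min_dur_s * frame_rate_hz
    buf = int(round(buffer_s * frame_rate_hz))
    # run-length scan
    idx = 0
    n = v.size
    while idx < n:
        if above[idx]:
            j = idx
            while j < n and above[j]:
                j += 1
            if (j - idx) > min_frames:
                lo = max(0, idx - buf)
                hi = min(n, j + buf)
                mask[lo:hi] = True
            idx = j
        else:
            idx += 1
    return mask


def segment_laps(
    angle_rad: np.ndarray,
    speed_mm_s: np.ndarray | None = None,
    speed_cutoff_mm_s: float = 180.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign frames to laps and flag laps run too fast to keep.

    A lap boundary occurs at each signed accumulation of a full 2*pi of
    rotation from the previous boundary (net rotation, so direction
    reversals only complete a lap once the net displacement reaches a full
    turn). Partial laps at the session edges get ``lap_id = -1``. A lap
    whose mean instantaneous speed exceeds 180 mm/s is flagged
    ``lap_kept = False`` (slow calcium signals cannot be attributed to the
    small spatial bins on such laps).

    Returns
    -------
    lap_id : int array, -1 where unassigned
    lap_kept : bool array, one entry per completed lap
    """
    ang = np.unwrap(np.asarray(angle_rad, dtype=float))
    n = ang.size
    lap_id = np.full(n, -1, dtype=int)
    boundaries = [0]
    ref = ang[0]
    two_pi = 2.0 * np.pi
    for i in range(1, n):
        delta = ang[i] - ref
        if abs(delta) >= two_pi:
            boundaries.append(i)
            ref = ref + np.sign(delta) * two_pi
    if len(boundaries) < 2:
        return lap_id, np.zeros(0, dtype=bool)
    n_laps = len(boundaries) - 1
    kept = np.ones(n_laps, dtype=bool)
    for k in range(n_laps):
        lo, hi = boundaries[k], boundaries[k + 1]
        lap_id[lo:hi] = k
        if speed_mm_s is not None:
            if np.mean(np.asarray(speed_mm_s, float)[lo:hi]) > speed_cutoff_mm_s:
                kept[k] = False
    return lap_id, kept


def process_session(
    samples: pd.DataFrame,
    frame_times_s: np.ndarray,
    track: TrackGeometry,
    smooth: bool = True,
) -> BehaviorFrames:
    """Full behavior pipeline: aggregate, mask movement, segment laps."""
    frames = aggregate_to_frames(samples, frame_times_s)
    rate = 1.0 / float(np.median(np.diff(np.asarray(frame_times_s))))
    moving = movement_mask(frames["speed_mm_s"].to_numpy(), rate, smooth=smooth)
    lap_id, lap_kept = segment_laps(
        frames["angle_rad"].to_numpy(), frames["speed_mm_s"].to_numpy()
    )
    angle = frames["angle_rad"].to_numpy()
    return BehaviorFrames(
        frame_times_s=np.asarray(frame_times_s, dtype=float),
        angle_rad=angle,
        position_cm=track.position_from_angle(angle),
        speed_mm_s=frames["speed_mm_s"].to_numpy(),
        heading=frames["heading"].to_numpy()
        if "heading" in frames
        else np.zeros(angle.size),
        moving=moving,
        lap_id=lap_id,
        lap_kept=lap_kept,
        interpolated=frames["interpolated"].to_numpy(),
    )
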