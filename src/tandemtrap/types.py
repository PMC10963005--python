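"""Core data containers for paired-trajectory and posture analysis.

Conventions
-----------
* Coordinates are millimetres with y increasing upward; the origin is
  arbitrary per recording.  Readers expose a flag to flip y for data that
  came from image coordinates (origin top-left).
* Headings are radians, counter-clockwise from the +x axis, stored wrapped
  to ``[0, 2*pi)``.  A missing heading is NaN.
* Frame indices are 0-based integers; all intervals are half-open
  ``[start, stop)``.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

TWO_PI = 2.0 * np.pi

#: The six tracked body points: (f)emale / (m)ale head, pronotum border,
#: abdomen tip.
BODY_PARTS = ("fHead", "fPro", "fTip", "mHead", "mPro", "mTip")


def wrap_angle(h: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to [0, 2*pi); NaN passes through."""
    return np.mod(h, TWO_PI)


@dataclasses.dataclass
class TrackedIndividual:
    """One animal's per-frame centroid (and optional heading) series.

    Parameters
    ----------
    individual_id : str
        Stable identifier, e.g. ``"p01-e01-F"``.
    sex : {"F", "M"}
    body_length_mm : float
        Head-to-abdomen-tip length, used to normalise distances and speeds.
    frame_index, x_mm, y_mm : arrays of equal length
        Strictly increasing frame indices and centroid coordinates.
    heading_rad : array or None
        Heading per frame; NaN (or None for the whole array) means missing.
    """

    individual_id: str
    sex: str
    body_length_mm: float
    frame_index: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    heading_rad: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        self.body_length_mm = float(self.body_length_mm)
        if not self.body_length_mm > 0:
            raise ValueError("body_length_mm must be positive")
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        n = self.frame_index.size
        if self.x_mm.size != n or self.y_mm.size != n:
            raise ValueError("frame_index, x_mm, y_mm must have equal length")
        if n > 1 and not np.all(np.diff(self.frame_index) > 0):
            raise ValueError(
                f"{self.individual_id}: frame_index must be strictly increasing "
                "with no duplicates"
            )
        if self.heading_rad is None:
            self.heading_rad = np.full(n, np.nan)
        else:
            h = np.array(self.heading_rad, dtype=float, copy=True)
            if h.size != n:
                raise ValueError("heading_rad length mismatch")
            ok = np.isfinite(h)
            h[ok] = np.mod(h[ok], TWO_PI)
            self.heading_rad = h

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.size)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of centroid coordinates in mm."""
        return np.column_stack([self.x_mm, self.y_mm])

    def copy(self) -> "TrackedIndividual":
        return TrackedIndividual(
            self.individual_id,
            self.sex,
            self.body_length_mm,
            self.frame_index.copy(),
            self.x_mm.copy(),
            self.y_mm.copy(),
            self.heading_rad.copy(),
        )

    def window(self, start: int, stop: int) -> "TrackedIndividual":
        """Frames with ``start <= frame_index < stop``."""
        m = (self.frame_index >= start) & (self.frame_index < stop)
        return TrackedIndividual(
            self.individual_id,
            self.sex,
            self.body_length_mm,
            self.frame_index[m],
            self.x_mm[m],
            self.y_mm[m],
            self.heading_rad[m],
        )


@dataclasses.dataclass
class PairEvent:
    """Female + male trajectories for one recording / trap-entry event.

    ``entry_frame`` is the frame at which the leader first touched the
    sticky surface (trapped condition only).  ``f_escape_frame`` /
    ``m_escape_frame`` record when an individual left the surface; ``None``
    means censored (still trapped when the recording ended).  Natural
    events carry none of these.
    """

    pair_id: str
    event_id: str
    condition: str
    fps: float
    female: TrackedIndividual
    male: TrackedIndividual
    entry_frame: int | None = None
    f_escape_frame: int | None = None
    m_escape_frame: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("natural", "trapped"):
            raise ValueError(f"condition must be natural|trapped, got {self.condition!r}")
        self.fps = float(self.fps)
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.female.sex != "F":
            raise ValueError(f"event {self.event_id}: female track has sex {self.female.sex!r}")
        if self.male.sex != "M":
            raise ValueError(f"event {self.event_id}: male track has sex {self.male.sex!r}")
        if self.condition == "natural":
            if any(v is not None for v in (self.entry_frame, self.f_escape_frame, self.m_escape_frame)):
                raise ValueError(f"event {self.event_id}: natural events carry no entry/escape frames")
        else:
            for name in ("f_escape_frame", "m_escape_frame"):
                esc = getattr(self, name)
                if esc is not None and self.entry_frame is not None and esc < self.entry_frame:
                    raise ValueError(f"event {self.event_id}: {name} precedes entry_frame")

    @property
    def key(self) -> tuple[str, str]:
        return (self.pair_id, self.event_id)

    @property
    def mean_body_length_mm(self) -> float:
        return 0.5 * (self.female.body_length_mm + self.male.body_length_mm)

    @property
    def last_frame(self) -> int:
        """Last frame index observed for both individuals."""
        return int(min(self.female.frame_index[-1], self.male.frame_index[-1]))

    def window(self, start: int, stop: int) -> "PairEvent":
        """Restrict both tracks to frames in [start, stop); metadata kept."""
        return dataclasses.replace(
            self, female=self.female.window(start, stop), male=self.male.window(start, stop)
        )

    def both_trapped_stop(self) -> int:
        """First frame at which the pair stops being jointly trapped.

        The earlier of the two escape frames, or one past the last
        jointly-observed frame when both are censored.
        """
        if self.condition != "trapped":
            raise ValueError("both_trapped_stop is defined for trapped events only")
        stop = self.last_frame + 1
        for esc in (self.f_escape_frame, self.m_escape_frame):
            if esc is not None:
                stop = min(stop, esc)
        return stop


@dataclasses.dataclass
class PostureFrame:
    """Six labelled body points for one frame.

    ``points`` maps each name in :data:`BODY_PARTS` to ``(x_mm, y_mm,
    likelihood)``.  A point whose likelihood fell below the configured
    cutoff is stored with NaN coordinates — it is marked missing, never
    silently kept.
    """

    frame_index: int
    points: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        unknown = set(self.points) - set(BODY_PARTS)
        if unknown:
            raise ValueError(
                f"unknown body part(s) {sorted(unknown)}; expected {list(BODY_PARTS)}"
            )
        pts = {}
        for name in BODY_PARTS:
            x, y, lik = self.points.get(name, (np.nan, np.nan, np.nan))
            pts[name] = (float(x), float(y), float(lik))
        self.points = pts

    def xy(self, name: str) -> np.ndarray | None:
        """Coordinates of a point, or None if missing."""
        x, y, _ = self.points[name]
        if np.isnan(x) or np.isnan(y):
            return None
        return np.array([x, y])

    def has(self, *names: str) -> bool:
        return all(self.xy(n) is not None for n in names)
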