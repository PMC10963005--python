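"""Per-frame and per-event spatial-organization metrics.

The quantities here describe how two animals in a pair are arranged
relative to each other:

* ``distance_bl`` — centroid-to-centroid distance normalised by the mean
  of the two body lengths, so "1 BL" is about one animal length.
* ``rel_dir_f`` / ``rel_dir_m`` — unsigned angle in [0, pi] between the
  focal animal's heading and the bearing to its partner (0 = partner
  directly ahead, pi = directly behind).
* ``heading_diff`` — unsigned difference of the two headings in [0, pi]
  (0 = parallel same direction, pi = antiparallel).
* ``interacting`` — True when the raw mm distance is below the sum of the
  two body lengths ("twice a termite body length"), the conservative
  reach within which tandem partners can interact.

Speeds are forward differences of the centroid, in body lengths per
second of the focal animal's own body length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .types import PairEvent, TrackedIndividual, wrap_angle


def estimate_heading(ind: TrackedIndividual, min_step_mm: float = 0.1) -> TrackedIndividual:
    """Fill missing headings from centroid displacements.

    The heading at frame t is the direction of the displacement t -> t+1
    when that displacement is at least ``min_step_mm`` long; otherwise the
    last valid heading is carried forward (the animal is standing still).
    Leading undefined headings are back-filled from the first valid one.
    Headings already present on the input are kept.
    """
    if ind.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate headings")
    out = ind.copy()
    h = out.heading_rad
    dx = np.diff(out.x_mm)
    dy = np.diff(out.y_mm)
    steps = np.hypot(dx, dy)
    disp_dir = np.arctan2(dy, dx)
    last = np.nan
    for t in range(out.n_frames):
        if np.isfinite(h[t]):
            last = h[t]
            continue
        if t < out.n_frames - 1 and steps[t] >= min_step_mm:
            last = wrap_angle(disp_dir[t])
        h[t] = last
    if np.isnan(h[0]):
        valid = np.flatnonzero(np.isfinite(h))
        if valid.size == 0:
            raise ValueError(
                f"{ind.individual_id}: heading unresolvable "
                f"(all displacements below {min_step_mm} mm and no prior heading)"
            )
        h[: valid[0]] = h[valid[0]]
    out.heading_rad = wrap_angle(h)
    return out


def speed_bl_s(
    ind: TrackedIndividual, fps: float, body_length_mm: float | None = None
) -> np.ndarray:
    """Per-frame speed in body lengths per second (forward differences).

    The speed at frame t is ``||pos(t+1) - pos(t)|| * fps /
    body_length_mm``; the last frame has no forward difference and is
    dropped, so the result has ``n_frames - 1`` entries.
    """
    if ind.n_frames < 2:
        raise ValueError("need at least 2 frames for speeds")
    bl = ind.body_length_mm if body_length_mm is None else float(body_length_mm)
    if bl <= 0:
        raise ValueError("body length must be positive")
    steps = np.hypot(np.diff(ind.x_mm), np.diff(ind.y_mm))
    return steps * float(fps) / bl


def relative_direction(
    focal_pos: np.ndarray, focal_heading: np.ndarray | float, partner_pos: np.ndarray
) -> np.ndarray | float:
    """Unsigned angle in [0, pi] between a heading and the bearing to the partner.

    Returns NaN where the two positions coincide (bearing undefined).
    Vectorised over leading axes; positions are (..., 2) arrays.
    """
    focal_pos = np.asarray(focal_pos, dtype=float)
    partner_pos = np.asarray(partner_pos, dtype=float)
    d = partner_pos - focal_pos
    bearing = np.arctan2(d[..., 1], d[..., 0])
    ang = np.abs(np.angle(np.exp(1j * (bearing - np.asarray(focal_heading, dtype=float)))))
    coincident = (d[..., 0] == 0) & (d[..., 1] == 0)
    return np.where(coincident, np.nan, ang) if np.ndim(ang) else (np.nan if coincident else float(ang))


def heading_difference(h1, h2) -> np.ndarray | float:
    """Unsigned heading difference in [0, pi]."""
    return np.abs(np.angle(np.exp(1j * (np.asarray(h1, float) - np.asarray(h2, float)))))


def _aligned(event: PairEvent) -> tuple[np.ndarray, TrackedIndividual, TrackedIndividual, np.ndarray, np.ndarray]:
    """Common frames of the two tracks, with headings estimated if needed."""
    f, m = event.female, event.male
    if np.isnan(f.heading_rad).any():
        f = estimate_heading(f)
    if np.isnan(m.heading_rad).any():
        m = estimate_heading(m)
    common, fi, mi = np.intersect1d(f.frame_index, m.frame_index, return_indices=True)
    if common.size == 0:
        raise ValueError(f"event {event.event_id}: tracks share no frames")
    return common, f, m, fi, mi


def pair_metrics_arrays(event: PairEvent) -> dict[str, np.ndarray]:
    """Per-frame pair metrics as plain arrays (fast path; see module docs)."""
    common, f, m, fi, mi = _aligned(event)
    pf = f.positions[fi]
    pm = m.positions[mi]
    hf = f.heading_rad[fi]
    hm = m.heading_rad[mi]
    raw = np.hypot(*(pf - pm).T)
    mean_bl = event.mean_body_length_mm
    thresh = f.body_length_mm + m.body_length_mm
    n = common.size
    sp_f = np.full(n, np.nan)
    sp_m = np.full(n, np.nan)
    if n >= 2:
        sp_f[:-1] = np.hypot(*np.diff(pf, axis=0).T) * event.fps / f.body_length_mm
        sp_m[:-1] = np.hypot(*np.diff(pm, axis=0).T) * event.fps / m.body_length_mm
    return {
        "frame_index": common,
        "distance_bl": raw / mean_bl,
        "rel_dir_f": np.asarray(relative_direction(pf, hf, pm)),
        "rel_dir_m": np.asarray(relative_direction(pm, hm, pf)),
        "heading_diff": np.asarray(heading_difference(hf, hm)),
        "speed_f_bl_s": sp_f,
        "speed_m_bl_s": sp_m,
        "interacting": raw < thresh,
    }


def pair_metrics(event: PairEvent) -> pd.DataFrame:
    """Per-frame spatial-organization metrics for one event.

    Columns: frame_index, distance_bl, rel_dir_f, rel_dir_m, heading_diff,
    speed_f_bl_s, speed_m_bl_s, interacting.  The interaction flag is True
    when the raw distance is strictly below the sum of the two body
    lengths.
    """
    return pd.DataFrame(pair_metrics_arrays(event))


@dataclasses.dataclass
class DensityMap:
    """Egocentric partner-position density on a square grid.

    The focal animal sits at the origin heading toward +y; the grid spans
    ``[-extent_bl, extent_bl]`` on both axes with square bins of
    ``bin_size_bl``.  Entries sum to 1 over in-range observations.
    """

    focal_sex: str
    extent_bl: float
    bin_size_bl: float
    grid: np.ndarray
    n_obs: int

    @property
    def edges(self) -> np.ndarray:
        nbins = self.grid.shape[0]
        return np.linspace(-self.extent_bl, self.extent_bl, nbins + 1)


def density_map(
    events: list[PairEvent],
    focal_sex: str = "F",
    extent_bl: float = 2.0,
    bin_size_bl: float = 0.1,
    interacting_only: bool = True,
) -> DensityMap:
    """Pooled density of the partner's position in the focal animal's frame.

    Each kept frame contributes the partner centroid translated and
    rotated so the focal animal is at the origin heading +y, in units of
    the event's mean body length.
    """
    if focal_sex not in ("F", "M"):
        raise ValueError("focal_sex must be 'F' or 'M'")
    xs, ys = [], []
    for ev in events:
        common, f, m, fi, mi = _aligned(ev)
        if focal_sex == "F":
            fp, fh, pp = f.positions[fi], f.heading_rad[fi], m.positions[mi]
        else:
            fp, fh, pp = m.positions[mi], m.heading_rad[mi], f.positions[fi]
        d = (pp - fp) / ev.mean_body_length_mm
        if interacting_only:
            raw = np.hypot(*(pp - fp).T)
            keep = raw < (f.body_length_mm + m.body_length_mm)
            d, fh = d[keep], fh[keep]
        a = np.pi / 2 - fh  # rotate heading onto +y
        ca, sa = np.cos(a), np.sin(a)
        xs.append(ca * d[:, 0] - sa * d[:, 1])
        ys.append(sa * d[:, 0] + ca * d[:, 1])
    x = np.concatenate(xs) if xs else np.empty(0)
    if x.size == 0:
        raise ValueError("empty density: no interacting frames in the input events")
    y = np.concatenate(ys)
    nbins = int(round(2 * extent_bl / bin_size_bl))
    edges = np.linspace(-extent_bl, extent_bl, nbins + 1)
    grid, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    total = grid.sum()
    if total > 0:
        grid = grid / total
    return DensityMap(focal_sex, float(extent_bl), float(bin_size_bl), grid, int(x.size))


def trapped_counts(events: list[PairEvent], times_min: list[float]) -> pd.DataFrame:
    """Both-trapped / observed counts at each elapsed time since trap entry.

    An event enters the denominator at time t if its outcome at t is
    known: either the recording covers entry + t, or an escape was seen
    earlier (the pair is then known not to be jointly trapped).  The
    numerator counts events with neither individual escaped by entry + t.
    """
    rows = []
    for ev in events:
        if ev.condition != "trapped":
            raise ValueError(f"event {ev.event_id} is not a trapped event")
        if ev.entry_frame is None:
            raise ValueError(f"trapped event {ev.event_id} lacks entry_frame")
    for t in times_min:
        num = obs = 0
        for ev in events:
            t_frame = ev.entry_frame + t * 60.0 * ev.fps
            escapes = [e for e in (ev.f_escape_frame, ev.m_escape_frame) if e is not None]
            first_escape = min(escapes) if escapes else None
            if first_escape is not None and first_escape <= t_frame:
                obs += 1  # outcome known: not both trapped
            elif ev.last_frame >= t_frame:
                obs += 1
                num += 1
            # else: recording ended with both still trapped -> unobserved
        rows.append((t, num, obs))
    return pd.DataFrame(rows, columns=["time_min", "both_trapped", "observed"])


__all__ = [
    "estimate_heading",
    "speed_bl_s",
    "relative_direction",
    "heading_difference",
    "pair_metrics",
    "pair_metrics_arrays",
    "DensityMap",
    "density_map",
    "trapped_counts",
]
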