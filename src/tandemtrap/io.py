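"""Reading and writing trajectory and posture tables.

Formats
-------
``tracks.csv``
    Tidy long form, one row per animal per frame:
    ``pair_id,event_id,sex,frame,x_mm,y_mm[,heading_rad]``.
``events_meta.csv``
    One row per event: ``pair_id,event_id,condition,fps,body_length_f_mm,
    body_length_m_mm,entry_frame,f_escape_frame,m_escape_frame`` (the last
    three blank for natural events; blank escape = censored).
``posture.csv``
    Either the pose-estimation dialect (three header rows:
    scorer / bodyparts / coords, then ``x,y,likelihood`` triplets per body
    part) or tidy long form ``frame,bodypart,x_mm,y_mm,likelihood``.

All files are comma-separated UTF-8 with '.' decimal.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BODY_PARTS, PairEvent, PostureFrame, TrackedIndividual

TRACK_COLUMNS = ["pair_id", "event_id", "sex", "frame", "x_mm", "y_mm", "heading_rad"]
META_COLUMNS = [
    "pair_id",
    "event_id",
    "condition",
    "fps",
    "body_length_f_mm",
    "body_length_m_mm",
    "entry_frame",
    "f_escape_frame",
    "m_escape_frame",
]


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return int(value)


def read_pair_events(tracks_path, meta_path, flip_y: bool = False) -> list[PairEvent]:
    """Read tidy track and metadata tables into :class:`PairEvent` records.

    Parameters
    ----------
    flip_y : bool
        Negate y on read, for tables exported from image coordinates
        (origin top-left, y increasing downward).
    """
    tracks = pd.read_csv(tracks_path)
    meta = pd.read_csv(meta_path)
    missing = {"pair_id", "event_id", "sex", "frame", "x_mm", "y_mm"} - set(tracks.columns)
    if missing:
        raise ValueError(f"tracks table missing columns: {sorted(missing)}")
    if "heading_rad" not in tracks.columns:
        tracks = tracks.assign(heading_rad=np.nan)
    meta = meta.set_index(["pair_id", "event_id"], verify_integrity=True)

    events: list[PairEvent] = []
    for key, grp in tracks.groupby(["pair_id", "event_id"], sort=True):
        pair_id, event_id = key
        if key not in meta.index:
            raise ValueError(f"no metadata row for event ({pair_id}, {event_id})")
        row = meta.loc[key]
        tracks_by_sex = {}
        for sex, sub in grp.groupby("sex"):
            sub = sub.sort_values("frame")
            bl = row["body_length_f_mm"] if sex == "F" else row["body_length_m_mm"]
            y = -sub["y_mm"].to_numpy() if flip_y else sub["y_mm"].to_numpy()
            h = sub["heading_rad"].to_numpy(dtype=float)
            if flip_y:
                ok = np.isfinite(h)
                h = h.copy()
                h[ok] = -h[ok]
            tracks_by_sex[sex] = TrackedIndividual(
                f"{pair_id}-{event_id}-{sex}",
                sex,
                float(bl),
                sub["frame"].to_numpy(),
                sub["x_mm"].to_numpy(),
                y,
                h,
            )
        for sex, label in (("F", "female"), ("M", "male")):
            if sex not in tracks_by_sex:
                raise ValueError(f"event ({pair_id}, {event_id}): {label} track missing")
        events.append(
            PairEvent(
                str(pair_id),
                str(event_id),
                str(row["condition"]),
                float(row["fps"]),
                tracks_by_sex["F"],
                tracks_by_sex["M"],
                entry_frame=_opt_int(row.get("entry_frame")),
                f_escape_frame=_opt_int(row.get("f_escape_frame")),
                m_escape_frame=_opt_int(row.get("m_escape_frame")),
            )
        )
    return events


def write_pair_events(events: list[PairEvent], tracks_path, meta_path) -> None:
    """Write events in the tidy formats read by :func:`read_pair_events`."""
    track_rows = []
    meta_rows = []
    for ev in sorted(events, key=lambda e: e.key):
        for ind in (ev.female, ev.male):
            for i in range(ind.n_frames):
                track_rows.append(
                    (
                        ev.pair_id,
                        ev.event_id,
                        ind.sex,
                        int(ind.frame_index[i]),
                        ind.x_mm[i],
                        ind.y_mm[i],
                        ind.heading_rad[i],
                    )
                )
        meta_rows.append(
            (
                ev.pair_id,
                ev.event_id,
                ev.condition,
                ev.fps,
                ev.female.body_length_mm,
                ev.male.body_length_mm,
                ev.entry_frame,
                ev.f_escape_frame,
                ev.m_escape_frame,
            )
        )
    pd.DataFrame(track_rows, columns=TRACK_COLUMNS).to_csv(tracks_path, index=False)
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    for col in ("entry_frame", "f_escape_frame", "m_escape_frame"):
        meta[col] = meta[col].astype("Int64")
    meta.to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# posture tables

def _frames_from_wide(df: pd.DataFrame, p_cutoff: float) -> list[PostureFrame]:
    frames = []
    for _, row in df.iterrows():
        pts = {}
        for part in BODY_PARTS:
            x, y, lik = row[(part, "x")], row[(part, "y")], row[(part, "likelihood")]
            if np.isnan(lik) or lik < p_cutoff:
                pts[part] = (np.nan, np.nan, lik)
            else:
                pts[part] = (x, y, lik)
        frames.append(PostureFrame(int(row[("frame", "")]), pts))
    frames.sort(key=lambda f: f.frame_index)
    return frames


def read_posture_table(path, p_cutoff: float = 0.9, flip_y: bool = False) -> list[PostureFrame]:
    """Read a posture table, masking points below the likelihood cutoff.

    Accepts the pose-estimation three-header-row dialect
    (scorer/bodyparts/coords) or tidy long form.  Points whose likelihood
    is below ``p_cutoff`` come back with NaN coordinates.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline().split(",")[0].strip()
    if first == "scorer":
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        bodyparts = list(dict.fromkeys(raw.columns.get_level_values(1)))
        unknown = set(bodyparts) - set(BODY_PARTS)
        if unknown:
            raise ValueError(
                f"unknown body part(s) {sorted(unknown)}; expected the six labels {list(BODY_PARTS)}"
            )
        coords = set(raw.columns.get_level_values(2))
        if not {"x", "y", "likelihood"} <= coords:
            raise ValueError(
                "malformed pose-estimation header: third row must hold x/y/likelihood"
            )
        wide = pd.DataFrame(index=raw.index)
        for part in bodyparts:
            sub = raw.xs(part, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            for c in ("x", "y", "likelihood"):
                wide[(part, c)] = sub[c].astype(float)
        wide[("frame", "")] = raw.index.astype(int)
    else:
        tidy = pd.read_csv(path)
        need = {"frame", "bodypart", "x_mm", "y_mm", "likelihood"}
        if not need <= set(tidy.columns):
            raise ValueError(
                f"tidy posture table must have columns {sorted(need)}; "
                "for the pose-estimation dialect the first header cell must be 'scorer'"
            )
        unknown = set(tidy["bodypart"].unique()) - set(BODY_PARTS)
        if unknown:
            raise ValueError(
                f"unknown body part(s) {sorted(unknown)}; expected the six labels {list(BODY_PARTS)}"
            )
        wide = tidy.pivot(index="frame", columns="bodypart", values=["x_mm", "y_mm", "likelihood"])
        out = pd.DataFrame(index=wide.index)
        for part in set(tidy["bodypart"]):
            out[(part, "x")] = wide[("x_mm", part)]
            out[(part, "y")] = wide[("y_mm", part)]
            out[(part, "likelihood")] = wide[("likelihood", part)]
        out[("frame", "")] = out.index.astype(int)
        wide = out
    if flip_y:
        for part in BODY_PARTS:
            if (part, "y") in wide:
                wide[(part, "y")] = -wide[(part, "y")]
    return _frames_from_wide(wide, p_cutoff)


def write_posture_table(frames: list[PostureFrame], path) -> None:
    """Write posture frames in tidy long form."""
    rows = []
    for fr in frames:
        for part in BODY_PARTS:
            x, y, lik = fr.points[part]
            rows.append((fr.frame_index, part, x, y, lik))
    pd.DataFrame(rows, columns=["frame", "bodypart", "x_mm", "y_mm", "likelihood"]).to_csv(
        path, index=False
    )


def read_snapshot(path, p_cutoff: float = 0.0, flip_y: bool = False) -> PostureFrame:
    """Read a single-frame posture file (e.g. measurements of a fossil pair)."""
    frames = read_posture_table(path, p_cutoff=p_cutoff, flip_y=flip_y)
    if len(frames) != 1:
        raise ValueError(f"snapshot file must contain exactly one frame, found {len(frames)}")
    return frames[0]


# ---------------------------------------------------------------------------
# downsampling & config

def downsample(event: PairEvent, target_fps: float) -> PairEvent:
    """Downsample an event to the analysis rate (default study rate: 1 FPS).

    Keeps frames where ``(frame_index - first_frame) % (fps/target_fps)
    == 0``; entry/escape frames map to the nearest kept frame at or after
    the original.  Requires an integer rate ratio.
    """
    ratio = event.fps / float(target_fps)
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"fps {event.fps} is not an integer multiple of target {target_fps}; "
            "resampling to non-divisor rates is out of scope"
        )
    step = int(round(ratio))
    if step == 1:
        return event
    first = int(min(event.female.frame_index[0], event.male.frame_index[0]))

    def keep(ind: TrackedIndividual) -> TrackedIndividual:
        m = (ind.frame_index - first) % step == 0
        return TrackedIndividual(
            ind.individual_id,
            ind.sex,
            ind.body_length_mm,
            ind.frame_index[m],
            ind.x_mm[m],
            ind.y_mm[m],
            ind.heading_rad[m],
        )

    def snap(f: int | None) -> int | None:
        if f is None:
            return None
        return first + int(np.ceil((f - first) / step)) * step

    return PairEvent(
        event.pair_id,
        event.event_id,
        event.condition,
        float(target_fps),
        keep(event.female),
        keep(event.male),
        entry_frame=snap(event.entry_frame),
        f_escape_frame=snap(event.f_escape_frame),
        m_escape_frame=snap(event.m_escape_frame),
    )


def load_config(path) -> dict:
    """Load a TOML config file (p_cutoff, target_fps, axis flip, columns...)."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


__all__ = [
    "read_pair_events",
    "write_pair_events",
    "read_posture_table",
    "write_posture_table",
    "read_snapshot",
    "downsample",
    "load_config",
    "Path",
]
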