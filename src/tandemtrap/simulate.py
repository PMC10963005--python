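"""Seeded synthetic tandem-pair trajectories and postures.

The generator produces :class:`~tandemtrap.types.PairEvent` records with
the statistical structure the downstream analysis assumes:

* **Natural tandems** — the leader is a correlated random walk (per-step
  speed ~ Normal(mean, sd) truncated at zero, heading increments ~
  Normal(0, turn_sd * sqrt(dt))); the follower pursues the point
  ``contact_dist_bl`` body lengths behind the leader's centroid along the
  follower-to-leader line with proportional gain, so its head rides at
  the leader's abdomen tip.  (Pursuit along the line of following, rather
  than along the leader's instantaneous body axis, keeps the follower's
  path length independent of the integration step: a target pinned to the
  diffusing heading axis would sweep laterally at a rate growing like
  1/sqrt(dt).)
* **Trapped pairs** — the natural law runs until the leader crosses the
  boundary of a square sticky patch (80 mm side, centred in a
  221 x 114 mm arena).  On the patch all speeds are multiplied by
  ``trap_speed_factor`` and the leader cannot leave.  The follower keeps
  following (as observed: followers do not abandon a trapped leader),
  catches up, and settles beside the leader — same heading with
  probability ``heading_mix_w``, otherwise opposite — with its head near
  the leader's abdomen tip.  Each individual escapes with an independent
  exponential hazard per minute; an escapee resumes free walking.
* **Skeleton postures** — head / pronotum-border / abdomen-tip points
  placed collinearly along the heading axis through the centroid, at
  configurable fractions of body length, plus isotropic noise.

The settling geometry (lateral offset, head-near-tip alignment) is a
stand-in for unquantified behaviour on the trap; its constants are not
claims about termites.  All randomness flows from a single seed through
deterministic substreams, so the same seed and parameters give
bit-identical output.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import estimate_heading
from .types import PairEvent, PostureFrame, TrackedIndividual, wrap_angle


@dataclasses.dataclass
class SyntheticParams:
    """Generator parameters (defaults mirror the study conditions).

    Speeds are body lengths per second; the natural leader mean of 2.0
    with the trap factor 0.03 yields trapped speeds near 0.06 BL/s.  The
    default escape hazard of 0.021 /min/individual puts the expected
    both-trapped fraction at 10 minutes near exp(-2 * 0.021 * 10) = 0.66.
    ``proportions`` locate the head, pronotum-border, and abdomen-tip
    points along the body axis, with the head-to-tip span defining one
    body length.
    """

    leader_speed_mean_bl_s: float = 2.0
    leader_speed_sd: float = 0.5
    turn_sd_rad: float = 0.4  # heading diffusion, rad per sqrt(second)
    contact_dist_bl: float = 1.0  # centroid-to-centroid offset when in contact
    follower_gain: float = 20.0  # proportional pursuit gain, 1/s
    trap_speed_factor: float = 0.03
    escape_hazard_per_min: float = 0.021
    heading_mix_w: float = 0.5  # P(settle heading same direction as leader)
    pos_noise_sd_mm: float = 0.0  # additive observation noise on recorded centroids
    body_length_f_mm: float = 8.0
    body_length_m_mm: float = 8.0
    proportions: tuple[float, float, float] = (0.0, 0.15, 1.0)
    fps: float = 30.0
    duration_s: float = 1800.0
    seed: int = 0
    arena_mm: tuple[float, float] = (221.0, 114.0)
    patch_side_mm: float = 80.0

    # settling geometry (stand-in constants, fractions of mean body length)
    settle_lateral_bl: float = 0.25
    settle_behind_bl: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "leader_speed_mean_bl_s",
            "leader_speed_sd",
            "turn_sd_rad",
            "contact_dist_bl",
            "follower_gain",
            "body_length_f_mm",
            "body_length_m_mm",
            "fps",
            "duration_s",
            "patch_side_mm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.trap_speed_factor <= 1:
            raise ValueError("trap_speed_factor must be in (0, 1]")
        if self.escape_hazard_per_min < 0:
            raise ValueError("escape_hazard_per_min must be nonnegative")
        if not 0 <= self.heading_mix_w <= 1:
            raise ValueError("heading_mix_w must be in [0, 1]")
        if self.pos_noise_sd_mm < 0:
            raise ValueError("pos_noise_sd_mm must be nonnegative")
        ph, pp, pt = self.proportions
        if not ph < pp < pt:
            raise ValueError("proportions must be ordered head < pronotum < tip")


def _unit(h):
    return np.stack([np.cos(h), np.sin(h)], axis=-1)


def _streams(seed: int | None, default_seed: int, n: int):
    ss = np.random.SeedSequence(default_seed if seed is None else seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def _n_frames(params: SyntheticParams) -> int:
    n = int(round(params.duration_s * params.fps)) + 1
    if n < 2:
        raise ValueError("duration_s * fps must yield at least 2 frames")
    return n


def _contact_point(
    leader_pos: np.ndarray, follower_pos: np.ndarray, contact: float, leader_heading: float
) -> np.ndarray:
    """Point ``contact`` mm behind the leader along the follower-to-leader line.

    Falls back to the leader's body axis when the two centroids coincide.
    """
    d = leader_pos - follower_pos
    r = np.hypot(*d)
    if r < 1e-12:
        return leader_pos - contact * _unit(leader_heading)
    return leader_pos - (contact / r) * d


def _leader_draws(rng, params: SyntheticParams, n: int):
    """Heading series (length n) and per-step speeds (length n-1, BL/s)."""
    dt = 1.0 / params.fps
    h0 = rng.uniform(0.0, 2.0 * np.pi)
    inc = rng.normal(0.0, params.turn_sd_rad * np.sqrt(dt), n - 1)
    headings = wrap_angle(h0 + np.concatenate([[0.0], np.cumsum(inc)]))
    speeds = np.clip(rng.normal(params.leader_speed_mean_bl_s, params.leader_speed_sd, n - 1), 0.0, None)
    return headings, speeds


def _make_event(
    params: SyntheticParams,
    leader_sex: str,
    pos_l: np.ndarray,
    h_l: np.ndarray,
    pos_f: np.ndarray,
    h_f: np.ndarray,
    noise_rng,
    condition: str,
    pair_id: str,
    event_id: str,
    **meta,
) -> PairEvent:
    n = pos_l.shape[0]
    if params.pos_noise_sd_mm > 0:
        pos_l = pos_l + noise_rng.normal(0.0, params.pos_noise_sd_mm, (n, 2))
        pos_f = pos_f + noise_rng.normal(0.0, params.pos_noise_sd_mm, (n, 2))
    frames = np.arange(n)
    by_sex = {}
    for sex, pos, h in ((leader_sex, pos_l, h_l), ("M" if leader_sex == "F" else "F", pos_f, h_f)):
        bl = params.body_length_f_mm if sex == "F" else params.body_length_m_mm
        by_sex[sex] = TrackedIndividual(f"{pair_id}-{event_id}-{sex}", sex, bl, frames, pos[:, 0], pos[:, 1], h)
    return PairEvent(pair_id, event_id, condition, params.fps, by_sex["F"], by_sex["M"], **meta)


def simulate_natural_pair(
    params: SyntheticParams,
    leader_sex: str = "F",
    seed: int | None = None,
    pair_id: str = "sim",
    event_id: str = "nat",
) -> PairEvent:
    """Simulate one natural tandem run.

    The follower's centroid relaxes toward the contact point
    ``contact_dist_bl`` mean body lengths behind the leader's centroid
    along the follower-to-leader line (head-to-tip contact for touching
    bodies) at rate ``follower_gain``; its heading is the direction of
    its own displacement.
    """
    if leader_sex not in ("F", "M"):
        raise ValueError("leader_sex must be 'F' or 'M'")
    n = _n_frames(params)
    dt = 1.0 / params.fps
    r_lead, r_fol, r_noise = _streams(seed, params.seed, 3)
    bl_lead = params.body_length_f_mm if leader_sex == "F" else params.body_length_m_mm
    bl_mean = 0.5 * (params.body_length_f_mm + params.body_length_m_mm)
    contact = params.contact_dist_bl * bl_mean

    headings, speeds = _leader_draws(r_lead, params, n)
    steps = (speeds * bl_lead * dt)[:, None] * _unit(headings[1:])
    pos_l = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

    a = -np.expm1(-params.follower_gain * dt)  # per-step approach fraction
    pos_f = np.empty_like(pos_l)
    h_f = np.empty(n)
    pos_f[0] = pos_l[0] - contact * _unit(headings[0])
    h_f[0] = headings[0]
    for t in range(n - 1):
        target = _contact_point(pos_l[t + 1], pos_f[t], contact, headings[t + 1])
        pos_f[t + 1] = pos_f[t] + a * (target - pos_f[t])
        d = pos_f[t + 1] - pos_f[t]
        h_f[t + 1] = np.arctan2(d[1], d[0]) if np.hypot(*d) > 1e-12 else h_f[t]
    return _make_event(
        params, leader_sex, pos_l, headings, pos_f, wrap_angle(h_f), r_noise, "natural", pair_id, event_id
    )


def simulate_independent_pair(
    params: SyntheticParams,
    seed: int | None = None,
    pair_id: str = "sim",
    event_id: str = "ind",
) -> PairEvent:
    """Two non-interacting correlated random walks from a tandem start.

    The male starts at the contact point behind the female with her
    heading, then walks independently.  Useful as a ground-truth null for
    calibrating interaction tests.
    """
    n = _n_frames(params)
    dt = 1.0 / params.fps
    r_f, r_m, r_noise = _streams(seed, params.seed, 3)
    bl_mean = 0.5 * (params.body_length_f_mm + params.body_length_m_mm)

    h_f, sp_f = _leader_draws(r_f, params, n)
    pos_f = np.vstack([[0.0, 0.0], np.cumsum((sp_f * params.body_length_f_mm * dt)[:, None] * _unit(h_f[1:]), axis=0)])
    h_m, sp_m = _leader_draws(r_m, params, n)
    start_m = pos_f[0] - params.contact_dist_bl * bl_mean * _unit(h_f[0])
    h_m = wrap_angle(h_m - h_m[0] + h_f[0])  # same initial heading as the female
    pos_m = start_m + np.vstack(
        [[0.0, 0.0], np.cumsum((sp_m * params.body_length_m_mm * dt)[:, None] * _unit(h_m[1:]), axis=0)]
    )
    return _make_event(params, "F", pos_f, h_f, pos_m, h_m, r_noise, "natural", pair_id, event_id)


def _clamp(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(p, lo), hi)


def simulate_trapped_pair(
    params: SyntheticParams,
    leader_sex: str = "F",
    seed: int | None = None,
    pair_id: str = "sim",
    event_id: str = "trap",
) -> PairEvent:
    """Simulate one trap-entry event on the sticky patch.

    The pair starts outside the patch heading toward it under the natural
    law; ``entry_frame`` is set when the leader's centroid first lies
    inside the square.  With ``trap_speed_factor == 1`` the surface has
    no adhesion: entry is recorded but the natural update law continues
    unchanged.  Otherwise speeds on the patch are scaled by the factor,
    the leader is confined to the patch, and the follower settles beside
    it.  Escape times are drawn per individual from an exponential with
    rate ``escape_hazard_per_min``; frames beyond an individual's escape
    show free (unstuck) walking.
    """
    if leader_sex not in ("F", "M"):
        raise ValueError("leader_sex must be 'F' or 'M'")
    n = _n_frames(params)
    base_seed = params.seed if seed is None else seed
    # A leader aimed at the patch almost always enters; on the rare miss,
    # retry with a deterministically derived substream so the output is
    # still a pure function of (params, seed).
    result = None
    for attempt in range(20):
        ss = np.random.SeedSequence(base_seed if attempt == 0 else [base_seed, attempt])
        streams = [np.random.default_rng(s) for s in ss.spawn(4)]
        result = _trapped_once(params, leader_sex, n, streams)
        if result is not None:
            break
    if result is None:
        raise RuntimeError(
            "leader never entered the sticky patch in 20 attempts; increase duration_s"
        )
    pos_l, h_l, pos_f, h_f, entry, esc_lead_frame, esc_fol_frame, r_noise = result

    f_escape = m_escape = None
    if leader_sex == "F":
        f_escape, m_escape = esc_lead_frame, esc_fol_frame
    else:
        f_escape, m_escape = esc_fol_frame, esc_lead_frame
    return _make_event(
        params,
        leader_sex,
        pos_l,
        h_l,
        pos_f,
        wrap_angle(h_f),
        r_noise,
        "trapped",
        pair_id,
        event_id,
        entry_frame=entry,
        f_escape_frame=f_escape,
        m_escape_frame=m_escape,
    )


def _trapped_once(params: SyntheticParams, leader_sex: str, n: int, streams):
    dt = 1.0 / params.fps
    r_lead, r_fol, r_noise, r_misc = streams
    bl_lead = params.body_length_f_mm if leader_sex == "F" else params.body_length_m_mm
    bl_mean = 0.5 * (params.body_length_f_mm + params.body_length_m_mm)
    contact = params.contact_dist_bl * bl_mean
    sticky = params.trap_speed_factor < 1.0

    cx, cy = params.arena_mm[0] / 2.0, params.arena_mm[1] / 2.0
    half = params.patch_side_mm / 2.0
    lo = np.array([cx - half, cy - half])
    hi = np.array([cx + half, cy + half])

    def on_patch(p) -> bool:
        return bool(np.all(p >= lo) and np.all(p <= hi))

    # start to the left of the patch, aimed at its centre
    start = np.array([cx - half - 2.5 * bl_mean, cy + r_misc.uniform(-0.3, 0.3) * half])
    aim = np.arctan2(cy - start[1], cx - start[0]) + r_misc.normal(0.0, 0.1)

    headings, speeds = _leader_draws(r_lead, params, n)
    headings = wrap_angle(headings - headings[0] + aim)
    h_fol_draws, sp_fol_draws = _leader_draws(r_fol, params, n)  # used only after escape
    settle_same = r_misc.random() < params.heading_mix_w
    settle_side = 1.0 if r_misc.random() < 0.5 else -1.0
    settle_jitter = r_misc.normal(0.0, 0.1, n)

    pos_l = np.empty((n, 2))
    pos_f = np.empty((n, 2))
    h_l = headings.copy()
    h_f = np.empty(n)
    pos_l[0] = start
    pos_f[0] = start - contact * _unit(aim)
    h_f[0] = aim

    entry: int | None = None
    esc_lead_frame: int | None = None
    esc_fol_frame: int | None = None
    settled = False
    a_nat = -np.expm1(-params.follower_gain * dt)
    a_trap = -np.expm1(-params.follower_gain * params.trap_speed_factor * dt)

    for t in range(n - 1):
        lead_escaped = esc_lead_frame is not None and t >= esc_lead_frame
        fol_escaped = esc_fol_frame is not None and t >= esc_fol_frame
        lead_stuck = sticky and entry is not None and not lead_escaped

        # --- leader
        v = speeds[t] * bl_lead * dt
        if lead_stuck:
            v *= params.trap_speed_factor
        nxt = pos_l[t] + v * _unit(headings[t + 1])
        if lead_stuck:
            nxt = _clamp(nxt, lo, hi)
        pos_l[t + 1] = nxt
        if entry is None and on_patch(nxt):
            entry = t + 1
            if params.escape_hazard_per_min > 0:
                lam = params.escape_hazard_per_min
                te_l = entry + int(round(r_misc.exponential(1.0 / lam) * 60.0 * params.fps))
                te_f = entry + int(round(r_misc.exponential(1.0 / lam) * 60.0 * params.fps))
                esc_lead_frame = te_l if te_l < n else None
                esc_fol_frame = te_f if te_f < n else None

        # --- follower
        if fol_escaped:
            pos_f[t + 1] = pos_f[t] + sp_fol_draws[t] * (
                params.body_length_f_mm if leader_sex == "M" else params.body_length_m_mm
            ) * dt * _unit(h_fol_draws[t + 1])
            h_f[t + 1] = h_fol_draws[t + 1]
            continue
        if not settled:
            target = _contact_point(pos_l[t + 1], pos_f[t], contact, h_l[t + 1])
            gain = a_trap if (sticky and on_patch(pos_f[t])) else a_nat
            pos_f[t + 1] = pos_f[t] + gain * (target - pos_f[t])
            d = pos_f[t + 1] - pos_f[t]
            h_f[t + 1] = np.arctan2(d[1], d[0]) if np.hypot(*d) > 1e-12 else h_f[t]
            if (
                sticky
                and entry is not None
                and on_patch(pos_f[t + 1])
                and np.hypot(*(pos_f[t + 1] - pos_l[t + 1])) < 1.3 * contact
            ):
                settled = True
        else:
            u = _unit(h_l[t + 1])
            perp = np.array([-u[1], u[0]])
            behind = params.settle_behind_bl if settle_same else 0.0
            target = pos_l[t + 1] - behind * bl_mean * u + settle_side * params.settle_lateral_bl * bl_mean * perp
            pos_f[t + 1] = pos_f[t] + a_trap * (target - pos_f[t])
            base = h_l[t + 1] if settle_same else h_l[t + 1] + np.pi
            h_f[t + 1] = wrap_angle(base + settle_jitter[t + 1])

    if entry is None:
        return None
    return pos_l, h_l, pos_f, h_f, entry, esc_lead_frame, esc_fol_frame, r_noise


def skeleton_postures(
    event: PairEvent,
    params: SyntheticParams,
    noise_sd_mm: float | None = None,
    seed: int | None = None,
) -> list[PostureFrame]:
    """Place the six body points along each animal's heading axis.

    For each animal the head, pronotum-border, and abdomen-tip points lie
    collinearly along the heading through the centroid at the configured
    ``proportions`` of body length (head-to-tip span = one body length,
    centroid at the segment midpoint), plus isotropic Gaussian noise.
    Likelihood is 1 for every point.
    """
    noise = params.pos_noise_sd_mm if noise_sd_mm is None else float(noise_sd_mm)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed if seed is None else seed))
    f, m = event.female, event.male
    if np.isnan(f.heading_rad).any():
        f = estimate_heading(f)
    if np.isnan(m.heading_rad).any():
        m = estimate_heading(m)
    common, fi, mi = np.intersect1d(f.frame_index, m.frame_index, return_indices=True)
    ph, pp, pt = params.proportions
    centre = 0.5 * (ph + pt)
    frames = []
    for k in range(common.size):
        pts = {}
        for prefix, ind, idx in (("f", f, fi[k]), ("m", m, mi[k])):
            scale = ind.body_length_mm / (pt - ph)
            pos = np.array([ind.x_mm[idx], ind.y_mm[idx]])
            u = _unit(ind.heading_rad[idx])
            for label, prop in (("Head", ph), ("Pro", pp), ("Tip", pt)):
                pt_xy = pos + (centre - prop) * scale * u
                if noise > 0:
                    pt_xy = pt_xy + rng.normal(0.0, noise, 2)
                pts[prefix + label] = (pt_xy[0], pt_xy[1], 1.0)
        frames.append(PostureFrame(int(common[k]), pts))
    return frames


def simulate_ensemble(
    params: SyntheticParams,
    condition: str,
    n_events: int,
    seed: int | None = None,
    leader_sex: str = "F",
) -> list[PairEvent]:
    """Simulate ``n_events`` independent events with per-event substreams."""
    sims = {
        "natural": simulate_natural_pair,
        "trapped": simulate_trapped_pair,
    }
    if condition == "independent":
        maker = lambda p, s, pid, eid: simulate_independent_pair(p, seed=s, pair_id=pid, event_id=eid)
    elif condition in sims:
        fn = sims[condition]
        maker = lambda p, s, pid, eid: fn(p, leader_sex=leader_sex, seed=s, pair_id=pid, event_id=eid)
    else:
        raise ValueError("condition must be natural|trapped|independent")
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    child_seeds = root.generate_state(n_events) % (2**31)
    return [
        maker(params, int(child_seeds[i]), f"p{i:03d}", f"e{i:03d}")
        for i in range(n_events)
    ]


__all__ = [
    "SyntheticParams",
    "simulate_natural_pair",
    "simulate_independent_pair",
    "simulate_trapped_pair",
    "skeleton_postures",
    "simulate_ensemble",
]
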