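"""Randomized-pairing null for inter-individual interaction.

The null keeps every individual's own movement intact but breaks the
interaction between partners: each female is re-paired with a male from a
*different* event (a derangement, so no male meets his own female), and
the swapped male's trajectory is rigidly realigned so that it starts at
the original male's initial position and heading — as if the two animals
had entered the surface together, after which each moves independently.
Repeating the re-pairing gives a replicate ensemble of metric summaries
against which the real pairs are compared.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kinematics import estimate_heading, pair_metrics_arrays
from .stats import TestResult, ks_two_sample, rank_sum
from .types import PairEvent, TrackedIndividual, wrap_angle


def _initial_pose(ind: TrackedIndividual) -> tuple[np.ndarray, float]:
    """First position and first resolvable heading of a trajectory."""
    if np.isfinite(ind.heading_rad[0]):
        h0 = float(ind.heading_rad[0])
    else:
        est = estimate_heading(ind)
        h0 = float(est.heading_rad[0])
    return ind.positions[0].copy(), h0


def rigid_align(
    traj: TrackedIndividual, target_origin: np.ndarray, target_heading: float
) -> TrackedIndividual:
    """Rotate-then-translate a trajectory onto a target initial pose.

    The unique rigid motion mapping the first position to
    ``target_origin`` and the first heading to ``target_heading``.  All
    inter-frame displacement lengths (indeed all pairwise distances
    within the trajectory) are preserved.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    origin, h0 = _initial_pose(traj)
    rot = float(target_heading) - h0
    c, s = np.cos(rot), np.sin(rot)
    rel = traj.positions - origin
    xy = np.empty_like(rel)
    xy[:, 0] = c * rel[:, 0] - s * rel[:, 1]
    xy[:, 1] = s * rel[:, 0] + c * rel[:, 1]
    xy += np.asarray(target_origin, dtype=float)
    h = traj.heading_rad.copy()
    ok = np.isfinite(h)
    h[ok] = wrap_angle(h[ok] + rot)
    return TrackedIndividual(
        traj.individual_id, traj.sex, traj.body_length_mm, traj.frame_index.copy(), xy[:, 0], xy[:, 1], h
    )


def draw_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random permutation of 0..n-1 with no fixed points (rejection)."""
    if n < 2:
        raise ValueError("derangement impossible for fewer than 2 items")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


@dataclasses.dataclass
class NullEnsemble:
    """Replicate-indexed metrics from randomized (swapped, realigned) pairings."""

    n_replicates: int
    seed: int
    event_ids: list[tuple[str, str]]
    permutations: np.ndarray  # (n_replicates, n_events)
    mean_distance_bl: np.ndarray  # per-replicate mean
    mean_heading_diff: np.ndarray
    pooled: dict[str, np.ndarray]  # per-frame values pooled over replicates


def randomize_pairs(
    events: list[PairEvent], n_replicates: int, seed: int
) -> NullEnsemble:
    """Build the randomized-pairing null ensemble.

    Per replicate: draw a derangement sigma, pair female i with male
    sigma(i) after rigidly aligning that male's trajectory to male i's
    initial position and heading, truncate to the shorter of the two
    series, and compute pair metrics.  Female trajectories are never
    modified.
    """
    if len(events) < 2:
        raise ValueError("derangement impossible: need at least 2 events")
    conditions = {ev.condition for ev in events}
    if len(conditions) > 1:
        raise ValueError(f"events mix conditions {sorted(conditions)}; scope the null per condition")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    n_ev = len(events)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    poses = [_initial_pose(ev.male) for ev in events]
    # pre-estimate headings once so replicates share the work
    males = []
    females = []
    for ev in events:
        m = ev.male if not np.isnan(ev.male.heading_rad).any() else estimate_heading(ev.male)
        f = ev.female if not np.isnan(ev.female.heading_rad).any() else estimate_heading(ev.female)
        males.append(m)
        females.append(f)

    perms = np.empty((n_replicates, n_ev), dtype=np.int64)
    mean_dist = np.empty(n_replicates)
    mean_hd = np.empty(n_replicates)
    pooled_dist: list[np.ndarray] = []
    pooled_hd: list[np.ndarray] = []
    for r in range(n_replicates):
        perm = draw_derangement(rng, n_ev)
        perms[r] = perm
        dists = []
        hds = []
        for i, j in enumerate(perm):
            origin, h0 = poses[i]
            male = rigid_align(males[j], origin, h0)
            n_keep = min(females[i].n_frames, male.n_frames)
            female = females[i]
            # reindex the swapped male onto the female's frame grid before truncation
            male = TrackedIndividual(
                male.individual_id,
                "M",
                male.body_length_mm,
                female.frame_index[:n_keep],
                male.x_mm[:n_keep],
                male.y_mm[:n_keep],
                male.heading_rad[:n_keep],
            )
            female = female.window(female.frame_index[0], int(female.frame_index[:n_keep][-1]) + 1)
            ev = events[i]
            pair = PairEvent(
                ev.pair_id,
                f"{ev.event_id}-null",
                ev.condition,
                ev.fps,
                female,
                male,
                entry_frame=ev.entry_frame,
                f_escape_frame=None,
                m_escape_frame=None,
            )
            met = pair_metrics_arrays(pair)
            dists.append(met["distance_bl"])
            hds.append(met["heading_diff"])
        d = np.concatenate(dists)
        h = np.concatenate(hds)
        mean_dist[r] = np.nanmean(d)
        mean_hd[r] = np.nanmean(h)
        pooled_dist.append(d)
        pooled_hd.append(h)
    return NullEnsemble(
        n_replicates,
        seed,
        [ev.key for ev in events],
        perms,
        mean_dist,
        mean_hd,
        {"distance_bl": np.concatenate(pooled_dist), "heading_diff": np.concatenate(pooled_hd)},
    )


@dataclasses.dataclass
class NullComparison:
    """Real-vs-null comparison for one metric.

    ``test`` is a distribution-level test on pooled per-frame values
    (which treats frames as independent, so it is anticonservative for
    autocorrelated trajectories); ``real_mean_quantile`` and ``p_mc`` are
    the Monte-Carlo placement of the real replicate-level mean within the
    null distribution of replicate means, which is calibrated under the
    null.
    """

    metric: str
    test: TestResult
    real_mean: float
    null_mean: float
    real_mean_quantile: float
    p_mc: float
    n_replicates: int


def compare_real_null(
    real_values: np.ndarray,
    ensemble: NullEnsemble,
    metric: str = "distance_bl",
    test: str = "ks",
) -> NullComparison:
    """Compare real per-frame metric values against the null ensemble.

    Parameters
    ----------
    real_values : array
        Pooled per-frame values of the metric over the real pairs.
    metric : {"distance_bl", "heading_diff"}
    test : {"ks", "rank_sum"}
        Distribution test applied to real frames vs pooled null frames.
    """
    if metric not in ("distance_bl", "heading_diff"):
        raise ValueError("metric must be distance_bl or heading_diff")
    real_values = np.asarray(real_values, dtype=float)
    real_values = real_values[np.isfinite(real_values)]
    if real_values.size == 0:
        raise ValueError("empty real metric series")
    null_pool = ensemble.pooled[metric]
    null_pool = null_pool[np.isfinite(null_pool)]
    if test == "ks":
        tr = ks_two_sample(real_values, null_pool)
    elif test == "rank_sum":
        tr = rank_sum(real_values, null_pool, exact=False)
    else:
        raise ValueError("test must be ks or rank_sum")
    null_means = ensemble.mean_distance_bl if metric == "distance_bl" else ensemble.mean_heading_diff
    real_mean = float(np.mean(real_values))
    n_rep = null_means.size
    k = int(np.sum(null_means < real_mean)) + 0.5 * int(np.sum(null_means == real_mean))
    # mid-rank quantile: uniform on a symmetric grid under the null
    q = (k + 0.5) / (n_rep + 1)
    p_mc = min(1.0, 2.0 * min(q, 1.0 - q))
    return NullComparison(metric, tr, real_mean, float(np.mean(null_means)), q, p_mc, n_rep)


__all__ = [
    "rigid_align",
    "draw_derangement",
    "NullEnsemble",
    "randomize_pairs",
    "NullComparison",
    "compare_real_null",
]
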