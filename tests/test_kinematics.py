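"""Spatial-organization metrics: headings, speeds, angles, densities, counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemtrap import (
    density_map,
    estimate_heading,
    heading_difference,
    pair_metrics,
    relative_direction,
    speed_bl_s,
    trapped_counts,
)

from conftest import make_event, make_individual


# ---------------------------------------------------------------- headings

def test_straight_rightward_walk_heading_zero():
    ind = make_individual(np.arange(5.0), np.zeros(5))
    est = estimate_heading(ind)
    np.testing.assert_allclose(est.heading_rad, 0.0, atol=1e-12)


def test_stationary_frame_carries_heading_forward():
    xs = [0.0, 1.0, 1.0, 2.0]
    ys = [0.0, 1.0, 1.0, 1.0]
    est = estimate_heading(make_individual(xs, ys), min_step_mm=0.5)
    assert est.heading_rad[1] == pytest.approx(np.pi / 4)  # carried from frame 0->1 step
    assert est.heading_rad[2] == pytest.approx(0.0)  # next real step


def test_leading_undefined_headings_backfilled():
    xs = [0.0, 0.0, 0.0, 1.0, 2.0]
    ys = [0.0, 0.0, 0.0, 0.0, 0.0]
    est = estimate_heading(make_individual(xs, ys), min_step_mm=0.5)
    np.testing.assert_allclose(est.heading_rad, 0.0, atol=1e-12)


def test_all_stationary_heading_unresolvable():
    with pytest.raises(ValueError, match="unresolvable"):
        estimate_heading(make_individual([0.0, 0.0], [0.0, 0.0]), min_step_mm=0.5)


def test_circle_headings_match_tangent():
    n = 400
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 20.0
    est = estimate_heading(make_individual(r * np.cos(theta), r * np.sin(theta)), min_step_mm=0.0)
    tangent = np.mod(theta + np.pi / 2, 2 * np.pi)
    err = np.abs(np.angle(np.exp(1j * (est.heading_rad[:-1] - tangent[:-1]))))
    assert err.max() <= 2 * np.pi / n + 1e-9


# ------------------------------------------------------------------ speeds

def test_stationary_speed_zero():
    ind = make_individual(np.ones(4), np.ones(4))
    np.testing.assert_allclose(speed_bl_s(ind, 1.0), 0.0)


def test_unit_speed_construction():
    """5 mm per frame at 1 FPS with a 5 mm body is exactly 1 BL/s."""
    ind = make_individual([0.0, 5.0, 10.0], [0.0, 0.0, 0.0], bl=5.0)
    np.testing.assert_allclose(speed_bl_s(ind, 1.0), 1.0)


def test_speed_rejects_bad_body_length():
    ind = make_individual([0.0, 1.0], [0.0, 0.0])
    with pytest.raises(ValueError):
        speed_bl_s(ind, 1.0, body_length_mm=0.0)


# ------------------------------------------------------- relative direction

@pytest.mark.parametrize(
    "partner,expected",
    [((1.0, 0.0), 0.0), ((-1.0, 0.0), np.pi), ((0.0, 1.0), np.pi / 2), ((0.0, -1.0), np.pi / 2)],
)
def test_relative_direction_cardinal(partner, expected):
    assert relative_direction(np.zeros(2), 0.0, np.array(partner)) == pytest.approx(expected)


def test_relative_direction_coincident_is_missing():
    assert np.isnan(relative_direction(np.zeros(2), 0.3, np.zeros(2)))


@given(
    st.floats(-100, 100), st.floats(-100, 100),
    st.floats(0, 2 * np.pi), st.floats(-50, 50), st.floats(-50, 50),
    st.floats(0, 2 * np.pi), st.floats(-100, 100), st.floats(-100, 100),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_relative_direction_rigid_invariance(fx, fy, h, px, py, rot, tx, ty):
    """relative_direction is invariant under global rotation + translation."""
    focal = np.array([fx, fy])
    partner = focal + np.array([px, py])
    if np.hypot(px, py) < 1e-6:
        return
    base = relative_direction(focal, h, partner)
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    moved = relative_direction(R @ focal + [tx, ty], h + rot, R @ partner + [tx, ty])
    assert moved == pytest.approx(base, abs=1e-9)
    assert 0.0 <= base <= np.pi


# ------------------------------------------------------------ pair metrics

def test_interaction_threshold_is_sum_of_body_lengths():
    """Body lengths 6.5 + 5.5 mm give a 12 mm threshold, strict inequality."""
    just_in = make_event([0, 0], [0, 0], [11.999, 11.999], [0, 0], fh=[0, 0], mh=[0, 0], f_bl=6.5, m_bl=5.5)
    at_thresh = make_event([0, 0], [0, 0], [12.0, 12.0], [0, 0], fh=[0, 0], mh=[0, 0], f_bl=6.5, m_bl=5.5)
    assert pair_metrics(just_in)["interacting"].all()
    assert not pair_metrics(at_thresh)["interacting"].any()
    # distance normalised by the mean body length
    assert pair_metrics(at_thresh)["distance_bl"].iloc[0] == pytest.approx(12.0 / 6.0)


def test_coincident_centroids_zero_distance_interacting():
    ev = make_event([0, 1], [0, 0], [0, 1], [0, 0], fh=[0, 0], mh=[0, 0])
    m = pair_metrics(ev)
    assert m["distance_bl"].iloc[0] == 0.0
    assert bool(m["interacting"].iloc[0])


def test_heading_difference_parallel_antiparallel():
    ev = make_event([0, 1], [0, 0], [0, 1], [1, 1], fh=[0.3, 0.3], mh=[0.3, 0.3])
    assert pair_metrics(ev)["heading_diff"].iloc[0] == pytest.approx(0.0)
    ev2 = make_event([0, 1], [0, 0], [0, 1], [1, 1], fh=[0.3, 0.3], mh=[0.3 + np.pi, 0.3 + np.pi])
    assert pair_metrics(ev2)["heading_diff"].iloc[0] == pytest.approx(np.pi)
    assert heading_difference(0.1, 2 * np.pi - 0.1) == pytest.approx(0.2)


def test_pair_metrics_symmetric_in_partners():
    rng = np.random.default_rng(5)
    fx, fy, mx, my = rng.normal(size=(4, 10)).cumsum(axis=1) * 3
    fh = rng.uniform(0, 2 * np.pi, 10)
    mh = rng.uniform(0, 2 * np.pi, 10)
    a = pair_metrics(make_event(fx, fy, mx, my, fh, mh))
    b = pair_metrics(make_event(mx, my, fx, fy, mh, fh))
    np.testing.assert_allclose(a["distance_bl"], b["distance_bl"], atol=1e-12)
    np.testing.assert_allclose(a["heading_diff"], b["heading_diff"], atol=1e-12)
    np.testing.assert_allclose(a["rel_dir_f"], b["rel_dir_m"], atol=1e-12)


# ----------------------------------------------------------------- density

def test_density_single_observation_ahead():
    """Partner one BL directly ahead gives a single unit bin at (0, +1)."""
    ev = make_event([0, 0], [0, 0], [8.0, 8.0], [0, 0], fh=[0, 0], mh=[0, 0])
    dm = density_map([ev], "F", extent_bl=2.0, bin_size_bl=0.1)
    assert dm.grid.sum() == pytest.approx(1.0)
    idx = np.argwhere(dm.grid > 0)
    assert idx.shape[0] == 1
    cx = (dm.edges[idx[0, 0]] + dm.edges[idx[0, 0] + 1]) / 2
    cy = (dm.edges[idx[0, 1]] + dm.edges[idx[0, 1] + 1]) / 2
    # the observation sits on a bin edge at x=0, so allow one bin of slack
    assert cx == pytest.approx(0.0, abs=0.1)
    assert cy == pytest.approx(1.0, abs=0.1)


def test_density_mirror_equivariance():
    rng = np.random.default_rng(9)
    fx, fy, mx, my = rng.normal(scale=3.0, size=(4, 40)).cumsum(axis=1)
    fh = rng.uniform(0, 2 * np.pi, 40)
    mh = rng.uniform(0, 2 * np.pi, 40)
    ev = make_event(fx, fy, mx, my, fh, mh)
    mirrored = make_event(-fx, fy, -mx, my, np.pi - fh, np.pi - mh)
    a = density_map([ev], "F", interacting_only=False)
    b = density_map([mirrored], "F", interacting_only=False)
    np.testing.assert_allclose(b.grid, a.grid[::-1, :], atol=1e-12)


def test_density_empty_errors():
    ev = make_event([0, 0], [0, 0], [500.0, 500.0], [0, 0], fh=[0, 0], mh=[0, 0])
    with pytest.raises(ValueError, match="empty density"):
        density_map([ev], "F")


def test_density_grid_sums_to_one(trapped_event):
    dm = density_map([trapped_event], "M")
    assert dm.grid.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------- trapped counts

def _trap_event(n, entry, f_esc=None, m_esc=None, fps=1.0, eid="e0"):
    t = np.arange(n)
    ev = make_event(
        t * 0.1, t * 0, t * 0.1 + 1, t * 0, fps=fps, condition="trapped",
        entry_frame=entry, f_escape_frame=f_esc, m_escape_frame=m_esc,
    )
    ev.event_id = eid
    return ev


def test_trapped_counts_no_escape():
    events = [_trap_event(2000, 10, eid=f"e{i}") for i in range(4)]
    out = trapped_counts(events, [10.0, 20.0])
    assert (out["both_trapped"] == out["observed"]).all()
    assert (out["observed"] == 4).all()


def test_trapped_counts_escape_and_censoring():
    # escape at 15 min: counts at 10 min, excluded from numerator later
    esc = _trap_event(2000, 0, f_esc=15 * 60)
    # recording ends at 25 min with both still trapped: unobserved at 30 min
    short = _trap_event(25 * 60, 0, eid="e1")
    long_ok = _trap_event(2000, 0, eid="e2")
    out = trapped_counts([esc, short, long_ok], [10.0, 20.0, 30.0])
    assert out.loc[0, "both_trapped"] == 3 and out.loc[0, "observed"] == 3
    assert out.loc[1, "both_trapped"] == 2 and out.loc[1, "observed"] == 3
    assert out.loc[2, "both_trapped"] == 1 and out.loc[2, "observed"] == 2


def test_trapped_counts_rejects_natural():
    ev = make_event([0, 1], [0, 0], [1, 1], [0, 0])
    with pytest.raises(ValueError, match="not a trapped event"):
        trapped_counts([ev], [10.0])
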