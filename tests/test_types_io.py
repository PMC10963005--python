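"""Trajectory/posture table reading, writing, downsampling, validation."""

import numpy as np
import pytest

from tandemtrap import (
    PairEvent,
    downsample,
    read_pair_events,
    read_posture_table,
    write_pair_events,
)
from tandemtrap.types import TrackedIndividual

from conftest import make_event, make_individual


def _events_for_io():
    nat = make_event([0, 1, 2], [0, 0, 0], [1, 2, 3], [0.5, 0.5, 0.5], fps=25.0)
    trap = make_event(
        [0, 1, 2, 3],
        [0, 0, 1, 1],
        [1, 2, 3, 4],
        [0, 0, 0, 0],
        fps=30.0,
        condition="trapped",
        entry_frame=1,
        f_escape_frame=3,
        m_escape_frame=None,
    )
    trap.pair_id, trap.event_id = "p1", "e1"
    trap.female.individual_id, trap.male.individual_id = "p1-e1-F", "p1-e1-M"
    return [nat, trap]


def test_round_trip_identity(tmp_path):
    """write -> read reproduces records; a second write is byte-stable."""
    events = _events_for_io()
    t1, m1 = tmp_path / "tracks.csv", tmp_path / "meta.csv"
    write_pair_events(events, t1, m1)
    back = read_pair_events(t1, m1)
    assert [e.key for e in back] == [e.key for e in events]
    for a, b in zip(events, back):
        assert a.condition == b.condition and a.fps == b.fps
        assert a.entry_frame == b.entry_frame
        assert a.f_escape_frame == b.f_escape_frame and a.m_escape_frame == b.m_escape_frame
        for ia, ib in zip((a.female, a.male), (b.female, b.male)):
            np.testing.assert_array_equal(ia.frame_index, ib.frame_index)
            np.testing.assert_allclose(ia.positions, ib.positions)
            assert ia.body_length_mm == ib.body_length_mm
    t2, m2 = tmp_path / "tracks2.csv", tmp_path / "meta2.csv"
    write_pair_events(back, t2, m2)
    assert t1.read_bytes() == t2.read_bytes()
    assert m1.read_bytes() == m2.read_bytes()


def test_study_frame_rates_accepted(tmp_path):
    """Both recording rates used in the study (30 and 25 FPS) round-trip."""
    events = _events_for_io()
    write_pair_events(events, tmp_path / "t.csv", tmp_path / "m.csv")
    back = read_pair_events(tmp_path / "t.csv", tmp_path / "m.csv")
    assert {e.fps for e in back} == {25.0, 30.0}


def test_single_sex_event_errors(tmp_path):
    (tmp_path / "t.csv").write_text(
        "pair_id,event_id,sex,frame,x_mm,y_mm\np0,e0,F,0,0.0,0.0\np0,e0,F,1,1.0,0.0\n"
    )
    (tmp_path / "m.csv").write_text(
        "pair_id,event_id,condition,fps,body_length_f_mm,body_length_m_mm,"
        "entry_frame,f_escape_frame,m_escape_frame\np0,e0,natural,25,8,8,,,\n"
    )
    with pytest.raises(ValueError, match="male track missing"):
        read_pair_events(tmp_path / "t.csv", tmp_path / "m.csv")


def test_missing_metadata_row_errors(tmp_path):
    (tmp_path / "t.csv").write_text(
        "pair_id,event_id,sex,frame,x_mm,y_mm\n"
        "p0,e0,F,0,0.0,0.0\np0,e0,M,0,1.0,0.0\n"
    )
    (tmp_path / "m.csv").write_text(
        "pair_id,event_id,condition,fps,body_length_f_mm,body_length_m_mm,"
        "entry_frame,f_escape_frame,m_escape_frame\npX,eX,natural,25,8,8,,,\n"
    )
    with pytest.raises(ValueError, match="no metadata row"):
        read_pair_events(tmp_path / "t.csv", tmp_path / "m.csv")


def test_non_monotone_frames_error():
    with pytest.raises(ValueError, match="strictly increasing"):
        make_individual([0, 1, 2], [0, 0, 0], frames=np.array([0, 2, 2]))


def test_invariant_escape_before_entry():
    with pytest.raises(ValueError, match="precedes entry"):
        make_event([0, 1], [0, 0], [1, 1], [0, 0], condition="trapped", entry_frame=5, f_escape_frame=2)


def test_natural_event_rejects_entry_frame():
    with pytest.raises(ValueError, match="natural events"):
        make_event([0, 1], [0, 0], [1, 1], [0, 0], condition="natural", entry_frame=0)


# ---------------------------------------------------------------------------
# posture tables

DLC_HEADER = (
    "scorer," + ",".join(["net"] * 18) + "\n"
    "bodyparts," + ",".join(sum([[p] * 3 for p in ("fHead", "fPro", "fTip", "mHead", "mPro", "mTip")], [])) + "\n"
    "coords," + ",".join(["x", "y", "likelihood"] * 6) + "\n"
)


def _dlc_file(tmp_path, liks):
    vals = []
    for i, lik in enumerate(liks):
        vals += [f"{i + 1.0}", f"{i + 2.0}", f"{lik}"]
    path = tmp_path / "posture.csv"
    path.write_text(DLC_HEADER + "0," + ",".join(vals) + "\n")
    return path


@pytest.mark.parametrize(
    "lik,cutoff,kept",
    [(0.85, 0.9, False), (0.95, 0.9, True), (0.85, 0.0, True)],
)
def test_likelihood_cutoff(tmp_path, lik, cutoff, kept):
    """Points below the likelihood cutoff are masked, never silently kept."""
    path = _dlc_file(tmp_path, [lik] + [1.0] * 5)
    frames = read_posture_table(path, p_cutoff=cutoff)
    assert len(frames) == 1
    got = frames[0].xy("fHead")
    if kept:
        np.testing.assert_allclose(got, [1.0, 2.0])
    else:
        assert got is None
    # other points retained with original coordinates
    np.testing.assert_allclose(frames[0].xy("mTip"), [6.0, 7.0])


def test_cutoff_zero_is_identity(tmp_path):
    path = _dlc_file(tmp_path, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    frames = read_posture_table(path, p_cutoff=0.0)
    for i, part in enumerate(("fHead", "fPro", "fTip", "mHead", "mPro", "mTip")):
        np.testing.assert_allclose(frames[0].xy(part), [i + 1.0, i + 2.0])


def test_retained_points_respect_cutoff(tmp_path):
    """Property: no retained point has stored likelihood below the cutoff."""
    rng = np.random.default_rng(0)
    rows = []
    for f in range(20):
        for part in ("fHead", "fPro", "fTip", "mHead", "mPro", "mTip"):
            rows.append(f"{f},{part},{rng.normal()},{rng.normal()},{rng.random():.3f}")
    path = tmp_path / "tidy.csv"
    path.write_text("frame,bodypart,x_mm,y_mm,likelihood\n" + "\n".join(rows) + "\n")
    frames = read_posture_table(path, p_cutoff=0.9)
    for fr in frames:
        for part, (x, y, lik) in fr.points.items():
            if not np.isnan(x):
                assert lik >= 0.9


def test_unknown_bodypart_errors(tmp_path):
    path = tmp_path / "tidy.csv"
    path.write_text("frame,bodypart,x_mm,y_mm,likelihood\n0,fAntenna,0,0,1\n")
    with pytest.raises(ValueError, match="fAntenna"):
        read_posture_table(path)


def test_malformed_header_errors(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("scorer,net\nbodyparts,fHead\nwrong,x\n0,1\n")
    with pytest.raises(ValueError, match="pose-estimation"):
        read_posture_table(path)


# ---------------------------------------------------------------------------
# downsampling

def _uniform_event(fps, n):
    t = np.arange(n)
    return make_event(t * 0.5, t * 0.0, t * 0.5 + 1, t * 0.0, fps=fps)


@pytest.mark.parametrize("fps", [30.0, 25.0])
def test_downsample_to_1fps(fps):
    ev = _uniform_event(fps, int(fps) * 4 + 1)
    out = downsample(ev, 1.0)
    np.testing.assert_array_equal(out.female.frame_index, np.arange(0, int(fps) * 4 + 1, int(fps)))
    assert out.fps == 1.0


def test_downsample_identity():
    ev = _uniform_event(1.0, 5)
    assert downsample(ev, 1.0) is ev


def test_downsample_idempotent():
    ev = _uniform_event(30.0, 121)
    once = downsample(ev, 1.0)
    twice = downsample(once, 1.0)
    np.testing.assert_array_equal(once.female.frame_index, twice.female.frame_index)
    np.testing.assert_allclose(once.female.positions, twice.female.positions)


def test_downsample_snaps_event_frames_forward():
    t = np.arange(121)
    ev = make_event(
        t * 0.5, t * 0, t * 0.5, t * 0, fps=30.0, condition="trapped",
        entry_frame=31, f_escape_frame=61, m_escape_frame=None,
    )
    out = downsample(ev, 1.0)
    assert out.entry_frame == 60  # nearest kept frame at or after 31
    assert out.f_escape_frame == 90
    assert out.m_escape_frame is None


def test_downsample_non_integer_ratio_errors():
    ev = _uniform_event(25.0, 26)
    with pytest.raises(ValueError, match="out of scope"):
        downsample(ev, 2.0)
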