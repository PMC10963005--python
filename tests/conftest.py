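import numpy as np
import pytest

from tandemtrap import (
    PairEvent,
    SyntheticParams,
    TrackedIndividual,
    simulate_natural_pair,
    simulate_trapped_pair,
)


def make_individual(xs, ys, sex="F", bl=8.0, headings=None, frames=None, ind_id="ind"):
    xs = np.asarray(xs, dtype=float)
    if frames is None:
        frames = np.arange(xs.size)
    return TrackedIndividual(ind_id, sex, bl, frames, xs, np.asarray(ys, dtype=float), headings)


def make_event(fx, fy, mx, my, fh=None, mh=None, f_bl=8.0, m_bl=8.0, fps=1.0, condition="natural", **meta):
    return PairEvent(
        "p0",
        "e0",
        condition,
        fps,
        make_individual(fx, fy, "F", f_bl, fh, ind_id="f"),
        make_individual(mx, my, "M", m_bl, mh, ind_id="m"),
        **meta,
    )


@pytest.fixture(scope="session")
def small_params():
    return SyntheticParams(duration_s=60.0, fps=10.0, seed=11)


@pytest.fixture(scope="session")
def natural_event(small_params):
    return simulate_natural_pair(small_params, seed=1)


@pytest.fixture(scope="session")
def trapped_event():
    params = SyntheticParams(duration_s=240.0, fps=10.0, seed=11, escape_hazard_per_min=0.0)
    return simulate_trapped_pair(params, seed=7)
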