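"""Shared fixtures: synthetic sessions and image stacks, generated once."""

from __future__ import annotations

import numpy as np
import pytest

from hippo2p import behavior, signals, synthetic


@pytest.fixture(scope="session")
def track():
    return behavior.make_track()


@pytest.fixture(scope="session")
def small_session(track):
    """A modest session for unit-level checks (fast)."""
    spec = synthetic.SimSessionSpec(
        n_cells=12,
        frac_place=0.5,
        frac_speed=0.25,
        frac_conjunctive=0.0,
        duration_s=420.0,
        seed=11,
    )
    samples = synthetic.simulate_behavior(track, spec)
    frame_times = np.arange(int(spec.duration_s * spec.frame_rate_hz)) / spec.frame_rate_hz
    frames = behavior.process_session(samples, frame_times, track)
    soma, npil, truth = synthetic.simulate_population(frames, spec, track)
    f_s = soma.pivot(index="cell_id", columns="frame", values="f").to_numpy()
    f_n = npil.pivot(index="cell_id", columns="frame", values="f").to_numpy()
    processed = signals.process_traces(frame_times, f_s, f_n)
    return {
        "spec": spec,
        "samples": samples,
        "frames": frames,
        "truth": truth,
        "f_soma": f_s,
        "f_neuropil": f_n,
        "processed": processed,
    }


@pytest.fixture(scope="session")
def full_session(track):
    """The study-condition session: >=100 cells, >=20 kept laps.

    Shared by the classifier-performance and false-positive tests; built
    once per test run.
    """
    spec = synthetic.SimSessionSpec(n_cells=120, duration_s=600.0, seed=1)
    samples = synthetic.simulate_behavior(track, spec)
    frame_times = np.arange(int(spec.duration_s * spec.frame_rate_hz)) / spec.frame_rate_hz
    frames = behavior.process_session(samples, frame_times, track)
    soma, npil, truth = synthetic.simulate_population(frames, spec, track)
    f_s = soma.pivot(index="cell_id", columns="frame", values="f").to_numpy()
    f_n = npil.pivot(index="cell_id", columns="frame", values="f").to_numpy()
    processed = signals.process_traces(frame_times, f_s, f_n)
    assert frames.lap_kept.sum() >= 20
    return {
        "spec": spec,
        "frames": frames,
        "truth": truth,
        "f_soma": f_s,
        "f_neuropil": f_n,
        "processed": processed,
    }


@pytest.fixture(scope="session")
def dendrite_day1():
    spec = synthetic.SimDendriteSpec(seed=4)
    images, truth = synthetic.simulate_dendrite_timeseries(spec, days=1)
    return spec, images, truth


@pytest.fixture(scope="session")
def bead_stack():
    spec = synthetic.SimBeadSpec(seed=2)
    stack, truth = synthetic.simulate_bead_stack(spec)
    return spec, stack, truth
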