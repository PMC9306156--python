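"""Shared fixtures.

The default benchmark session (full 256-channel montage, seed 42) and the
quantities derived from it are expensive, so they are computed once per test
run and shared session-wide.  Cheap property tests use a reduced montage
(4 grids of 4x4) through ``small_session``; it exercises the same code paths
at a fraction of the cost.
"""

from __future__ import annotations

import numpy as np
import pytest

import myogrid as mg
from myogrid.synth import SimulationConfig, simulate_session

BENCH_SEED = 42


@pytest.fixture(scope="session")
def default_session():
    return simulate_session(SimulationConfig(), seed=BENCH_SEED)


@pytest.fixture(scope="session")
def default_segments(default_session):
    return mg.session_segments(default_session)


@pytest.fixture(scope="session")
def combined_features(default_session, default_segments):
    return mg.session_features(default_session, segments=default_segments)


@pytest.fixture(scope="session")
def split70(combined_features):
    return mg.stratified_split(combined_features, 0.70, BENCH_SEED)


@pytest.fixture(scope="session")
def sfs_trace8(split70):
    tr, _ = split70
    return mg.sfs_select(tr, 8, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark_models(default_session, split70, sfs_trace8):
    """LDA models and channel sets for ALL / SFS-8 / CIRC-8 on the split."""
    tr, te = split70
    sets = {
        "ALL": mg.all_select(default_session.layout),
        "SFS": sfs_trace8.channel_prefix(8),
        "CIRC": mg.circ_select(default_session.layout),
    }
    models, accs = {}, {}
    for m, cs in sets.items():
        model, acc = mg.score_on_channels(tr, te, None if m == "ALL" else cs)
        models[m], accs[m] = model, acc
    return sets, models, accs


def make_small_session(seed=0, **overrides):
    """A reduced-montage session for cheap pipeline tests."""
    layout = mg.build_layout(4, 4, 4, 10.0, overrides.pop("corrupted", ()))
    cfg = SimulationConfig(corrupted=tuple(layout.corrupted), **overrides)
    return simulate_session(cfg, layout=layout, seed=seed)


@pytest.fixture(scope="session")
def small_session():
    return make_small_session(seed=0)
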