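"""Shared fixtures: SDP solutions and extractions are expensive, so they
are solved once per session (the solver is deterministic and internally
cached) with wall-clock times recorded for the runtime budgets."""

import time

import numpy as np
import pytest

from koges import (
    DirectionSet,
    ExtractionConfig,
    extract_points,
    solve_koptimal,
)

SOLVE_TIMES: dict[tuple, float] = {}


def _timed_solve(order, N, method):
    t0 = time.perf_counter()
    res = solve_koptimal(order, N, method)
    SOLVE_TIMES[(order, N, method)] = time.perf_counter() - t0
    return res


@pytest.fixture(scope="session")
def sdp4_30():
    return _timed_solve(4, 30, "direct")


@pytest.fixture(scope="session")
def sdp4_15():
    return _timed_solve(4, 15, "direct")


@pytest.fixture(scope="session")
def sdp4_30_ls():
    return _timed_solve(4, 30, "line_search")


@pytest.fixture(scope="session")
def sdp4_15_ls():
    return _timed_solve(4, 15, "line_search")


@pytest.fixture(scope="session")
def sdp2():
    return _timed_solve(2, 6, "direct")


@pytest.fixture(scope="session")
def sdp2_ls():
    return _timed_solve(2, 6, "line_search")


@pytest.fixture(scope="session")
def extraction30(sdp4_30):
    t0 = time.perf_counter()
    res = extract_points(sdp4_30.q_star, ExtractionConfig(N=30, seed=1))
    SOLVE_TIMES[("extract", 30, 1)] = time.perf_counter() - t0
    return res


@pytest.fixture(scope="session")
def extraction30_alt(sdp4_30):
    return extract_points(sdp4_30.q_star, ExtractionConfig(N=30, seed=2))


def random_directions(n: int, seed: int) -> DirectionSet:
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 3))
    return DirectionSet(pts / np.linalg.norm(pts, axis=1, keepdims=True))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
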