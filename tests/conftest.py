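import numpy as np
import pytest

from meaburst import (
    BurstDetectionParams,
    BurstRecord,
    BurstTable,
    ElectrodeID,
    PlateLayout,
    SynthParams,
    TimeWindow,
    parse_electrode_id,
)


@pytest.fixture(scope="session")
def layout():
    return PlateLayout()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_spike_train(rng, n_max=50, t_scale=0.15):
    """A random train with ISIs straddling the 0.1 s threshold."""
    n = int(rng.integers(0, n_max + 1))
    isis = rng.exponential(t_scale, size=n)
    return np.cumsum(isis)


def brute_force_bursts(times, params: BurstDetectionParams):
    """Independent oracle: enumerate every contiguous index range, keep
    those whose internal ISIs are all <= max_isi and length >= min_spikes,
    then select the maximal ones."""
    times = list(times)
    n = len(times)
    candidates = []
    for i in range(n):
        for j in range(i + params.min_spikes - 1, n):
            if all(
                times[k + 1] - times[k] <= params.max_isi_s for k in range(i, j)
            ):
                candidates.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in candidates
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in candidates)
    ]
    return sorted(maximal)


def records_to_ranges(records, times):
    """Map detected BurstRecords back to (first, last) spike indices."""
    times = list(times)
    out = []
    for r in records:
        i = times.index(r.start_time_s)
        out.append((i, i + r.size_spikes - 1))
    return sorted(out)


@pytest.fixture()
def b6_like_table(layout):
    """A small hand-built burst table on well B6 spanning two windows."""
    recs = [
        BurstRecord(parse_electrode_id("B6_11"), 1.0, 10, 0.09),
        BurstRecord(parse_electrode_id("B6_11"), 5.0, 20, 0.19),
        BurstRecord(parse_electrode_id("B6_11"), 130.0, 5, 0.05),
        BurstRecord(parse_electrode_id("B6_12"), 2.5, 8, 0.14),
        BurstRecord(parse_electrode_id("B6_13"), 119.9, 17, 0.09216),
    ]
    return BurstTable(tuple(recs), recording_id="fixture", layout=layout,
                      recording_length_s=240.0)


@pytest.fixture()
def two_windows():
    return (TimeWindow("w1", 0.0, 120.0), TimeWindow("w2", 120.0, 240.0))


@pytest.fixture()
def small_synth_params():
    return SynthParams(
        wells=("A1",),
        recording_length_s=60.0,
        burst_rate_per_min=20.0,
        seed=7,
    )
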