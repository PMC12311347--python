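"""Seeded synthetic multi-well spike trains with known burst ground truth.

The generator emulates the structure of a bursty in-vitro MEA recording:
a multi-well CytoView-style plate where each active electrode fires in
discrete bursts. Bursts arrive with exponential inter-burst gaps floored
well above the detector's ISI threshold; burst sizes follow a shifted
Poisson with a minimum at the detector's spike threshold; within-burst
ISIs are log-normal, truncated below the ISI threshold. Timestamps are
quantized to the 12.5 kHz sampling grid (80 us ticks) before anything
downstream sees them, so fixtures share real data's granularity.

The two truncation rules make generated burst boundaries *identical* to
what the ISI-threshold detector finds: no generated burst can be split
(every internal ISI stays below threshold, by one tick of slack so float
rounding of tick times can never cross it) and no two bursts can merge
(every gap exceeds the threshold). The ground truth is therefore exact,
recomputed from the emitted quantized spike times, and every downstream
module can be tested against it without external data.

Default parameters mirror a 597-s baseline hippocampal culture recording
on a 24-well, 16-electrode plate: ~10 bursts/min per active electrode,
burst sizes around 20 spikes (min 5), within-burst ISIs with a 6 ms
median — the ranges observed on real baseline electrodes (roughly
0.08-0.2 s durations, 7-42 spikes, 4-29 ms mean ISIs).
"""

from __future__ import annotations

import hashlib
import json
import math
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .axis_io import (
    BurstRecord,
    BurstTable,
    ElectrodeID,
    PlateLayout,
    parse_electrode_id,
    write_electrode_burst_list,
)
from .burst_detection import (
    BurstDetectionParams,
    SpikeTrain,
    detect_bursts,
    write_spike_times,
)
from .burst_metrics import TimeWindow
from .errors import ConfigError

__all__ = [
    "SAMPLE_RATE_HZ",
    "SynthParams",
    "GroundTruth",
    "simulate_spike_trains",
    "generate_fixture",
    "load_synth_params",
]

#: acquisition sampling rate emulated by the generator
SAMPLE_RATE_HZ = 12500.0
_DT = 1.0 / SAMPLE_RATE_HZ


@dataclass(frozen=True)
class SynthParams:
    """Generative parameters of the synthetic plate.

    Rates are per active electrode; ``modulation`` maps window labels to
    burst-rate multipliers (e.g. a KCl-like transient doubling). The
    effective mean inter-burst interval is ``gap_floor_s + 60 / rate``.
    """

    wells: tuple[str, ...] | None = None  # None -> all wells of the layout
    recording_length_s: float = 597.0
    burst_rate_per_min: float = 10.0
    mean_burst_size: float = 20.0
    isi_median_s: float = 0.006
    isi_sigma: float = 0.5
    gap_floor_s: float = 0.25
    silent_electrodes: frozenset[str] = frozenset()
    windows: tuple[TimeWindow, ...] | None = None  # None -> one full-length window
    modulation: Mapping[str, float] = field(default_factory=dict)
    detection: BurstDetectionParams = field(default_factory=BurstDetectionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "silent_electrodes", frozenset(self.silent_electrodes))
        object.__setattr__(self, "modulation", dict(self.modulation))
        if self.wells is not None:
            object.__setattr__(self, "wells", tuple(self.wells))
        if self.windows is not None:
            object.__setattr__(self, "windows", tuple(self.windows))
        if self.recording_length_s <= 0:
            raise ConfigError("recording_length_s must be positive")
        if self.burst_rate_per_min < 0:
            raise ConfigError("burst_rate_per_min must be >= 0")
        if self.mean_burst_size < self.detection.min_spikes:
            raise ConfigError(
                f"mean_burst_size ({self.mean_burst_size}) below the detector's "
                f"min_spikes ({self.detection.min_spikes})"
            )
        if self.isi_median_s <= 0 or self.isi_median_s > self.detection.max_isi_s:
            raise ConfigError(
                "isi_median_s must lie in (0, max_isi_s] so truncation is mild"
            )
        if self.isi_sigma < 0:
            raise ConfigError("isi_sigma must be >= 0")
        if self.gap_floor_s <= self.detection.max_isi_s:
            raise ConfigError(
                f"gap_floor_s ({self.gap_floor_s}) must exceed max_isi_s "
                f"({self.detection.max_isi_s}) so bursts never merge"
            )
        if self.windows is not None:
            for w in self.windows:
                if w.label in self.modulation and self.modulation[w.label] < 0:
                    raise ConfigError(f"negative rate multiplier for {w.label!r}")
        elif self.modulation:
            raise ConfigError("modulation given but no windows defined")

    def effective_windows(self) -> tuple[TimeWindow, ...]:
        if self.windows is not None:
            return self.windows
        return (TimeWindow("all", 0.0, self.recording_length_s),)


@dataclass(frozen=True)
class GroundTruth:
    """True bursts per electrode, recomputed from the emitted spike times."""

    windows: tuple[TimeWindow, ...]
    bursts: dict[str, tuple[BurstRecord, ...]]

    def table(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        """Per-(electrode, window) true values of the four burst parameters.

        Computed by direct arithmetic over the true burst list, independent
        of the summary pipeline it is used to test.
        """
        import pandas as pd

        rows = []
        for token in sorted(self.bursts):
            for window in self.windows:
                inw = [
                    b
                    for b in self.bursts[token]
                    if window.contains(b.start_time_s)
                ]
                if inw:
                    durs = [b.duration_s for b in inw]
                    sizes = [b.size_spikes for b in inw]
                    isis = [b.duration_s / (b.size_spikes - 1) for b in inw]
                    vals = (
                        len(inw),
                        float(np.mean(durs)),
                        float(np.mean(sizes)),
                        float(np.mean(isis)),
                    )
                else:
                    vals = (0, math.nan, math.nan, math.nan)
                rows.append(
                    {
                        "electrode": token,
                        "window": window.label,
                        "n_bursts": vals[0],
                        "mean_duration_s": vals[1],
                        "mean_spikes_per_burst": vals[2],
                        "mean_burst_isi_s": vals[3],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "windows": [
                {"label": w.label, "t0_s": w.t0_s, "t1_s": w.t1_s}
                for w in self.windows
            ],
            "bursts": {
                token: [
                    [b.start_time_s, b.size_spikes, b.duration_s]
                    for b in bursts
                ]
                for token, bursts in sorted(self.bursts.items())
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        windows = tuple(
            TimeWindow(w["label"], w["t0_s"], w["t1_s"]) for w in payload["windows"]
        )
        bursts = {
            token: tuple(
                BurstRecord(parse_electrode_id(token), start, int(size), dur)
                for start, size, dur in items
            )
            for token, items in payload["bursts"].items()
        }
        return cls(windows, bursts)


def _electrode_rng(seed: int, electrode: ElectrodeID) -> np.random.Generator:
    """Per-electrode substream: stable hash of the token, so adding
    electrodes never perturbs existing trains."""
    sub = zlib.crc32(str(electrode).encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def _rate_multiplier(params: SynthParams, t_s: float) -> float:
    if not params.modulation or params.windows is None:
        return 1.0
    for w in params.windows:
        if w.contains(t_s):
            return float(params.modulation.get(w.label, 1.0))
    return 1.0


def _simulate_electrode(
    params: SynthParams, electrode: ElectrodeID
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One electrode's quantized spike times plus burst index ranges."""
    rng = _electrode_rng(params.seed, electrode)
    det = params.detection
    # one tick of slack below / above threshold so tick->float conversion
    # can never flip an ISI across max_isi_s
    max_isi_ticks = int(math.floor(det.max_isi_s / _DT)) - 1
    min_gap_ticks = int(math.floor(det.max_isi_s / _DT)) + 2
    end_tick = int(math.floor(params.recording_length_s / _DT))
    mu = math.log(params.isi_median_s)

    ticks: list[int] = []
    bounds: list[tuple[int, int]] = []
    t = 0
    while True:
        mult = _rate_multiplier(params, t * _DT)
        rate = params.burst_rate_per_min * mult
        if rate <= 0:
            # rate silenced in the current window: jump to its end
            nxt = None
            if params.windows is not None:
                for w in params.windows:
                    if w.contains(t * _DT):
                        nxt = int(math.ceil(w.t1_s / _DT))
                        break
            if nxt is None or nxt >= end_tick:
                break
            t = nxt
            continue
        gap_s = params.gap_floor_s + rng.exponential(60.0 / rate)
        start = t + max(int(math.ceil(gap_s / _DT)), min_gap_ticks)
        size = det.min_spikes + int(
            rng.poisson(params.mean_burst_size - det.min_spikes)
        )
        isis = rng.lognormal(mean=mu, sigma=params.isi_sigma, size=size - 1)
        isi_ticks = np.clip(np.rint(isis / _DT).astype(int), 1, max_isi_ticks)
        spike_ticks = start + np.concatenate([[0], np.cumsum(isi_ticks)])
        if spike_ticks[-1] >= end_tick:
            break  # burst would not fit entirely inside the recording
        bounds.append((len(ticks), len(ticks) + size))
        ticks.extend(int(x) for x in spike_ticks)
        t = int(spike_ticks[-1])
    return np.asarray(ticks, dtype=float) * _DT, bounds


def simulate_spike_trains(
    params: SynthParams, layout: PlateLayout | None = None
) -> tuple[tuple[SpikeTrain, ...], GroundTruth]:
    """Generate one plate's spike trains and their exact burst ground truth.

    Deterministic for a given seed. Silent electrodes emit no spikes.
    Every generated burst survives ISI-threshold detection intact (see
    module docstring), which downstream tests assert rather than assume.
    """
    layout = layout or PlateLayout()
    wells = params.wells if params.wells is not None else layout.wells
    trains: list[SpikeTrain] = []
    bursts: dict[str, tuple[BurstRecord, ...]] = {}
    for well in wells:
        for electrode in layout.electrodes(well):
            token = str(electrode)
            if token in params.silent_electrodes:
                trains.append(SpikeTrain(electrode, np.empty(0)))
                bursts[token] = ()
                continue
            times, bounds = _simulate_electrode(params, electrode)
            trains.append(SpikeTrain(electrode, times))
            # truth recomputed from the emitted (quantized) times with the
            # same float arithmetic the detector uses
            bursts[token] = tuple(
                BurstRecord(
                    electrode,
                    start_time_s=float(times[i]),
                    size_spikes=j - i,
                    duration_s=float(times[j - 1] - times[i]),
                )
                for i, j in bounds
            )
    return tuple(trains), GroundTruth(params.effective_windows(), bursts)


def _params_hash(params: SynthParams) -> str:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        if hasattr(o, "__dict__"):
            return vars(o)
        raise TypeError(type(o))

    blob = json.dumps(asdict(params), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def generate_fixture(
    params: SynthParams,
    out_dir: str | Path,
    layout: PlateLayout | None = None,
) -> dict:
    """Write a complete test fixture and return its manifest.

    Emits ``spikes.csv`` (two-column spike times), ``bursts.csv`` (the
    detector's output in the AxIS burst-list dialect), and
    ``ground_truth.json``; ``manifest.json`` records the seed and a
    parameter hash. Re-running with the same params is idempotent.
    """
    layout = layout or PlateLayout()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trains, truth = simulate_spike_trains(params, layout)

    spikes_path = out / "spikes.csv"
    bursts_path = out / "bursts.csv"
    truth_path = out / "ground_truth.json"
    manifest_path = out / "manifest.json"

    write_spike_times(trains, spikes_path)
    records: list[BurstRecord] = []
    for train in trains:
        records.extend(detect_bursts(train, params.detection))
    table = BurstTable(
        tuple(records),
        recording_id=f"synthetic-seed{params.seed}",
        layout=layout,
        recording_length_s=params.recording_length_s,
    )
    write_electrode_burst_list(table, bursts_path)
    truth_path.write_text(truth.to_json(), encoding="utf-8")

    manifest = {
        "seed": params.seed,
        "params_sha256": _params_hash(params),
        "n_electrodes": len(trains),
        "n_spikes": int(sum(len(t) for t in trains)),
        "n_bursts": len(records),
        "files": {
            "spikes": spikes_path.name,
            "bursts": bursts_path.name,
            "ground_truth": truth_path.name,
        },
    }
    manifest_path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def load_synth_params(source: str | Path, *, seed: int | None = None) -> SynthParams:
    """Load :class:`SynthParams` from a YAML config; ``seed`` overrides."""
    raw = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError("synth config must be a mapping")
    if "windows" in raw and raw["windows"] is not None:
        raw["windows"] = tuple(
            TimeWindow(str(w["label"]), float(w["t0_s"]), float(w["t1_s"]))
            for w in raw["windows"]
        )
    if "detection" in raw and raw["detection"] is not None:
        raw["detection"] = BurstDetectionParams(**raw["detection"])
    if "wells" in raw and raw["wells"] is not None:
        raw["wells"] = tuple(raw["wells"])
    if "silent_electrodes" in raw and raw["silent_electrodes"] is not None:
        raw["silent_electrodes"] = frozenset(raw["silent_electrodes"])
    params = SynthParams(**raw)
    if seed is not None:
        params = replace(params, seed=int(seed))
    return params
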