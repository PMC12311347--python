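"""Time-window filtering and the four burst parameters.

For each electrode and labeled time window this module computes the
number of bursts, the average burst duration, the average number of
spikes per burst, and the average mean within-burst ISI. The mean
within-burst ISI of one burst is ``duration / (size - 1)``; the
electrode-level value is the arithmetic mean of that quantity over
bursts, not the ratio of the mean duration to the mean size minus one
(the two differ whenever bursts are heterogeneous).

Window membership is decided by the burst *start* time on the half-open
interval ``[t0, t1)``, so any partition of the recording into windows
conserves per-electrode burst counts exactly.

Whole-well summaries average electrode-level values with an SEM
(sample standard deviation / sqrt(n)). Burst counts include inactive
electrodes as zeros by default; the duration/size/ISI means are
averaged over active electrodes only, since they are undefined for an
electrode with no bursts. Both policies are switchable.
"""

from __future__ import annotations


import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .axis_io import BurstTable, ElectrodeID
from .errors import FormatError, ValidationError

__all__ = [
    "TimeWindow",
    "ElectrodeSummary",
    "WellSummary",
    "ComparisonEntry",
    "ComparisonReport",
    "PARAMETERS",
    "load_windows",
    "filter_window",
    "mean_burst_isi",
    "summarize_electrode",
    "summarize_well",
    "summarize_table",
    "compare_with_reference",
]

#: canonical parameter column names used in tidy exports
PARAMETERS = (
    "n_bursts",
    "mean_duration_s",
    "mean_spikes_per_burst",
    "mean_burst_isi_s",
)


@dataclass(frozen=True, order=True)
class TimeWindow:
    """A labeled half-open analysis window ``[t0_s, t1_s)``."""

    label: str
    t0_s: float
    t1_s: float

    def __post_init__(self) -> None:
        if not self.t1_s > self.t0_s:
            raise ValidationError(
                f"window {self.label!r}: t1 ({self.t1_s}) must exceed t0 ({self.t0_s})"
            )

    def contains(self, t: float) -> bool:
        return self.t0_s <= t < self.t1_s


def load_windows(source: str | Path) -> tuple[TimeWindow, ...]:
    """Load windows from a YAML or JSON list of ``{label, t0_s, t1_s}``."""
    text = Path(source).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse windows config: {exc}") from None
    if not isinstance(raw, list) or not raw:
        raise FormatError("windows config must be a non-empty list")
    windows = []
    for i, item in enumerate(raw):
        try:
            windows.append(
                TimeWindow(str(item["label"]), float(item["t0_s"]), float(item["t1_s"]))
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(f"windows entry {i}: {exc}") from None
    labels = [w.label for w in windows]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate window labels")
    return tuple(windows)


def filter_window(table: BurstTable, window: TimeWindow) -> BurstTable:
    """Keep exactly the records whose start time lies in ``[t0, t1)``."""
    kept = tuple(r for r in table.records if window.contains(r.start_time_s))
    return BurstTable(
        kept,
        recording_id=table.recording_id,
        layout=table.layout,
        recording_length_s=table.recording_length_s,
    )


def mean_burst_isi(duration_s: float, size_spikes: int) -> float:
    """Mean within-burst ISI of one burst: ``duration / (size - 1)``."""
    if size_spikes < 2:
        raise ValidationError(
            f"mean ISI undefined for a burst of {size_spikes} spike(s)"
        )
    return duration_s / (size_spikes - 1)


@dataclass(frozen=True)
class ElectrodeSummary:
    """The four burst parameters for one electrode in one window.

    The three means are NaN iff ``n_bursts == 0`` (never reported as 0).
    """

    electrode: ElectrodeID
    window: TimeWindow
    n_bursts: int
    mean_duration_s: float
    mean_spikes_per_burst: float
    mean_burst_isi_s: float

    @property
    def active(self) -> bool:
        return self.n_bursts > 0


@dataclass(frozen=True)
class WellSummary:
    """Across-electrode mean and SEM of each parameter for one well/window."""

    well_label: str
    window: TimeWindow
    n_electrodes_active: int
    mean_n_bursts: float
    sem_n_bursts: float
    mean_duration_s: float
    sem_duration_s: float
    mean_spikes_per_burst: float
    sem_spikes_per_burst: float
    mean_burst_isi_s: float
    sem_burst_isi_s: float


def _mean_sem(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return math.nan, math.nan
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return mean, sem


def summarize_electrode(
    table: BurstTable, electrode: ElectrodeID, window: TimeWindow
) -> ElectrodeSummary:
    """The four burst parameters for one electrode within one window."""
    bursts = [
        r
        for r in table.for_electrode(electrode)
        if window.contains(r.start_time_s)
    ]
    if not bursts:
        return ElectrodeSummary(
            electrode, window, 0, math.nan, math.nan, math.nan
        )
    durations = [b.duration_s for b in bursts]
    sizes = [b.size_spikes for b in bursts]
    isis = [mean_burst_isi(b.duration_s, b.size_spikes) for b in bursts]
    return ElectrodeSummary(
        electrode,
        window,
        n_bursts=len(bursts),
        mean_duration_s=float(np.mean(durations)),
        mean_spikes_per_burst=float(np.mean(sizes)),
        mean_burst_isi_s=float(np.mean(isis)),
    )


def summarize_well(
    table: BurstTable,
    well_label: str,
    window: TimeWindow,
    *,
    count_policy: Literal["include_inactive", "active_only"] = "include_inactive",
) -> WellSummary:
    """Across-electrode mean +/- SEM of each parameter for one well.

    With the default ``count_policy`` the burst-count mean runs over all
    electrodes of the well (inactive ones contribute 0); the other three
    parameters always average over active electrodes only, where they
    are defined.
    """
    electrodes = table.layout.electrodes(well_label)  # raises if well unknown
    summaries = [summarize_electrode(table, e, window) for e in electrodes]
    active = [s for s in summaries if s.active]

    count_pool = summaries if count_policy == "include_inactive" else active
    mean_n, sem_n = _mean_sem([s.n_bursts for s in count_pool])
    mean_dur, sem_dur = _mean_sem([s.mean_duration_s for s in active])
    mean_spk, sem_spk = _mean_sem([s.mean_spikes_per_burst for s in active])
    mean_isi, sem_isi = _mean_sem([s.mean_burst_isi_s for s in active])
    return WellSummary(
        well_label,
        window,
        n_electrodes_active=len(active),
        mean_n_bursts=mean_n,
        sem_n_bursts=sem_n,
        mean_duration_s=mean_dur,
        sem_duration_s=sem_dur,
        mean_spikes_per_burst=mean_spk,
        sem_spikes_per_burst=sem_spk,
        mean_burst_isi_s=mean_isi,
        sem_burst_isi_s=sem_isi,
    )


def summarize_table(
    table: BurstTable,
    windows: Sequence[TimeWindow],
    *,
    level: Literal["electrode", "well"] = "electrode",
    wells: Sequence[str] | None = None,
    count_policy: Literal["include_inactive", "active_only"] = "include_inactive",
) -> pd.DataFrame:
    """Tidy per-(electrode|well, window) summary of the four parameters.

    ``wells`` defaults to the wells with at least one record in the
    table. Undefined means are emitted as missing values (NaN).
    """
    wells = tuple(wells) if wells is not None else table.wells()
    rows: list[dict] = []
    if level == "electrode":
        for well in wells:
            for electrode in table.layout.electrodes(well):
                for window in windows:
                    s = summarize_electrode(table, electrode, window)
                    rows.append(
                        {
                            "electrode": str(electrode),
                            "well": well,
                            "window": window.label,
                            "t0_s": window.t0_s,
                            "t1_s": window.t1_s,
                            "n_bursts": s.n_bursts,
                            "mean_duration_s": s.mean_duration_s,
                            "mean_spikes_per_burst": s.mean_spikes_per_burst,
                            "mean_burst_isi_s": s.mean_burst_isi_s,
                        }
                    )
    elif level == "well":
        for well in wells:
            for window in windows:
                s = summarize_well(table, well, window, count_policy=count_policy)
                rows.append(
                    {
                        "well": well,
                        "window": window.label,
                        "t0_s": window.t0_s,
                        "t1_s": window.t1_s,
                        "n_electrodes_active": s.n_electrodes_active,
                        "mean_n_bursts": s.mean_n_bursts,
                        "sem_n_bursts": s.sem_n_bursts,
                        "mean_duration_s": s.mean_duration_s,
                        "sem_duration_s": s.sem_duration_s,
                        "mean_spikes_per_burst": s.mean_spikes_per_burst,
                        "sem_spikes_per_burst": s.sem_spikes_per_burst,
                        "mean_burst_isi_s": s.mean_burst_isi_s,
                        "sem_burst_isi_s": s.sem_burst_isi_s,
                    }
                )
    else:
        raise ValidationError(f"unknown summary level {level!r}")
    return pd.DataFrame(rows)


# --- reference comparison ----------------------------------------------------


@dataclass(frozen=True)
class ComparisonEntry:
    electrode: str
    parameter: str
    value: float
    reference: float
    abs_diff: float
    passed: bool


@dataclass(frozen=True)
class ComparisonReport:
    """Per-electrode, per-parameter absolute differences against a reference."""

    entries: tuple[ComparisonEntry, ...]
    tol: float
    only_in_summaries: tuple[str, ...]
    only_in_reference: tuple[str, ...]

    @property
    def mismatches(self) -> tuple[ComparisonEntry, ...]:
        return tuple(e for e in self.entries if not e.passed)

    @property
    def passed(self) -> bool:
        return not self.mismatches

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def _as_parameter_frame(
    summaries: Iterable[ElectrodeSummary] | pd.DataFrame | str | Path,
) -> pd.DataFrame:
    """Coerce summaries / a flat CSV / a DataFrame into electrode-keyed parameters."""
    if isinstance(summaries, (str, Path)):
        df = pd.read_csv(summaries)
    elif isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame(
            {
                "electrode": [str(s.electrode) for s in summaries],
                "n_bursts": [s.n_bursts for s in summaries],
                "mean_duration_s": [s.mean_duration_s for s in summaries],
                "mean_spikes_per_burst": [s.mean_spikes_per_burst for s in summaries],
                "mean_burst_isi_s": [s.mean_burst_isi_s for s in summaries],
            }
        )
    if "electrode" not in df.columns:
        raise FormatError("reference table needs an 'electrode' column")
    params = [c for c in PARAMETERS if c in df.columns]
    if not params:
        raise FormatError(
            f"reference table has none of the parameter columns {list(PARAMETERS)}"
        )
    return df.set_index("electrode")[params]


def compare_with_reference(
    summaries: Iterable[ElectrodeSummary] | pd.DataFrame | str | Path,
    reference: pd.DataFrame | str | Path,
    tol: float = 1e-3,
) -> ComparisonReport:
    """Compare per-electrode parameters against a flat reference table.

    Each shared (electrode, parameter) cell passes iff the absolute
    difference is at most ``tol``. Electrodes present on only one side
    are flagged, not fatal.
    """
    left = _as_parameter_frame(summaries)
    right = _as_parameter_frame(reference)
    shared_params = [c for c in PARAMETERS if c in left.columns and c in right.columns]
    shared = sorted(set(left.index) & set(right.index))
    entries = []
    for electrode in shared:
        for param in shared_params:
            a = float(left.at[electrode, param])
            b = float(right.at[electrode, param])
            diff = abs(a - b)
            ok = bool(diff <= tol) or (math.isnan(a) and math.isnan(b))
            entries.append(ComparisonEntry(electrode, param, a, b, diff, ok))
    return ComparisonReport(
        entries=tuple(entries),
        tol=tol,
        only_in_summaries=tuple(sorted(set(left.index) - set(right.index))),
        only_in_reference=tuple(sorted(set(right.index) - set(left.index))),
    )
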