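"""Bar-chart views of burst summaries and the plate schematic.

Figures are views, never recomputations: every chart writes a sidecar
CSV of exactly the values it drew, so plots are regression-testable
without image comparison. Electrode-level charts arrange one panel per
electrode in the physical 4x4 in-well grid (column = first position
digit, row = second; row 1 drawn at the top by default, flippable).
Electrodes with no bursts in any plotted window are rendered as empty
panels labeled "inactive", never as zero-height bars, and a well mean
that is undefined is omitted with an annotation rather than drawn as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd

from .axis_io import PlateLayout
from .burst_metrics import PARAMETERS, ElectrodeSummary, WellSummary
from .errors import ValidationError

__all__ = [
    "ChartSpec",
    "plot_well_bars",
    "plot_electrode_bars",
    "plot_plate_schematic",
]

_PARAM_LABELS = {
    "n_bursts": "Number of bursts",
    "mean_duration_s": "Average burst duration (s)",
    "mean_spikes_per_burst": "Average spikes per burst",
    "mean_burst_isi_s": "Average mean burst ISI (s)",
}

_PNG_META = {"Software": None}  # strip the toolkit stamp for byte-stable output


@dataclass(frozen=True)
class ChartSpec:
    """What to draw: level, parameter, window order, error bars, output path."""

    level: Literal["well", "electrode"]
    parameter: str
    output: str | Path
    windows: tuple[str, ...] | None = None  # None -> order of the summaries
    error_bars: bool = True
    row_one_top: bool = True

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValidationError(
                f"unknown parameter {self.parameter!r}; expected one of {list(PARAMETERS)}"
            )
        if self.windows is not None:
            object.__setattr__(self, "windows", tuple(self.windows))


def _sidecar_path(output: str | Path) -> Path:
    out = Path(output)
    return out.with_suffix(out.suffix + ".csv") if out.suffix != ".csv" else out


def _window_order(spec: ChartSpec, labels: Sequence[str]) -> list[str]:
    if spec.windows is not None:
        return list(spec.windows)
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return seen


def plot_well_bars(summaries: Sequence[WellSummary], spec: ChartSpec) -> Path:
    """One bar per time window of a well-level parameter, +/- SEM whiskers."""
    if not summaries:
        raise ValidationError("no well summaries to plot")
    wells = {s.well_label for s in summaries}
    if len(wells) != 1:
        raise ValidationError(f"well chart needs one well, got {sorted(wells)}")
    well = wells.pop()
    by_window = {s.window.label: s for s in summaries}
    order = _window_order(spec, [s.window.label for s in summaries])

    mean_attr = "mean_n_bursts" if spec.parameter == "n_bursts" else spec.parameter
    sem_attr = mean_attr.replace("mean_", "sem_", 1)

    rows = []
    for label in order:
        s = by_window.get(label)
        if s is None:
            raise ValidationError(f"no summary for window {label!r}")
        rows.append(
            {
                "well": well,
                "window": label,
                "parameter": spec.parameter,
                "value": getattr(s, mean_attr),
                "sem": getattr(s, sem_attr),
                "n_electrodes_active": s.n_electrodes_active,
            }
        )
    data = pd.DataFrame(rows)

    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(order), 3.6))
    for i, row in data.iterrows():
        if math.isnan(row["value"]):
            ax.annotate(
                "no active\nelectrodes",
                (i, 0),
                ha="center",
                va="bottom",
                fontsize=8,
                color="0.4",
            )
            continue
        err = row["sem"] if spec.error_bars and not math.isnan(row["sem"]) else None
        ax.bar(
            i,
            row["value"],
            yerr=err,
            capsize=3,
            color="#4878a8",
            edgecolor="black",
            linewidth=0.5,
        )
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel(_PARAM_LABELS[spec.parameter])
    ax.set_title(f"Well {well}")
    fig.tight_layout()
    out = Path(spec.output)
    fig.savefig(out, dpi=150, metadata=_PNG_META if out.suffix == ".png" else None)
    plt.close(fig)
    data.to_csv(_sidecar_path(out), index=False)
    return out


def plot_electrode_bars(summaries: Sequence[ElectrodeSummary], spec: ChartSpec) -> Path:
    """Per-electrode bars laid out in the physical 4x4 in-well grid.

    Each panel sits at (column, row) of its electrode's position;
    electrodes inactive in every window become labeled empty panels.
    """
    if not summaries:
        raise ValidationError("no electrode summaries to plot")
    wells = {s.electrode.well_label for s in summaries}
    if len(wells) != 1:
        raise ValidationError(
            f"electrode chart needs electrodes of one well, got {sorted(wells)}"
        )
    well = wells.pop()
    order = _window_order(spec, [s.window.label for s in summaries])
    by_key: dict[tuple[str, str], ElectrodeSummary] = {
        (str(s.electrode), s.window.label): s for s in summaries
    }
    electrodes = sorted({s.electrode for s in summaries})

    # an electrode with no bursts in any plotted window is "inactive":
    # its panel stays empty and its sidecar values are missing, never 0
    active_tokens = {
        str(e)
        for e in electrodes
        if any(
            (s := by_key.get((str(e), lab))) is not None and s.n_bursts > 0
            for lab in order
        )
    }
    rows = []
    for e in electrodes:
        for label in order:
            s = by_key.get((str(e), label))
            value = (
                getattr(s, spec.parameter)
                if s is not None and str(e) in active_tokens
                else math.nan
            )
            rows.append(
                {
                    "electrode": str(e),
                    "col": e.col,
                    "row": e.row,
                    "window": label,
                    "parameter": spec.parameter,
                    "value": value,
                }
            )
    data = pd.DataFrame(rows)

    side = 4
    fig, axes = plt.subplots(
        side, side, figsize=(2.2 * side, 1.8 * side), sharex=True, sharey=True
    )
    used = set()
    for e in electrodes:
        grid_row = (e.row - 1) if spec.row_one_top else (side - e.row)
        ax = axes[grid_row][e.col - 1]
        used.add((grid_row, e.col - 1))
        vals = data[data["electrode"] == str(e)].set_index("window")["value"]
        if vals.isna().all():
            ax.annotate(
                "inactive", (0.5, 0.5), xycoords="axes fraction", ha="center", va="center"
            )
            ax.set_xticks([])
        else:
            for i, label in enumerate(order):
                v = vals.get(label, math.nan)
                if not math.isnan(v):
                    ax.bar(i, v, color="#4878a8", edgecolor="black", linewidth=0.5)
            ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
        ax.set_title(str(e), fontsize=8)
    for i in range(side):
        for j in range(side):
            if (i, j) not in used:
                axes[i][j].axis("off")
    fig.suptitle(f"Well {well} - {_PARAM_LABELS[spec.parameter]}")
    fig.tight_layout()
    out = Path(spec.output)
    fig.savefig(out, dpi=150, metadata=_PNG_META if out.suffix == ".png" else None)
    plt.close(fig)
    data.to_csv(_sidecar_path(out), index=False)
    return out


def plot_plate_schematic(layout: PlateLayout, output: str | Path) -> Path:
    """To-scale schematic of one well's electrode grid with ``col,row`` labels.

    Electrode circles use the layout's true diameter and pitch (um).
    """
    if layout.electrode_pitch_um < layout.electrode_diameter_um:
        raise ValidationError(
            "electrode pitch smaller than diameter: electrodes would overlap"
        )
    side = layout.electrodes_per_well_side
    pitch = layout.electrode_pitch_um
    radius = layout.electrode_diameter_um / 2

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    rows_csv = []
    for c in range(1, side + 1):
        for r in range(1, side + 1):
            x = (c - 1) * pitch
            y = (side - r) * pitch  # row 1 at top
            ax.add_patch(plt.Circle((x, y), radius, color="#333333"))
            ax.annotate(
                f"{c},{r}", (x, y + radius + 0.12 * pitch), ha="center", fontsize=8
            )
            rows_csv.append(
                {"col": c, "row": r, "x_um": x, "y_um": y, "diameter_um": 2 * radius}
            )
    margin = pitch * 0.6
    ax.set_xlim(-margin, (side - 1) * pitch + margin)
    ax.set_ylim(-margin, (side - 1) * pitch + margin)
    ax.set_aspect("equal")
    ax.set_xlabel("um")
    ax.set_ylabel("um")
    ax.set_title(
        f"{side}x{side} electrode grid "
        f"({layout.electrode_diameter_um:g} um diameter, {pitch:g} um pitch)"
    )
    fig.tight_layout()
    out = Path(output)
    fig.savefig(out, dpi=150, metadata=_PNG_META if out.suffix == ".png" else None)
    plt.close(fig)
    pd.DataFrame(rows_csv).to_csv(_sidecar_path(out), index=False)
    return out
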