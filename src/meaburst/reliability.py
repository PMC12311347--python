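"""Intraclass correlation ICC(2,k) over single-electrode mean results.

The reliability question: do the electrodes of a well tell a consistent
story, so that the well average is a trustworthy readout of network
activity? We treat each electrode as a "rater" scoring each "subject"
(a well, or a time window) on one burst parameter, and compute the
Shrout-Fleiss two-way random-effects, absolute-agreement, average-of-k
intraclass correlation:

    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

where MSR, MSC and MSE are the subject, rater and residual mean squares
of the two-way ANOVA decomposition of the n x k ratings matrix
(df = n-1, k-1 and (n-1)(k-1)). Values near 1 indicate that the
average over electrodes is reliable; the statistic can be negative and
is undefined when all cells are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .burst_metrics import PARAMETERS, ElectrodeSummary
from .errors import DegenerateMatrixError, ValidationError

__all__ = ["RatingsMatrix", "ICCResult", "icc2k", "build_ratings_matrix"]


@dataclass(frozen=True)
class RatingsMatrix:
    """A complete n x k matrix of ratings: subjects in rows, raters in columns."""

    values: np.ndarray
    subject_labels: tuple[str, ...]
    rater_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_labels", tuple(self.subject_labels))
        object.__setattr__(self, "rater_labels", tuple(self.rater_labels))
        if values.ndim != 2:
            raise ValidationError("ratings must form a 2-D matrix")
        n, k = values.shape
        if n < 2 or k < 2:
            raise ValidationError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
        if len(self.subject_labels) != n or len(self.rater_labels) != k:
            raise ValidationError("label counts do not match matrix shape")
        if not np.all(np.isfinite(values)):
            raise ValidationError("ratings matrix must be complete (no missing cells)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_labels), columns=list(self.rater_labels)
        )


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,k) with the mean squares of its two-way ANOVA decomposition."""

    icc2k: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int

    def summary(self) -> str:
        return (
            f"ICC(2,k) = {self.icc2k:.6f}  "
            f"(n={self.n_subjects} subjects x k={self.k_raters} raters; "
            f"MSR={self.ms_rows:.6g}, MSC={self.ms_cols:.6g}, MSE={self.ms_error:.6g})"
        )


def icc2k(matrix: RatingsMatrix) -> ICCResult:
    """Two-way random-effects, absolute-agreement, average-raters ICC.

    Raises
    ------
    DegenerateMatrixError
        If every cell is identical, where the ICC is undefined (never
        silently reported as 0 or 1).
    """
    x = matrix.values
    n, k = x.shape
    if np.ptp(x) == 0:
        raise DegenerateMatrixError(
            "all ratings identical: ICC(2,k) is undefined (0/0)"
        )
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom == 0:
        raise DegenerateMatrixError("ICC(2,k) denominator is zero")
    value = (msr - mse) / denom
    return ICCResult(
        icc2k=value,
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        n_subjects=n,
        k_raters=k,
    )


Orientation = Literal["wells-by-electrodes", "windows-by-electrodes"]


def build_ratings_matrix(
    summaries: Iterable[ElectrodeSummary],
    parameter: str,
    orientation: Orientation = "wells-by-electrodes",
    *,
    drop_incomplete_raters: bool = False,
) -> RatingsMatrix:
    """Arrange electrode summaries into a subjects x raters matrix.

    ``wells-by-electrodes``: subjects are wells, raters are the in-well
    electrode positions (summaries must cover one window). ``windows-by-
    electrodes``: subjects are time windows, raters are electrodes
    (summaries must cover one well). Cells come from the named burst
    parameter; electrodes with undefined values make the matrix
    incomplete, which raises unless ``drop_incomplete_raters`` removes
    the offending columns.
    """
    if parameter not in PARAMETERS:
        raise ValidationError(
            f"unknown parameter {parameter!r}; expected one of {list(PARAMETERS)}"
        )
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no summaries provided")

    if orientation == "wells-by-electrodes":
        windows = {s.window.label for s in summaries}
        if len(windows) != 1:
            raise ValidationError(
                f"wells-by-electrodes needs a single window, got {sorted(windows)}"
            )
        subject_of = lambda s: s.electrode.well_label
        rater_of = lambda s: f"{s.electrode.col}{s.electrode.row}"
    elif orientation == "windows-by-electrodes":
        wells = {s.electrode.well_label for s in summaries}
        if len(wells) != 1:
            raise ValidationError(
                f"windows-by-electrodes needs a single well, got {sorted(wells)}"
            )
        subject_of = lambda s: s.window.label
        rater_of = lambda s: str(s.electrode)
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")

    cells: dict[tuple[str, str], float] = {}
    subject_order: list[str] = []
    rater_order: list[str] = []
    for s in summaries:
        key = (subject_of(s), rater_of(s))
        if key in cells:
            raise ValidationError(f"duplicate cell for subject/rater {key}")
        cells[key] = getattr(s, parameter)
        if key[0] not in subject_order:
            subject_order.append(key[0])
        if key[1] not in rater_order:
            rater_order.append(key[1])

    missing = [
        (subj, rater)
        for subj in subject_order
        for rater in rater_order
        if (subj, rater) not in cells or not np.isfinite(cells[(subj, rater)])
    ]
    if missing:
        if drop_incomplete_raters:
            bad = {rater for _, rater in missing}
            rater_order = [r for r in rater_order if r not in bad]
            if len(rater_order) < 2:
                raise ValidationError(
                    "fewer than 2 complete raters remain after dropping "
                    f"incomplete ones ({sorted(bad)})"
                )
        else:
            raise ValidationError(
                f"incomplete ratings matrix; missing/undefined cells: {missing[:10]}"
            )

    values = np.array(
        [[cells[(subj, rater)] for rater in rater_order] for subj in subject_order]
    )
    return RatingsMatrix(values, tuple(subject_order), tuple(rater_order))
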