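"""Bundled reference datasets.

The package ships one small plain-text dataset: per-electrode burst
parameters for well B6 of a 597-second baseline recording of a
hippocampal neuron culture (22 DIV, CytoView 24-well plate), as
computed by two independent pipelines over the same AxIS electrode
burst list — an R analysis package (``source == "r_pipeline"``) and
the values extracted from the vendor's advanced-metrics export
(``source == "axion"``). The two agree to at least three decimal
places on every cell except the B6_23 spikes-per-burst pair, making
the table a compact cross-software validation target for
:func:`meaburst.burst_metrics.compare_with_reference`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_b6_baseline_reference"]

#: electrodes of the reference well whose window contains exactly one burst,
#: so their mean within-burst ISI is duration / (size - 1) verbatim
SINGLE_BURST_ELECTRODES = ("B6_13", "B6_21", "B6_31", "B6_32", "B6_41")


def load_b6_baseline_reference(source: str | None = None) -> pd.DataFrame:
    """Load the B6 baseline cross-software reference table.

    Parameters
    ----------
    source
        ``"r_pipeline"`` or ``"axion"`` to select one pipeline's values
        (dropping the ``source`` column), or ``None`` for the full table.
    """
    path = resources.files("meaburst.data").joinpath("b6_baseline_reference.csv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    if source is not None:
        if source not in set(df["source"]):
            raise ValueError(f"unknown source {source!r}")
        df = df[df["source"] == source].drop(columns="source").reset_index(drop=True)
    return df
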