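"""Embedded normative reference percentiles.

Ships the published normative percentile table for 282,140 valid
first tests of the 50-item online CRT as machine-readable package
data, so individual sessions can be located against population norms
without any download.  See ``data/reference_percentiles.csv`` for the
tabulated values and conventions.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .population import MetricPercentile, PercentileTable, individual_percentile
from .scoring import SessionScore

REFERENCE_N = 282_140


@lru_cache(maxsize=1)
def reference_table() -> PercentileTable:
    """Load the embedded normative PercentileTable."""
    source = resources.files("crtlab.data").joinpath("reference_percentiles.csv")
    with source.open("r") as handle:
        frame = pd.read_csv(handle, comment="#")
    columns = {}
    for metric, group in frame.groupby("metric", sort=False):
        group = group.sort_values("threshold")
        columns[metric] = (group["threshold"].to_numpy(dtype=float),
                           group["fraction"].to_numpy(dtype=float))
    return PercentileTable(columns=columns, n=REFERENCE_N)


def score_percentiles(score: SessionScore) -> dict[str, MetricPercentile]:
    """Locate one session against the embedded normative table."""
    return individual_percentile(score, reference_table())
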