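"""Sample-reliability filters applied before population analysis.

Two screens are implemented:

* :func:`duplicate_concordance_filter` -- the duplicate-treatment
  concordance test. The heteroplasmy pipeline is run once with PCR
  duplicates retained and once with them removed; a sample whose two
  counts disagree too much is unreliable. The cutoff is derived from the
  per-sample absolute count differences: differences more than two
  interquartile ranges below Q1 or above Q3 are discarded as outliers, the
  cutoff is floor(mean + 2*sd) of the remaining differences (sample sd,
  n-1), and samples whose difference exceeds the cutoff are flagged.
* :func:`coverage_filter` -- drop samples whose mean coverage falls below
  a threshold (default 1000X, where caller power degrades).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConcordanceRecord:
    sample_id: str
    count_with_duplicates: int
    count_without_duplicates: int

    @property
    def difference(self) -> int:
        return abs(self.count_with_duplicates - self.count_without_duplicates)


@dataclass
class ConcordanceResult:
    table: pd.DataFrame          # sample_id, counts, difference, outlier, reliable
    cutoff: int
    retained_differences: np.ndarray

    @property
    def reliable_samples(self) -> list[str]:
        return list(self.table.loc[self.table["reliable"], "sample_id"])

    @property
    def unreliable_samples(self) -> list[str]:
        return list(self.table.loc[~self.table["reliable"], "sample_id"])


def duplicate_concordance_filter(
    records: Iterable[ConcordanceRecord | tuple],
    iqr_multiplier: float = 2.0,
    sd_multiplier: float = 2.0,
    quartile_method: str = "linear",
) -> ConcordanceResult:
    """Derive the concordance cutoff and flag unreliable samples.

    `records` may be :class:`ConcordanceRecord` objects or
    ``(sample_id, count_with_dup, count_without_dup)`` tuples. Quartiles
    use linear interpolation by default (configurable, since the original
    convention is not stated). The outlier screen is two-sided on the IQR;
    the cutoff is applied only upward because differences are non-negative.
    """
    recs = [r if isinstance(r, ConcordanceRecord) else ConcordanceRecord(*r)
            for r in records]
    if len(recs) < 4:
        raise ValueError("need at least 4 records for meaningful quartiles")
    diffs = np.array([r.difference for r in recs], dtype=float)

    q1, q3 = np.percentile(diffs, [25, 75], method=quartile_method)
    iqr = q3 - q1
    lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
    outlier = (diffs < lo) | (diffs > hi)
    retained = diffs[~outlier]
    if retained.size == 0:
        raise ValueError("IQR screen removed every record")
    mean = float(retained.mean())
    sd = float(retained.std(ddof=1)) if retained.size > 1 else 0.0
    cutoff = math.floor(mean + sd_multiplier * sd)

    table = pd.DataFrame({
        "sample_id": [r.sample_id for r in recs],
        "count_with_duplicates": [r.count_with_duplicates for r in recs],
        "count_without_duplicates": [r.count_without_duplicates for r in recs],
        "difference": diffs.astype(int),
        "outlier": outlier,
        "reliable": diffs <= cutoff,
    })
    return ConcordanceResult(table, cutoff, retained)


def coverage_filter(
    coverages: Mapping[str, float] | pd.Series | Sequence[tuple[str, float]],
    threshold: float = 1000.0,
) -> tuple[list[str], list[str]]:
    """Retain samples with mean coverage at or above `threshold`.

    The rule drops samples *below* the threshold, so a sample at exactly
    the boundary is retained. Returns ``(retained, removed)`` sample lists.
    """
    if isinstance(coverages, pd.Series):
        items = list(coverages.items())
    elif isinstance(coverages, Mapping):
        items = list(coverages.items())
    else:
        items = list(coverages)
    for _, cov in items:
        if cov < 0:
            raise ValueError("coverage must be non-negative")
    retained = [s for s, cov in items if cov >= threshold]
    removed = [s for s, cov in items if cov < threshold]
    return retained, removed
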