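"""Caller benchmarking: Power, Accuracy, FPR and the composite score.

Given a planted truth set, a call set and the number of assayable sites:

* power     = proportion of true sites called;
* accuracy  = proportion of called true sites whose predicted frequency is
  within +-0.01 (absolute, inclusive) of the true frequency -- conditional
  on detection by default, so accuracy and power measure distinct failure
  modes; the unconditional reading (denominator = all true sites) is
  available via ``accuracy_denominator="true"``;
* FPR       = called non-true sites / assayable non-true sites by default;
  the 1-precision reading (false calls / all calls) is available via
  ``fpr_denominator="calls"``;
* score     = power * accuracy * (1 - FPR), a single number in [0, 1].

:func:`benchmark_grid` runs any set of callers over the standard coverage
grid (50X .. 25,000X) on shared pileups and ranks them by score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from mitodyn.calling import HeteroplasmyCall, call_sites, filter_calls
from mitodyn.genome import Mitogenome
from mitodyn.simulate import PileupSet, TruthSet, generate_truth_set, simulate_pileup

COVERAGE_GRID = (50, 100, 250, 500, 1000, 2500, 5000, 10000, 25000)

#: a caller maps one pileup to a list of calls
Caller = Callable[[PileupSet], list[HeteroplasmyCall]]


@dataclass(frozen=True)
class CallerMetrics:
    caller: str
    coverage: float
    power: float
    accuracy: float
    fpr: float
    n_true: int
    n_called: int
    n_true_called: int
    n_false: int

    def __post_init__(self) -> None:
        for v in (self.power, self.accuracy, self.fpr):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"metric {v} outside [0, 1]")

    @property
    def score(self) -> float:
        return composite_score(self.power, self.accuracy, self.fpr)


def composite_score(power: float, accuracy: float, fpr: float) -> float:
    """Composite caller score ``power * accuracy * (1 - FPR)``."""
    for v in (power, accuracy, fpr):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"input {v} outside [0, 1]")
    return power * accuracy * (1.0 - fpr)


def evaluate_calls(
    truth_set: TruthSet,
    calls: Sequence[HeteroplasmyCall],
    n_assayable_sites: int,
    freq_tol: float = 0.01,
    accuracy_denominator: str = "called",
    fpr_denominator: str = "assayable",
    caller: str = "caller",
    coverage: float = float("nan"),
) -> CallerMetrics:
    """Score one call set against a truth set."""
    if len(truth_set) == 0:
        raise ValueError("empty truth set")
    if accuracy_denominator not in ("called", "true"):
        raise ValueError(f"unknown accuracy denominator {accuracy_denominator!r}")
    if fpr_denominator not in ("assayable", "calls"):
        raise ValueError(f"unknown FPR denominator {fpr_denominator!r}")
    truth = truth_set.by_position()
    if not set(truth) <= set(range(1, n_assayable_sites + 1)) and \
            n_assayable_sites < len(truth):
        raise ValueError("truth set larger than the assayable site count")

    called_by_pos: dict[int, HeteroplasmyCall] = {}
    for c in calls:
        called_by_pos.setdefault(c.position, c)

    true_called = [p for p in truth if p in called_by_pos]
    # inclusive tolerance; the epsilon keeps |0.05 - 0.04| <= 0.01 true in floats
    accurate = [p for p in true_called
                if abs(called_by_pos[p].maf - truth[p].true_frequency)
                <= freq_tol + 1e-12]
    false_positions = [p for p in called_by_pos if p not in truth]

    power = len(true_called) / len(truth)
    if accuracy_denominator == "called":
        accuracy = len(accurate) / len(true_called) if true_called else 0.0
    else:
        accuracy = len(accurate) / len(truth)
    if fpr_denominator == "assayable":
        denom = n_assayable_sites - len(truth)
        fpr = len(false_positions) / denom if denom > 0 else 0.0
    else:
        fpr = len(false_positions) / len(called_by_pos) if called_by_pos else 0.0

    return CallerMetrics(caller=caller, coverage=coverage, power=power,
                         accuracy=accuracy, fpr=fpr,
                         n_true=len(truth), n_called=len(called_by_pos),
                         n_true_called=len(true_called),
                         n_false=len(false_positions))


def native_caller(
    alpha: float = 0.05,
    maf_min: float | None = None,
    cov_min: int | None = None,
    masked_regions=(),
) -> Caller:
    """Factory for the package's binomial-test caller as a `Caller`.

    With `maf_min`/`cov_min` left as None the raw significant sites are
    returned; supply thresholds to include the retention filters.
    """

    def _call(pileup: PileupSet) -> list[HeteroplasmyCall]:
        raw = call_sites(pileup, alpha=alpha)
        if maf_min is None and cov_min is None and not masked_regions:
            return raw
        kept, _ = filter_calls(raw, maf_min=maf_min or 0.0, cov_min=cov_min or 0,
                               masked_regions=masked_regions)
        return kept

    return _call


@dataclass
class BenchmarkResult:
    table: pd.DataFrame
    failures: list[tuple[str, float, str]]

    def ranking(self) -> pd.DataFrame:
        """Mean score per caller over the grid, best first."""
        return (self.table.groupby("caller", as_index=False)["score"].mean()
                .sort_values("score", ascending=False).reset_index(drop=True))


def benchmark_grid(
    callers: Mapping[str, Caller],
    genome: Mitogenome,
    truth_set: TruthSet | None = None,
    coverages: Sequence[float] = COVERAGE_GRID,
    error_rate: float = 0.001,
    seed: int | None = None,
    n_assayable_sites: int | None = None,
    exact_mode: bool = False,
    **evaluate_kwargs,
) -> BenchmarkResult:
    """Score every caller at every coverage on shared simulated pileups.

    One pileup is simulated per coverage and shared by all callers so the
    comparison is paired. A caller crash on one cell is recorded in
    `failures` and leaves that row out, rather than failing the grid.
    """
    if not callers:
        raise ValueError("at least one caller is required")
    rng = np.random.default_rng(seed)
    if truth_set is None:
        truth_set = generate_truth_set(genome, seed=int(rng.integers(2 ** 31)))
    if n_assayable_sites is None:
        n_assayable_sites = len(genome)

    rows, failures = [], []
    for cov in coverages:
        pileup = simulate_pileup(genome, truth_set, cov, error_rate=error_rate,
                                 seed=int(rng.integers(2 ** 31)),
                                 exact_mode=exact_mode)
        for name, caller in callers.items():
            try:
                calls = caller(pileup)
                m = evaluate_calls(truth_set, calls, n_assayable_sites,
                                   caller=name, coverage=cov, **evaluate_kwargs)
            except Exception as exc:  # recorded as a missing row
                failures.append((name, cov, repr(exc)))
                continue
            rows.append({"caller": name, "coverage": cov, "power": m.power,
                         "accuracy": m.accuracy, "fpr": m.fpr, "score": m.score,
                         "n_true": m.n_true, "n_called": m.n_called,
                         "n_false": m.n_false})
    table = pd.DataFrame(rows, columns=["caller", "coverage", "power", "accuracy",
                                        "fpr", "score", "n_true", "n_called",
                                        "n_false"])
    return BenchmarkResult(table, failures)
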