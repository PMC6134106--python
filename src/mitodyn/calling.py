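"""Heteroplasmy detection from pileups, with circular-genome handling.

The native caller tests, at every assayed site, the minor-allele count
against an exact binomial null Binomial(depth, error_rate * 2/3) -- the
per-specific-base substitution probability implied by a scalar error rate
spread uniformly over three alternative bases -- and keeps sites that stay
significant after Bonferroni correction across assayed sites. Detected
sites then pass through the study filters: minor allele frequency strictly
above 1%, depth strictly above 1000X, and position outside primer-binding
and repeat masks.

Circularity is handled the way short-read pipelines handle it: the first
and last `pad` bases of the genome are copied to the opposite ends
(:func:`extend_circular`), calls made on the extended reference are mapped
back with :func:`merge_circular_calls`, and duplicate detections of one
original site are collapsed keeping the deeper record.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from mitodyn.genome import BASES, Mitogenome
from mitodyn.simulate import PileupSet

FILTER_PASS = "PASS"
FILTER_MAF = "min_maf"
FILTER_COVERAGE = "min_coverage"
FILTER_MASK = "masked"


@dataclass(frozen=True)
class HeteroplasmyCall:
    """One heteroplasmic site in one sample.

    `alt` is the minor-allele base and `maf` its within-sample frequency
    (minor-allele convention, always <= 0.5).
    """

    position: int
    ref: str
    alt: str
    maf: float
    depth: int
    sample_id: str
    p_value: float | None = None
    filter: str = FILTER_PASS

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"MAF {self.maf} outside (0, 0.5]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class ExtendedReference:
    """Circularly padded reference with an invertible coordinate map."""

    sequence: str
    pad: int
    original_length: int

    def __len__(self) -> int:
        return len(self.sequence)

    def to_original(self, position: int) -> int:
        """Map a 1-based extended position back to the original genome."""
        pad, L = self.pad, self.original_length
        if not 1 <= position <= L + 2 * pad:
            raise KeyError(f"extended position {position} outside 1..{L + 2 * pad}")
        if position <= pad:
            return L - pad + position
        if position <= pad + L:
            return position - pad
        return position - pad - L

    def to_extended(self, position: int) -> list[int]:
        """All extended positions mapping to an original position."""
        pad, L = self.pad, self.original_length
        if not 1 <= position <= L:
            raise KeyError(f"position {position} outside 1..{L}")
        out = [position + pad]
        if position > L - pad:
            out.append(position - (L - pad))
        if position <= pad:
            out.append(pad + L + position)
        return sorted(out)


def extend_circular(genome: Mitogenome | str, pad: int = 500) -> ExtendedReference:
    """Copy the first and last `pad` bases to the opposite ends."""
    seq = genome.sequence if isinstance(genome, Mitogenome) else genome
    L = len(seq)
    if not 0 <= pad < L:
        raise ValueError(f"pad {pad} must satisfy 0 <= pad < genome length {L}")
    if pad == 0:
        return ExtendedReference(seq, 0, L)
    return ExtendedReference(seq[-pad:] + seq + seq[:pad], pad, L)


def call_sites(
    pileup: PileupSet,
    alpha: float = 0.05,
    multiple_test: str | None = "bonferroni",
) -> list[HeteroplasmyCall]:
    """Binomial-tail test of the minor allele at every assayed site.

    A site is assayed when its depth is positive; zero-depth sites are
    skipped, never called. The upper-tail p-value of the minor-allele count
    under Binomial(depth, error_rate*2/3) is Bonferroni-corrected across
    assayed sites (or used raw with ``multiple_test=None``).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if multiple_test not in (None, "bonferroni"):
        raise ValueError(f"unknown multiple-test rule {multiple_test!r}")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    assayed = depth > 0
    n_tests = int(assayed.sum())
    if n_tests == 0:
        return []

    order = np.argsort(counts, axis=1, kind="stable")
    minor_idx = order[:, -2]
    minor = counts[np.arange(len(counts)), minor_idx]
    p_base = pileup.error_rate * 2.0 / 3.0
    pvals = stats.binom.sf(minor - 1, depth, p_base)
    factor = n_tests if multiple_test == "bonferroni" else 1
    significant = assayed & (minor >= 1) & (np.minimum(pvals * factor, 1.0) <= alpha)

    calls = []
    for i in np.flatnonzero(significant):
        d = int(depth[i])
        calls.append(HeteroplasmyCall(
            position=int(i) + 1,
            ref=pileup.reference[i],
            alt=BASES[int(minor_idx[i])],
            maf=float(minor[i]) / d,
            depth=d,
            sample_id=pileup.sample_id,
            p_value=float(min(pvals[i] * factor, 1.0)),
        ))
    return calls


def _in_regions(position: int, regions) -> bool:
    for region in regions:
        start, end = (region.start, region.end) if hasattr(region, "start") \
            else (region[0], region[1])
        if start <= position <= end:
            return True
    return False


def filter_calls(
    calls: list[HeteroplasmyCall],
    maf_min: float = 0.01,
    cov_min: int = 1000,
    masked_regions=(),
) -> tuple[list[HeteroplasmyCall], list[HeteroplasmyCall]]:
    """Apply the study retention filters: MAF > maf_min, depth > cov_min,
    position outside masked regions (strict inequalities).

    Returns ``(kept, dropped)``; each dropped call is tagged with the first
    failing filter in the order MAF, coverage, mask. The kept set is
    independent of filter order since filters are conjunctive.
    """
    kept, dropped = [], []
    for call in calls:
        if not call.maf > maf_min:
            dropped.append(replace(call, filter=FILTER_MAF))
        elif not call.depth > cov_min:
            dropped.append(replace(call, filter=FILTER_COVERAGE))
        elif _in_regions(call.position, masked_regions):
            dropped.append(replace(call, filter=FILTER_MASK))
        else:
            kept.append(replace(call, filter=FILTER_PASS))
    return kept, dropped


def merge_circular_calls(
    calls: list[HeteroplasmyCall],
    extended: ExtendedReference,
) -> list[HeteroplasmyCall]:
    """Remap calls from extended to original coordinates, collapsing
    duplicate detections of one site (pad copy + body) to the deeper record."""
    best: dict[tuple[str, int, str], HeteroplasmyCall] = {}
    for call in calls:
        orig = extended.to_original(call.position)  # KeyError if unmappable
        key = (call.sample_id, orig, call.alt)
        candidate = replace(call, position=orig)
        if key not in best or candidate.depth > best[key].depth:
            best[key] = candidate
    return sorted(best.values(), key=lambda c: (c.sample_id, c.position))


def call_heteroplasmies(
    pileup: PileupSet,
    genome: Mitogenome | None = None,
    alpha: float = 0.05,
    maf_min: float = 0.01,
    cov_min: int = 1000,
    masked_regions=None,
) -> list[HeteroplasmyCall]:
    """Full single-sample pipeline: test sites, then apply retention filters.

    Masked regions default to the genome's primer/repeat features when a
    genome is supplied.
    """
    if masked_regions is None:
        masked_regions = genome.masked_regions() if genome is not None else ()
    raw = call_sites(pileup, alpha=alpha)
    kept, _ = filter_calls(raw, maf_min=maf_min, cov_min=cov_min,
                           masked_regions=masked_regions)
    return kept
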