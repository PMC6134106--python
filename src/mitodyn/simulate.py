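"""Synthetic data generation: truth variants, pileups and whole populations.

Three layers of simulation feed the downstream pipeline:

1. :func:`generate_truth_set` plants low-frequency variants on a mitogenome
   using the 5-frequency x 100-site design (1, 4, 7, 10 and 15% minor-allele
   frequency), with positions drawn in two or more frequency sets excluded
   from all of them.
2. :func:`simulate_pileup` produces per-site base counts for one sample:
   Poisson depth around a nominal coverage (or exact depth for tests),
   binomial minor-allele counts at truth sites, and i.i.d. substitution
   errors spread uniformly over the three non-reference bases.
3. :func:`simulate_population` produces a population-scale sample table and
   heteroplasmy call table with the statistical structure the association
   and longitudinal analyses assume: negative-binomially distributed
   per-sample heteroplasmy counts whose log-mean is linear in age, a
   four-class mutation spectrum, a low-frequency-skewed MAF distribution,
   sequencing batches, multi-year recaptures with per-site persistence, and
   sporadic oxidative "spike" events concentrated in few individuals.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mitodyn.genome import BASES, BASE_INDEX, Mitogenome, generate_mitogenome

DEFAULT_FREQS = (0.01, 0.04, 0.07, 0.10, 0.15)

# class order used throughout: index 1 is the oxidative (G:C<->T:A) class
CLASS_NAMES = (
    "GC_AT_transition",
    "GC_TA_transversion",
    "AT_TA_transversion",
    "GC_CG_transversion",
)
# alt base implied by (class index, ref base); the 12 ordered substitutions
# partition into the four strand-symmetric classes
_ALT_FOR_CLASS = {
    (0, "G"): "A", (0, "A"): "G", (0, "C"): "T", (0, "T"): "C",
    (1, "G"): "T", (1, "T"): "G", (1, "C"): "A", (1, "A"): "C",
    (2, "A"): "T", (2, "T"): "A",
    (3, "G"): "C", (3, "C"): "G",
}

COLONIES = ("Beganne", "Noyal-Muzillac", "Ferel", "La Roche-Bernard", "Limerzel")
COLONY_WEIGHTS = (112, 20, 78, 32, 10)


@dataclass(frozen=True)
class TruthVariant:
    position: int  # 1-based
    ref: str
    alt: str
    true_frequency: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("alt base equals ref base")
        if not 0.0 < self.true_frequency < 1.0:
            raise ValueError(f"frequency {self.true_frequency} outside (0, 1)")


@dataclass
class TruthSet:
    """Planted variants surviving the multi-set collision exclusion."""

    variants: list[TruthVariant]
    n_drawn: int
    n_excluded_sites: int

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variants]
        if len(positions) != len(set(positions)):
            raise ValueError("duplicate positions within a TruthSet")

    def __len__(self) -> int:
        return len(self.variants)

    def positions(self) -> set[int]:
        return {v.position for v in self.variants}

    def by_position(self) -> dict[int, TruthVariant]:
        return {v.position: v for v in self.variants}


def generate_truth_set(
    genome: Mitogenome,
    freqs: tuple[float, ...] = DEFAULT_FREQS,
    n_per_freq: int = 100,
    seed: int | None = None,
) -> TruthSet:
    """Draw planted variants in independent per-frequency sets.

    For each frequency, `n_per_freq` positions are drawn uniformly without
    replacement. A position drawn in two or more frequency sets is excluded
    from every set it occurred in, so the surviving count is
    ``n_drawn - sum(multiplicities of collided sites)``.
    """
    L = len(genome)
    for f in freqs:
        if not 0.0 < f < 1.0:
            raise ValueError(f"frequency {f} outside (0, 1)")
    if n_per_freq < 1:
        raise ValueError("n_per_freq must be positive")
    if n_per_freq > L:
        raise ValueError(f"cannot draw {n_per_freq} distinct positions from {L} sites")
    rng = np.random.default_rng(seed)

    sets = [rng.choice(L, size=n_per_freq, replace=False) + 1 for _ in freqs]
    counts = Counter(int(p) for s in sets for p in s)
    excluded = {p for p, c in counts.items() if c >= 2}

    seq = genome.sequence
    variants: list[TruthVariant] = []
    for f, positions in zip(freqs, sets):
        keep = np.sort(positions[~np.isin(positions, list(excluded))]) if excluded \
            else np.sort(positions)
        offsets = rng.integers(1, 4, size=len(keep))
        for p, off in zip(keep, offsets):
            ref = seq[p - 1]
            alt = BASES[(BASE_INDEX[ref] + int(off)) % 4]
            variants.append(TruthVariant(int(p), ref, alt, f))
    variants.sort(key=lambda v: v.position)
    return TruthSet(variants, n_drawn=n_per_freq * len(freqs),
                    n_excluded_sites=len(excluded))


@dataclass
class PileupSet:
    """Per-site base observation counts for one sample.

    `counts` has shape (L, 4) in A, C, G, T order; depth at a site is the
    row sum (the conservation invariant the tests assert).
    """

    sample_id: str
    reference: str
    counts: np.ndarray
    coverage: float
    error_rate: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.reference), 4):
            raise ValueError("counts must have shape (len(reference), 4)")
        if (self.counts < 0).any():
            raise ValueError("negative base counts")

    def __len__(self) -> int:
        return len(self.reference)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "ref", list(self.reference))
        df.insert(0, "pos", np.arange(1, len(self.reference) + 1))
        df["depth"] = self.depth
        return df


def simulate_pileup(
    genome: Mitogenome,
    truth_set: TruthSet | None,
    coverage: float,
    error_rate: float = 0.0,
    seed: int | None = None,
    exact_mode: bool = False,
    sample_id: str = "sim",
) -> PileupSet:
    """Simulate per-site base counts for one sample.

    Depth is Poisson around `coverage` (or exactly `coverage` in
    `exact_mode`); the minor-allele count at each truth site is binomial at
    the planted frequency (rounded deterministic in exact mode); each
    observed base is then mis-read with probability `error_rate`, uniformly
    into the three other bases.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    L = len(genome)
    ref_idx = np.fromiter((BASE_INDEX[b] for b in genome.sequence), dtype=np.int64, count=L)

    if exact_mode:
        depth = np.full(L, int(round(coverage)), dtype=np.int64)
    else:
        depth = rng.poisson(coverage, size=L).astype(np.int64)

    counts = np.zeros((L, 4), dtype=np.int64)
    counts[np.arange(L), ref_idx] = depth

    for v in (truth_set.variants if truth_set is not None else ()):
        i = v.position - 1
        d = int(depth[i])
        alt_n = int(round(v.true_frequency * d)) if exact_mode \
            else int(rng.binomial(d, v.true_frequency))
        counts[i, BASE_INDEX[v.ref]] -= alt_n
        counts[i, BASE_INDEX[v.alt]] += alt_n

    if error_rate > 0.0:
        for b in range(4):
            n = counts[:, b].copy()
            errs = rng.binomial(n, error_rate)
            if errs.sum() == 0:
                continue
            spread = rng.multinomial(errs, [1 / 3] * 3)
            counts[:, b] -= errs
            others = [j for j in range(4) if j != b]
            counts[:, others] += spread

    return PileupSet(sample_id, genome.sequence, counts, coverage, error_rate)


# ---------------------------------------------------------------------------
# Population-scale simulation


@dataclass(frozen=True)
class PopulationParams:
    """Study conditions for the population generator.

    Defaults emulate the published study population: ~167 unique
    individuals in age cohorts 0..6+ (oldest cohort coded as age 6),
    negative-binomial heteroplasmy counts with log-mean linear in age,
    marginal mutation-class mixture (60.6% transitions, 31.9% oxidative
    G:C<->T:A, 7.5% A:T<->T:A, 0% G:C<->C:G), 77.6% of MAFs below 5%,
    four sequencing batches, a 21-individual multi-year recapture design
    (3x4, 8x3, 10x2 samples) and sporadic oxidative spike events.
    """

    cohort_sizes: tuple[tuple[int, int], ...] = (
        (0, 88), (1, 26), (2, 22), (3, 12), (4, 3), (5, 3), (6, 13))
    oldest_cohort: int = 6
    nb_intercept: float = -0.1288     # log heteroplasmy count at age 0
    nb_slope: float = 0.1289          # log-linear age effect
    nb_theta: float = 2.0             # NB2 dispersion; inf = Poisson
    class_probs: tuple[float, float, float, float] = (0.606, 0.319, 0.075, 0.0)
    maf_below_5pct: float = 0.776     # target P(MAF < 0.05)
    maf_min: float = 0.01
    maf_max: float = 0.5
    maf_jitter_sd: float = 0.2        # log-scale jitter on persisted MAFs
    n_batches: int = 4
    recapture_design: tuple[tuple[int, int], ...] = ((4, 3), (3, 8), (2, 10))
    persistence: float = 0.15         # per-site year-to-year carry probability
    spike_prob: float = 0.05          # per-sample oxidative spike probability
    spike_min: int = 4
    spike_poisson_mean: float = 1.0
    genome_length: int = 16211
    n_hotspots: int = 40              # recurrently heteroplasmic sites
    hotspot_fraction: float = 0.25    # fraction of fresh calls at hotspots
    first_year: int = 2013
    n_years: int = 4
    coverage_range: tuple[float, float] = (1355.0, 7800.0)

    def __post_init__(self) -> None:
        for p in (*self.class_probs, self.maf_below_5pct, self.persistence,
                  self.spike_prob, self.hotspot_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if not 0.0 < self.maf_min < self.maf_max <= 0.5:
            raise ValueError("require 0 < maf_min < maf_max <= 0.5")


@dataclass
class PopulationTable:
    """Sample table plus heteroplasmy call table for one synthetic population."""

    samples: pd.DataFrame
    calls: pd.DataFrame
    genome: Mitogenome | None = None

    def __post_init__(self) -> None:
        known = set(self.samples["sample_id"])
        orphans = set(self.calls["sample_id"]) - known
        if orphans:
            raise ValueError(f"calls reference unknown samples: {sorted(orphans)[:5]}")

    def heteroplasmy_counts(self) -> pd.Series:
        """Per-sample heteroplasmy count, zero for call-free samples."""
        counts = self.calls.groupby("sample_id").size()
        return counts.reindex(self.samples["sample_id"], fill_value=0)


def _nb_draw(rng: np.random.Generator, mu: float, theta: float) -> int:
    if math.isinf(theta):
        return int(rng.poisson(mu))
    return int(rng.negative_binomial(theta, theta / (theta + mu)))


def _truncated_exp_maf(rng: np.random.Generator, lam: float, lo: float, hi: float,
                       size: int) -> np.ndarray:
    """Exponential(lam) truncated to (lo, hi], by inverse CDF."""
    u = rng.random(size)
    tail = 1.0 - np.exp(-lam * (hi - lo))
    return lo - np.log1p(-u * tail) / lam


def simulate_population(
    params: PopulationParams | None = None,
    seed: int | None = None,
    genome: Mitogenome | None = None,
) -> PopulationTable:
    """Generate a population sample table and heteroplasmy call table.

    The generator proceeds in two passes. A structural pass lays out
    individuals, recapture schedules and per-sample call skeletons: fresh
    calls (count targets drawn NB(mu(age), theta)), spike calls (forced
    oxidative class) and carried calls (each previous-year site persists
    with the configured probability). A second pass then assigns mutation
    classes, positions, alleles and MAFs. Because spike calls are forced
    into the oxidative class, the class vector applied to fresh calls is
    corrected using the realized spike load so that the *marginal* class
    mixture matches ``params.class_probs`` in expectation.
    """
    p = params or PopulationParams()
    rng = np.random.default_rng(seed)
    genome = genome or generate_mitogenome(p.genome_length,
                                           seed=int(rng.integers(2 ** 31)))
    L = len(genome)
    seq = genome.sequence
    years = list(range(p.first_year, p.first_year + p.n_years))
    last_year = years[-1]

    # --- individuals and their sampling schedules -------------------------
    individuals: list[dict] = []
    for age, n in p.cohort_sizes:
        for _ in range(n):
            individuals.append({"age": age})
    for i, ind in enumerate(individuals):
        ind["id"] = f"MM{i + 1:04d}"
        ind["years"] = None

    assigned: set[int] = set()
    for times, n_ind in sorted(p.recapture_design, reverse=True):
        if times > p.n_years:
            raise ValueError("recapture design longer than the year range")
        eligible = [i for i, ind in enumerate(individuals)
                    if i not in assigned and ind["age"] >= times - 1]
        if len(eligible) < n_ind:
            raise ValueError("not enough old-enough individuals for recapture design")
        chosen = rng.choice(eligible, size=n_ind, replace=False)
        for i in chosen:
            assigned.add(int(i))
            individuals[int(i)]["years"] = years[-times:]
    for ind in individuals:
        if ind["years"] is None:
            ind["years"] = [int(rng.choice(years))]

    colony_p = np.array(COLONY_WEIGHTS, dtype=float)
    colony_p /= colony_p.sum()

    sample_rows: list[dict] = []
    # structural call skeleton: each record is a dict with keys
    # sample_id, individual_id, year, origin in {base, spike, carried}, parent
    records: list[dict] = []
    for ind in individuals:
        sched = ind["years"]
        colony = str(rng.choice(COLONIES, p=colony_p))
        prev_call_idx: list[int] = []
        for year in sched:
            age_at = ind["age"] - (sched[-1] - year)
            sid = f"{ind['id']}_{year}"
            sample_rows.append({
                "sample_id": sid,
                "individual_id": ind["id"],
                "age": age_at,
                "cohort": f"{p.oldest_cohort}+" if age_at >= p.oldest_cohort
                          else str(age_at),
                "batch": f"B{int(rng.integers(1, p.n_batches + 1))}",
                "year": year,
                "colony": colony,
                "times_sampled": len(sched),
                "mean_coverage": float(rng.uniform(*p.coverage_range)),
            })
            mu = math.exp(p.nb_intercept + p.nb_slope * age_at)
            target = _nb_draw(rng, mu, p.nb_theta)
            this_year: list[int] = []
            carried = [j for j in prev_call_idx if rng.random() < p.persistence]
            for j in carried:
                records.append({"sample_id": sid, "individual_id": ind["id"],
                                "year": year, "origin": "carried", "parent": j})
                this_year.append(len(records) - 1)
            for _ in range(max(0, target - len(carried))):
                records.append({"sample_id": sid, "individual_id": ind["id"],
                                "year": year, "origin": "base", "parent": None})
                this_year.append(len(records) - 1)
            if rng.random() < p.spike_prob:
                n_spike = p.spike_min + int(rng.poisson(p.spike_poisson_mean))
                for _ in range(n_spike):
                    records.append({"sample_id": sid, "individual_id": ind["id"],
                                    "year": year, "origin": "spike", "parent": None})
                    this_year.append(len(records) - 1)
            prev_call_idx = this_year

    samples = pd.DataFrame(sample_rows)

    if not records:
        calls = pd.DataFrame(columns=["sample_id", "individual_id", "year", "position",
                                      "ref", "alt", "maf", "depth", "mutation_class",
                                      "origin"])
        return PopulationTable(samples, calls, genome)

    # --- marginal class correction ---------------------------------------
    # weight of each root = itself plus all records carried from it
    root_of = [0] * len(records)
    for i, r in enumerate(records):
        root_of[i] = i if r["parent"] is None else root_of[r["parent"]]
    weight = Counter(root_of)
    w_base = sum(w for i, w in weight.items() if records[i]["origin"] == "base")
    w_spike = sum(w for i, w in weight.items() if records[i]["origin"] == "spike")
    w_total = w_base + w_spike

    targets = np.array(p.class_probs, dtype=float)
    if w_base == 0:
        base_probs = targets
    else:
        ox = (targets[1] * w_total - w_spike) / w_base
        if ox < 0.0:
            # spike load alone exceeds the oxidative target; fresh calls get none
            ox = 0.0
        base_probs = targets * (w_total / w_base)
        base_probs[1] = ox
        base_probs = np.clip(base_probs, 0.0, None)
        base_probs /= base_probs.sum()

    # --- assignment pass ---------------------------------------------------
    hotspots = rng.choice(L, size=min(p.n_hotspots, L), replace=False) + 1
    lam = -math.log(1.0 - p.maf_below_5pct) / (0.05 - p.maf_min)
    mean_cov = dict(zip(samples["sample_id"], samples["mean_coverage"]))

    used_positions: dict[str, set[int]] = {}
    out_rows: list[dict] = []
    info: dict[int, dict] = {}  # per-record assigned attributes, for children
    for i, r in enumerate(records):
        sid = r["sample_id"]
        used = used_positions.setdefault(sid, set())
        if r["origin"] == "carried":
            parent = info.get(r["parent"])
            if parent is None or parent["position"] in used:
                continue  # parent dropped, or collides within this sample
            maf = parent["maf"] * math.exp(rng.normal(0.0, p.maf_jitter_sd))
            maf = min(max(maf, p.maf_min * 1.02), p.maf_max)
            rec = {**parent, "maf": maf}
        else:
            cls = 1 if r["origin"] == "spike" else int(rng.choice(4, p=base_probs))
            position = None
            for _ in range(200):
                if rng.random() < p.hotspot_fraction:
                    cand = int(rng.choice(hotspots))
                else:
                    cand = int(rng.integers(1, L + 1))
                if cand in used:
                    continue
                if (cls, seq[cand - 1]) in _ALT_FOR_CLASS:
                    position = cand
                    break
            if position is None:
                continue  # pathological genome/params; skip record
            ref = seq[position - 1]
            maf = float(_truncated_exp_maf(rng, lam, p.maf_min, p.maf_max, 1)[0])
            rec = {"position": position, "ref": ref,
                   "alt": _ALT_FOR_CLASS[(cls, ref)],
                   "mutation_class": CLASS_NAMES[cls], "maf": maf}
        info[i] = rec
        used.add(rec["position"])
        out_rows.append({
            "sample_id": sid, "individual_id": r["individual_id"], "year": r["year"],
            "position": rec["position"], "ref": rec["ref"], "alt": rec["alt"],
            "maf": rec["maf"], "depth": int(rng.poisson(mean_cov[sid])),
            "mutation_class": rec["mutation_class"], "origin": r["origin"],
        })

    calls = pd.DataFrame(out_rows)
    return PopulationTable(samples, calls, genome)


def write_population(pop: PopulationTable, samples_path: str, calls_path: str) -> None:
    pop.samples.to_csv(samples_path, sep="\t", index=False)
    pop.calls.to_csv(calls_path, sep="\t", index=False)


def read_population(samples_path: str, calls_path: str) -> PopulationTable:
    samples = pd.read_csv(samples_path, sep="\t")
    calls = pd.read_csv(calls_path, sep="\t")
    return PopulationTable(samples, calls, None)
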