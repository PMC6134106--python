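"""Age-association and longitudinal inference for heteroplasmy counts.

The core model is a negative-binomial (NB2) generalized linear model with
log link,

    log mu_i = b0 + b1 * age_i,      Var(y_i) = mu_i + mu_i^2 / theta,

fit by maximum likelihood (statsmodels), chosen because per-sample
heteroplasmy counts are overdispersed relative to Poisson. Around the fit:

* :func:`cooks_influence` -- generalized Cook's distances from the GLM
  leverage and Pearson residuals, to diagnose unduly influential samples;
* :func:`bootstrap_fit` -- case-resampling (default) or parametric
  bootstrap of the coefficient bias and standard error;
* :func:`recapture_permutation` -- re-fits the model over datasets in
  which the sample kept for each recaptured individual is chosen at
  random, quantifying the sensitivity of the age effect to that choice;
* :func:`batch_effect_test` -- Kruskal-Wallis comparison of counts across
  sequencing batches, plus the maximum pairwise mean difference;
* :func:`longitudinal_summary` -- year-to-year count changes and
  shared-site proportions for individuals sampled in multiple years.

The oldest age cohort ("6+") is coded as its lower bound, age 6.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_K_PARAMS = 3  # intercept, slope, dispersion


def code_age(value) -> float:
    """Map an age or cohort label to a numeric age ('6+' -> 6)."""
    if isinstance(value, str):
        value = value.strip()
        if value.endswith("+"):
            value = value[:-1]
        if value == "" or value.lower() in ("na", "nan", "none"):
            return float("nan")
    return float(value)


@dataclass
class NBModelFit:
    """A fitted NB2 age regression on the log link."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_slope: float
    theta: float
    alpha: float                  # 1/theta, statsmodels parameterization
    llf: float
    aic: float
    aicc: float
    fitted: np.ndarray
    converged: bool
    n: int
    counts: np.ndarray = field(repr=False, default=None)
    ages: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> tuple[float, float]:
        return (self.intercept, self.slope)


def _design(ages: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"intercept": np.ones(len(ages)), "age": ages})


def fit_nb_glm(
    counts: Sequence[int],
    ages: Sequence,
    start_params: Sequence[float] | None = None,
) -> NBModelFit:
    """Maximum-likelihood NB2 regression of counts on age.

    Non-convergence is reported through the `converged` flag rather than an
    exception. AICc = AIC + 2k(k+1)/(n-k-1) with k = 3 (two coefficients
    plus the dispersion).
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.array([code_age(a) for a in ages], dtype=float)
    if counts.shape != ages.shape:
        raise ValueError("counts and ages must have equal length")
    if len(counts) < 3:
        raise ValueError("need at least 3 observations")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if np.isnan(ages).any():
        raise ValueError("ages contain missing values; drop unusable ages first")

    X = _design(ages)
    model = sm.NegativeBinomial(counts, X)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=500, start_params=start_params)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            try:
                res = model.fit(method="nm", disp=0, maxiter=2000)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                nan = float("nan")
                return NBModelFit(nan, nan, nan, nan, nan, nan, nan, nan, nan, nan,
                                  np.full(len(counts), nan), False, len(counts),
                                  counts, ages)

    alpha = float(res.params["alpha"])
    theta = 1.0 / alpha if alpha > 1e-8 else math.inf
    n, k = len(counts), _K_PARAMS
    aicc = res.aic + (2 * k * (k + 1) / (n - k - 1)) if n - k - 1 > 0 else math.inf
    mu = np.exp(res.params["intercept"] + res.params["age"] * ages)
    return NBModelFit(
        intercept=float(res.params["intercept"]),
        slope=float(res.params["age"]),
        se_intercept=float(res.bse["intercept"]),
        se_slope=float(res.bse["age"]),
        p_slope=float(res.pvalues["age"]),
        theta=theta,
        alpha=alpha,
        llf=float(res.llf),
        aic=float(res.aic),
        aicc=float(aicc),
        fitted=mu,
        converged=converged,
        n=n,
        counts=counts,
        ages=ages,
    )


@dataclass
class InfluenceResult:
    cooks: np.ndarray
    threshold: float
    flagged: np.ndarray           # indices above the threshold

    def top(self, m: int = 5) -> np.ndarray:
        return np.argsort(self.cooks)[::-1][:m]


def cooks_influence(fit: NBModelFit, threshold: float | None = None) -> InfluenceResult:
    """Generalized Cook's distances for each observation of a fitted model.

    Computed from the GLM with the MLE dispersion held fixed. The default
    flag threshold is 8/(n - 2k) with k = 2 coefficients; flagging is a
    diagnostic -- removal is an explicit caller action.
    """
    if not fit.converged:
        raise ValueError("influence requires a converged fit")
    X = _design(fit.ages)
    alpha = fit.alpha if fit.alpha > 1e-8 else 1e-8
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(fit.counts, X,
                     family=sm.families.NegativeBinomial(alpha=alpha)).fit()
        cooks = glm.get_influence(observed=False).cooks_distance[0]
    if threshold is None:
        denom = fit.n - 2 * 2
        if denom <= 0:
            raise ValueError("too few observations for the default threshold")
        threshold = 8.0 / denom
    flagged = np.flatnonzero(cooks > threshold)
    return InfluenceResult(np.asarray(cooks), float(threshold), flagged)


@dataclass
class BootstrapResult:
    se: dict[str, float]
    bias: dict[str, float]
    estimates: pd.DataFrame       # columns intercept, slope
    n_failed: int


def bootstrap_fit(
    counts: Sequence[int],
    ages: Sequence,
    B: int = 1000,
    seed: int | None = None,
    parametric: bool = False,
    fit: NBModelFit | None = None,
) -> BootstrapResult:
    """Bootstrap bias and standard error of the NB regression coefficients.

    Case resampling with replacement by default; ``parametric=True``
    simulates responses from the fitted NB law instead. Replicates that
    fail to converge are dropped and counted.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, dtype=float)
    ages = np.array([code_age(a) for a in ages], dtype=float)
    fit = fit or fit_nb_glm(counts, ages)
    start = (fit.intercept, fit.slope, fit.alpha) if fit.converged else None

    rows, n_failed = [], 0
    n = len(counts)
    for _ in range(B):
        if parametric:
            mu = fit.fitted
            if math.isinf(fit.theta):
                y = rng.poisson(mu)
            else:
                y = rng.negative_binomial(fit.theta, fit.theta / (fit.theta + mu))
            a = ages
        else:
            idx = rng.integers(0, n, size=n)
            y, a = counts[idx], ages[idx]
        boot = fit_nb_glm(y, a, start_params=start)
        if not boot.converged or not np.isfinite(boot.slope):
            n_failed += 1
            continue
        rows.append({"intercept": boot.intercept, "slope": boot.slope})

    est = pd.DataFrame(rows)
    if est.empty:
        raise RuntimeError("every bootstrap replicate failed to converge")
    se = {c: float(est[c].std(ddof=1)) if len(est) > 1 else 0.0 for c in est}
    bias = {"intercept": float(est["intercept"].mean() - fit.intercept),
            "slope": float(est["slope"].mean() - fit.slope)}
    return BootstrapResult(se, bias, est, n_failed)


@dataclass
class PermutationResult:
    fraction_significant: float
    slopes: np.ndarray
    mean_slope: float
    min_slope: float
    max_slope: float
    n_replicates: int
    n_failed: int


def recapture_permutation(
    samples: pd.DataFrame,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PermutationResult:
    """Permute the recapture choice and re-fit the age model B times.

    `samples` needs ``individual_id``, ``age`` (numeric or cohort label;
    missing = unusable) and ``count`` columns. Each replicate keeps one
    uniformly chosen usable-age sample per individual, fits the NB GLM,
    and records the age slope and whether its Wald p-value is below
    `alpha`. Influence points are not removed inside replicates.
    """
    required = {"individual_id", "age", "count"}
    if not required <= set(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    df = samples.copy()
    df["age_num"] = [code_age(a) for a in df["age"]]
    df = df[np.isfinite(df["age_num"])]
    if df.empty:
        raise ValueError("no usable-age samples")
    groups = [g.index.to_numpy() for _, g in df.groupby("individual_id")]
    rng = np.random.default_rng(seed)
    full = fit_nb_glm(
        df.loc[[g[0] for g in groups], "count"].to_numpy(),
        df.loc[[g[0] for g in groups], "age_num"].to_numpy())
    start = (full.intercept, full.slope, full.alpha) if full.converged else None

    slopes, sig, n_failed = [], 0, 0
    for _ in range(B):
        chosen = [int(rng.choice(g)) for g in groups]
        sub = df.loc[chosen]
        fit = fit_nb_glm(sub["count"].to_numpy(), sub["age_num"].to_numpy(),
                         start_params=start)
        if not fit.converged or not np.isfinite(fit.slope):
            n_failed += 1
            continue
        slopes.append(fit.slope)
        if fit.p_slope < alpha:
            sig += 1
    if not slopes:
        raise RuntimeError("every permutation replicate failed to converge")
    slopes = np.array(slopes)
    return PermutationResult(
        fraction_significant=sig / len(slopes),
        slopes=slopes,
        mean_slope=float(slopes.mean()),
        min_slope=float(slopes.min()),
        max_slope=float(slopes.max()),
        n_replicates=len(slopes),
        n_failed=n_failed,
    )


@dataclass(frozen=True)
class BatchTestResult:
    statistic: float
    p_value: float
    max_mean_difference: float


def _exact_kruskal_p(groups: list[np.ndarray], observed: float) -> float:
    """Exact permutation p-value of the (tie-corrected) KW statistic."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx = list(range(n))
    count = total = 0
    for perm in itertools.permutations(idx):
        total += 1
        start, parts = 0, []
        for s in sizes:
            parts.append(pooled[list(perm[start:start + s])])
            start += s
        try:
            h = stats.kruskal(*parts).statistic
        except ValueError:        # all values identical in this permutation
            h = 0.0
        if h >= observed - 1e-12:
            count += 1
    return count / total


def batch_effect_test(
    counts: Sequence[int],
    batches: Sequence,
    method: str = "asymptotic",
) -> BatchTestResult:
    """Kruskal-Wallis test of heteroplasmy counts across sequencing batches,
    plus the maximum pairwise difference of batch means.

    ``method="exact"`` enumerates permutations (small n only, <= 10
    observations); the default is the tie-corrected asymptotic test.
    """
    counts = np.asarray(counts, dtype=float)
    batches = np.asarray(batches)
    labels = pd.unique(batches)
    if len(labels) < 2:
        raise ValueError("need at least 2 batches")
    groups = [counts[batches == lab] for lab in labels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty batch")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = stats.kruskal(*groups)
        if not np.isfinite(stat):  # every observation identical: no evidence
            stat, p = 0.0, 1.0
    except ValueError:
        stat, p = 0.0, 1.0
    if method == "exact":
        if len(counts) > 10:
            raise ValueError("exact enumeration limited to n <= 10")
        p = _exact_kruskal_p(groups, stat)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    means = [g.mean() for g in groups]
    max_diff = max(abs(a - b) for a, b in itertools.combinations(means, 2))
    return BatchTestResult(float(stat), float(p), float(max_diff))


# ---------------------------------------------------------------------------
# Longitudinal analysis


@dataclass(frozen=True)
class LongitudinalHistory:
    """Ordered multi-year call-set observations for one individual.

    Each observation is ``(year, frozenset of site keys)``; a site key is
    ``(position, minor allele)`` so sites are matched across years by both.
    """

    individual_id: str
    observations: tuple[tuple[int, frozenset], ...]

    def __post_init__(self) -> None:
        years = [y for y, _ in self.observations]
        if len(years) < 2:
            raise ValueError("a history needs at least 2 time-points")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")

    @property
    def years(self) -> list[int]:
        return [y for y, _ in self.observations]

    @property
    def counts(self) -> list[int]:
        return [len(s) for _, s in self.observations]


@dataclass
class LongitudinalSummary:
    intervals: pd.DataFrame       # individual, year_from, year_to, consecutive, change, direction
    mean_change: float            # consecutive-year intervals only
    sd_change: float
    n_increase: int
    n_decrease: int
    n_no_change: int
    prop_shared_two: float        # (individual, site) pairs seen at >= 2 time-points
    prop_shared_all: float        # pairs seen at every time-point of the individual


def longitudinal_summary(histories: Iterable[LongitudinalHistory]) -> LongitudinalSummary:
    """Interval count changes and shared-site proportions across histories.

    Only consecutive-year intervals contribute to the mean/sd and the
    increase/decrease/no-change tallies; non-consecutive gaps are kept in
    the interval table but flagged and excluded from those statistics.
    """
    rows = []
    n_pairs = n_two = n_all = 0
    for h in histories:
        obs = h.observations
        for (y0, s0), (y1, s1) in zip(obs, obs[1:]):
            change = len(s1) - len(s0)
            rows.append({
                "individual_id": h.individual_id,
                "year_from": y0, "year_to": y1,
                "consecutive": y1 - y0 == 1,
                "change": change,
                "direction": "no change" if change == 0
                             else ("increase" if change > 0 else "decrease"),
            })
        site_presence = {}
        for _, sites in obs:
            for site in sites:
                site_presence[site] = site_presence.get(site, 0) + 1
        n_pairs += len(site_presence)
        n_two += sum(1 for c in site_presence.values() if c >= 2)
        n_all += sum(1 for c in site_presence.values() if c == len(obs))

    intervals = pd.DataFrame(rows, columns=["individual_id", "year_from", "year_to",
                                            "consecutive", "change", "direction"])
    consec = intervals[intervals["consecutive"]] if not intervals.empty else intervals
    changes = consec["change"].to_numpy(dtype=float) if not consec.empty else np.array([])
    return LongitudinalSummary(
        intervals=intervals,
        mean_change=float(changes.mean()) if changes.size else float("nan"),
        sd_change=float(changes.std(ddof=1)) if changes.size > 1 else float("nan"),
        n_increase=int((consec["direction"] == "increase").sum()) if not consec.empty else 0,
        n_decrease=int((consec["direction"] == "decrease").sum()) if not consec.empty else 0,
        n_no_change=int((consec["direction"] == "no change").sum()) if not consec.empty else 0,
        prop_shared_two=n_two / n_pairs if n_pairs else float("nan"),
        prop_shared_all=n_all / n_pairs if n_pairs else float("nan"),
    )


def histories_from_population(pop) -> list[LongitudinalHistory]:
    """Build longitudinal histories for every individual with >= 2 samples
    in a :class:`~mitodyn.simulate.PopulationTable`."""
    histories = []
    calls_by_sample: dict[str, set] = {}
    for _, call in pop.calls.iterrows():
        calls_by_sample.setdefault(call["sample_id"], set()).add(
            (int(call["position"]), call["alt"]))
    for ind, group in pop.samples.groupby("individual_id"):
        if len(group) < 2:
            continue
        group = group.sort_values("year")
        obs = tuple(
            (int(r["year"]), frozenset(calls_by_sample.get(r["sample_id"], set())))
            for _, r in group.iterrows())
        histories.append(LongitudinalHistory(str(ind), obs))
    return histories


def age_association_dataset(pop) -> pd.DataFrame:
    """Primary-analysis dataset: one row per individual (most recent sample),
    with numeric age and heteroplasmy count columns."""
    from mitodyn.characterize import most_recent_samples

    samples = most_recent_samples(pop.samples)
    counts = pop.calls.groupby("sample_id").size()
    out = samples.copy()
    out["count"] = out["sample_id"].map(counts).fillna(0).astype(int)
    out["age_num"] = [code_age(a) for a in out["age"]]
    return out
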