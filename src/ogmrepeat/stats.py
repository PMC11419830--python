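"""Somatic-instability statistics.

The statistical layer mirrors how single-molecule repeat-size data are
analysed: a composite Anderson-Darling normality check on per-sample means
(motivating non-parametric tests), Spearman correlation between progenitor
allele size and measured molecule size with a subject-level bootstrap CI,
Mann-Whitney and paired Wilcoxon group comparisons with exact small-sample
enumeration, and an ordinary least-squares model of log mean molecule size
on mean-centred progenitor size, age and their interaction (centring
removes the collinearity between a positive-valued main effect and its
product term).

All tests are two-sided.  Zero paired differences are dropped and ties take
midranks, following the classical conventions.  No multiple-testing
correction is applied; p-values are reported individually.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import normal_ad
import statsmodels.api as sm

__all__ = [
    "SubjectRecord",
    "ADResult",
    "SpearmanResult",
    "MannWhitneyResult",
    "WilcoxonResult",
    "RegressionSpec",
    "expansion_status",
    "anderson_darling",
    "spearman",
    "mann_whitney",
    "wilcoxon_paired",
    "fit_log_linear",
    "EXPANSION_THRESHOLD_REPEATS",
]

# An allele of >= 50 repeats is the disease-associated, expansion-positive
# class.
EXPANSION_THRESHOLD_REPEATS = 50


def expansion_status(long_allele_repeats: float) -> str:
    return "positive" if long_allele_repeats >= EXPANSION_THRESHOLD_REPEATS else "negative"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's metadata joined with their per-sample sizing summary."""

    subject_id: str
    sampling_age: float
    sex: str
    tissue: str
    progenitor_alleles: tuple[int, int]  # (short, long) repeat counts
    mean_size: float  # bp
    sizes: tuple[float, ...] = ()  # per-molecule expansion sizes

    def __post_init__(self) -> None:
        if self.progenitor_alleles[0] > self.progenitor_alleles[1]:
            raise ValueError("progenitor alleles must be ordered (short, long)")

    @property
    def expansion_status(self) -> str:
        return expansion_status(self.progenitor_alleles[1])


# ---------------------------------------------------------------------------
# normality


@dataclass(frozen=True)
class ADResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def anderson_darling(values: Sequence[float]) -> ADResult:
    """Composite Anderson-Darling test of normality (case 3: both mean and
    variance estimated), small-sample modified A^2 with the standard
    p-value approximation.  Constant input is flagged degenerate."""
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(x) == 0:
        return ADResult(float("nan"), float("nan"), degenerate=True)
    a2, p = normal_ad(x)
    return ADResult(float(a2), float(p))


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    subject_ids: Sequence | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> SpearmanResult:
    """Spearman rank correlation (midranks for ties) with a percentile
    bootstrap CI.

    When ``subject_ids`` is given, bootstrap resampling is at the subject
    level (whole subjects redrawn with replacement), reflecting the
    clustering of molecules within subjects; otherwise observations are
    resampled directly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"), float("nan"), True)
    rho = float(sps.spearmanr(x, y).statistic)

    rng = np.random.default_rng(seed)
    if subject_ids is not None:
        ids = np.asarray(subject_ids)
        groups = {s: np.nonzero(ids == s)[0] for s in np.unique(ids)}
        keys = list(groups)
        draws = []
        for _ in range(n_boot):
            pick = rng.choice(len(keys), size=len(keys), replace=True)
            idx = np.concatenate([groups[keys[k]] for k in pick])
            if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
                continue
            draws.append(sps.spearmanr(x[idx], y[idx]).statistic)
    else:
        n = x.size
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
                continue
            draws.append(sps.spearmanr(x[idx], y[idx]).statistic)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return SpearmanResult(rho, float(lo), float(hi))


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    pvalue: float
    exact: bool


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all group labelings (midranks, so ties are handled
    exactly) when n_a + n_b <= 12; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 1 or nb < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2.0)

    if na + nb <= 12:
        centre = na * nb / 2.0
        dev_obs = abs(u_obs - centre)
        hits = total = 0
        for combo in itertools.combinations(range(na + nb), na):
            u = ranks[list(combo)].sum() - na * (na + 1) / 2.0
            total += 1
            if abs(u - centre) >= dev_obs - 1e-9:
                hits += 1
        return MannWhitneyResult(u_obs, hits / total, exact=True)

    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u_obs, float(res.pvalue), exact=False)


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    w_minus: float
    pvalue: float
    n_used: int
    exact: bool


def wilcoxon_paired(
    first: Sequence[float], second: Sequence[float] | None = None
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Accepts either paired samples or precomputed differences.  Zero
    differences are dropped; |differences| take midranks.  Exact sign-flip
    enumeration (2^n) for n <= 15 non-zero pairs, otherwise the normal
    approximation with tie correction.
    """
    d = np.asarray(first, dtype=float)
    if second is not None:
        d = d - np.asarray(second, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w_minus = total - w_plus

    if n <= 15:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        w_all = signs @ ranks
        dev_obs = abs(w_plus - total / 2.0)
        p = float(np.mean(np.abs(w_all - total / 2.0) >= dev_obs - 1e-9))
        return WilcoxonResult(w_plus, w_minus, p, n, exact=True)

    mu = total / 2.0
    # variance of W+ under random sign flips: sum r_i^2 / 4 (ties included)
    sigma = math.sqrt(float((ranks**2).sum()) / 4.0)
    z = (abs(w_plus - mu) - 0.5) / sigma
    p = 2.0 * sps.norm.sf(z)
    return WilcoxonResult(w_plus, w_minus, min(1.0, float(p)), n, exact=False)


# ---------------------------------------------------------------------------
# log-linear progenitor-size x age model


@dataclass(frozen=True)
class RegressionSpec:
    """Fitted log-linear model of mean molecule size.

    Coefficients are on mean-centred predictors; ``corr_uncentred`` /
    ``corr_centred`` give the correlation between the progenitor main
    effect and the interaction column before and after centring.
    """

    params: pd.Series
    bse: pd.Series
    adj_r2: float
    corr_uncentred: float | None
    corr_centred: float | None
    model: object


def fit_log_linear(
    records: pd.DataFrame,
    with_age: bool = True,
    with_interaction: bool = True,
) -> RegressionSpec:
    """OLS of log(mean_size) on centred progenitor size (and age).

    ``records`` needs columns ``mean_size`` (bp, positive), ``progenitor_long``
    (repeats) and, when ``with_age``, ``age`` (years).  Predictors are
    mean-centred before the interaction product is formed.
    """
    n_params = 2 + int(with_age) + int(with_age and with_interaction)
    if len(records) < n_params + 3:
        raise ValueError("need at least 3 more subjects than parameters")
    y = np.log(records["mean_size"].to_numpy(dtype=float))
    if not np.isfinite(y).all():
        raise ValueError("mean_size must be positive and finite")

    size = records["progenitor_long"].to_numpy(dtype=float)
    c_size = size - size.mean()
    data = {"progenitor_size_c": c_size}
    corr_unc = corr_cen = None
    if with_age:
        age = records["age"].to_numpy(dtype=float)
        c_age = age - age.mean()
        data["age_c"] = c_age
        if with_interaction:
            data["size_x_age_c"] = c_size * c_age
            corr_unc = float(np.corrcoef(size, size * age)[0, 1])
            corr_cen = float(np.corrcoef(c_size, c_size * c_age)[0, 1])
    X = sm.add_constant(pd.DataFrame(data))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is collinear after centring")
    fit = sm.OLS(y, X).fit()
    return RegressionSpec(
        params=fit.params,
        bse=fit.bse,
        adj_r2=float(fit.rsquared_adj),
        corr_uncentred=corr_unc,
        corr_centred=corr_cen,
        model=fit,
    )
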