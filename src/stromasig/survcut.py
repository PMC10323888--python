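"""Survival machinery: Kaplan–Meier, log-rank, maximally selected cutpoints,
quantile dichotomization and Cox modelling.

The Kaplan–Meier estimator, the log-rank test and the entire maximally
selected cutpoint search are native implementations: the cutpoint search is
*defined* as exhaustive maximization of the standardized log-rank statistic
over admissible splits, with a seeded permutation null, and the search and
the test must therefore agree exactly.  Cox proportional-hazards fitting
delegates to lifelines (Efron tie handling).

Conventions
-----------
* Times are months of overall survival; ``event`` is 1 = death, 0 = censored.
* The log-rank score ``U`` counts observed minus expected events in *group
  1*, defined as the lexicographically smallest group label.
* In all dichotomizations "high" means score strictly above the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import SurvivalTable

logger = logging.getLogger("stromasig")

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CutpointResult",
    "CoxResult",
    "CoxScreenResult",
    "km_estimate",
    "logrank_test",
    "maxstat_cutpoint",
    "categorize_by_quantile",
    "cox_fit",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # nan when S never reaches 0.5
    median_ci: tuple[float, float]  # nan endpoints when undetermined

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(surv: SurvivalTable, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Pointwise confidence intervals use the Greenwood variance on the
    log(-log) scale.  The median is the smallest event time with
    ``S(t) <= 0.5``; its confidence interval inverts the pointwise bands
    (Brookmeyer–Crowley): each endpoint is the smallest event time at which
    the corresponding confidence limit of S drops to 0.5 or below.
    """
    if surv.n == 0:
        raise ValueError("empty survival table")
    time = surv.time.to_numpy()
    event = surv.event.to_numpy()

    event_times = np.unique(time[event == 1])
    n = len(time)
    if event_times.size == 0:
        return KMCurve(
            event_times=np.array([]),
            survival=np.array([]),
            at_risk=np.array([]),
            n_events=np.array([]),
            ci_lower=np.array([]),
            ci_upper=np.array([]),
            median=np.nan,
            median_ci=(np.nan, np.nan),
        )

    at_risk = np.array([(time >= t).sum() for t in event_times])
    d = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    frac = 1.0 - d / at_risk
    S = np.cumprod(frac)

    # Greenwood on the log(-log) scale
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.cumsum(d / (at_risk * (at_risk - d)))
        log_s = np.log(S)
        se_cll = np.sqrt(gw_terms) / np.abs(log_s)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(invalid="ignore", over="ignore"):
        lo = np.exp(-np.exp(np.log(-log_s) + z * se_cll))
        hi = np.exp(-np.exp(np.log(-log_s) - z * se_cll))
    lo = np.where(S <= 0.0, 0.0, lo)
    hi = np.where(S <= 0.0, 0.0, hi)
    lo = np.where(S >= 1.0, 1.0, np.nan_to_num(lo, nan=0.0))
    hi = np.where(S >= 1.0, 1.0, np.nan_to_num(hi, nan=1.0))

    median = _first_time_leq(event_times, S, 0.5)
    med_lo = _first_time_leq(event_times, lo, 0.5)
    med_hi = _first_time_leq(event_times, hi, 0.5)
    return KMCurve(
        event_times=event_times,
        survival=S,
        at_risk=at_risk,
        n_events=d,
        ci_lower=lo,
        ci_upper=hi,
        median=median,
        median_ci=(med_lo, med_hi),
    )


def _first_time_leq(times: np.ndarray, values: np.ndarray, level: float) -> float:
    hit = np.nonzero(values <= level)[0]
    return float(times[hit[0]]) if hit.size else np.nan


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    U: float  # observed - expected events in group 1
    V: float  # hypergeometric variance
    chi2: float
    z: float
    p: float
    group1: str


def logrank_test(surv: SurvivalTable, groups: pd.Series) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time i with ``di`` events among ``ni`` at risk
    (``n1i`` of them in group 1): ``U = sum(d1i - n1i*di/ni)`` and
    ``V = sum(di*(n1i/ni)*(1-n1i/ni)*(ni-di)/(ni-1))``; ``chi2 = U^2/V`` is
    referred to a chi-square with 1 df.  Group 1 is the lexicographically
    smallest label.
    """
    groups = groups.reindex(surv.sample_ids)
    if groups.isna().any():
        raise ValueError("groups missing for some samples")
    labels = sorted(map(str, groups.unique()))
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {labels}")
    if surv.event.sum() == 0:
        raise ValueError("no events")

    time = surv.time.to_numpy()
    event = surv.event.to_numpy()
    in1 = (groups.astype(str) == labels[0]).to_numpy()
    U, V = _logrank_uv(time, event, in1)
    if V <= 0:
        raise ValueError("log-rank variance is zero (no information)")
    chi2 = U * U / V
    return LogRankResult(
        U=U,
        V=V,
        chi2=chi2,
        z=U / np.sqrt(V),
        p=float(stats.chi2.sf(chi2, 1)),
        group1=labels[0],
    )


def _logrank_uv(time: np.ndarray, event: np.ndarray, in1: np.ndarray) -> tuple[float, float]:
    taus = np.unique(time[event == 1])
    U = 0.0
    V = 0.0
    for t in taus:
        at_risk = time >= t
        ni = at_risk.sum()
        di = ((time == t) & (event == 1)).sum()
        n1i = (at_risk & in1).sum()
        d1i = ((time == t) & (event == 1) & in1).sum()
        U += d1i - n1i * di / ni
        if ni > 1:
            V += di * (n1i / ni) * (1.0 - n1i / ni) * (ni - di) / (ni - 1)
    return float(U), float(V)


# ---------------------------------------------------------------------------
# Maximally selected log-rank cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    cutpoint: float
    max_stat: float  # max |z| over admissible candidate cutpoints
    p_perm: float
    n_candidates: int
    groups: pd.Series  # per-sample "high"/"low"
    candidate_cutpoints: np.ndarray = field(repr=False, default=None)
    candidate_stats: np.ndarray = field(repr=False, default=None)


def maxstat_cutpoint(
    score: pd.Series,
    surv: SurvivalTable,
    minprop: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint (Hothorn–Lausen style search).

    Candidate cutpoints are midpoints between consecutive distinct score
    values whose split leaves at least ``ceil(minprop * n)`` samples on each
    side.  Every candidate is scored with the standardized log-rank
    statistic |z| = |U|/sqrt(V); the selected cutpoint maximizes |z| (ties
    broken toward the smallest cutpoint).  The selection p-value is a
    permutation p for the *maximum* statistic under random relabeling of
    scores against survival: ``(1 + #{perm max >= observed max}) /
    (1 + n_perm)``.
    """
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must lie in (0, 0.5)")
    score = score.reindex(surv.sample_ids)
    if score.isna().any():
        raise ValueError("scores missing for some samples")
    n = surv.n
    time = surv.time.to_numpy()
    event = surv.event.to_numpy()
    s = score.to_numpy().astype(float)

    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    m = int(np.ceil(minprop * n))
    # k = number of samples on the low side; admissible when both sides >= m
    # and the boundary separates distinct score values
    ks = np.array(
        [k for k in range(m, n - m + 1) if k < n and s_sorted[k - 1] < s_sorted[k]],
        dtype=int,
    )
    if ks.size == 0:
        raise ValueError("no admissible candidate cutpoint")
    cutpoints = (s_sorted[ks - 1] + s_sorted[ks]) / 2.0

    # Observed statistics go through the identical accumulation path as
    # logrank_test so the search is bit-exact against enumeration; the
    # permutation null uses the vectorized kernel below.
    z_obs = np.empty(ks.size)
    for i, cut in enumerate(cutpoints):
        U, V = _logrank_uv(time, event, s <= cut)
        z_obs[i] = U / np.sqrt(V) if V > 0 else np.nan
    coef = _split_precompute(time, event)
    finite = np.isfinite(z_obs)
    if not finite.any():
        raise ValueError("no candidate cutpoint with positive log-rank variance")
    abs_z = np.where(finite, np.abs(z_obs), -np.inf)
    best = int(np.argmax(abs_z))  # first max -> smallest cutpoint on ties
    max_stat = float(abs_z[best])
    cutpoint = float(cutpoints[best])

    rng = np.random.Generator(np.random.PCG64(seed))
    n_ge = 0
    for _ in range(n_perm):
        perm_order = rng.permutation(n)
        z_perm = _split_stats(time, event, perm_order, ks, coef)
        z_perm = np.abs(z_perm[np.isfinite(z_perm)])
        if z_perm.size and z_perm.max() >= max_stat:
            n_ge += 1
    p_perm = (1.0 + n_ge) / (1.0 + n_perm)

    labels = pd.Series(
        np.where(s > cutpoint, "high", "low"), index=score.index, name="group"
    )
    return CutpointResult(
        cutpoint=cutpoint,
        max_stat=max_stat,
        p_perm=p_perm,
        n_candidates=int(ks.size),
        groups=labels,
        candidate_cutpoints=cutpoints,
        candidate_stats=z_obs,
    )


def _split_precompute(time: np.ndarray, event: np.ndarray):
    """Per-event-time constants reused across splits and permutations."""
    taus = np.unique(time[event == 1])
    ni = (time[None, :] >= taus[:, None]).sum(axis=1).astype(float)
    di = ((time[None, :] == taus[:, None]) & (event[None, :] == 1)).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef_v = np.where(ni > 1, di * (ni - di) / (ni * ni * (ni - 1)), 0.0)
    return taus, ni, di, coef_v


def _split_stats(
    time: np.ndarray,
    event: np.ndarray,
    order: np.ndarray,
    ks: np.ndarray,
    coef,
) -> np.ndarray:
    """Standardized log-rank z for every split size in ``ks``, where the
    low-side group is the first k samples of ``order``.

    Identical, by construction, to calling :func:`logrank_test` on each
    split: U and V use the same per-event-time hypergeometric terms,
    accumulated via cumulative sums over the ordered samples.
    """
    taus, ni, di, coef_v = coef
    t_ord = time[order]
    e_ord = event[order]
    R = t_ord[None, :] >= taus[:, None]  # at-risk indicator, T x n
    D = (t_ord[None, :] == taus[:, None]) & (e_ord[None, :] == 1)
    N1 = np.cumsum(R, axis=1)[:, ks - 1].astype(float)  # n1i per split
    D1 = np.cumsum(D, axis=1)[:, ks - 1].astype(float)  # d1i per split
    U = (D1 - N1 * (di / ni)[:, None]).sum(axis=0)
    V = (coef_v[:, None] * N1 * (ni[:, None] - N1)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(V > 0, U / np.sqrt(V), np.nan)
    return z


# ---------------------------------------------------------------------------
# Quantile dichotomization
# ---------------------------------------------------------------------------

def categorize_by_quantile(
    score: pd.Series, q: float = 2.0 / 3.0
) -> tuple[pd.Series, float]:
    """Dichotomize a score at its empirical q-quantile.

    The threshold is ``numpy.quantile`` with linear interpolation; a sample
    is "high" iff its score is strictly above the threshold, so with
    ``q = 2/3`` roughly the upper third is labeled high (ties at the
    threshold fall low).
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    values = score.to_numpy().astype(float)
    if np.ptp(values) == 0:
        raise ValueError("scores are constant; no quantile split possible")
    threshold = float(np.quantile(values, q))
    labels = pd.Series(
        np.where(values > threshold, "high", "low"), index=score.index, name="group"
    )
    return labels, threshold


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs, plus the model fit."""

    summary: pd.DataFrame  # index covariate; hazard_ratio, ci_lower, ci_upper, p
    log_likelihood: float


@dataclass
class CoxScreenResult:
    """Univariate screen followed by a multivariable model of the survivors."""

    univariate: pd.DataFrame
    selected: list[str]
    final: CoxResult | None  # None when no covariate passes the entry p


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: categoricals one-hot-expanded against the
    lexicographically first level as reference."""
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # first sorted level is the reference
                cols.append(
                    (col.astype(str) == level).astype(float).rename(f"{name}[{level}]")
                )
    return pd.concat(cols, axis=1)


def cox_fit(
    surv: SurvivalTable,
    covariates: pd.DataFrame | None = None,
    mode: str = "multivariable",
    entry_p: float = 0.05,
) -> CoxResult | CoxScreenResult:
    """Cox proportional-hazards regression (lifelines backend, Efron ties).

    ``mode="multivariable"`` fits all covariates jointly.
    ``mode="univariate_screen"`` fits each covariate alone, then refits
    jointly those with univariate Wald ``p < entry_p``.

    Zero-variance covariates and rank-deficient (collinear) designs are
    rejected before fitting.
    """
    from lifelines import CoxPHFitter

    if covariates is None:
        covariates = surv.covariates
    covariates = covariates.reindex(surv.sample_ids)
    if covariates.shape[1] == 0:
        raise ValueError("no covariates supplied")
    if covariates.isna().any().any():
        raise ValueError("missing covariate values")
    design = _design_matrix(covariates)
    for name in design.columns:
        if design[name].nunique() <= 1:
            raise ValueError(f"zero-variance covariate: {name!r}")
    if surv.event.sum() == 0:
        raise ValueError("no events")

    def _fit(cols: list[str]) -> CoxResult:
        X = design[cols]
        if np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0)) < len(cols):
            raise ValueError(f"collinear covariates: {cols}")
        frame = pd.concat(
            [surv.time.rename("T"), surv.event.rename("E"), X], axis=1
        )
        cph = CoxPHFitter()
        cph.fit(frame, duration_col="T", event_col="E")
        summ = cph.summary
        out = pd.DataFrame(
            {
                "hazard_ratio": np.exp(summ["coef"]),
                "ci_lower": np.exp(summ["coef lower 95%"]),
                "ci_upper": np.exp(summ["coef upper 95%"]),
                "p": summ["p"],
            }
        )
        out.index.name = "covariate"
        return CoxResult(summary=out, log_likelihood=float(cph.log_likelihood_))

    if mode == "multivariable":
        return _fit(list(design.columns))
    if mode != "univariate_screen":
        raise ValueError(f"unknown mode {mode!r}")

    uni_rows = []
    for name in design.columns:
        res = _fit([name])
        uni_rows.append(res.summary.loc[name])
    uni = pd.DataFrame(uni_rows)
    uni.index.name = "covariate"
    selected = list(uni.index[uni["p"] < entry_p])
    final = _fit(selected) if selected else None
    if final is None:
        logger.info("cox_fit: no covariate passed the entry p < %g", entry_p)
    return CoxScreenResult(univariate=uni, selected=selected, final=final)
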