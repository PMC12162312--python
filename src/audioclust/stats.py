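"""The statistical battery of the prognostic analysis.

Implements closed-form ordinary least squares with t-based Wald inference,
binary logistic regression by iteratively reweighted least squares with
normal-based Wald inference and odds-ratio reporting, the univariate →
multivariate p < 0.05 selection rule, pooled-variance Student's t,
Mann–Whitney U (tie-corrected normal approximation with continuity
correction; exact null distribution when the smaller sample has <= 8
untied observations), Pearson chi-square, and quartile binning of age.

The regression and test engines are written out from the normal equations /
IRLS updates rather than delegated, so that independent implementations
(statsmodels, scipy) can serve as cross-checks in the test-suite;
p-values come from scipy's t, normal and chi-square distributions.

Covariate encoding mirrors the clinical analysis: cluster enters as an
indicator for Y (X reference), age either raw in years or as quartile
indicators (youngest quartile reference), affected-ear audiogram type as
indicators with "upsloping" reference, side as a right indicator (left
reference) and sex as a female indicator (male reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .audiogram_io import PatientRecord
from .cohort import (
    AUDIOGRAM_TYPES,
    EfficacyGrade,
    SiegelCriteria,
    TypeRules,
    classify_audiogram_type,
    grade_siegel,
    improvement_db,
)
from .errors import ContractError, DegenerateDataError, FittingError, ConvergenceError


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class Coefficient:
    """One row of a regression table."""

    variable: str
    level: str  # "" for continuous terms
    estimate: float
    se: float
    statistic: float
    p: float
    ci_low: float
    ci_high: float
    odds_ratio: Optional[float] = None
    or_ci: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class RegressionResult:
    """Fitted model: coefficient table plus fit metadata.

    ``coefficients`` excludes the intercept, which is reported separately;
    for logistic fits each coefficient also carries OR = exp(beta) with a
    matching exponentiated CI.
    """

    kind: str  # "ols" or "logistic"
    n: int
    intercept: Coefficient
    coefficients: tuple[Coefficient, ...]
    df_resid: Optional[int] = None
    log_likelihood: Optional[float] = None

    def coefficient(self, variable: str, level: str = "") -> Coefficient:
        for c in self.coefficients:
            if c.variable == variable and (level == "" or c.level == level):
                return c
        raise KeyError(f"no coefficient for {variable!r} level {level!r}")

    def min_p(self, variable: str) -> float:
        ps = [c.p for c in self.coefficients if c.variable == variable]
        if not ps:
            raise KeyError(f"no coefficient for {variable!r}")
        return min(ps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in (self.intercept, *self.coefficients):
            rows.append({
                "variable": c.variable, "level": c.level,
                "estimate": c.estimate, "se": c.se,
                "statistic": c.statistic, "p": c.p,
                "ci_low": c.ci_low, "ci_high": c.ci_high,
                "odds_ratio": c.odds_ratio,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design-matrix encoding

def encode_design(
    frame: pd.DataFrame, variables: Sequence[str]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Build an intercept + dummy-coded design matrix.

    Supported variable names: ``cluster`` (indicator for Y), ``age``
    (years, continuous), ``age_quartile`` (indicators for quartiles 2–4),
    ``type`` (indicators for downsloping/flat/profound vs. upsloping),
    ``side`` (right vs. left), ``sex`` (female vs. male).  Returns the
    matrix and ``(variable, level)`` names per non-intercept column.
    """
    n = len(frame)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[tuple[str, str]] = []
    for var in variables:
        if var == "cluster":
            cols.append((frame["cluster"].to_numpy() == "Y").astype(float))
            names.append(("cluster", "Y"))
        elif var == "age":
            cols.append(frame["age"].to_numpy(dtype=float))
            names.append(("age", ""))
        elif var == "age_quartile":
            q = frame["age_quartile"].to_numpy()
            for level in (2, 3, 4):
                ind = (q == level).astype(float)
                if ind.any():  # absent levels carry no column
                    cols.append(ind)
                    names.append(("age_quartile", str(level)))
        elif var == "type":
            t = frame["audiogram_type"].to_numpy()
            for level in AUDIOGRAM_TYPES[1:]:  # upsloping is the reference
                ind = (t == level).astype(float)
                if ind.any():
                    cols.append(ind)
                    names.append(("type", level))
        elif var == "side":
            cols.append((frame["side"].to_numpy() == "R").astype(float))
            names.append(("side", "R"))
        elif var == "sex":
            cols.append((frame["sex"].to_numpy() == "F").astype(float))
            names.append(("sex", "F"))
        else:
            raise ContractError(f"unknown design variable {var!r}")
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: Sequence[tuple[str, str]]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR points at the dependent columns
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = sorted(piv[rank:])
        labels = ["intercept" if j == 0 else "/".join(filter(None, names[j - 1]))
                  for j in bad]
        raise FittingError(f"design matrix is rank deficient; collinear columns: {labels}")


# ---------------------------------------------------------------------------
# ordinary least squares

def ols_fit(
    X: np.ndarray, y: np.ndarray, names: Sequence[tuple[str, str]]
) -> RegressionResult:
    """Closed-form least squares with t-distribution Wald inference.

    ``X`` must contain the intercept as its first column; ``names`` labels
    the remaining columns.  Standard errors come from
    ``sigma2 * (X'X)^{-1}`` with ``sigma2 = RSS / (n - p)``; two-sided
    p-values and 95% CIs use the t distribution with ``n - p`` degrees of
    freedom.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ContractError(f"need n > p, got n={n}, p={p}")
    if len(names) != p - 1:
        raise ContractError("names must label the non-intercept columns")
    _check_rank(X, names)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), df)
    q = sps.t.ppf(0.975, df)
    lo, hi = beta - q * se, beta + q * se

    def row(j: int, variable: str, level: str) -> Coefficient:
        return Coefficient(variable, level, float(beta[j]), float(se[j]),
                           float(tstat[j]), float(pvals[j]),
                           float(lo[j]), float(hi[j]))

    return RegressionResult(
        kind="ols", n=n, df_resid=df,
        intercept=row(0, "intercept", ""),
        coefficients=tuple(row(j + 1, v, l) for j, (v, l) in enumerate(names)),
    )


# ---------------------------------------------------------------------------
# binary logistic regression

def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[tuple[str, str]],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RegressionResult:
    """Maximum-likelihood logistic regression via IRLS (Newton with
    step-halving).

    ``y`` is 0/1 with the adverse outcome ("no improvement") coded 1.
    Converges when the gradient's max-norm is <= ``tol``.  Wald z tests
    with standard-normal p-values and 95% CIs; each non-intercept term is
    also reported as an odds ratio ``exp(beta)`` with exponentiated CI.

    Raises
    ------
    DegenerateDataError
        Constant outcome.
    FittingError
        (Quasi-)separation, detected as diverging estimates.
    ConvergenceError
        Iteration budget exhausted before the gradient tolerance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ContractError(f"need n > p, got n={n}, p={p}")
    if np.all(y == y[0]):
        raise DegenerateDataError("outcome is constant")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ContractError("outcome must be coded 0/1")
    _check_rank(X, names)

    def loglik(beta: np.ndarray) -> float:
        eta = X @ beta
        # log(1 + e^eta) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    beta = np.zeros(p)
    ll = loglik(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise FittingError(
                "singular information matrix (separation or collinearity)"
            ) from None
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = loglik(beta)
        if np.max(np.abs(beta)) > 30.0:
            raise FittingError(
                "diverging estimates: outcome is (quasi-)separated by the design"
            )
    if not converged:
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        if np.max(np.abs(X.T @ (y - mu))) > tol:
            raise ConvergenceError(
                f"IRLS did not converge within {max_iter} iterations"
            )
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    q = sps.norm.ppf(0.975)
    lo, hi = beta - q * se, beta + q * se

    def row(j: int, variable: str, level: str) -> Coefficient:
        is_term = variable != "intercept"
        return Coefficient(
            variable, level, float(beta[j]), float(se[j]), float(z[j]),
            float(pvals[j]), float(lo[j]), float(hi[j]),
            odds_ratio=float(np.exp(beta[j])) if is_term else None,
            or_ci=(float(np.exp(lo[j])), float(np.exp(hi[j]))) if is_term else None,
        )

    return RegressionResult(
        kind="logistic", n=n, log_likelihood=ll,
        intercept=row(0, "intercept", ""),
        coefficients=tuple(row(j + 1, v, l) for j, (v, l) in enumerate(names)),
    )


# ---------------------------------------------------------------------------
# univariate -> multivariate selection

def select_multivariate(
    results_uni: Sequence[tuple[str, RegressionResult]],
    alpha: float = 0.05,
) -> list[str]:
    """Variables whose univariate p < alpha, in candidate order.

    For a categorical variable the minimum p across its non-reference
    levels decides inclusion (one significant level suffices).
    """
    selected = []
    for variable, result in results_uni:
        p = min(c.p for c in result.coefficients)
        if p < alpha:
            selected.append(variable)
    return selected


# ---------------------------------------------------------------------------
# two-group tests

def two_group_tests(
    a: Sequence[float], b: Sequence[float], kind: str
) -> tuple[float, float]:
    """Student's t (pooled variance) or Mann–Whitney U, two-sided.

    ``student_t``
        Classic pooled-variance two-sample t; zero pooled variance raises
        :class:`DegenerateDataError`.
    ``mann_whitney``
        U counts pairs (i, j) with ``a_i < b_j`` plus half-ties.  The p-value
        uses the exact null distribution when the smaller sample has <= 8
        observations and there are no cross-sample ties, otherwise the
        tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if kind == "student_t":
        if n1 < 2 or n2 < 2:
            raise ContractError("t-test needs n >= 2 per group")
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0.0:
            raise DegenerateDataError("zero pooled variance")
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * sps.t.sf(abs(t), n1 + n2 - 2)
        return float(t), float(p)
    if kind == "mann_whitney":
        if n1 < 1 or n2 < 1:
            raise ContractError("Mann-Whitney needs n >= 1 per group")
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        r1 = ranks[:n1].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0  # pairs with a_i > b_j (+ half ties)
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        has_ties = np.any(tie_counts > 1)
        if min(n1, n2) <= 8 and not has_ties:
            p = _mann_whitney_exact_p(u1, n1, n2)
        else:
            tie_term = float(((tie_counts**3 - tie_counts)).sum())
            sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
            if sigma2 <= 0:
                raise DegenerateDataError("all observations tied")
            mu = n1 * n2 / 2.0
            z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(sigma2)
            p = 2.0 * sps.norm.sf(abs(z))
        return float(u1), float(min(1.0, p))
    raise ContractError(f"unknown test kind {kind!r}")


def _mann_whitney_exact_p(u: float, n1: int, n2: int) -> float:
    """Two-sided exact p from the null count recurrence (no ties).

    ``f(u; m, n) = f(u - n; m-1, n) + f(u; m, n-1)`` counts the
    interleavings of samples of sizes m and n whose statistic equals u;
    the two-sided p doubles the smaller tail (clipped at 1).
    """
    max_u = n1 * n2
    # rows indexed by n = 0..n2; start at m = 0 where only u = 0 occurs
    prev = np.zeros((n2 + 1, max_u + 1))
    prev[:, 0] = 1.0
    for m in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for n in range(1, n2 + 1):
            cur[n] = cur[n - 1]
            cur[n, n:] = cur[n, n:] + prev[n, : max_u + 1 - n]
        prev = cur
    counts = prev[n2]
    total = counts.sum()
    u_low = min(u, max_u - u)
    p = 2.0 * counts[: int(round(u_low)) + 1].sum() / total
    return min(1.0, p)


def chi_square_2xk(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction.

    Expected counts from the margins; p from the chi-square distribution
    with (r-1)(c-1) degrees of freedom.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ContractError("contingency table must be at least 2x2")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateDataError("zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# age quartiles

@dataclass(frozen=True)
class QuartileBins:
    """Quartile binning of a numeric vector.

    ``bins`` holds 1–4 per observation; ``boundaries`` are the sample
    quartiles (linear-interpolation convention); ``ranges`` the observed
    (min, max) per bin; ``degenerate`` flags coincident boundaries.
    """

    bins: np.ndarray
    boundaries: tuple[float, float, float]
    ranges: tuple[tuple[float, float], ...]
    degenerate: bool


def age_quartile_bins(ages: Sequence[float]) -> QuartileBins:
    """Assign each age to a quartile class 1 (youngest) … 4 (oldest).

    Boundaries are the 25/50/75% sample quantiles with linear
    interpolation; bins are closed on the right at interior boundaries,
    so on integer ages quartiles (35, 49, 63) with range 18–82 give the
    classes 18–35, 36–49, 50–63 and 64–82.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 4:
        raise ContractError("quartile binning needs n >= 4")
    q1, q2, q3 = np.quantile(ages, [0.25, 0.5, 0.75])  # linear interpolation
    bins = 1 + (ages > q1).astype(int) + (ages > q2).astype(int) + (ages > q3).astype(int)
    degenerate = not (q1 < q2 < q3)
    ranges = []
    for k in (1, 2, 3, 4):
        members = ages[bins == k]
        if members.size:
            ranges.append((float(members.min()), float(members.max())))
        else:
            ranges.append((float("nan"), float("nan")))
    return QuartileBins(
        bins=bins, boundaries=(float(q1), float(q2), float(q3)),
        ranges=tuple(ranges), degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# the full Table-style analysis

def build_analysis_frame(
    records: Sequence[PatientRecord],
    cluster_codes: Sequence[int],
    criteria: SiegelCriteria = SiegelCriteria(),
    type_rules: TypeRules = TypeRules(),
) -> pd.DataFrame:
    """Assemble the per-patient analysis table.

    Columns: patient_id, cluster (X/Y), age, age_quartile, sex, side,
    audiogram_type, improvement_db, grade, improved, no_improvement.
    Requires pre and post affected audiograms on every record.
    """
    if len(records) != len(cluster_codes):
        raise ContractError("cluster codes must align with records")
    rows = []
    for r, code in zip(records, cluster_codes):
        if r.affected_pre is None or r.affected_post is None:
            raise ContractError(
                f"patient {r.patient_id} lacks pre/post affected audiograms"
            )
        grade = grade_siegel(r.affected_pre, r.affected_post, criteria)
        rows.append({
            "patient_id": r.patient_id,
            "cluster": "X" if int(code) == 0 else "Y",
            "age": r.age,
            "sex": r.sex,
            "side": r.side,
            "audiogram_type": classify_audiogram_type(r.affected_pre, type_rules),
            "improvement_db": improvement_db(r),
            "grade": grade.value,
            "improved": grade.improved,
            "no_improvement": int(not grade.improved),
        })
    frame = pd.DataFrame(rows)
    frame["age_quartile"] = age_quartile_bins(frame["age"].to_numpy()).bins
    return frame


LINEAR_CANDIDATES = ("cluster", "age", "type", "side", "sex")
LOGISTIC_CANDIDATES = ("cluster", "age_quartile", "type", "side", "sex")


@dataclass(frozen=True)
class AnalysisTables:
    """Univariate + multivariate regression battery for one outcome.

    ``failed`` lists candidate variables whose univariate fit raised a
    diagnostic error (e.g. separation on a sparse categorical level);
    they are excluded from selection rather than aborting the battery.
    """

    univariate: tuple[tuple[str, RegressionResult], ...]
    selected: tuple[str, ...]
    multivariate: Optional[RegressionResult]
    failed: tuple[str, ...] = ()


def _run_battery(
    frame: pd.DataFrame,
    y: np.ndarray,
    candidates: Sequence[str],
    fit,
) -> AnalysisTables:
    uni = []
    failed = []
    for var in candidates:
        X, names = encode_design(frame, [var])
        try:
            uni.append((var, fit(X, y, names)))
        except (FittingError, DegenerateDataError):
            failed.append(var)
    selected = select_multivariate(uni)
    multi = None
    if selected:
        X, names = encode_design(frame, selected)
        multi = fit(X, y, names)
    return AnalysisTables(
        univariate=tuple(uni), selected=tuple(selected), multivariate=multi,
        failed=tuple(failed),
    )


def linear_tables(frame: pd.DataFrame) -> AnalysisTables:
    """Threshold-improvement OLS battery (dependent: improvement_db)."""
    y = frame["improvement_db"].to_numpy(dtype=float)
    return _run_battery(frame, y, LINEAR_CANDIDATES, ols_fit)


def logistic_tables(frame: pd.DataFrame) -> AnalysisTables:
    """No-improvement logistic battery (dependent: no_improvement = 1)."""
    y = frame["no_improvement"].to_numpy(dtype=float)
    return _run_battery(frame, y, LOGISTIC_CANDIDATES, logistic_fit)


def tables_to_frame(tables: AnalysisTables, kind: str) -> pd.DataFrame:
    """Flatten a battery into the exported delimited layout."""
    rows = []
    for model_tag, items in (
        ("uni", [(v, r) for v, r in tables.univariate]),
        ("multi", [("", tables.multivariate)] if tables.multivariate else []),
    ):
        for _, result in items:
            if result is None:
                continue
            for c in result.coefficients:
                rows.append({
                    "variable": c.variable, "level": c.level,
                    "estimate": c.estimate,
                    "odds_ratio": c.odds_ratio,
                    "se": c.se, "statistic": c.statistic, "p": c.p,
                    "ci_low": c.ci_low, "ci_high": c.ci_high,
                    "model": model_tag, "kind": kind,
                })
    frame = pd.DataFrame(
        rows,
        columns=["variable", "level", "estimate", "odds_ratio", "se",
                 "statistic", "p", "ci_low", "ci_high", "model", "kind"],
    )
    for col in ("estimate", "odds_ratio", "se", "statistic", "p",
                "ci_low", "ci_high"):
        frame[col] = pd.to_numeric(frame[col])
    return frame
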