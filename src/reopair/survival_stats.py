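"""Survival-analysis primitives: Cox proportional hazards (Efron ties),
Kaplan-Meier / log-rank, Harrell's concordance, BH-FDR, Spearman tests and a
two-cohort differential-expression direction-concordance check.

The Cox solver is a plain Newton-Raphson on the Efron partial likelihood
(tolerance 1e-9, at most 100 iterations, step halving); it is cross-checked
against lifelines in the test suite rather than delegating to it, because the
screening stages fit thousands of tiny univariate models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reo_core import ExpressionMatrix, log_binomial_tail, binomial_consistency_test

__all__ = [
    "SurvivalTable",
    "CoxResult",
    "ConcordanceResult",
    "cox_univariate",
    "cox_multivariate",
    "km_logrank",
    "km_curve",
    "harrell_c",
    "bh_fdr",
    "spearman_test",
    "deg_concordance",
]


class SurvivalTable:
    """Per-sample follow-up: recurrence-free time (months), event flag and
    optional covariates (age, grade, size_cm, node, treated...)."""

    REQUIRED = ("sample_id", "time_months", "event")

    def __init__(
        self,
        sample_ids: Sequence[str],
        time: Sequence[float],
        event: Sequence[int],
        covariates: pd.DataFrame | None = None,
    ) -> None:
        sample_ids = [str(s) for s in sample_ids]
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample ids are not unique")
        if not (len(sample_ids) == len(time) == len(event)):
            raise ValueError("inconsistent lengths")
        if np.any(time <= 0):
            raise ValueError("all times must be positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event flags must be 0/1")
        self.sample_ids = sample_ids
        self.time = time
        self.event = event.astype(int)
        self.covariates = (
            covariates.reset_index(drop=True)
            if covariates is not None
            else pd.DataFrame(index=range(len(sample_ids)))
        )
        if len(self.covariates) != len(sample_ids):
            raise ValueError("covariate table length mismatch")
        self._index = {s: i for i, s in enumerate(sample_ids)}

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        idx = [self._index[s] for s in samples]
        return SurvivalTable(
            [self.sample_ids[i] for i in idx],
            self.time[idx],
            self.event[idx],
            self.covariates.iloc[idx].reset_index(drop=True),
        )

    def align_to(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        missing = [s for s in sample_ids if s not in self._index]
        if missing:
            raise KeyError(f"samples absent from survival table: {missing}")
        return self.subset(sample_ids)

    @classmethod
    def from_tsv(cls, path) -> "SurvivalTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        for col in cls.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        cov = df.drop(columns=list(cls.REQUIRED))
        return cls(df["sample_id"], df["time_months"], df["event"], cov)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "time_months": self.time, "event": self.event}
        )
        df = pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class CoxResult:
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    se: float
    n: int
    n_events: int
    converged: bool = True
    name: str | None = None


@dataclass
class ConcordanceResult:
    c: float
    n_usable: int
    n_concordant: int
    n_tied: int


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron tie handling)


def _efron_quantities(beta, X, time, event):
    """Log partial likelihood, gradient and Hessian at beta."""
    n, p = X.shape
    order = np.argsort(-time, kind="stable")  # decreasing time
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in ratios
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    # running risk-set sums as time decreases
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        block = slice(i, j)
        wb = w[block]
        xb = Xs[block]
        s0 += wb.sum()
        s1 += xb.T @ wb
        s2 += (xb * wb[:, None]).T @ xb
        dmask = es[block] == 1
        d = int(dmask.sum())
        if d > 0:
            xd = xb[dmask]
            wd = wb[dmask]
            d0 = wd.sum()
            d1 = xd.T @ wd
            d2 = (xd * wd[:, None]).T @ xd
            ll += float(eta[block][dmask].sum())
            for r in range(d):
                f = r / d
                denom = s0 - f * d0
                num1 = s1 - f * d1
                num2 = s2 - f * d2
                ll -= math.log(denom)
                mu = num1 / denom
                grad_r = mu
                grad -= grad_r
                hess -= num2 / denom - np.outer(mu, mu)
            grad += xd.sum(axis=0)
        i = j
    return ll, grad, -hess  # return observed information (positive definite)


def _cox_fit(X, time, event, tol: float = 1e-9, max_iter: int = 100):
    """Newton-Raphson with step halving; returns (beta, info, converged)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, info = _efron_quantities(beta, X, time, event)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll2, grad2, info2 = _efron_quantities(cand, X, time, event)
            if np.isfinite(ll2) and ll2 >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            break
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, info = cand, ll2, grad2, info2
        if delta < tol or np.max(np.abs(grad)) < tol:
            converged = True
            break
    return beta, info, converged


def _wald_results(beta, info, n, n_events, names) -> list[CoxResult]:
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    out = []
    with np.errstate(over="ignore"):
        for b, s, name in zip(beta, se, names):
            z = b / s if s > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            out.append(
                CoxResult(
                    coef=float(b),
                    hr=float(np.exp(b)),
                    ci_low=float(np.exp(b - 1.96 * s)),
                    ci_high=float(np.exp(b + 1.96 * s)),
                    p_wald=float(p),
                    se=float(s),
                    n=n,
                    n_events=n_events,
                    name=name,
                )
            )
    return out


def cox_univariate(x: Sequence[float], surv: SurvivalTable) -> CoxResult:
    """Single-covariate Cox PH fit (Efron ties, Wald inference)."""
    x = np.asarray(x, dtype=float)
    if len(x) != len(surv):
        raise ValueError("covariate length does not match survival table")
    if surv.n_events < 2:
        raise ValueError("need at least two events")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    beta, info, converged = _cox_fit(x, surv.time, surv.event)
    res = _wald_results(beta, info, len(surv), surv.n_events, [None])[0]
    res.converged = converged
    return res


def cox_multivariate(X: pd.DataFrame, surv: SurvivalTable) -> list[CoxResult]:
    """Joint Cox PH fit over several covariates; complete cases only."""
    X = pd.DataFrame(X)
    if len(X) != len(surv):
        raise ValueError("covariate matrix length does not match survival table")
    complete = ~X.isna().any(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} rows with missing covariates")
    Xc = X.loc[complete].to_numpy(dtype=float)
    time = surv.time[complete]
    event = surv.event[complete]
    if event.sum() < Xc.shape[1]:
        raise ValueError("fewer events than covariates")
    centred = Xc - Xc.mean(axis=0)
    if np.linalg.matrix_rank(centred) < Xc.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, info, converged = _cox_fit(Xc, time, event)
    results = _wald_results(beta, info, int(complete.sum()), int(event.sum()), list(X.columns))
    for r in results:
        r.converged = converged
    return results


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit estimate as a step table (time, survival, at_risk)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    rows = []
    surv = 1.0
    n_at_risk = len(t)
    i = 0
    while i < len(t):
        j = i
        while j < len(t) and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            surv *= 1.0 - d / n_at_risk
        rows.append((t[i], surv, n_at_risk))
        n_at_risk -= j - i
        i = j
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk"])


def km_logrank(groups: Sequence, surv: SurvivalTable) -> dict:
    """Log-rank test across >= 2 groups plus per-group KM curves."""
    groups = np.asarray(groups)
    if len(groups) != len(surv):
        raise ValueError("group labels do not match survival table")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    res = multivariate_logrank_test(surv.time, groups, surv.event)
    curves = {
        str(lab): km_curve(surv.time[groups == lab], surv.event[groups == lab])
        for lab in labels
    }
    return {
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
        "df": len(labels) - 1,
        "curves": curves,
    }


# ---------------------------------------------------------------------------
# concordance


def harrell_c(score: Sequence[float], surv: SurvivalTable) -> ConcordanceResult:
    """Harrell's C by direct pair enumeration.

    Usable pairs are (i, j) with t_i < t_j and event_i = 1; higher scores are
    riskier; tied scores contribute one half.
    """
    score = np.asarray(score, dtype=float)
    if len(score) != len(surv):
        raise ValueError("score length does not match survival table")
    t = surv.time
    e = surv.event
    usable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    conc = usable & (score[:, None] > score[None, :])
    tied = usable & (score[:, None] == score[None, :])
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    n_conc = int(conc.sum())
    n_tied = int(tied.sum())
    return ConcordanceResult(
        c=(n_conc + 0.5 * n_tied) / n_usable,
        n_usable=n_usable,
        n_concordant=n_conc,
        n_tied=n_tied,
    )


# ---------------------------------------------------------------------------
# multiple testing, correlation, DEG concordance


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_test(x: Sequence[float], y: Sequence[float]) -> dict:
    """Spearman rank correlation with midrank ties.

    Two-sided p-value: exact permutation enumeration for n <= 10, otherwise
    the usual t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > 10:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        # exact two-sided permutation distribution of |rho|
        from itertools import permutations

        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        obs = abs((rx_c * ry_c).sum() / denom)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = (rx_c[list(perm)] * ry_c).sum() / denom
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / total
    return {"rho": rho, "p": p}


def _welch_degs(matrix: ExpressionMatrix, labels: Sequence, fdr: float):
    """Per-gene Welch t-test between the two label groups; returns
    (DEG gene set, direction map gene -> +-1 with group2 - group1 sign)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    m1 = labels == groups[0]
    m2 = labels == groups[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least two samples")
    a = matrix.values[:, m1]
    b = matrix.values[:, m2]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        pv = np.asarray(res.pvalue, dtype=float)
    testable = np.isfinite(pv)
    q = np.full(len(pv), np.nan)
    if testable.any():
        q[testable] = bh_fdr(pv[testable])
    sig = testable & (q < fdr)
    direction = np.sign(b.mean(axis=1) - a.mean(axis=1))
    genes = np.array(matrix.gene_ids, dtype=object)
    return set(genes[sig]), {g: int(d) for g, d in zip(genes[sig], direction[sig])}


def deg_concordance(
    matrixA: ExpressionMatrix,
    labelsA: Sequence,
    matrixB: ExpressionMatrix,
    labelsB: Sequence,
    fdr: float = 0.05,
) -> dict:
    """Direction agreement of differential-expression calls in two cohorts.

    Each cohort's DEGs come from per-gene Welch t-tests at BH-FDR < ``fdr``;
    the binomial tail tests whether the shared genes agree in deregulation
    direction more often than fair-coin chance.
    """
    degA, dirA = _welch_degs(matrixA, labelsA, fdr)
    degB, dirB = _welch_degs(matrixB, labelsB, fdr)
    shared = degA & degB
    same = sum(1 for g in shared if dirA[g] == dirB[g])
    p = binomial_consistency_test(len(shared), same) if shared else 1.0
    return {"shared": len(shared), "same_direction": same, "p": p}
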