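"""Statistical layer: nonparametric tests, logistic regression and PCA.

All study variables were treated as non-normal, so the pre/post
comparisons use paired two-tailed Wilcoxon signed-rank tests, group
contrasts use the unpaired two-tailed Wilcoxon rank-sum test, and the
rank-delta vs inflammation association uses Spearman's rho.  The
dichotomous hierarchy outcome (downgraded vs ascended) is modelled with
multiple logistic regression fitted by iteratively reweighted least
squares; the exploratory layer is a PCA on standardized variables.

Conventions (chosen to reproduce the default behavior of the R routines
practitioners in this field use):

* signed-rank test: zero differences dropped, ties mid-ranked; exact null
  distribution by enumeration when the effective n <= 25 and the absolute
  differences are tie-free, otherwise a normal approximation with
  continuity correction;
* rank-sum test: exact enumeration for small tie-free samples, otherwise
  normal approximation with tie and continuity corrections;
* Spearman p-value from the t approximation on n - 2 degrees of freedom;
* logistic outcome coding: 1 = downgraded (delta non-positive),
  0 = ascended — recorded in the fit result;
* PCA on the correlation matrix (variables standardized to zero mean and
  unit variance), loadings signed so each component's largest-magnitude
  loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

EXACT = "exact"
NORMAL_APPROX = "normal_approx_cc"

#: Largest effective sample size for which the exact signed-rank null
#: distribution is enumerated.
EXACT_N_MAX = 25
#: With tied |differences| the null distribution must be enumerated over all
#: 2^n sign patterns of the midranks; affordable up to a herd-sized n.
TIE_EXACT_N_MAX = 14


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    method: str
    n_effective: int
    n_zeros_dropped: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class LogisticFit:
    """Per-term Wald summary of a binomial GLM fitted by IRLS."""

    terms: tuple[str, ...]
    estimate: np.ndarray
    std_error: np.ndarray
    z_value: np.ndarray
    p_value: np.ndarray
    converged: bool
    separated: bool
    n: int
    outcome_coding: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimate,
                "std_error": self.std_error,
                "z_value": self.z_value,
                "p_value": self.p_value,
            },
            index=list(self.terms),
        )

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {
            "estimate": float(self.estimate[i]),
            "std_error": float(self.std_error[i]),
            "z_value": float(self.z_value[i]),
            "p_value": float(self.p_value[i]),
        }


@dataclass(frozen=True)
class PCAResult:
    variables: tuple[str, ...]
    loadings: np.ndarray  # variables x components, columns orthonormal
    eigenvalues: np.ndarray  # non-increasing
    proportion: np.ndarray  # sums to 1
    scores: np.ndarray  # rows x components
    scaling: str = "correlation"
    n_dropped_rows: int = 0


def _has_rank_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def wilcoxon_paired(x, y) -> WilcoxonResult:
    """Paired two-tailed Wilcoxon signed-rank test on x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    n_zeros = int((d == 0).sum())
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, method=EXACT, n_effective=0,
            n_zeros_dropped=n_zeros, degenerate=True,
        )
    ties = _has_rank_ties(np.abs(d))
    if not ties and n_eff <= EXACT_N_MAX:
        res = stats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided", method="exact"
        )
        return WilcoxonResult(
            statistic=float(res.statistic),
            p_value=float(min(res.pvalue, 1.0)),
            method=EXACT,
            n_effective=n_eff,
            n_zeros_dropped=n_zeros,
        )
    if ties and n_eff <= TIE_EXACT_N_MAX:
        # tied |d|: enumerate all 2^n sign patterns of the midranks
        ranks = stats.rankdata(np.abs(d))
        w_obs = float(ranks[d > 0].sum())
        bits = (
            np.arange(2**n_eff)[:, None] >> np.arange(n_eff)[None, :]
        ) & 1
        dist = bits @ ranks
        p = 2 * min(
            float((dist <= w_obs + 1e-12).mean()),
            float((dist >= w_obs - 1e-12).mean()),
        )
        return WilcoxonResult(
            statistic=w_obs,
            p_value=min(p, 1.0),
            method=EXACT,
            n_effective=n_eff,
            n_zeros_dropped=n_zeros,
        )
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative="two-sided",
        method="approx",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=NORMAL_APPROX,
        n_effective=n_eff,
        n_zeros_dropped=n_zeros,
    )


def wilcoxon_unpaired(x, y) -> WilcoxonResult:
    """Unpaired two-tailed Wilcoxon rank-sum (Mann-Whitney) test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    exact_ok = not _has_rank_ties(pooled) and len(pooled) <= 2 * EXACT_N_MAX
    res = stats.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        use_continuity=True,
        method="exact" if exact_ok else "asymptotic",
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=EXACT if exact_ok else NORMAL_APPROX,
        n_effective=len(pooled),
    )


def spearman_corr(x, y) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties; t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        return SpearmanResult(rho=np.nan, p_value=np.nan, n=len(x), degenerate=True)
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=len(x))


def fit_logistic(
    X: pd.DataFrame,
    y,
    *,
    tol: float = 1e-8,
    max_iter: int = 25,
    outcome_coding: str = "1 = downgraded (delta non-positive), 0 = ascended",
) -> LogisticFit:
    """Binomial GLM (logit link) by IRLS, with Wald standard errors.

    ``X`` is the full design matrix including the intercept column.
    Degenerate designs fail loudly: a constant outcome or a rank-deficient
    design raise ``ValueError``.  Quasi-complete separation (all fitted
    probabilities at 0/1) is detected and flagged, not silently reported.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; the logistic model is undefined")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # name the smallest trailing set of columns whose removal restores rank
        collinear = [
            c
            for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy(dtype=float)) == rank
        ]
        raise ValueError(f"design matrix is rank-deficient; collinear terms: {collinear}")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # separation is detected and flagged explicitly below
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
        mu = np.asarray(fit.fittedvalues)
    separated = bool(np.all((mu < 1e-6) | (mu > 1 - 1e-6)))
    z = np.asarray(fit.params) / np.asarray(fit.bse)
    p = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        terms=tuple(X.columns.astype(str)),
        estimate=np.asarray(fit.params, dtype=float),
        std_error=np.asarray(fit.bse, dtype=float),
        z_value=z.astype(float),
        p_value=p.astype(float),
        converged=bool(fit.converged),
        separated=separated,
        n=len(y),
        outcome_coding=outcome_coding,
    )


def logistic_score_permutation(
    X: pd.DataFrame,
    y,
    term: str,
    *,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Permutation test for one logistic-regression term.

    At n = 14 the asymptotic single-term tests are badly calibrated: the
    Wald test is crippled by the Hauck-Donner effect (separation inflates
    the standard error, driving rejections toward zero) while the
    likelihood-ratio and score tests over-reject.  This test instead
    permutes the values of ``term`` across observations and compares Rao
    score statistics (computed at the reduced-model fit, so no refitting
    is needed): under the null hypothesis that the term is independent of
    the outcome and the remaining covariates, the permutation distribution
    is exact at any sample size.

    Returns the observed score statistic, the permutation p-value and the
    number of permutations; coefficient estimates come from
    :func:`fit_logistic`.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if term not in X.columns:
        raise ValueError(f"term {term!r} not in design matrix columns {list(X.columns)}")
    if len(np.unique(y)) < 2:
        return {"statistic": np.nan, "p_value": np.nan, "n_perm": 0}
    x = X[term].to_numpy(dtype=float)
    X0 = X.drop(columns=[term]).to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reduced = sm.GLM(y, X0, family=sm.families.Binomial()).fit(
            maxiter=25, tol=1e-8, scale=1.0
        )
        mu = np.asarray(reduced.fittedvalues)
    w = mu * (1 - mu)
    resid = y - mu
    wx0 = X0 * w[:, None]
    v00_inv = np.linalg.pinv(X0.T @ wx0)

    def score_stat(cols: np.ndarray) -> np.ndarray:
        # cols: (m, n) matrix of candidate covariate vectors
        u = cols @ resid
        vxx = (cols**2) @ w
        vx0 = cols @ wx0  # (m, k0)
        v = vxx - np.einsum("mk,kl,ml->m", vx0, v00_inv, vx0)
        v = np.maximum(v, 1e-300)
        return u**2 / v

    obs = float(score_stat(x[None, :])[0])
    perms = np.stack([rng.permutation(x) for _ in range(n_perm)])
    stats_perm = score_stat(perms)
    p = (1 + int((stats_perm >= obs - 1e-12).sum())) / (n_perm + 1)
    return {"statistic": obs, "p_value": float(p), "n_perm": n_perm}


def pca_standardized(table: pd.DataFrame, *, scaling: str = "correlation") -> PCAResult:
    """PCA with listwise deletion and (by default) unit-variance scaling.

    ``scaling='correlation'`` standardizes every variable before the
    eigen-decomposition, so variables measured in thousands (testosterone,
    pg/mL) do not dominate unitless network scores.  ``'covariance'`` is
    available for sensitivity analysis.
    """
    if scaling not in ("correlation", "covariance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    table = pd.DataFrame(table)
    n_before = len(table)
    table = table.dropna()
    dropped = n_before - len(table)
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("PCA needs >= 2 variables and >= 3 complete rows")
    values = table.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    dead = [c for c, s in zip(table.columns, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    centered = values - values.mean(axis=0)
    z = centered / sd if scaling == "correlation" else centered
    cov = (z.T @ z) / (len(z) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1
    scores = z @ eigvec
    return PCAResult(
        variables=tuple(table.columns.astype(str)),
        loadings=eigvec,
        eigenvalues=eigval,
        proportion=eigval / eigval.sum(),
        scores=scores,
        scaling=scaling,
        n_dropped_rows=dropped,
    )


def group_summary(values) -> dict[str, float]:
    """Median (min; max) plus mean-and-range summary of one group."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    return {
        "n": int(arr.size),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
    }
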