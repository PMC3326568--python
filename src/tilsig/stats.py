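"""Treatment-response association statistics.

2×2 contingency machinery (two-sided Fisher exact test by
probability-mass ordering, odds ratios with Woolf log-intervals and the
Haldane-Anscombe 0.5 correction for zero cells, predictive values),
single-gene upper-quartile response analysis, multivariate logistic
regression fitted by iteratively reweighted least squares, and
validation-style comparisons of signature expression between outcome
groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit, gammaln, logsumexp

from .signature import mann_whitney_test

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "PredictiveMetrics",
    "LogisticModel",
    "build_table",
    "fisher_exact_two_sided",
    "odds_ratio",
    "woolf_ci",
    "associate",
    "predictive_metrics",
    "upper_quartile_gene_analysis",
    "fit_logistic_irls",
    "group_signature_comparison",
]

Z_95 = 1.959964  # N(0,1) quantile for a 95% two-sided interval


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts laid out rows = exposure, columns = outcome:
    a = exposed·positive, b = exposed·negative,
    c = unexposed·positive, d = unexposed·negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("table total must be at least 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def cells(self, haldane: bool = False) -> tuple[float, float, float, float]:
        shift = 0.5 if haldane else 0.0
        return (self.a + shift, self.b + shift, self.c + shift, self.d + shift)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    haldane_corrected: bool
    method: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PredictiveMetrics:
    ppv: float
    npv: float
    accuracy: float
    ppv_fraction: tuple[int, int]
    npv_fraction: tuple[int, int]
    accuracy_fraction: tuple[int, int]


def build_table(
    exposure: pd.Series | dict,
    outcome: pd.Series | dict,
    exposure_positive: str,
    outcome_positive: str,
) -> ContingencyTable2x2:
    """Cross-tabulate paired binary labels into a 2×2 table.

    Pairs with NA in either label are dropped (count logged in the
    table's construction site); a zero row or column margin after NA
    removal is an error because every downstream statistic degenerates.
    """
    exposure = pd.Series(dict(exposure) if not isinstance(exposure, pd.Series) else exposure)
    outcome = pd.Series(dict(outcome) if not isinstance(outcome, pd.Series) else outcome)
    common = exposure.index.intersection(outcome.index)
    exposure = exposure.loc[common]
    outcome = outcome.loc[common]
    keep = exposure.notna() & outcome.notna()
    exposure, outcome = exposure[keep], outcome[keep]
    if len(exposure) == 0:
        raise ValueError("no complete exposure/outcome pairs")
    exp_pos = exposure == exposure_positive
    out_pos = outcome == outcome_positive
    a = int((exp_pos & out_pos).sum())
    b = int((exp_pos & ~out_pos).sum())
    c = int((~exp_pos & out_pos).sum())
    d = int((~exp_pos & ~out_pos).sum())
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("zero margin after NA removal")
    return ContingencyTable2x2(a, b, c, d)


def _log_hypergeom_pmf(k: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(a = k) for tables with row margins (r1, r2), first column c1."""
    n = r1 + r2

    def logC(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    return logC(r1, k) + logC(r2, c1 - k) - logC(n, c1)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by probability-mass ordering.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed the observed table's
    (within 1e-12 relative tolerance); computed in log space.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support.astype(float), r1, r2, c1)
    log_obs = float(logp[support == a][0])
    keep = logp <= log_obs + 1e-12
    return float(min(1.0, math.exp(logsumexp(logp[keep]))))


def odds_ratio(table: ContingencyTable2x2) -> float:
    """(a·d)/(b·c), with the Haldane-Anscombe +0.5 applied to every cell
    when any cell is zero."""
    a, b, c, d = table.cells(haldane=table.has_zero_cell)
    return (a * d) / (b * c)


def woolf_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float]:
    """Woolf logit interval: exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d))."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a, b, c, d = table.cells(haldane=table.has_zero_cell)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z_95 if level == 0.95 else float(sps.norm.ppf(0.5 + level / 2))
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def associate(table: ContingencyTable2x2, level: float = 0.95) -> AssociationResult:
    """Fisher p + OR + Woolf CI bundle for one 2×2 comparison."""
    ci_low, ci_high = woolf_ci(table, level)
    return AssociationResult(
        odds_ratio=odds_ratio(table),
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_sided=fisher_exact_two_sided(table),
        haldane_corrected=table.has_zero_cell,
        method={"p": "fisher-two-sided", "ci": f"woolf-{level:g}"},
    )


def predictive_metrics(table: ContingencyTable2x2) -> PredictiveMetrics:
    """PPV, NPV and accuracy treating exposure as the test-positive call."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("empty test-positive or test-negative margin")
    return PredictiveMetrics(
        ppv=a / (a + b),
        npv=d / (c + d),
        accuracy=(a + d) / table.n,
        ppv_fraction=(a, a + b),
        npv_fraction=(d, c + d),
        accuracy_fraction=(a + d, table.n),
    )


def upper_quartile_gene_analysis(
    matrix, gene: str, outcomes: pd.Series | dict
) -> AssociationResult:
    """Single-gene response association using the upper quartile as the
    expression cut-point (high = strictly above Q3)."""
    outcomes = pd.Series(dict(outcomes) if not isinstance(outcomes, pd.Series) else outcomes)
    outcomes = outcomes.dropna()
    samples = [s for s in matrix.sample_ids if s in outcomes.index]
    if len(samples) < 4:
        raise ValueError("need at least 4 assessed samples")
    values = pd.Series(matrix.subset_samples(samples).row(gene), index=samples)
    q3 = float(np.percentile(values.to_numpy(), 75, method="linear"))
    high = values > q3
    if not high.any():
        raise ValueError(f"upper quartile equals maximum for {gene}: empty high group")
    exposure = high.map({True: "high", False: "low"})
    table = build_table(exposure, outcomes.loc[samples], "high", "pCR")
    return associate(table)


@dataclass
class LogisticModel:
    """Maximum-likelihood logistic fit with Wald inference.

    Odds ratios are exp(coefficient); confidence intervals are
    exp(coefficient ± 1.96·SE).
    """

    params: pd.Series
    bse: pd.Series
    converged: bool
    n_iter: int
    coding: dict = field(default_factory=dict)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def conf_int(self) -> pd.DataFrame:
        low = np.exp(self.params - Z_95 * self.bse)
        high = np.exp(self.params + Z_95 * self.bse)
        return pd.DataFrame({"ci_low": low, "ci_high": high})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * sps.norm.sf(np.abs(z)), index=self.params.index)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "OR": self.odds_ratios,
                "p": self.pvalues,
            }
        )
        return out.join(self.conf_int)


def fit_logistic_irls(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    add_intercept: bool = True,
    coding: dict | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    separation_bound: float = 15.0,
) -> LogisticModel:
    """Fit logistic regression by iteratively reweighted least squares.

    Converges when the largest absolute coefficient change drops below
    ``tol`` (or after ``max_iter`` iterations); Wald standard errors come
    from the inverse observed information.  Coefficients wandering past
    ``separation_bound`` in absolute value indicate (quasi-)separation
    and the result is flagged non-converged rather than reported silently.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if yv.min() == yv.max():
        raise ValueError("both outcome classes must be present")
    if add_intercept:
        Xv = np.column_stack([np.ones(len(yv)), Xv])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear columns)")

    beta = np.zeros(Xv.shape[1])
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xv @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (yv - mu) / w
        WX = Xv * w[:, None]
        beta_new = np.linalg.solve(Xv.T @ WX, Xv.T @ (w * z))
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > separation_bound:
            separated = True
            break
        if delta < tol:
            converged = True
            break
    mu = expit(Xv @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = Xv.T @ (Xv * w[:, None])
    cov = np.linalg.inv(info)
    bse = np.sqrt(np.diag(cov))
    return LogisticModel(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        converged=converged and not separated,
        n_iter=it,
        coding=coding or {},
    )


def group_signature_comparison(
    matrix, genes: list[str] | tuple[str, ...], groups: pd.Series | dict
) -> tuple[pd.DataFrame, float]:
    """Validation-cohort style comparison between two outcome groups.

    Returns per-gene mean expression in each group and the two-sided
    Mann-Whitney p comparing the per-sample mean signature score between
    the groups.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    samples = [s for s in matrix.sample_ids if s in groups.index]
    sub = matrix.subset_samples(samples).data.loc[list(genes)]
    membership = groups.loc[samples]
    means = pd.DataFrame(
        {level: sub.loc[:, membership == level].mean(axis=1) for level in levels}
    )
    score = sub.mean(axis=0)
    g0 = score[membership == levels[0]].to_numpy()
    g1 = score[membership == levels[1]].to_numpy()
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("one group is empty")
    _, p = mann_whitney_test(g0, g1)
    return means, float(p)
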