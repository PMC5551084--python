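"""Statistical layer: t-tests, one-way ANOVA, and OLS error models.

Three linear error models relate the per-quadrat measurement standard error
sigma_SR to its plausible drivers:

* ``coverage``:            sigma_SR ~ avg_coverage + coverage_variation
* ``rugosity``:            sigma_SR ~ SR
* ``rugosity+morphotype``: sigma_SR ~ SR + C(morphotype), treatment-coded
  against the "Mixed" base category, so each coral-morphotype coefficient is
  an additive offset to the Mixed error level at fixed rugosity.

Fits go through statsmodels OLS; the t and F statistics through scipy. All
p-values are two-tailed and no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MIXED, MODEL_LEVELS
from .errors import (
    AlignmentError,
    CollinearityError,
    InsufficientReplicationError,
    ParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "TTestResult",
    "AnovaResult",
    "OLSTerm",
    "OLSModel",
    "one_sample_t",
    "paired_t",
    "oneway_anova",
    "fit_error_model",
    "FORMULAS",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class AnovaResult:
    """One-way ANOVA. ``df_within`` is the textbook N - k used for the
    p-value; ``df_display`` mirrors the (k-1, N-1) convention some reports
    quote alongside F."""

    F: float
    df_between: int
    df_within: int
    p: float

    @property
    def df_display(self) -> tuple[int, int]:
        # N - 1 = (N - k) + (k - 1)
        return (self.df_between, self.df_within + self.df_between)


@dataclass
class OLSTerm:
    name: str
    coef: float
    se: float
    p: float


@dataclass
class OLSModel:
    """A fitted OLS error model: per-term coefficient/SE/p plus fit summary."""

    terms: dict[str, OLSTerm]
    adj_r2: float
    n_obs: int
    residual_df: int
    contrast: str = ""
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)
    residuals: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    design: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.name, t.coef, t.se, t.p) for t in self.terms.values()],
            columns=["term", "coef", "se", "p"],
        )


def one_sample_t(values, reference: float) -> TTestResult:
    """Two-tailed one-sample t-test of mean(values) against a fixed reference.

    The sample sd uses the n-1 denominator; df = n - 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientReplicationError("need n >= 2 for a t-test")
    if np.ptp(values) == 0 and values[0] == reference:
        return TTestResult(0.0, values.size - 1, 1.0)
    if np.ptp(values) == 0:
        raise UndefinedStatisticError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(values, reference)
    return TTestResult(float(res.statistic), int(values.size - 1), float(res.pvalue))


def paired_t(a, b) -> TTestResult:
    """Two-tailed paired t-test: one-sample t on the differences a - b vs 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    return one_sample_t(a - b, 0.0)


def oneway_anova(groups) -> AnovaResult:
    """One-way ANOVA across >= 2 groups of values.

    ``groups`` is a sequence of 1-D arrays, or a mapping label -> values
    (e.g. per-survey delta_SR samples). Standard between/within decomposition;
    p from F(k-1, N-k).
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientReplicationError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise InsufficientReplicationError("every ANOVA group needs >= 2 values")
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    res = stats.f_oneway(*arrays)
    return AnovaResult(
        F=float(res.statistic),
        df_between=k - 1,
        df_within=n - k,
        p=float(res.pvalue),
    )


FORMULAS = ("coverage", "rugosity", "rugosity+morphotype")

_COLMAP = {
    "sigma": "sigma",
    "sr": "mu",
    "avg_coverage": "avg_coverage",
    "coverage_variation": "coverage_variation",
    "morphotype": "morphotype",
}


def _design(table: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["Intercept"]
    if formula == "coverage":
        for c in ("avg_coverage", "coverage_variation"):
            cols.append(table[c].to_numpy(dtype=float))
        names += ["avg_coverage", "coverage_variation"]
    elif formula in ("rugosity", "rugosity+morphotype"):
        cols.append(table["mu"].to_numpy(dtype=float))
        names.append("rugosity")
        if formula == "rugosity+morphotype":
            labels = table["morphotype"].astype(str)
            bad = set(labels) - set(MODEL_LEVELS)
            if bad:
                raise ParameterError(
                    f"morphotype labels {sorted(bad)} not in model levels {MODEL_LEVELS}"
                )
            for level in MODEL_LEVELS:
                if level == MIXED:
                    continue  # base category absorbed by the intercept
                cols.append((labels == level).to_numpy(dtype=float))
                names.append(f"type[{level}]")
    else:
        raise ParameterError(f"unknown formula {formula!r}; use one of {FORMULAS}")
    return np.column_stack(cols), names


def fit_error_model(table: pd.DataFrame, formula: str = "rugosity") -> OLSModel:
    """Fit one of the three OLS error models to a merged quadrat table.

    ``table`` needs columns ``sigma`` (response) plus, depending on formula,
    ``mu`` (quadrat mean or true SR), ``avg_coverage``/``coverage_variation``,
    and ``morphotype`` (labels from :data:`MODEL_LEVELS`; treatment coding
    with "Mixed" as base). Raises :class:`CollinearityError` on rank-deficient
    designs, naming the offending terms.
    """
    import statsmodels.api as sm

    if "sigma" not in table.columns:
        raise ParameterError("table needs a 'sigma' response column")
    X, names = _design(table, formula)
    y = table["sigma"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns that add no rank
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise CollinearityError(f"design is rank-deficient; collinear term(s): {bad}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    terms = {
        name: OLSTerm(name, float(c), float(s), float(p))
        for name, c, s, p in zip(names, fit.params, fit.bse, fit.pvalues)
    }
    return OLSModel(
        terms=terms,
        adj_r2=float(fit.rsquared_adj) if X.shape[1] > 1 else float("nan"),
        n_obs=int(fit.nobs),
        residual_df=int(fit.df_resid),
        contrast=f"treatment coding, base category {MIXED!r}"
        if formula == "rugosity+morphotype"
        else "",
        conf_int={name: (float(lo), float(hi)) for name, (lo, hi) in zip(names, ci)},
        residuals=np.asarray(fit.resid),
        design=X,
    )
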