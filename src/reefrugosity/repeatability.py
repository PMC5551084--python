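"""Precision and bias of rugosity measurements from repeated co-registered surveys.

Given per-quadrat SR measurements from N_survey repeats of the same site (all
registered to a common frame, so quadrat ids align), the error statistics are

    mu_j     = (1/N) * sum_i SR_ji          mean SR of quadrat j
    delta_ji = SR_ji - mu_j                 deviation of survey i at quadrat j
    sigma_j  = sqrt((1/N) * sum_i delta_ji^2)   quadrat measurement standard error
    b_i      = (1/N_quad) * sum_j delta_ji      per-survey bias

sigma_j uses the population denominator N (a flag offers N-1). Deltas are
centred by construction, so per-quadrat deltas and per-group survey biases sum
to zero at machine precision.

Surveys are grouped as ``single_day`` (back-to-back repeats, similar ambient
conditions) versus ``multi_day`` (repeats across days, varying lighting and
water clarity); statistics are computed per group. Site-level summaries
express the mean sigma and the RMS of the b_i as percentages of the observed
SR range at the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    InsufficientReplicationError,
    ParameterError,
    UndefinedStatisticError,
)

__all__ = [
    "GROUPS",
    "SurveySet",
    "QuadratErrorSummary",
    "SurveyBias",
    "SiteErrorReport",
    "summarize_quadrat",
    "quadrat_summaries",
    "survey_bias",
    "group_errors",
    "site_report",
]

logger = logging.getLogger(__name__)

GROUPS = ("single_day", "multi_day")


@dataclass
class SurveySet:
    """Repeated SR measurements of one site at one link size.

    ``measurements`` is tidy with columns (survey_id, quadrat_id, sr);
    ``manifest`` has one row per survey with columns (survey_id, group) and
    optionally date. Groups must be drawn from :data:`GROUPS`.
    """

    site_id: str
    measurements: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"survey_id", "quadrat_id", "sr"}
        if not need.issubset(self.measurements.columns):
            raise ParameterError(f"measurements needs columns {sorted(need)}")
        if not {"survey_id", "group"}.issubset(self.manifest.columns):
            raise ParameterError("manifest needs columns survey_id, group")
        bad = set(self.manifest["group"]) - set(GROUPS)
        if bad:
            raise ParameterError(f"unknown survey group(s) {sorted(bad)}; use {GROUPS}")

    def surveys_in_group(self, group: str) -> list:
        if group not in GROUPS:
            raise ParameterError(f"unknown group {group!r}; use {GROUPS}")
        return list(self.manifest.loc[self.manifest["group"] == group, "survey_id"])

    def wide(self, group: str | None = None) -> pd.DataFrame:
        """Quadrat-by-survey SR matrix (complete cases only).

        Quadrats missing from any survey of the selection are dropped (logged),
        so every statistic is computed on a shared quadrat set.
        """
        df = self.measurements
        if group is not None:
            ids = self.surveys_in_group(group)
            if len(ids) < 2:
                raise InsufficientReplicationError(
                    f"group {group!r} has {len(ids)} survey(s); need >= 2"
                )
            df = df[df["survey_id"].isin(ids)]
        dup = df.duplicated(["survey_id", "quadrat_id"])
        if dup.any():
            raise AlignmentError(
                "duplicate (survey, quadrat) measurements: "
                f"{df.loc[dup, ['survey_id', 'quadrat_id']].values.tolist()}"
            )
        wide = df.pivot(index="quadrat_id", columns="survey_id", values="sr")
        complete = wide.dropna()
        n_drop = len(wide) - len(complete)
        if n_drop:
            dropped = sorted(set(wide.index) - set(complete.index))
            logger.info(
                "dropping %d quadrat(s) missing from some survey: %s", n_drop, dropped
            )
        if complete.shape[1] < 2:
            raise InsufficientReplicationError("need >= 2 surveys for error estimation")
        if complete.empty:
            raise AlignmentError("no quadrat is present in every selected survey")
        return complete


@dataclass
class QuadratErrorSummary:
    """mu, deltas and sigma for one quadrat (population-form sigma by default)."""

    quadrat_id: int
    mu: float
    deltas: np.ndarray
    sigma: float


@dataclass
class SurveyBias:
    """Per-survey bias b_i: mean delta across quadrats for survey i."""

    survey_id: object
    b: float


@dataclass
class SiteErrorReport:
    """Site-level error summary as percentages of the observed SR range."""

    site_id: str
    group: str
    mean_sigma: float
    rms_bias: float
    sr_range: float
    sigma_pct_of_range: float
    bias_pct_of_range: float
    n_quadrats: int = 0
    n_surveys: int = 0
    extras: dict = field(default_factory=dict)


def summarize_quadrat(
    srs, quadrat_id: int = 0, unbiased: bool = False
) -> QuadratErrorSummary:
    """mu, deltas, sigma for one quadrat's repeated SR values.

    ``unbiased=True`` switches the sigma denominator from N to N-1.
    """
    srs = np.asarray(srs, dtype=float)
    if srs.size < 2:
        raise InsufficientReplicationError("need >= 2 surveys per quadrat")
    mu = float(srs.mean())
    deltas = srs - mu
    denom = srs.size - 1 if unbiased else srs.size
    sigma = float(np.sqrt((deltas**2).sum() / denom))
    return QuadratErrorSummary(int(quadrat_id), mu, deltas, sigma)


def quadrat_summaries(
    sset: SurveySet, group: str | None = None, unbiased: bool = False
) -> pd.DataFrame:
    """Per-quadrat (mu, sigma) table for the selected surveys.

    Columns: quadrat_id, mu, sigma, n_surveys.
    """
    wide = sset.wide(group)
    vals = wide.to_numpy()
    mu = vals.mean(axis=1)
    deltas = vals - mu[:, None]
    denom = vals.shape[1] - 1 if unbiased else vals.shape[1]
    sigma = np.sqrt((deltas**2).sum(axis=1) / denom)
    return pd.DataFrame(
        {
            "quadrat_id": wide.index.to_numpy(),
            "mu": mu,
            "sigma": sigma,
            "n_surveys": vals.shape[1],
        }
    )


def survey_bias(sset: SurveySet, group: str | None = None) -> list[SurveyBias]:
    """Per-survey biases b_i over the selected surveys; sum_i b_i = 0."""
    wide = sset.wide(group)
    deltas = wide.to_numpy() - wide.to_numpy().mean(axis=1, keepdims=True)
    b = deltas.mean(axis=0)
    return [SurveyBias(sid, float(bi)) for sid, bi in zip(wide.columns, b)]


def group_errors(sset: SurveySet, group: str) -> pd.DataFrame:
    """Per-quadrat sigma computed from only one group's surveys."""
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}; use {GROUPS}")
    return quadrat_summaries(sset, group=group)


def site_report(
    sset: SurveySet,
    group: str | None = None,
    range_scope: str = "pooled",
    unbiased: bool = False,
) -> SiteErrorReport:
    """Mean sigma and RMS per-survey bias as percentages of the observed range.

    ``range_scope``:

    * ``"pooled"`` (default): range = max - min of every quadrat-survey SR
      value at the site, across all groups.
    * ``"group"``: range over the selected group's values only.
    * ``"quadrat_means"``: range of the per-quadrat mean SR.
    """
    summ = quadrat_summaries(sset, group=group, unbiased=unbiased)
    biases = survey_bias(sset, group=group)
    b = np.array([x.b for x in biases])
    rms_bias = float(np.sqrt((b**2).mean()))
    mean_sigma = float(summ["sigma"].mean())

    if range_scope == "pooled":
        vals = sset.measurements["sr"].to_numpy(dtype=float)
    elif range_scope == "group":
        vals = sset.wide(group).to_numpy().ravel()
    elif range_scope == "quadrat_means":
        vals = summ["mu"].to_numpy()
    else:
        raise ParameterError(f"unknown range_scope {range_scope!r}")
    sr_range = float(np.nanmax(vals) - np.nanmin(vals))
    if sr_range <= 0:
        raise UndefinedStatisticError("observed SR range is zero; percentages undefined")
    return SiteErrorReport(
        site_id=sset.site_id,
        group=group or "all",
        mean_sigma=mean_sigma,
        rms_bias=rms_bias,
        sr_range=sr_range,
        sigma_pct_of_range=100.0 * mean_sigma / sr_range,
        bias_pct_of_range=100.0 * rms_bias / sr_range,
        n_quadrats=int(len(summ)),
        n_surveys=int(summ["n_surveys"].iloc[0]) if len(summ) else 0,
    )
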