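"""The network survival estimator: reported deaths, death counts and rates.

For a demographic group ``a`` the estimator chains three design-weighted
quantities:

* reported deaths  ``y_hat = sum_{i in s} y_i,Da * w_i``  — a
  Horvitz-Thompson total of every respondent's reports about deaths of
  members of ``a`` (respondents of every group report about any decedent
  group);
* average personal network size ``dbar_hat`` of group ``a`` respondents
  (see :mod:`netsurvival.degree`), which stands in for the average number
  of times each death would be reported under the decedent-network and
  accurate-reporting conditions;
* exposure ``N_hat = sum_{i in s_a} w_i`` — the design-weight total of the
  group's respondents, valid when the sampling frame is complete for ``a``.

The death count is ``D_hat = y_hat / dbar_hat`` and the death rate is
``M_hat = y_hat / (dbar_hat * N_hat)``, scaled to an annual rate when the
recall window is not 12 months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from netsurvival.data import KnownPopulationRegistry, RateEstimate, SurveySample
from netsurvival.degree import estimate_avg_degree
from netsurvival.errors import EstimationError
from netsurvival.groups import AgeSchedule, DemographicGroup, DEFAULT_ADULT_SCHEDULE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeathTotalEstimate:
    """All intermediate quantities behind one group's death rate."""

    group: DemographicGroup
    y_hat: float
    dbar: float
    d_hat: float
    n_hat: float
    m_hat: float


def estimate_reported_deaths(sample: SurveySample, group: DemographicGroup) -> float:
    """Design-weighted total of reports about deaths in ``group``.

    Reports missing the decedent's sex or age contribute only to groups
    that do not restrict the missing dimension.
    """
    counts = sample.report_counts(group)
    total = float(np.dot(counts, sample.weights))
    if total == 0:
        logger.debug("no reported deaths for group %s", group.label)
    return total


def estimate_exposure(sample: SurveySample, group: DemographicGroup) -> float:
    """Design-weighted count of frame members in ``group`` (persons).

    Requires the frame to be complete for the group: every member of the
    group must have been eligible for sampling.
    """
    mask = sample.group_mask(group)
    return float(np.sum(sample.weights[mask]))


def estimate_num_deaths(
    sample: SurveySample,
    registry: KnownPopulationRegistry,
    group: DemographicGroup,
    n_falpha: Union[float, str] = "estimate",
) -> float:
    """Estimated number of deaths in ``group``: reported deaths over degree."""
    y_hat = estimate_reported_deaths(sample, group)
    if y_hat == 0:
        return 0.0
    dbar = estimate_avg_degree(sample, registry, group, n_falpha=n_falpha).dbar
    if dbar == 0:
        raise EstimationError(
            f"average degree estimate is zero for group {group.label}; the death "
            "count is undefined — review the known-population responses and run "
            "a sensitivity analysis before interpreting any estimate"
        )
    return y_hat / dbar


def estimate_death_rate(
    sample: SurveySample,
    registry: KnownPopulationRegistry,
    group: DemographicGroup,
    n_falpha: Union[float, str] = "estimate",
    window_months: float = 12.0,
) -> RateEstimate:
    """Point estimate of the group's death rate (deaths per person-year).

    With internally estimated group sizes the exposure cancels against the
    degree estimator's group-size factor, so the rate reduces to
    ``y_hat * sum_j N_j / (y_hat_known * N_F)`` and is invariant to a common
    rescaling of all weights.  Uncertainty is added by
    :func:`netsurvival.bootstrap.bootstrap_estimate`.
    """
    totals = estimate_totals(sample, registry, group, n_falpha=n_falpha, window_months=window_months)
    n_reports = int(sample.report_counts(group).sum())
    return RateEstimate(point=totals.m_hat, n_contributing=n_reports)


def estimate_totals(
    sample: SurveySample,
    registry: KnownPopulationRegistry,
    group: DemographicGroup,
    n_falpha: Union[float, str] = "estimate",
    window_months: float = 12.0,
) -> DeathTotalEstimate:
    """Compute every intermediate quantity behind one group's death rate."""
    y_hat = estimate_reported_deaths(sample, group)
    n_hat = estimate_exposure(sample, group)
    if n_hat == 0:
        raise EstimationError(f"zero estimated exposure for group {group.label}; rate undefined")
    dbar = estimate_avg_degree(sample, registry, group, n_falpha=n_falpha).dbar
    if dbar == 0:
        raise EstimationError(f"zero degree estimate for group {group.label}; rate undefined")
    d_hat = y_hat / dbar
    # persons ~ person-years for a 12-month recall window; shorter or longer
    # windows scale the annualized rate accordingly
    m_hat = d_hat / (n_hat * window_months / 12.0)
    return DeathTotalEstimate(group=group, y_hat=y_hat, dbar=dbar, d_hat=d_hat, n_hat=n_hat, m_hat=m_hat)


def deaths_per_interview(
    sample: SurveySample,
    weighted: bool = False,
    arm: Optional[str] = None,
) -> float:
    """Mean number of death reports per respondent, optionally by study arm."""
    if arm is not None:
        sample = sample.filter_arm(arm)
    counts = sample.report_counts(DemographicGroup())
    if weighted:
        return float(np.dot(counts, sample.weights) / np.sum(sample.weights))
    return float(np.mean(counts))


def rate_table(
    sample: SurveySample,
    registry: KnownPopulationRegistry,
    schedule: AgeSchedule = DEFAULT_ADULT_SCHEDULE,
    sexes: tuple[str, ...] = ("female", "male"),
    n_falpha: Union[float, str] = "estimate",
    window_months: float = 12.0,
) -> pd.DataFrame:
    """One row per (sex, age band): y_hat, dbar, D_hat, N_hat, M_hat."""
    rows = []
    for sex in sexes:
        for band in schedule:
            group = DemographicGroup(sex, band)
            try:
                t = estimate_totals(
                    sample, registry, group, n_falpha=n_falpha, window_months=window_months
                )
                rows.append(
                    {
                        "sex": sex,
                        "age_band": band.label,
                        "y_hat": t.y_hat,
                        "dbar": t.dbar,
                        "d_hat": t.d_hat,
                        "n_hat": t.n_hat,
                        "m_hat": t.m_hat,
                        "error": "",
                    }
                )
            except EstimationError as exc:
                rows.append(
                    {
                        "sex": sex,
                        "age_band": band.label,
                        "y_hat": np.nan,
                        "dbar": np.nan,
                        "d_hat": np.nan,
                        "n_hat": np.nan,
                        "m_hat": np.nan,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
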