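"""Average personal network size from known-population responses.

The known-population approach calibrates reported connection counts against
groups whose total size is known from external records: if respondents in a
demographic group report many connections to (say) teachers, and the number
of teachers is known, the group's average personal network size can be
estimated.  The group-level estimator used here is

    dbar_hat = [ sum_{i in s_a} sum_j y_ij * w_i / sum_j N_j ] * N_F / N_Fa

where ``y_ij`` is respondent i's reported connections to known population j,
``N_j`` that population's size, ``N_F`` the frame-population size and
``N_Fa`` the size of the demographic group within the frame (either supplied
externally or estimated from the design weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from netsurvival.data import KnownPopulationRegistry, SurveySample
from netsurvival.errors import EstimationError
from netsurvival.groups import DemographicGroup

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DegreeEstimate:
    """Estimated average connections from group members to the frame population."""

    group: DemographicGroup
    dbar: float
    n_respondents: int

    def __post_init__(self) -> None:
        if self.dbar < 0:
            raise EstimationError("average degree estimate must be nonnegative")


def _complete_kp_rows(sample: SurveySample, registry: KnownPopulationRegistry, mask: np.ndarray):
    """Mask of group respondents with a complete set of known-pop answers.

    Respondents missing any known-population item are dropped from degree
    estimation (and counted in the log); a partially answered battery would
    otherwise bias the calibration downward.
    """
    kp = sample.known_pop_matrix(registry.names)
    complete = ~np.isnan(kp).any(axis=1)
    dropped = int(np.sum(mask & ~complete))
    if dropped:
        logger.info("degree estimation: dropped %d respondents with missing known-pop items", dropped)
    return kp, mask & complete


def estimate_avg_degree(
    sample: SurveySample,
    registry: KnownPopulationRegistry,
    group: DemographicGroup = DemographicGroup(),
    n_falpha: Union[float, str] = "estimate",
) -> DegreeEstimate:
    """Estimate the group's average personal network size.

    ``n_falpha`` is either an externally supplied group size ``N_Fa`` or the
    token ``"estimate"``, in which case the design-weight total of the
    group's respondents is used.  The default keeps the composed death-rate
    estimator internally consistent: the group-size factor then cancels
    against the exposure term.
    """
    mask = sample.group_mask(group)
    if not mask.any():
        raise EstimationError(f"no respondents in group {group.label}")
    total_known = registry.total_size
    if total_known <= 0:
        raise ValueError("total known-population size must be positive")
    kp, used = _complete_kp_rows(sample, registry, mask)
    w = sample.weights
    numerator = float(np.sum(kp[used].sum(axis=1) * w[used]))
    if n_falpha == "estimate":
        n_fa = float(np.sum(w[mask]))
    else:
        n_fa = float(n_falpha)
        if not n_fa > 0:
            raise ValueError(f"n_falpha must be positive, got {n_fa}")
    dbar = (numerator / total_known) * (sample.frame_total / n_fa)
    return DegreeEstimate(group=group, dbar=dbar, n_respondents=int(used.sum()))


def holdout_known_population_check(
    sample: SurveySample,
    registry: KnownPopulationRegistry,
    held_out: str,
) -> tuple[float, int]:
    """Internal-consistency diagnostic: re-estimate one known population's size.

    The held-out group's size is estimated from the remaining groups as

        N_hat = [ sum_i y_i,held * w_i / sum_i sum_{j!=held} y_ij * w_i ]
                * sum_{j!=held} N_j

    and returned together with the registry size.  Large discrepancies point
    at reporting problems for that group (or for the battery as a whole).
    """
    if len(registry.entries) < 2:
        raise ValueError("holdout check requires at least two known populations")
    if held_out not in registry.names:
        raise ValueError(f"{held_out!r} is not in the registry")
    names = list(registry.names)
    j_held = names.index(held_out)
    kp = sample.known_pop_matrix(names)
    complete = ~np.isnan(kp).any(axis=1)
    w = sample.weights
    num = float(np.sum(kp[complete, j_held] * w[complete]))
    rest = np.delete(kp[complete], j_held, axis=1)
    den = float(np.sum(rest.sum(axis=1) * w[complete]))
    if den == 0:
        raise EstimationError(
            f"holdout diagnostic undefined for {held_out!r}: no reported "
            "connections to the remaining known populations"
        )
    rest_total = registry.total_size - registry.sizes[held_out]
    return num / den * rest_total, registry.sizes[held_out]
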