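"""Rao-Wu rescaled bootstrap for stratified multistage cluster designs.

Within each stratum ``h`` containing ``n_h`` sampled primary sampling
units, a replicate draws ``n_h - 1`` PSUs with replacement; every
respondent's weight is multiplied by ``(n_h / (n_h - 1)) * r_hi``, where
``r_hi`` counts how often the respondent's PSU was drawn.  The multiplier
has expectation 1, so replicate weights are unbiased for the original
weights, and resampling ``n_h - 1`` units makes the replicate variance of
a total match the textbook with-replacement variance estimator for the
first sampling stage.  Intervals are equal-tailed percentile intervals of
the replicate distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from netsurvival.data import RateEstimate, SurveySample
from netsurvival.errors import DesignError, InstabilityError, NetSurvivalError
from netsurvival.groups import DemographicGroup  # noqa: F401  (re-exported convenience)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReplicateWeights:
    """One bootstrap replicate's weight per respondent."""

    replicate_id: int
    weights: np.ndarray


def _design_structure(sample: SurveySample):
    """Per-stratum PSU membership: list of (stratum, [index arrays per PSU])."""
    if "design_structure" in sample._cache:
        return sample._cache["design_structure"]
    strata = sample.strata
    psus = sample.psus
    structure = []
    for stratum in dict.fromkeys(strata):  # preserves first-appearance order
        s_idx = np.flatnonzero(strata == stratum)
        psu_groups = []
        for psu in dict.fromkeys(psus[s_idx]):
            psu_groups.append(s_idx[psus[s_idx] == psu])
        structure.append((stratum, psu_groups))
    sample._cache["design_structure"] = structure
    return structure


def rescaled_replicate(
    sample: SurveySample,
    rng_seed: Union[int, np.random.Generator],
    replicate_id: int = 0,
) -> ReplicateWeights:
    """Draw one rescaled-bootstrap replicate weight set.

    Requires every stratum to contain at least two sampled PSUs; a stratum
    with a single PSU contributes no estimable first-stage variance and is
    reported rather than silently collapsed.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    structure = _design_structure(sample)
    factors = np.zeros(sample.n)
    for stratum, psu_groups in structure:
        n_h = len(psu_groups)
        if n_h < 2:
            raise DesignError(
                f"stratum {stratum!r} has a single PSU; the rescaled bootstrap "
                "requires at least two PSUs per stratum"
            )
        draws = rng.integers(0, n_h, size=n_h - 1)
        counts = np.bincount(draws, minlength=n_h)
        scale = n_h / (n_h - 1)
        for i, idx in enumerate(psu_groups):
            factors[idx] = scale * counts[i]
    return ReplicateWeights(replicate_id=replicate_id, weights=sample.weights * factors)


def bootstrap_estimate(
    sample: SurveySample,
    statistic: Callable[[SurveySample], float],
    B: int,
    seed: Union[int, np.random.Generator],
    level: float = 0.95,
) -> RateEstimate:
    """Bootstrap a statistic of the survey under the complex design.

    ``statistic`` receives a sample view carrying replicate weights (some
    of them zero) and must return a scalar.  Replicates on which the
    statistic raises an estimation error are dropped; if more than half
    fail, the bootstrap is declared unstable.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    point = float(statistic(sample))
    replicates = np.empty(B)
    failures = 0
    for b in range(B):
        rw = rescaled_replicate(sample, rng, replicate_id=b)
        try:
            replicates[b] = float(statistic(sample.with_weights(rw.weights)))
        except (NetSurvivalError, ZeroDivisionError, FloatingPointError) as exc:
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
            replicates[b] = math.nan
            failures += 1
    if failures > B / 2:
        raise InstabilityError(
            f"statistic undefined on {failures}/{B} bootstrap replicates; the "
            "estimate is too unstable for interval construction"
        )
    valid = replicates[np.isfinite(replicates)]
    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.percentile(valid, [100 * alpha, 100 * (1 - alpha)])
    return RateEstimate(
        point=point,
        replicates=tuple(replicates),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_contributing=int(valid.size),
    )
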