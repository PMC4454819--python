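"""Effect-concentration estimation, hazard ranking and rank correlation.

Many materials in a first-pass screen never reach a 50 % integrated effect at
the highest tested dose, so sigmoidal regression is deliberately avoided.
Instead the effect concentration ECx (the concentration at which the weighted
EZ score crosses a target ``x``) is obtained by linear interpolation of the
score against log10 concentration between the first adjacent pair of
treatment points that straddles the target.  Profiles whose maximum score
stays below the target are reported as ``not_reached``; profiles already at
or above the target at the lowest tested dose are reported ``below_range``
with the lowest concentration as a conservative upper bound.  No
extrapolation is ever performed.

Materials are hazard-ranked most-toxic-first: those with an EC50 estimate
come before those ranked only by the fallback EC at score 0.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .ez_scoring import ConcentrationProfile, EZScore

__all__ = [
    "ECEstimate",
    "RankEntry",
    "HazardRanking",
    "SpearmanResult",
    "estimate_ec",
    "rank_hazard",
    "spearman",
]


@dataclass(frozen=True)
class ECEstimate:
    """Interpolated effect concentration for one material.

    status
        ``reached``: the profile crosses the target between two treatment
        points, ``value`` interpolated on log10 concentration.
        ``below_range``: already at/above target at the lowest treatment
        dose; ``value`` is that lowest concentration (an upper bound).
        ``not_reached``: the profile never attains the target; ``value`` is
        ``None``.
    """

    material_id: str
    target_score: float
    value: float | None
    status: str
    bracket: tuple[EZScore, EZScore] | None = None


class RankEntry(NamedTuple):
    material_id: str
    criterion: str  # "EC50" or "EC0.1"
    value: float


@dataclass(frozen=True)
class HazardRanking:
    """Materials ordered most toxic first; see :func:`rank_hazard`."""

    entries: tuple[RankEntry, ...]
    unranked: tuple[str, ...] = ()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, columns=["material_id", "criterion", "value_ppm"])


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    n: int


def estimate_ec(profile: ConcentrationProfile, target_score: float) -> ECEstimate:
    """Interpolate the concentration at which the EZ score reaches a target.

    Treatment points are scanned in ascending concentration for the first
    adjacent pair ``(c_j, c_j+1)`` with ``score_j < t <= score_j+1``; the
    estimate is ``10**x`` with ``x`` linearly interpolating ``t`` between
    ``(log10 c_j, score_j)`` and ``(log10 c_j+1, score_j+1)``.  The control
    point is never used (log10 of 0 is undefined).
    """
    if not 0 < target_score < 1:
        raise ValidationError(f"target score must be in (0, 1), got {target_score}")
    pts = profile.treatment_points
    if any(not math.isfinite(p.score) for p in pts):
        raise ValidationError(f"profile {profile.material_id}: non-finite score")
    t = target_score
    if pts[0].score >= t:
        return ECEstimate(
            material_id=profile.material_id,
            target_score=t,
            value=pts[0].concentration,
            status="below_range",
        )
    for lo, hi in zip(pts, pts[1:]):
        if lo.score < t <= hi.score:
            x_lo, x_hi = math.log10(lo.concentration), math.log10(hi.concentration)
            frac = (t - lo.score) / (hi.score - lo.score)
            value = 10 ** (x_lo + frac * (x_hi - x_lo))
            return ECEstimate(
                material_id=profile.material_id,
                target_score=t,
                value=value,
                status="reached",
                bracket=(lo, hi),
            )
    return ECEstimate(
        material_id=profile.material_id, target_score=t, value=None, status="not_reached"
    )


def rank_hazard(
    estimates: Mapping[str, tuple[ECEstimate, ECEstimate]],
) -> HazardRanking:
    """Rank materials most toxic first from (EC50, EC0.1) estimate pairs.

    Materials with a usable EC50 (status ``reached`` or the conservative
    ``below_range`` bound) are sorted ascending by EC50; materials ranked only
    by the EC0.1 fallback follow, sorted ascending by EC0.1.  Ties break
    lexicographically on material id.  Materials with neither estimate are
    returned separately as ``unranked``.
    """
    primary: list[RankEntry] = []
    fallback: list[RankEntry] = []
    unranked: list[str] = []
    for material_id, (ec50, ec01) in estimates.items():
        if ec50.value is not None:
            primary.append(RankEntry(material_id, "EC50", ec50.value))
        elif ec01.value is not None:
            fallback.append(RankEntry(material_id, "EC0.1", ec01.value))
        else:
            unranked.append(material_id)
    primary.sort(key=lambda e: (e.value, e.material_id))
    fallback.sort(key=lambda e: (e.value, e.material_id))
    return HazardRanking(entries=tuple(primary + fallback), unranked=tuple(sorted(unranked)))


def spearman(x: Sequence, y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with mid-ranked ties.

    ``rho`` is the Pearson correlation of the mid-ranks and the p-value comes
    from the t approximation with ``n - 2`` degrees of freedom.  ``x`` may be
    any orderable values (e.g. numerically encoded categories — the encoding
    of nominal factors such as core composition is the caller's choice and
    changes the result).  A constant vector has no rank ordering: rho is
    returned as NaN with a warning.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and the same length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), n)
    rho, p = stats.pearsonr(rx, ry)
    return SpearmanResult(float(rho), float(p), n)
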