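"""Weighted EZ Metric scoring of exposure groups.

The EZ Metric condenses the 21 binary endpoints of an exposure group (one
material at one concentration) into a single severity score::

    EZ = w_m24 * (n_dead_24 / n)
       + w_m120 * (n_dead_120 / n)
       + (n_viable / n) * sum_i w_i * (c_i / n_viable)

where ``n`` is the number of exposed embryos, ``n_dead_24`` died by 24 hpf,
``n_dead_120`` died between 24 and 120 hpf, and ``c_i`` counts viable embryos
showing sub-lethal endpoint *i* with weight ``w_i``.  The sub-lethal sum is 0
when no embryo survives.  This is algebraically the mean over embryos of a
per-embryo score (1.0 if dead at 24 hpf, 0.95 if dead by 120 hpf, otherwise
the sum of weights of its observed endpoints), which bounds the group score in
[0, 1] because the 19 sub-lethal weights sum to 0.94.

An unscaled variant (sub-lethal frequencies normalized by the viable count
only, not additionally by the surviving fraction) is available through
``scaled=False``; it can exceed 1 when mortality and malformations co-occur
and is provided for sensitivity analysis only.

A material's scores across its dilution series form a
:class:`ConcentrationProfile`; summing the treatment-concentration scores
gives the profile-level summary :func:`sum_ez`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .assay_io import SUBLETHAL_ENDPOINTS, EmbryoRecord, WeightTable
from .errors import ValidationError

__all__ = [
    "EndpointFrequencies",
    "EZScore",
    "ConcentrationProfile",
    "SumEZ",
    "tally_group",
    "weighted_ez_score",
    "embryo_score",
    "score_records",
    "build_profile",
    "build_profiles",
    "sum_ez",
]


@dataclass
class EndpointFrequencies:
    """Endpoint counts for one exposure group (one material x concentration)."""

    n_exposed: int
    n_dead_24: int
    n_dead_120: int
    n_viable: int
    sublethal_counts: dict[str, int]
    material_id: str = ""
    concentration: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_dead_24 + self.n_dead_120 + self.n_viable != self.n_exposed:
            raise ValidationError(
                "mortality and viability counts do not partition the group: "
                f"{self.n_dead_24} + {self.n_dead_120} + {self.n_viable} != {self.n_exposed}"
            )
        for name, count in self.sublethal_counts.items():
            if count > self.n_viable:
                raise ValidationError(
                    f"endpoint {name!r} count {count} exceeds viable count {self.n_viable}"
                )


@dataclass(frozen=True)
class EZScore:
    """Weighted EZ Metric score of one exposure group."""

    material_id: str
    concentration: float
    score: float
    n_exposed: int


@dataclass(frozen=True)
class ConcentrationProfile:
    """EZ scores of one material across its dilution series, ascending.

    The control point (0 ppm) is retained when present but excluded from both
    the sumEZ summary and EC interpolation.
    """

    material_id: str
    points: tuple[EZScore, ...]

    def __post_init__(self) -> None:
        concs = [p.concentration for p in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValidationError(
                f"profile {self.material_id}: concentrations must be strictly increasing"
            )
        if len(self.treatment_points) < 2:
            raise ValidationError(
                f"profile {self.material_id}: need >= 2 distinct treatment concentrations"
            )

    @property
    def control(self) -> EZScore | None:
        first = self.points[0]
        return first if first.concentration == 0 else None

    @property
    def treatment_points(self) -> tuple[EZScore, ...]:
        return tuple(p for p in self.points if p.concentration > 0)

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(p.concentration for p in self.points)

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(p.score for p in self.points)


@dataclass(frozen=True)
class SumEZ:
    """Sum of EZ scores over a material's treatment concentrations."""

    material_id: str
    value: float
    n_concentrations: int


def tally_group(records: Sequence[EmbryoRecord]) -> EndpointFrequencies:
    """Tally mortality and sub-lethal endpoint counts for one exposure group.

    All records must share one material and one concentration; sub-lethal
    counts are taken over viable (120 hpf) embryos only.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot tally an empty exposure group")
    materials = {r.material_id for r in records}
    concs = {r.concentration for r in records}
    if len(materials) > 1 or len(concs) > 1:
        raise ValidationError(
            f"exposure group mixes materials {sorted(materials)} / concentrations {sorted(concs)}"
        )
    counts = {name: 0 for name in SUBLETHAL_ENDPOINTS}
    n_dead_24 = n_dead_120 = n_viable = 0
    for rec in records:
        if rec.dead_24hpf:
            n_dead_24 += 1
        elif rec.dead_by_120hpf:
            n_dead_120 += 1
        else:
            n_viable += 1
            for name in rec.observed_endpoints():
                counts[name] += 1
    return EndpointFrequencies(
        n_exposed=len(records),
        n_dead_24=n_dead_24,
        n_dead_120=n_dead_120,
        n_viable=n_viable,
        sublethal_counts=counts,
        material_id=records[0].material_id,
        concentration=records[0].concentration,
    )


def weighted_ez_score(
    freq: EndpointFrequencies,
    weights: WeightTable | None = None,
    *,
    scaled: bool = True,
) -> EZScore:
    """Compute the weighted EZ Metric score of a tallied exposure group.

    With ``scaled=True`` (default) the sub-lethal term is weighted by the
    surviving fraction, which makes the group score the mean of per-embryo
    scores and bounds it in [0, 1].  ``scaled=False`` divides sub-lethal
    frequencies by the viable count only.
    """
    weights = weights or WeightTable.default()
    n = freq.n_exposed
    score = (
        weights.mortality_24 * freq.n_dead_24 / n
        + weights.mortality_120 * freq.n_dead_120 / n
    )
    if freq.n_viable > 0:
        sublethal = sum(
            weights[name] * count / freq.n_viable
            for name, count in freq.sublethal_counts.items()
        )
        score += (freq.n_viable / n) * sublethal if scaled else sublethal
    return EZScore(
        material_id=freq.material_id,
        concentration=freq.concentration,
        score=score,
        n_exposed=n,
    )


def embryo_score(record: EmbryoRecord, weights: WeightTable | None = None) -> float:
    """Per-embryo severity: 1.0 dead at 24 hpf, 0.95 dead by 120 hpf, else the
    sum of the weights of its observed endpoints."""
    weights = weights or WeightTable.default()
    if record.dead_24hpf:
        return weights.mortality_24
    if record.dead_by_120hpf:
        return weights.mortality_120
    return sum(weights[name] for name in record.observed_endpoints())


def score_records(
    records: Iterable[EmbryoRecord],
    weights: WeightTable | None = None,
    *,
    scaled: bool = True,
) -> list[EZScore]:
    """Group records by (material, concentration), tally and score each group."""
    groups: dict[tuple[str, float], list[EmbryoRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.material_id, rec.concentration)].append(rec)
    return [
        weighted_ez_score(tally_group(group), weights, scaled=scaled)
        for key, group in sorted(groups.items())
    ]


def build_profile(scores: Iterable[EZScore]) -> ConcentrationProfile:
    """Assemble one material's scores into an ascending concentration profile.

    Duplicate concentrations (replicate plates) are merged by pooling the
    embryos, i.e. the pooled score is the exposure-count-weighted mean of the
    replicate scores.
    """
    scores = list(scores)
    if not scores:
        raise ValidationError("cannot build a profile from no scores")
    materials = {s.material_id for s in scores}
    if len(materials) > 1:
        raise ValidationError(f"profile mixes materials: {sorted(materials)}")
    by_conc: dict[float, list[EZScore]] = defaultdict(list)
    for s in scores:
        by_conc[s.concentration].append(s)
    points = []
    for conc in sorted(by_conc):
        replicates = by_conc[conc]
        n = sum(r.n_exposed for r in replicates)
        pooled = sum(r.score * r.n_exposed for r in replicates) / n
        points.append(
            EZScore(
                material_id=scores[0].material_id,
                concentration=conc,
                score=pooled,
                n_exposed=n,
            )
        )
    return ConcentrationProfile(material_id=scores[0].material_id, points=tuple(points))


def build_profiles(scores: Iterable[EZScore]) -> dict[str, ConcentrationProfile]:
    """Build one profile per material from a flat score collection."""
    by_material: dict[str, list[EZScore]] = defaultdict(list)
    for s in scores:
        by_material[s.material_id].append(s)
    return {m: build_profile(v) for m, v in sorted(by_material.items())}


def sum_ez(profile: ConcentrationProfile) -> SumEZ:
    """Sum the EZ scores over the profile's treatment concentrations.

    The 0 ppm control, when present, is excluded: sumEZ summarizes the
    response over the tested dilution series.
    """
    treatment = profile.treatment_points
    return SumEZ(
        material_id=profile.material_id,
        value=float(sum(p.score for p in treatment)),
        n_concentrations=len(treatment),
    )
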