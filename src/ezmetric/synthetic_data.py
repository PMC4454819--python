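"""Synthetic plate-screen generator for the EZ Metric pipeline.

Emulates the study design of a high-throughput embryonic-zebrafish screen:
96-well plates with one embryo per well, fivefold serial dilutions from
250 ppm (eight treatment levels) plus a fishwater control, and a panel of 68
nanomaterials whose potency is driven by four surface functional groups
(TMAT, phosphate, phosphatidylcholine, amine).

The per-embryo noise model is a set of independent Bernoulli draws against
Hill dose-response curves ``H(c) = c^h / (ed50^h + c^h)``: an embryo dies by
24 hpf with probability ``H24(c)``, a survivor dies by 120 hpf with
probability ``H120(c)``, and a viable embryo acquires each sub-lethal
endpoint independently with its own ``Hi(c)``.  A material's potency
multiplier divides every ED50, so potency > 1 shifts all curves toward lower
concentrations.  An optional copula-style correlation knob couples a single
embryo-level severity draw to all endpoint draws for robustness studies.

Every generated table passes :mod:`ezmetric.assay_io` validation; ground
truth (effective Hill curves, panel potency strata) is returned beside the
data so downstream recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .assay_io import (
    MORTALITY_120HPF,
    MORTALITY_24HPF,
    SUBLETHAL_ENDPOINTS,
    SURFACE_GROUPS,
    EmbryoRecord,
    MaterialAnnotation,
)
from .errors import ValidationError
from .response_model import (
    GOLD_REFERENCE_COEFFICIENTS,
    ModelCoefficients,
    ModelObservation,
    design_row,
    inverse_mod_transform,
)

__all__ = [
    "HillCurve",
    "SimulationConfig",
    "PanelSpec",
    "PlateSimulation",
    "PanelSimulation",
    "dilution_series",
    "hill_response",
    "expected_ez_score",
    "simulate_plate",
    "simulate_panel",
    "simulate_model_observations",
]


class HillCurve(NamedTuple):
    """A monotone dose-response curve: ED50 in ppm and Hill slope."""

    ed50: float
    hill: float


def hill_response(concentration: float, curve: HillCurve) -> float:
    """Occurrence probability ``c^h / (ed50^h + c^h)``; 0 at the control."""
    c = float(concentration)
    if c == 0:
        return 0.0
    ratio = (c / curve.ed50) ** curve.hill
    return ratio / (1.0 + ratio)


#: Baseline dose-response parameters (potency multiplier 1).  Mortality sits
#: near the middle of the tested range; severe malformations (heart, brain,
#: yolk sac) appear at somewhat lower doses than mortality, mild ones near or
#: above it — the pattern typical of developmental screens.
DEFAULT_ENDPOINT_CURVES: dict[str, HillCurve] = {
    MORTALITY_24HPF: HillCurve(60.0, 1.8),
    MORTALITY_120HPF: HillCurve(40.0, 1.8),
    "heart malformation": HillCurve(20.0, 1.5),
    "brain malformation": HillCurve(25.0, 1.5),
    "yolk sac edema": HillCurve(18.0, 1.5),
    "notochord malformation": HillCurve(35.0, 1.5),
    "curved axis": HillCurve(30.0, 1.5),
    "trunk malformation": HillCurve(45.0, 1.4),
    "delayed developmental progression": HillCurve(25.0, 1.4),
    "occluded circulation": HillCurve(50.0, 1.4),
    "eye malformation": HillCurve(60.0, 1.4),
    "jaw malformation": HillCurve(55.0, 1.4),
    "lack of spontaneous movement": HillCurve(40.0, 1.4),
    "somite malformation": HillCurve(80.0, 1.3),
    "motility": HillCurve(70.0, 1.3),
    "lack of touch response": HillCurve(75.0, 1.3),
    "snout malformation": HillCurve(90.0, 1.3),
    "otic malformation": HillCurve(100.0, 1.3),
    "caudal/pectoral fin malformation": HillCurve(85.0, 1.3),
    "atypical pigmentation": HillCurve(120.0, 1.2),
    "atypical swim bladder inflation": HillCurve(110.0, 1.2),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Plate-level simulation settings.

    Defaults mirror the screen design: 12 embryos per exposure group, eight
    fivefold dilutions from 250 ppm plus a control column, no background
    malformation rate in controls, independent endpoint draws.
    """

    seed: int = 0
    embryos_per_group: int = 12
    top_concentration: float = 250.0
    dilution_factor: float = 5.0
    n_dilutions: int = 8
    endpoint_curves: Mapping[str, HillCurve] = field(
        default_factory=lambda: dict(DEFAULT_ENDPOINT_CURVES)
    )
    background_rate: float = 0.0
    severity_correlation: float = 0.0
    include_control: bool = True

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValidationError("dilution factor must exceed 1")
        if self.embryos_per_group < 1 or self.n_dilutions < 1:
            raise ValidationError("embryos_per_group and n_dilutions must be >= 1")
        if not 0 <= self.background_rate < 1:
            raise ValidationError("background rate must be in [0, 1)")
        if not 0 <= self.severity_correlation <= 1:
            raise ValidationError("severity correlation must be in [0, 1]")
        missing = [
            name
            for name in (MORTALITY_24HPF, MORTALITY_120HPF) + SUBLETHAL_ENDPOINTS
            if name not in self.endpoint_curves
        ]
        if missing:
            raise ValidationError(f"endpoint curves missing for: {missing}")
        for name, curve in self.endpoint_curves.items():
            if curve.ed50 <= 0 or curve.hill <= 0:
                raise ValidationError(f"curve for {name!r} needs ed50 > 0 and hill > 0")

    def concentrations(self) -> list[float]:
        """Treatment concentrations, descending, as pipetted."""
        return dilution_series(self.top_concentration, self.dilution_factor, self.n_dilutions)


@dataclass(frozen=True)
class PanelSpec:
    """Panel-level design: how many materials and how potency tracks chemistry.

    Materials carrying one of the four surface groups are drawn from the
    potent stratum (low effective ED50s) and the rest from the benign stratum
    (ED50s far above the tested range).  ``label_noise`` flips the potency
    stratum of a fraction of materials relative to their surface-group flags,
    creating the occasional chemistry/toxicity mismatch seen in real panels.
    """

    n_materials: int = 68
    toxic_fraction: float = 0.5
    potency_toxic: float = 8.0
    potency_benign: float = 0.05
    potency_log_sd: float = 0.4
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.n_materials < 2:
            raise ValidationError("panel needs at least 2 materials")
        if not 0 < self.toxic_fraction < 1:
            raise ValidationError("toxic fraction must be in (0, 1)")
        if not 0 <= self.label_noise <= 1:
            raise ValidationError("label noise must be in [0, 1]")
        if self.potency_toxic <= 0 or self.potency_benign <= 0:
            raise ValidationError("potency scales must be positive")


@dataclass(frozen=True)
class PlateSimulation:
    """Simulated plate records plus the generating truth."""

    records: tuple[EmbryoRecord, ...]
    truth: Mapping[str, HillCurve]  # effective (potency-scaled) curves
    material_id: str
    potency: float


@dataclass(frozen=True)
class PanelSimulation:
    """Simulated multi-material panel with annotations and ground truth."""

    records: tuple[EmbryoRecord, ...]
    annotations: tuple[MaterialAnnotation, ...]
    truth_labels: Mapping[str, str]  # material -> "toxic" | "benign"
    potencies: Mapping[str, float]


def dilution_series(top: float, factor: float, n: int) -> list[float]:
    """Serial dilution concentrations ``[top, top/factor, ..., top/factor^(n-1)]``."""
    if top <= 0:
        raise ValidationError("top concentration must be positive")
    if factor <= 1:
        raise ValidationError("dilution factor must exceed 1")
    if n < 1:
        raise ValidationError("need at least one dilution level")
    return [top / factor**k for k in range(n)]


def effective_curves(config: SimulationConfig, potency: float) -> dict[str, HillCurve]:
    """Potency-scaled curves: every ED50 divided by the potency multiplier."""
    if potency <= 0:
        raise ValidationError("potency must be positive")
    return {
        name: HillCurve(curve.ed50 / potency, curve.hill)
        for name, curve in config.endpoint_curves.items()
    }


def expected_ez_score(
    truth: Mapping[str, HillCurve],
    weights,
    concentration: float,
    *,
    background_rate: float = 0.0,
) -> float:
    """Expected per-embryo EZ score under the generator's independence model.

    ``E[score] = w24*H24 + (1-H24) * (w120*H120 + (1-H120) * sum_i w_i p_i)``
    with ``p_i = bg + (1 - bg) * Hi(c)``.
    """
    h24 = hill_response(concentration, truth[MORTALITY_24HPF])
    h120 = hill_response(concentration, truth[MORTALITY_120HPF])
    sub = sum(
        weights[name]
        * (background_rate + (1 - background_rate) * hill_response(concentration, truth[name]))
        for name in SUBLETHAL_ENDPOINTS
    )
    return weights.mortality_24 * h24 + (1 - h24) * (
        weights.mortality_120 * h120 + (1 - h120) * sub
    )


def _draw(rng: np.random.Generator, p: float, shared_u: float, correlation: float) -> bool:
    """Bernoulli(p) draw, optionally replaced by a shared uniform with prob rho."""
    if correlation > 0 and rng.random() < correlation:
        return shared_u < p
    return rng.random() < p


_PLATE_ROWS = "ABCDEFGH"


def simulate_plate(
    config: SimulationConfig,
    material_id: str = "NP-001",
    potency: float = 1.0,
    rng: np.random.Generator | None = None,
) -> PlateSimulation:
    """Simulate one material's exposure plates (one embryo per well).

    Each exposure group (control first when enabled, then descending
    dilutions) occupies one plate row of 12 columns, wrapping onto additional
    rows/plates for larger groups.  Reproducible from ``config.seed`` when no
    generator is passed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truth = effective_curves(config, potency)
    concs: list[float] = ([0.0] if config.include_control else []) + config.concentrations()
    records: list[EmbryoRecord] = []
    row_counter = 0
    for conc in concs:
        h24 = hill_response(conc, truth[MORTALITY_24HPF])
        h120 = hill_response(conc, truth[MORTALITY_120HPF])
        for k in range(config.embryos_per_group):
            plate, row = divmod(row_counter + k // 12, 8)
            well = f"P{plate + 1}:{_PLATE_ROWS[row]}{k % 12 + 1:02d}"
            shared_u = rng.random()
            dead24 = _draw(rng, h24, shared_u, config.severity_correlation)
            alive24 = not dead24
            alive120 = alive24 and not _draw(rng, h120, shared_u, config.severity_correlation)
            endpoints = {}
            if alive120:
                for name in SUBLETHAL_ENDPOINTS:
                    p = config.background_rate + (1 - config.background_rate) * hill_response(
                        conc, truth[name]
                    )
                    endpoints[name] = _draw(rng, p, shared_u, config.severity_correlation)
            records.append(
                EmbryoRecord(
                    material_id=material_id,
                    concentration=conc,
                    well_id=well,
                    alive_24hpf=alive24,
                    alive_120hpf=alive120,
                    endpoints=endpoints,
                )
            )
        row_counter += -(-config.embryos_per_group // 12)
    return PlateSimulation(
        records=tuple(records), truth=truth, material_id=material_id, potency=potency
    )


_GROUP_CORES = {
    "TMAT": "gold",
    "phosphatidylcholine": "gold",
    "phosphate": "silver/gold",
    "amine": "dendrimer",
}
_GROUP_CHARGES = {
    "TMAT": "positive",
    "phosphatidylcholine": "neutral",
    "phosphate": "negative",
    "amine": "positive",
}
_BENIGN_CORES = ("gold", "silver", "metal-oxide", "dendrimer")
_BENIGN_SURFACES = ("citrate", "MES", "MEE", "MEEE", "carboxyl", "hydroxyl")


def simulate_panel(spec: PanelSpec, config: SimulationConfig) -> PanelSimulation:
    """Simulate a multi-material screening panel with surface-driven potency.

    Roughly ``toxic_fraction`` of materials carry one of the four surface
    groups and draw their potency multiplier from the potent stratum; the
    rest are benign.  Potencies are lognormal around the stratum scale.
    """
    rng = np.random.default_rng(config.seed)
    all_records: list[EmbryoRecord] = []
    annotations: list[MaterialAnnotation] = []
    truth_labels: dict[str, str] = {}
    potencies: dict[str, float] = {}
    for i in range(spec.n_materials):
        material_id = f"NP-{i + 1:03d}"
        is_toxic_chem = rng.random() < spec.toxic_fraction
        if is_toxic_chem:
            group = SURFACE_GROUPS[rng.integers(len(SURFACE_GROUPS))]
            core = _GROUP_CORES[group]
            surface = group
            charge = _GROUP_CHARGES[group]
            groups = {g: g == group for g in SURFACE_GROUPS}
        else:
            group = None
            core = _BENIGN_CORES[rng.integers(len(_BENIGN_CORES))]
            surface = _BENIGN_SURFACES[rng.integers(len(_BENIGN_SURFACES))]
            charge = "neutral" if surface in ("MEE", "MEEE", "hydroxyl") else "negative"
            groups = {g: False for g in SURFACE_GROUPS}
        potent = is_toxic_chem
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            potent = not potent
        scale = spec.potency_toxic if potent else spec.potency_benign
        potency = float(np.exp(rng.normal(np.log(scale), spec.potency_log_sd)))
        size = float(np.exp(rng.normal(np.log(10.0), 0.8)))
        annotations.append(
            MaterialAnnotation(
                material_id=material_id,
                core=core,
                primary_size=round(size, 1),
                surface_chemistry=surface,
                surface_groups=groups,
                charge=charge,
            )
        )
        sim = simulate_plate(config, material_id=material_id, potency=potency, rng=rng)
        all_records.extend(sim.records)
        truth_labels[material_id] = "toxic" if potent else "benign"
        potencies[material_id] = potency
    return PanelSimulation(
        records=tuple(all_records),
        annotations=tuple(annotations),
        truth_labels=truth_labels,
        potencies=potencies,
    )


def simulate_model_observations(
    coefficients: ModelCoefficients | None = None,
    descriptors: Mapping[str, "object"] | None = None,
    size_grid: Sequence[float] = (0.8, 2.0, 5.0, 10.0),
    conc_grid: Sequence[float] | None = None,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    truncate: bool = True,
) -> list[ModelObservation]:
    """Generate response-surface observations by inverting the model.

    ``mod_ez = exp(x @ beta) + N(0, noise_sd)``.  By default noisy draws are
    truncated below at the mod offset 0.1, mirroring real assay readings
    (a measured EZ score is never negative); ``truncate=False`` keeps the
    raw Gaussian draws, the condition under which least-squares coefficient
    estimates are unbiased.  ``noise_sd = 0`` yields exact model data (never
    truncated) so a refit recovers the generating coefficients.  Defaults:
    the packaged gold-ligand descriptors, the reference coefficient set,
    four sizes and the standard eight-level fivefold dilution series from
    250 ppm.
    """
    from .assay_io import load_ligand_descriptors

    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    coefficients = coefficients or GOLD_REFERENCE_COEFFICIENTS
    descriptors = descriptors or load_ligand_descriptors()
    conc_grid = list(conc_grid) if conc_grid is not None else dilution_series(250.0, 5.0, 8)
    rng = np.random.default_rng(seed)
    beta = coefficients.to_array()
    observations = []
    for ligand, desc in descriptors.items():
        for size in size_grid:
            for conc in conc_grid:
                probe = ModelObservation(
                    ligand=ligand, descriptors=desc, size=float(size),
                    concentration=float(conc), ez_score=0.0,
                )
                mod = float(np.exp(design_row(probe) @ beta))
                if noise_sd > 0:
                    mod += float(rng.normal(0.0, noise_sd))
                    if truncate:
                        mod = max(mod, 0.1)
                observations.append(
                    ModelObservation(
                        ligand=ligand,
                        descriptors=desc,
                        size=float(size),
                        concentration=float(conc),
                        ez_score=inverse_mod_transform(mod),
                    )
                )
    return observations
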