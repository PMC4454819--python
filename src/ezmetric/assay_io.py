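"""Data model, validation and file I/O for embryonic-zebrafish plate screens.

The assay exposes dechorionated zebrafish embryos (one per well of a 96-well
plate) to a dilution series of a nanomaterial and scores 21 endpoints in a
binary fashion: mortality at 24 and 120 hours post fertilization (hpf) plus 19
sub-lethal morphological and behavioral endpoints assessed on embryos that
survive to 120 hpf.

This module defines the record types (:class:`EmbryoRecord`,
:class:`WeightTable`, :class:`MaterialAnnotation`, :class:`LigandDescriptorSet`),
their invariants, and CSV/YAML readers and writers.  All tables are plain
comma-separated UTF-8 with a header row; booleans are accepted as
``0/1/true/false/yes/no`` case-insensitively.  Concentrations are in ppm
(mg/L); ppb values are accepted only through an explicit ``unit`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "MORTALITY_24HPF",
    "MORTALITY_120HPF",
    "SUBLETHAL_ENDPOINTS",
    "ALL_ENDPOINTS",
    "DEFAULT_WEIGHTS",
    "ENDPOINT_SYNONYMS",
    "SURFACE_GROUPS",
    "EmbryoRecord",
    "WeightTable",
    "MaterialAnnotation",
    "LigandDescriptorSet",
    "read_embryo_table",
    "write_embryo_table",
    "read_weight_config",
    "read_material_table",
    "write_material_table",
    "load_ligand_descriptors",
]

MORTALITY_24HPF = "24 hpf mortality"
MORTALITY_120HPF = "120 hpf mortality"

#: The 19 sub-lethal endpoint names, scored only on embryos alive at 120 hpf.
SUBLETHAL_ENDPOINTS: tuple[str, ...] = (
    "heart malformation",
    "brain malformation",
    "yolk sac edema",
    "notochord malformation",
    "curved axis",
    "trunk malformation",
    "delayed developmental progression",
    "occluded circulation",
    "eye malformation",
    "jaw malformation",
    "lack of spontaneous movement",
    "somite malformation",
    "motility",
    "lack of touch response",
    "snout malformation",
    "otic malformation",
    "caudal/pectoral fin malformation",
    "atypical pigmentation",
    "atypical swim bladder inflation",
)

ALL_ENDPOINTS: tuple[str, ...] = (MORTALITY_24HPF, MORTALITY_120HPF) + SUBLETHAL_ENDPOINTS

#: Consensus severity weights for the 21 endpoints.  Mortality at 24 hpf is
#: the maximal response (1.0); death between 24 and 120 hpf weighs 0.95; the
#: 19 sub-lethal weights sum to 0.94, so no combination of malformations on a
#: surviving embryo outweighs a death.
DEFAULT_WEIGHTS: dict[str, float] = {
    MORTALITY_24HPF: 1.0,
    MORTALITY_120HPF: 0.95,
    "heart malformation": 0.12,
    "brain malformation": 0.12,
    "yolk sac edema": 0.10,
    "notochord malformation": 0.08,
    "curved axis": 0.08,
    "trunk malformation": 0.06,
    "delayed developmental progression": 0.06,
    "occluded circulation": 0.04,
    "eye malformation": 0.04,
    "jaw malformation": 0.04,
    "lack of spontaneous movement": 0.04,
    "somite malformation": 0.02,
    "motility": 0.02,
    "lack of touch response": 0.02,
    "snout malformation": 0.02,
    "otic malformation": 0.02,
    "caudal/pectoral fin malformation": 0.02,
    "atypical pigmentation": 0.02,
    "atypical swim bladder inflation": 0.02,
}

#: Optional alternative spellings seen in screen exports; applied only when a
#: reader is called with ``synonyms=True``.
ENDPOINT_SYNONYMS: dict[str, str] = {
    "pericardial edema": "heart malformation",
    "fin malformation": "caudal/pectoral fin malformation",
    "swim bladder": "atypical swim bladder inflation",
}

#: The four surface functional groups used for cluster classification.
SURFACE_GROUPS: tuple[str, ...] = ("TMAT", "phosphate", "phosphatidylcholine", "amine")

_TRUE_STRINGS = {"1", "true", "yes"}
_FALSE_STRINGS = {"0", "false", "no"}


def parse_bool(value, *, context: str = "value") -> bool:
    """Parse a boolean from 0/1/true/false/yes/no (case-insensitive) or a bool."""
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValidationError(f"cannot parse boolean {context}: {value!r}")


def canonical_endpoint(name: str, *, synonyms: bool = False) -> str:
    """Canonicalize an endpoint name: lowercase, collapsed whitespace.

    With ``synonyms=True`` a small map of alternative spellings is applied
    after canonicalization.
    """
    canon = " ".join(str(name).strip().lower().split())
    if synonyms:
        canon = ENDPOINT_SYNONYMS.get(canon, canon)
    return canon


@dataclass
class EmbryoRecord:
    """One embryo-well observation.

    Parameters
    ----------
    material_id:
        Identifier of the exposed nanomaterial; controls share the id of the
        plate's material with ``concentration == 0``.
    concentration:
        Exposure concentration in ppm; 0 denotes the fishwater control.
    well_id:
        Plate/row/column identifier, e.g. ``"P1:A01"``.
    alive_24hpf, alive_120hpf:
        Viability flags at the two assessment times.
    endpoints:
        Mapping of sub-lethal endpoint name to presence flag.  Names must be
        among the 19 canonical sub-lethal endpoints; missing names are treated
        as absent.  Embryos dead at 24 hpf carry no sub-lethal observations.
    """

    material_id: str
    concentration: float
    well_id: str
    alive_24hpf: bool
    alive_120hpf: bool
    endpoints: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentration = float(self.concentration)
        if not self.concentration >= 0:
            raise ValidationError(
                f"well {self.well_id}: concentration must be >= 0 ppm, got {self.concentration}"
            )
        if self.alive_120hpf and not self.alive_24hpf:
            raise ValidationError(
                f"well {self.well_id}: embryo dead at 24 hpf cannot be alive at 120 hpf"
            )
        clean: dict[str, bool] = {}
        for name, flag in self.endpoints.items():
            canon = canonical_endpoint(name)
            if canon not in SUBLETHAL_ENDPOINTS:
                raise ValidationError(
                    f"well {self.well_id}: unknown endpoint name {name!r}"
                )
            clean[canon] = parse_bool(flag, context=f"endpoint {name!r}")
        for name in SUBLETHAL_ENDPOINTS:
            clean.setdefault(name, False)
        if not self.alive_24hpf and any(clean.values()):
            raise ValidationError(
                f"well {self.well_id}: sub-lethal endpoint flagged on embryo dead at 24 hpf"
            )
        self.endpoints = clean

    @property
    def dead_24hpf(self) -> bool:
        return not self.alive_24hpf

    @property
    def dead_by_120hpf(self) -> bool:
        """Died between the 24 and 120 hpf assessments."""
        return self.alive_24hpf and not self.alive_120hpf

    @property
    def viable(self) -> bool:
        return self.alive_120hpf

    def observed_endpoints(self) -> list[str]:
        return [name for name, flag in self.endpoints.items() if flag]


@dataclass(frozen=True)
class WeightTable:
    """Severity weights for the 21 assay endpoints.

    The default table assigns 1.0 to 24-hpf mortality, 0.95 to 120-hpf
    mortality and sub-lethal weights that sum to 0.94.
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        weights = {canonical_endpoint(k): float(v) for k, v in dict(self.weights).items()}
        unknown = sorted(set(weights) - set(ALL_ENDPOINTS))
        if unknown:
            raise ValidationError(f"unknown endpoint name(s) in weight table: {unknown}")
        missing = sorted(set(ALL_ENDPOINTS) - set(weights))
        if missing:
            raise ValidationError(f"weight table missing endpoint(s): {missing}")
        negative = sorted(name for name, w in weights.items() if w < 0)
        if negative:
            raise ValidationError(f"negative weight(s) for: {negative}")
        object.__setattr__(self, "weights", weights)

    @classmethod
    def default(cls) -> "WeightTable":
        return cls(DEFAULT_WEIGHTS)

    def __getitem__(self, endpoint: str) -> float:
        return self.weights[canonical_endpoint(endpoint)]

    @property
    def mortality_24(self) -> float:
        return self.weights[MORTALITY_24HPF]

    @property
    def mortality_120(self) -> float:
        return self.weights[MORTALITY_120HPF]

    @property
    def sublethal_sum(self) -> float:
        """Sum of the 19 sub-lethal weights (0.94 for the default table)."""
        return sum(self.weights[name] for name in SUBLETHAL_ENDPOINTS)


@dataclass
class MaterialAnnotation:
    """Static annotation of one nanomaterial in a screening panel."""

    material_id: str
    core: str
    primary_size: float
    surface_chemistry: str
    surface_groups: dict[str, bool] = field(default_factory=dict)
    charge: str = "unknown"

    def __post_init__(self) -> None:
        self.primary_size = float(self.primary_size)
        if not self.primary_size > 0:
            raise ValidationError(
                f"material {self.material_id}: primary size must be > 0 nm, "
                f"got {self.primary_size}"
            )
        groups = {}
        for name in SURFACE_GROUPS:
            groups[name] = parse_bool(
                self.surface_groups.get(name, False), context=f"surface group {name}"
            )
        unknown = sorted(set(self.surface_groups) - set(SURFACE_GROUPS))
        if unknown:
            raise ValidationError(
                f"material {self.material_id}: unknown surface group(s) {unknown}"
            )
        self.surface_groups = groups
        if self.charge not in ("positive", "neutral", "negative", "unknown"):
            raise ValidationError(
                f"material {self.material_id}: invalid charge {self.charge!r}"
            )


@dataclass(frozen=True)
class LigandDescriptorSet:
    """Molecular descriptors of a gold-nanoparticle surface ligand.

    sasa
        Solvent-accessible surface area, Å².
    sasa_over_polar
        Ratio of SASA to the polar surface area (unitless).
    refractivity
        Molar refractivity, m³/mol — a volume-like descriptor.
    band_gap
        HOMO–LUMO energy difference, kcal/mol.
    """

    ligand: str
    sasa: float
    sasa_over_polar: float
    refractivity: float
    band_gap: float


_EMBRYO_META_COLUMNS = ("material_id", "concentration_ppm", "well_id", "alive_24hpf", "alive_120hpf")


def read_embryo_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    synonyms: bool = False,
) -> list[EmbryoRecord]:
    """Read a per-embryo CSV table into validated :class:`EmbryoRecord` objects.

    Required columns (after applying the optional ``schema`` remapping of file
    column names onto canonical names): ``material_id``, ``concentration_ppm``,
    ``well_id``, ``alive_24hpf``, ``alive_120hpf``.  Every remaining column
    must name one of the 19 sub-lethal endpoints.  An optional ``unit`` column
    with values ``ppm``/``ppb`` rescales concentrations row-wise.

    Raises
    ------
    SchemaError
        If a required column is missing or a column cannot be mapped to an
        endpoint.
    ValidationError
        If any row violates a record invariant; the message lists the
        offending file rows (header = row 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in _EMBRYO_META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    has_unit = "unit" in df.columns
    endpoint_cols: dict[str, str] = {}
    for col in df.columns:
        if col in _EMBRYO_META_COLUMNS or col == "unit":
            continue
        canon = canonical_endpoint(col, synonyms=synonyms)
        if canon not in SUBLETHAL_ENDPOINTS:
            raise SchemaError(f"{path.name}: column {col!r} is not a known endpoint")
        endpoint_cols[col] = canon

    records: list[EmbryoRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        file_row = int(idx) + 2  # header occupies row 1
        try:
            conc = float(row["concentration_ppm"])
            if has_unit:
                unit = str(row["unit"]).strip().lower()
                if unit == "ppb":
                    conc /= 1000.0
                elif unit != "ppm":
                    raise ValidationError(f"unknown concentration unit {unit!r}")
            records.append(
                EmbryoRecord(
                    material_id=str(row["material_id"]),
                    concentration=conc,
                    well_id=str(row["well_id"]),
                    alive_24hpf=parse_bool(row["alive_24hpf"], context="alive_24hpf"),
                    alive_120hpf=parse_bool(row["alive_120hpf"], context="alive_120hpf"),
                    endpoints={canon: row[col] for col, canon in endpoint_cols.items()},
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {file_row}: {exc}")
    if problems:
        raise ValidationError(
            f"{path.name}: {len(problems)} invalid record(s):\n" + "\n".join(problems)
        )
    return records


def write_embryo_table(records: Iterable[EmbryoRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column order (round-trips exactly)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "material_id": rec.material_id,
            "concentration_ppm": rec.concentration,
            "well_id": rec.well_id,
            "alive_24hpf": int(rec.alive_24hpf),
            "alive_120hpf": int(rec.alive_120hpf),
        }
        for name in SUBLETHAL_ENDPOINTS:
            row[name] = int(rec.endpoints[name])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_weight_config(source: str | Path) -> WeightTable:
    """Load endpoint weights from a YAML/JSON file, or return the default table.

    ``source == "default"`` returns the packaged default weights.  A file must
    map every one of the 21 endpoint names to a nonnegative number; partial
    configurations are rejected.
    """
    if str(source) == "default":
        return WeightTable.default()
    with open(source, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{source}: weight config must be a mapping of endpoint -> weight")
    return WeightTable(data)


_MATERIAL_COLUMNS = ("material_id", "core", "primary_size_nm", "surface_chemistry")


def read_material_table(path: str | Path) -> list[MaterialAnnotation]:
    """Read a material annotation CSV keyed by unique ``material_id``.

    Expected columns: ``material_id, core, primary_size_nm, surface_chemistry``
    plus one boolean column per surface group (``TMAT, phosphate,
    phosphatidylcholine, amine``) and an optional ``charge`` column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MATERIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    dupes = df["material_id"].astype(str)[df["material_id"].astype(str).duplicated()]
    if len(dupes):
        raise ValidationError(
            f"{path.name}: duplicate material_id(s): {sorted(set(dupes))}"
        )
    annotations = []
    for _, row in df.iterrows():
        groups = {g: row[g] for g in SURFACE_GROUPS if g in df.columns}
        annotations.append(
            MaterialAnnotation(
                material_id=str(row["material_id"]),
                core=str(row["core"]),
                primary_size=float(row["primary_size_nm"]),
                surface_chemistry=str(row["surface_chemistry"]),
                surface_groups=groups,
                charge=str(row["charge"]) if "charge" in df.columns else "unknown",
            )
        )
    return annotations


def write_material_table(annotations: Iterable[MaterialAnnotation], path: str | Path) -> None:
    rows = []
    for ann in annotations:
        row: dict[str, object] = {
            "material_id": ann.material_id,
            "core": ann.core,
            "primary_size_nm": ann.primary_size,
            "surface_chemistry": ann.surface_chemistry,
        }
        for g in SURFACE_GROUPS:
            row[g] = int(ann.surface_groups[g])
        row["charge"] = ann.charge
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_ligand_descriptors(path: str | Path | None = None) -> dict[str, LigandDescriptorSet]:
    """Load ligand descriptors; without ``path``, the packaged reference table.

    The packaged table carries the quantum-chemically derived descriptors for
    the four thiol surface ligands of the gold-nanoparticle series (MEE, MEEE,
    TMAT, MES): SASA, SASA/polar-surface ratio, molar refractivity and
    HOMO–LUMO band gap.
    """
    if path is None:
        source = resources.files("ezmetric.data").joinpath("ligand_descriptors.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = ("ligand", "sasa", "sasa_over_polar", "refractivity", "band_gap")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"descriptor table missing column(s): {missing}")
    out: dict[str, LigandDescriptorSet] = {}
    for _, row in df.iterrows():
        lig = str(row["ligand"])
        if lig in out:
            raise ValidationError(f"duplicate ligand {lig!r} in descriptor table")
        out[lig] = LigandDescriptorSet(
            ligand=lig,
            sasa=float(row["sasa"]),
            sasa_over_polar=float(row["sasa_over_polar"]),
            refractivity=float(row["refractivity"]),
            band_gap=float(row["band_gap"]),
        )
    return out
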