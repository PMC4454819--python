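"""Shared fixtures: record builders and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ezmetric import (
    EmbryoRecord,
    SimulationConfig,
    WeightTable,
    load_ligand_descriptors,
)
from ezmetric.assay_io import SUBLETHAL_ENDPOINTS


def make_embryo(
    material="NP-001",
    concentration=10.0,
    well="P1:A01",
    alive_24=True,
    alive_120=True,
    endpoints=(),
):
    """Build a valid EmbryoRecord with the given endpoint names flagged."""
    return EmbryoRecord(
        material_id=material,
        concentration=concentration,
        well_id=well,
        alive_24hpf=alive_24,
        alive_120hpf=alive_120,
        endpoints={name: True for name in endpoints},
    )


def make_group(n, material="NP-001", concentration=10.0, **kwargs):
    """n identical embryos at one concentration (distinct wells)."""
    return [
        make_embryo(material, concentration, well=f"P1:A{i + 1:02d}", **kwargs)
        for i in range(n)
    ]


def random_group(rng, n=12, material="NP-001", concentration=10.0):
    """A random but valid exposure group (dead embryos carry no flags)."""
    group = []
    for i in range(n):
        u = rng.random()
        alive_24 = u > 0.2
        alive_120 = alive_24 and rng.random() > 0.25
        endpoints = ()
        if alive_120:
            endpoints = tuple(
                name for name in SUBLETHAL_ENDPOINTS if rng.random() < 0.3
            )
        group.append(
            make_embryo(
                material,
                concentration,
                well=f"P1:B{i + 1:02d}",
                alive_24=alive_24,
                alive_120=alive_120,
                endpoints=endpoints,
            )
        )
    return group


@pytest.fixture
def weights():
    return WeightTable.default()


@pytest.fixture
def descriptors():
    return load_ligand_descriptors()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=42)
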