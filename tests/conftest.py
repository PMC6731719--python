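"""Shared fixtures: tiny hand-built designs and generated campaigns."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from trapcatch.core_io import ForestType, filter_samples
from trapcatch.covariates import DesignMatrix, DesignRow, assemble_design
from trapcatch.synthetic_data import generate_dataset, make_default_scenario

logging.getLogger("trapcatch").setLevel(logging.ERROR)


def make_toy_design(
    seed: int = 42,
    n_per_site: int = 8,
    deadwood_effect: float = 2.0,
    theta: float = 2.0,
) -> DesignMatrix:
    """Three one-trap sites (primary/disturbed/clearcut), two species."""
    rng = np.random.default_rng(seed)
    rows = []
    layout = [
        ("A", ForestType.PRIMARY),
        ("B", ForestType.DISTURBED),
        ("C", ForestType.CLEARCUT),
    ]
    for site, ft in layout:
        for j in range(n_per_site):
            date = 14.0 * j
            rain = float(rng.uniform(0, 8))
            dw = float(rng.uniform(0, 0.3))
            mu = 14 * np.exp(-3.5 + 0.003 * date - 0.05 * rain + deadwood_effect * dw)
            y1 = int(rng.negative_binomial(theta, theta / (theta + mu)))
            y2 = int(rng.negative_binomial(theta, theta / (theta + 0.8 * mu)))
            rows.append(
                DesignRow(
                    sample_id=f"{site}S{j}",
                    trap_id=f"{site}T1",
                    site_code=site,
                    days=14.0,
                    date=date,
                    rain=rain,
                    deadwood=dw,
                    forest_type=ft,
                    counts=(y1, y2),
                )
            )
    return DesignMatrix(rows=rows, species=["sp1", "sp2"])


@pytest.fixture(scope="session")
def toy_design() -> DesignMatrix:
    return make_toy_design()


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic campaign (34 traps, 6 species)."""
    return generate_dataset(make_default_scenario(seed=1))


@pytest.fixture(scope="session")
def default_design(default_dataset):
    return assemble_design(filter_samples(default_dataset))
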