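"""Shared fixtures: small seeded synthetic cohorts reused across modules."""

from __future__ import annotations

import pandas as pd
import pytest

from apopsens.cohort import CohortTable
from apopsens.panel import default_panel
from apopsens.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """~5k-cell cohort, 3 slides, no batch distortion (with ground truth)."""
    cfg = GeneratorConfig(
        n_patients=9, cores_per_patient=(2, 2), cells_per_core_mean=300,
        cells_per_core_sd=50, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """~17k-cell cohort used for batch-recovery and typing tests."""
    cfg = GeneratorConfig(
        n_patients=9, cores_per_patient=(2, 2), cells_per_core_mean=900,
        cells_per_core_sd=120, seed=5,
    )
    return generate_cohort(cfg)


def toy_table(rows: list[dict]) -> CohortTable:
    """Build a tiny valid cohort table from partial row dicts."""
    panel = default_panel()
    records = []
    for i, row in enumerate(rows):
        rec = {
            "cell_id": f"c{i}",
            "patient_id": "P0",
            "slide_id": "S0",
            "core_id": "C0",
            "position_id": "C0",
            "x": 1024.0,
            "y": 1024.0,
            "qc_score": 0.95,
            "cell_type": "unassigned",
        }
        rec.update({m: 10.0 for m in panel.names})
        rec.update(row)
        records.append(rec)
    return CohortTable(pd.DataFrame(records), panel)


@pytest.fixture()
def tiny_table():
    return toy_table([{} for _ in range(5)])
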