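"""Conversion of corrected intensities (a.u.) to molar concentrations (µM).

The five MOMP proteins are scaled against cell-line (HeLa) standards
imaged alongside the tissue: concentration = intensity / HeLa-mean x
HeLa-µM.  The four caspase-pathway proteins are aligned robustly to a
reference cohort: a per-marker linear map sends the observed intensity
(median, IQR) onto the reference (median µM, IQR µM).  APAF1, the limiting
apoptosome component, is not imaged and is fixed at 0.123 µM.

The shipped example standards (``example_standards``) are synthetic,
order-of-magnitude values for testing; real analyses supply measured
standards via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable
from .panel import CASPASE_MARKERS, MOMP_MARKERS

APAF1_DEFAULT_UM = 0.123

PROFILE_PROTEINS: tuple[str, ...] = MOMP_MARKERS + CASPASE_MARKERS + ("APAF1",)


@dataclass(frozen=True)
class ReferenceStandards:
    """Calibration anchors: HeLa intensities/µM and cohort reference stats."""

    hela_mean_intensity: Mapping[str, float]
    hela_concentration_um: Mapping[str, float]
    cohort_reference_um: Mapping[str, tuple[float, float]]  # marker -> (median, IQR)
    apaf1_um: float = APAF1_DEFAULT_UM

    def __post_init__(self) -> None:
        for m in MOMP_MARKERS:
            if m not in self.hela_mean_intensity or m not in self.hela_concentration_um:
                raise ValueError(f"HeLa standards missing for {m}")
            if self.hela_mean_intensity[m] <= 0:
                raise ValueError(f"non-positive HeLa intensity for {m}")
            if self.hela_concentration_um[m] <= 0:
                raise ValueError(f"non-positive HeLa concentration for {m}")
        for m in CASPASE_MARKERS:
            if m not in self.cohort_reference_um:
                raise ValueError(f"cohort reference missing for {m}")
            med, iqr = self.cohort_reference_um[m]
            if med <= 0 or iqr <= 0:
                raise ValueError(f"non-positive reference stats for {m}")
        if self.apaf1_um <= 0:
            raise ValueError("APAF1 concentration must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReferenceStandards":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            hela_mean_intensity=data["hela_mean_intensity"],
            hela_concentration_um=data["hela_concentration_um"],
            cohort_reference_um={
                m: tuple(v) for m, v in data["cohort_reference_um"].items()
            },
            apaf1_um=data.get("apaf1_um", APAF1_DEFAULT_UM),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "hela_mean_intensity": dict(self.hela_mean_intensity),
            "hela_concentration_um": dict(self.hela_concentration_um),
            "cohort_reference_um": {m: list(v) for m, v in self.cohort_reference_um.items()},
            "apaf1_um": self.apaf1_um,
        }))


def example_standards() -> ReferenceStandards:
    """Synthetic example standards (documented stand-ins, not measurements).

    HeLa intensities are set near the generator's cancer-cell medians so
    calibrated concentrations land in the physiological 0.01-1 µM range.
    """
    hela_int = {"BAK": 330.0, "BAX": 245.0, "BCL2": 90.0, "BCL(X)L": 200.0, "MCL1": 90.0}
    hela_um = {"BAK": 0.30, "BAX": 0.25, "BCL2": 0.15, "BCL(X)L": 0.20, "MCL1": 0.10}
    cohort_ref = {
        "PRO-CASPASE 3": (0.10, 0.08),
        "PRO-CASPASE 9": (0.02, 0.015),
        "SMAC": (0.40, 0.25),
        "XIAP": (0.10, 0.07),
    }
    return ReferenceStandards(hela_int, hela_um, cohort_ref)


def _profile_frame(index: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(index=index, columns=list(PROFILE_PROTEINS), dtype=float)


def calibrate_momp_proteins(
    intensities: pd.DataFrame, standards: ReferenceStandards
) -> pd.DataFrame:
    """Linear HeLa scaling of the five BCL2-family proteins.

    ``conc = intensity / hela_mean_intensity * hela_concentration`` per
    marker; positively homogeneous in intensity.
    """
    out = pd.DataFrame(index=intensities.index)
    for m in MOMP_MARKERS:
        out[m] = (
            intensities[m].to_numpy(float)
            / standards.hela_mean_intensity[m]
            * standards.hela_concentration_um[m]
        )
    return out


def calibrate_caspase_proteins(
    intensities: pd.DataFrame,
    standards: ReferenceStandards,
    cohort_stats: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Median/IQR alignment of the caspase-pathway proteins to the
    reference cohort.

    The observed cohort (median, IQR) per marker — computed from the given
    intensities unless supplied — is mapped onto the reference µM
    (median, IQR); negatives are floored at 0.
    """
    out = pd.DataFrame(index=intensities.index)
    for m in CASPASE_MARKERS:
        x = intensities[m].to_numpy(float)
        if cohort_stats is not None and m in cohort_stats:
            med, iqr = cohort_stats[m]
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
        if iqr <= 0:
            raise ValueError(f"zero IQR for {m}: cannot align to reference")
        ref_med, ref_iqr = standards.cohort_reference_um[m]
        conc = ref_med + (x - med) / iqr * ref_iqr
        out[m] = np.clip(conc, 0.0, None)
    return out


def calibrate_profiles(
    table: CohortTable,
    standards: ReferenceStandards,
    per: str = "cell",
) -> pd.DataFrame:
    """Full ten-protein profiles, per cell or per core (µM).

    Per-core profiles aggregate intensities by median within the core
    first, then convert (aggregate-then-convert), so a single outlier cell
    cannot move the core profile.
    """
    if per == "cell":
        ints = table.cells.set_index("cell_id")[list(MOMP_MARKERS + CASPASE_MARKERS)]
    elif per == "core":
        ints = aggregate_core_intensities(table)
    else:
        raise ValueError(f"per must be 'cell' or 'core', got {per!r}")
    momp = calibrate_momp_proteins(ints, standards)
    casp = calibrate_caspase_proteins(ints, standards)
    profile = pd.concat([momp, casp], axis=1)
    profile["APAF1"] = standards.apaf1_um
    return profile


def aggregate_core_intensities(table: CohortTable, method: str = "median") -> pd.DataFrame:
    """Per-core marker intensities aggregated across cells (median default)."""
    if len(table) == 0:
        raise ValueError("empty table: no cores to aggregate")
    g = table.cells.groupby("core_id", observed=True)[
        list(MOMP_MARKERS + CASPASE_MARKERS)
    ]
    if method == "median":
        return g.median()
    if method == "mean":
        return g.mean()
    raise ValueError(f"unknown aggregation method: {method!r}")
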