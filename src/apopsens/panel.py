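"""Marker panel definitions for the multiplexed immunofluorescence assay.

The default panel carries the nine intrinsic-apoptosis proteins used as
model inputs (five BCL2-family regulators of mitochondrial outer membrane
permeabilization, four caspase-pathway proteins) and the seven lineage
markers used for cell phenotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: BCL2-family proteins feeding the MOMP sensitivity model.
MOMP_MARKERS: tuple[str, ...] = ("BAK", "BAX", "BCL2", "BCL(X)L", "MCL1")

#: Caspase-pathway proteins feeding the caspase-activation model.
CASPASE_MARKERS: tuple[str, ...] = (
    "PRO-CASPASE 3",
    "PRO-CASPASE 9",
    "SMAC",
    "XIAP",
)

APOPTOSIS_MARKERS: tuple[str, ...] = MOMP_MARKERS + CASPASE_MARKERS

#: Lineage markers used for gating and random-forest phenotyping.
LINEAGE_MARKERS: tuple[str, ...] = (
    "CD3",
    "CD4",
    "CD8",
    "CD45",
    "FOXP3",
    "PCK26",
    "AE1",
)

#: The six assignable cell classes, plus the unassigned placeholder.
CELL_TYPES: tuple[str, ...] = (
    "cancer",
    "helper_T",
    "cytotoxic_T",
    "regulatory_T",
    "other_immune",
    "stroma",
)
UNASSIGNED = "unassigned"

IMMUNE_TYPES: tuple[str, ...] = (
    "helper_T",
    "cytotoxic_T",
    "regulatory_T",
    "other_immune",
)

#: Broad strata used for reporting (cancer vs pooled immune vs stroma).
BROAD_STRATA: dict[str, tuple[str, ...]] = {
    "cancer": ("cancer",),
    "immune": IMMUNE_TYPES,
    "stroma": ("stroma",),
}


@dataclass(frozen=True)
class MarkerPanel:
    """The marker set of a cohort plus the per-position image geometry.

    ``markers`` maps each marker name to its role (``apoptosis``,
    ``lineage`` or ``other``).  ``image_width``/``image_height`` give the
    pixel extent of a single imaged position and anchor the margin filter.
    """

    markers: tuple[tuple[str, str], ...] = field(
        default_factory=lambda: tuple(
            [(m, "apoptosis") for m in APOPTOSIS_MARKERS]
            + [(m, "lineage") for m in LINEAGE_MARKERS]
        )
    )
    image_width: float = 2048.0
    image_height: float = 2048.0

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.markers)

    @property
    def apoptosis(self) -> tuple[str, ...]:
        return tuple(n for n, role in self.markers if role == "apoptosis")

    @property
    def lineage(self) -> tuple[str, ...]:
        return tuple(n for n, role in self.markers if role == "lineage")

    def __post_init__(self) -> None:
        names = [n for n, _ in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")


def default_panel(image_width: float = 2048.0, image_height: float = 2048.0) -> MarkerPanel:
    """The shipped 16-marker panel (9 apoptosis + 7 lineage)."""
    return MarkerPanel(image_width=image_width, image_height=image_height)
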