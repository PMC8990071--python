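"""Two-step slide-batch correction for cohort intensity tables.

Stage 1 is upper-quantile normalization per (slide, marker): every group's
75th percentile is scaled onto the across-slide geometric mean of group
quantiles for that marker.  Stage 2 fits, per slide and marker, a straight
line through the quantile-versus-rankit plot of a reference immune
population (regulatory + helper T cells, excluding cells within 5% of the
image margins) and standardizes each slide so that line becomes the unit
diagonal: ``z = (x_uq - a) / b``.  A final pooled linear regression per
marker maps the standardized values back onto the normalized intensity
scale, so corrected intensities are comparable across slides but keep
physical units.

Rankits are the expected standard-normal order statistics, computed with
the Blom approximation ``Phi^-1((i - 3/8) / (n + 1/4))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import CohortTable

REFERENCE_TYPES = ("regulatory_T", "helper_T")


@dataclass
class BatchModel:
    """Fitted correction factors, serializable for audit.

    ``uq_factors[(slide, marker)]`` multiplies raw intensities; ``affine``
    holds the rankit-line intercept/slope ``(a, b)`` per (slide, marker);
    ``restore[marker]`` holds the pooled back-mapping ``(c0, c1)``.
    """

    q: float = 0.75
    uq_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    affine: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    restore: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "q": self.q,
            "uq_factors": {f"{s}|{m}": v for (s, m), v in self.uq_factors.items()},
            "affine": {f"{s}|{m}": list(v) for (s, m), v in self.affine.items()},
            "restore": {m: list(v) for m, v in self.restore.items()},
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BatchModel":
        data = yaml.safe_load(Path(path).read_text())
        split = lambda k: tuple(k.split("|", 1))
        return cls(
            q=data["q"],
            uq_factors={split(k): float(v) for k, v in data["uq_factors"].items()},
            affine={split(k): tuple(map(float, v)) for k, v in data["affine"].items()},
            restore={m: tuple(map(float, v)) for m, v in data["restore"].items()},
        )


def _slides(table: CohortTable) -> list[str]:
    return sorted(table.cells["slide_id"].unique())


def upper_quantile_normalize(
    table: CohortTable,
    q: float = 0.75,
    min_nonzero: int = 10,
    model: BatchModel | None = None,
) -> tuple[CohortTable, BatchModel]:
    """Scale each (slide, marker) group so its q-quantile matches the
    across-slide geometric mean of group q-quantiles for that marker.

    Raw intensities are preserved in ``<marker>__raw`` columns; the
    normalized values are written to ``<marker>__uq`` and become the
    working marker columns.
    """
    out = table.copy()
    model = model or BatchModel(q=q)
    model.q = q
    slides = _slides(out)
    for marker in out.markers:
        by_slide = {}
        for s in slides:
            vals = out.cells.loc[out.cells["slide_id"] == s, marker].to_numpy(float)
            if (vals > 0).sum() < min_nonzero:
                raise ValueError(
                    f"group (slide={s}, marker={marker}) has fewer than "
                    f"{min_nonzero} nonzero intensities"
                )
            qv = float(np.quantile(vals, q))
            if qv <= 0:
                raise ValueError(f"zero {q}-quantile in group (slide={s}, marker={marker})")
            by_slide[s] = qv
        target = float(np.exp(np.mean(np.log(list(by_slide.values())))))
        if f"{marker}__raw" not in out.cells.columns:
            out.cells[f"{marker}__raw"] = out.cells[marker]
        for s in slides:
            factor = target / by_slide[s]
            model.uq_factors[(s, marker)] = factor
            idx = out.cells["slide_id"] == s
            out.cells.loc[idx, marker] = out.cells.loc[idx, marker] * factor
        out.cells[f"{marker}__uq"] = out.cells[marker]
    out.log(f"upper_quantile_normalize: q={q}, {len(slides)} slides")
    return out, model


def rankits(n: int) -> np.ndarray:
    """Blom approximation to expected standard-normal order statistics."""
    i = np.arange(1, n + 1)
    return stats.norm.ppf((i - 0.375) / (n + 0.25))


def fit_rankit_affine(
    table: CohortTable,
    model: BatchModel,
    reference_types: Iterable[str] = REFERENCE_TYPES,
    exclusion_margin_frac: float = 0.05,
    min_ref: int = 50,
) -> BatchModel:
    """Fit the per-(slide, marker) rankit line in the reference population.

    The reference cells are the given types with cells within
    ``exclusion_margin_frac`` of the image margins excluded.  Ordered
    reference quantiles are regressed on their rankits; the fitted
    ``(a, b)`` standardizes that slide's reference distribution to the
    unit diagonal.  Requires upper-quantile-normalized intensities.
    """
    cells = table.cells
    w, h = table.panel.image_width, table.panel.image_height
    fx, fy = exclusion_margin_frac * w, exclusion_margin_frac * h
    ref = cells[
        cells["cell_type"].isin(tuple(reference_types))
        & (cells["x"] >= fx) & (cells["x"] <= w - fx)
        & (cells["y"] >= fy) & (cells["y"] <= h - fy)
    ]
    for s in _slides(table):
        sub = ref[ref["slide_id"] == s]
        if len(sub) < min_ref:
            raise ValueError(
                f"slide {s}: only {len(sub)} reference cells after margin "
                f"exclusion (need >= {min_ref})"
            )
        for marker in table.markers:
            vals = np.sort(sub[marker].to_numpy(float))
            r = rankits(len(vals))
            b, a = np.polyfit(r, vals, 1)
            if b <= 0:
                raise ValueError(f"non-positive rankit slope for ({s}, {marker})")
            model.affine[(s, marker)] = (float(a), float(b))
    return model


def apply_batch_model(table: CohortTable, model: BatchModel) -> CohortTable:
    """Standardize every cell: ``z = (x_uq - a) / b`` per (slide, marker).

    Strictly increasing per group, so within-slide rank order is preserved.
    """
    out = table.copy()
    for s in _slides(out):
        idx = out.cells["slide_id"] == s
        for marker in out.markers:
            if (s, marker) not in model.affine:
                raise ValueError(f"batch model missing entry for ({s}, {marker})")
            a, b = model.affine[(s, marker)]
            out.cells.loc[idx, marker] = (
                out.cells.loc[idx, marker].to_numpy(float) - a
            ) / b
    out.log("apply_batch_model: rankit-affine standardization applied")
    return out


def restore_intensity_scale(table: CohortTable, model: BatchModel) -> CohortTable:
    """Map standardized values back to the normalized-intensity scale.

    Per marker, one pooled OLS regression of the upper-quantile-normalized
    intensities on the standardized values defines ``(c0, c1)``; restored
    values are floored at 0 (intensities are non-negative).
    """
    out = table.copy()
    n_floored = 0
    for marker in out.markers:
        uq_col = f"{marker}__uq"
        if uq_col not in out.cells.columns:
            raise ValueError("restore requires upper-quantile-normalized columns")
        z = out.cells[marker].to_numpy(float)
        xuq = out.cells[uq_col].to_numpy(float)
        if np.ptp(z) == 0:
            raise ValueError(f"degenerate restore regression for {marker} (zero spread)")
        c1, c0 = np.polyfit(z, xuq, 1)
        model.restore[marker] = (float(c0), float(c1))
        restored = c0 + c1 * z
        n_floored += int((restored < 0).sum())
        out.cells[marker] = np.clip(restored, 0.0, None)
    out.log(f"restore_intensity_scale: {n_floored} values floored at 0")
    return out


def correct_batch(
    table: CohortTable,
    q: float = 0.75,
    reference_types: Iterable[str] = REFERENCE_TYPES,
    exclusion_margin_frac: float = 0.05,
    min_ref: int = 50,
) -> tuple[CohortTable, BatchModel]:
    """Run the full correction: UQ-normalize, fit rankit affine in the
    reference immune cells, standardize all cells, restore the scale."""
    out, model = upper_quantile_normalize(table, q=q)
    model = fit_rankit_affine(
        out, model, reference_types=reference_types,
        exclusion_margin_frac=exclusion_margin_frac, min_ref=min_ref,
    )
    out = apply_batch_model(out, model)
    out = restore_intensity_scale(out, model)
    return out, model


def estimated_relative_gains(model: BatchModel) -> pd.DataFrame:
    """Relative slide gains implied by the fitted model.

    For a slide with true multiplicative gain g, the reference rankit slope
    satisfies ``b = f * g * sigma_ref`` with f the UQ factor, so ``b / f``
    normalized by its geometric mean across slides estimates the gain up to
    the common reference spread.  Rows: slide_id, marker, relative_gain.
    """
    rows = []
    markers = sorted({m for _, m in model.affine})
    for marker in markers:
        slides = sorted({s for s, m in model.affine if m == marker})
        raw = {
            s: model.affine[(s, marker)][1] / model.uq_factors[(s, marker)]
            for s in slides
        }
        gmean = float(np.exp(np.mean(np.log(list(raw.values())))))
        for s in slides:
            rows.append((s, marker, raw[s] / gmean))
    return pd.DataFrame(rows, columns=["slide_id", "marker", "relative_gain"])
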