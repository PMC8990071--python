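"""Cell phenotyping: rule-gate annotation plus random-forest classification.

A small training subset is labeled with an ordered gating hierarchy on
lineage-marker positivity (epithelial first, then CD3+ T-cell subtypes,
then CD3- leukocytes, stroma last), and a 2000-tree random forest trained
on the seven lineage markers generalizes those labels to every cell.
Out-of-bag per-class type-II error (false-negative rate) is reported with
the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.ensemble import RandomForestClassifier
from sklearn.mixture import GaussianMixture

from .cohort import CohortTable
from .panel import CELL_TYPES, LINEAGE_MARKERS

FEATURES: tuple[str, ...] = LINEAGE_MARKERS


@dataclass
class GateConfig:
    """Per-marker positivity thresholds on (corrected) intensities.

    A cell is positive for a marker when its intensity exceeds the
    threshold.  ``epithelial_markers`` defines the top gate;
    ``foxp3_precedence`` resolves CD4+FOXP3+ double positives to
    regulatory T cells.
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    epithelial_markers: tuple[str, ...] = ("AE1", "PCK26")
    foxp3_precedence: bool = True

    def positive(self, cells: pd.DataFrame, marker: str) -> np.ndarray:
        return cells[marker].to_numpy(float) > self.thresholds[marker]


def derive_gates(
    table: CohortTable,
    markers: Sequence[str] = FEATURES,
    method: str = "gmm",
    seed: int = 0,
) -> GateConfig:
    """Data-driven positivity thresholds on log-intensity per marker.

    ``gmm`` (default) fits a two-component Gaussian mixture and places the
    cut at the equal-posterior point between the component means — robust
    when the positive class is rare (a marker positive in ~1% of cells
    leaves Otsu's between-class variance criterion with nothing to split).
    ``otsu`` is available for strongly bimodal markers.
    """
    thresholds = {}
    for m in markers:
        x = table.cells[m].to_numpy(float)
        # exact zeros are floored values, not a biological mode
        logx = np.log1p(x[x > 0])
        if method == "otsu":
            cut = threshold_otsu(logx)
        elif method == "gmm":
            gm = GaussianMixture(n_components=2, n_init=3, random_state=seed)
            gm.fit(logx.reshape(-1, 1))
            means = gm.means_.ravel()
            sds = np.sqrt(gm.covariances_.ravel())
            lo, hi = np.argsort(means)
            separation = (means[hi] - means[lo]) / np.sqrt(np.mean(sds**2))
            if separation >= 2.0 and gm.weights_.min() >= 0.005:
                # unweighted midpoint of the component means: stays between
                # the modes even when the positive class is rare
                cut = float(0.5 * (means[lo] + means[hi]))
            else:
                # no resolvable positive mode: upper-tail rule on the
                # robust spread of the negative bulk
                med = np.median(logx)
                mad_sd = 1.4826 * np.median(np.abs(logx - med))
                cut = float(med + 3.0 * mad_sd)
        else:
            raise ValueError(f"unknown gating method: {method!r}")
        thresholds[m] = float(np.expm1(cut))
    return GateConfig(thresholds=thresholds)


def gate_label(pos: Mapping[str, bool], gates: GateConfig) -> str:
    """Apply the ordered hierarchy to one cell's positivity calls."""
    if any(pos[m] for m in gates.epithelial_markers):
        return "cancer"
    if pos["CD3"]:
        if gates.foxp3_precedence and pos["FOXP3"]:
            return "regulatory_T"
        if pos["CD4"]:
            return "helper_T"
        if pos["CD8"]:
            return "cytotoxic_T"
        if pos["FOXP3"]:
            return "regulatory_T"
        return "other_immune"
    if pos["CD4"] or pos["CD45"] or pos["CD8"]:
        return "other_immune"
    return "stroma"


def annotate_by_gates(
    table: CohortTable,
    gates: GateConfig,
    sample_frac: float = 0.006,
    seed: int | None = None,
) -> pd.DataFrame:
    """Label a random training subset through the gating hierarchy.

    Returns a copy of the sampled rows with a ``gate_label`` column and an
    ``ambiguous`` flag marking double-positive cells resolved by hierarchy
    order (e.g. epithelial+ and CD3+).
    """
    missing = [m for m in FEATURES if m not in gates.thresholds]
    if missing:
        raise ValueError(f"gates missing thresholds for {missing}")
    n = max(1, int(round(sample_frac * len(table))))
    sub = table.cells.sample(
        n=min(n, len(table)), random_state=seed, replace=False
    ).copy()
    pos = {m: gates.positive(sub, m) for m in FEATURES}
    labels, ambiguous = [], []
    for i in range(len(sub)):
        p = {m: bool(pos[m][i]) for m in FEATURES}
        labels.append(gate_label(p, gates))
        epi = any(p[m] for m in gates.epithelial_markers)
        ambiguous.append(epi and (p["CD3"] or p["CD45"]))
    sub["gate_label"] = labels
    sub["ambiguous"] = ambiguous
    return sub


def annotate_per_slide(
    table: CohortTable,
    sample_frac: float = 1.0,
    seed: int | None = None,
    method: str = "gmm",
) -> pd.DataFrame:
    """Gate-annotate with slide-dependent thresholds.

    Before batch correction a single global threshold is wrong whenever a
    slide carries a multiplicative distortion, so gates are derived and
    applied per slide.  Used to define the batch-correction reference
    population (regulatory/helper T cells per slide).
    """
    parts = []
    for slide, idx in table.cells.groupby("slide_id", observed=True).groups.items():
        sub = CohortTable(table.cells.loc[idx], table.panel)
        gates = derive_gates(sub, method=method)
        parts.append(annotate_by_gates(sub, gates, sample_frac=sample_frac, seed=seed))
    return pd.concat(parts).sort_index()


@dataclass
class ClassifierModel:
    """Trained forest plus its feature list, classes, and OOB error table."""

    forest: RandomForestClassifier
    features: tuple[str, ...]
    classes: tuple[str, ...]
    oob_type2_error: dict[str, float]


def train_classifier(
    labeled: pd.DataFrame,
    features: Sequence[str] = FEATURES,
    n_trees: int = 2000,
    seed: int | None = 0,
    min_train: int = 20,
    label_column: str = "gate_label",
) -> ClassifierModel:
    """Train the random forest on gate-annotated cells.

    Every one of the six classes must be present with at least
    ``min_train`` examples.  Out-of-bag votes give the per-class type-II
    (false-negative) error reported alongside the model.
    """
    counts = labeled[label_column].value_counts()
    missing = [c for c in CELL_TYPES if counts.get(c, 0) == 0]
    if missing:
        raise ValueError(f"class(es) absent from training data: {missing}")
    weak = [c for c in CELL_TYPES if counts.get(c, 0) < min_train]
    if weak:
        raise ValueError(
            f"class(es) below min_train={min_train}: "
            + ", ".join(f"{c} (n={counts[c]})" for c in weak)
        )
    X = labeled[list(features)].to_numpy(float)
    y = labeled[label_column].to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)

    oob = forest.oob_decision_function_
    pred = forest.classes_[np.argmax(oob, axis=1)]
    # rows without any OOB vote (possible at tiny n) are excluded
    voted = oob.sum(axis=1) > 0
    errors = {}
    for c in forest.classes_:
        mask = (y == c) & voted
        errors[str(c)] = float(np.mean(pred[mask] != c)) if mask.any() else float("nan")
    return ClassifierModel(
        forest=forest,
        features=tuple(features),
        classes=tuple(str(c) for c in forest.classes_),
        oob_type2_error=errors,
    )


def classify(table: CohortTable, model: ClassifierModel) -> CohortTable:
    """Assign every cell one of the six classes; majority vote fraction is
    recorded in ``type_confidence``."""
    missing = [f for f in model.features if f not in table.cells.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    out = table.copy()
    X = out.cells[list(model.features)].to_numpy(float)
    proba = model.forest.predict_proba(X)
    idx = np.argmax(proba, axis=1)
    out.cells["cell_type"] = model.forest.classes_[idx]
    out.cells["type_confidence"] = proba[np.arange(len(idx)), idx]
    out.log(f"classify: {len(out)} cells typed with {len(model.forest.estimators_)} trees")
    return out


def type_fractions(table: CohortTable) -> pd.DataFrame:
    """Per-core cell-type composition (fractions sum to 1 per core)."""
    counts = (
        table.cells.groupby(["core_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)
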