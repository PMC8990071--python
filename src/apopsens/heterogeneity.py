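"""Inter- and intra-tumor heterogeneity statistics.

Quartile coefficient of dispersion (Q3-Q1)/(Q3+Q1), Shannon entropy of
binary state calls (log2, bits) and of z-score-binned protein levels
(natural log, bin width 0.1 SD), spatial autocorrelation via Moran's I
with inverse-distance weights capped at 2000 px, and a seeded bootstrap
testing whether cores of the same tumor have more similar cell-type
composition than random core pairings.

Moran's I conventions: computed without outliers (Tukey fences) and only
on populations of at least ``min_n`` cells (default 100); smaller
populations return ``None`` ("not computed").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

EPSILON = 1e-10


def quartile_cod(values: Sequence[float]) -> float:
    """Quartile coefficient of dispersion (Q3 - Q1) / (Q3 + Q1).

    Quartiles use linear interpolation.  Scale-invariant for positive
    scalings; 0 for constant data.
    """
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.percentile(x, [25, 75])
    if q1 + q3 == 0:
        raise ValueError("Q1 + Q3 is zero: COD undefined")
    return float((q3 - q1) / (q3 + q1))


def shannon_entropy_binary(labels: Sequence) -> float:
    """Entropy (bits) of a two-state label vector.

    ``H = -sum (p + eps) * log2(p + eps)`` over the two class proportions,
    with eps = 1e-10 guarding log(0).  0 for a single-state population,
    1 bit for a 50/50 split.
    """
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label vector")
    classes = pd.unique(arr)
    if len(classes) > 2:
        raise ValueError(f"expected <= 2 classes, got {len(classes)}")
    p = np.array([(arr == c).mean() for c in classes])
    if len(p) == 1:
        p = np.append(p, 0.0)
    q = p + EPSILON
    return float(-(q * np.log2(q)).sum())


def shannon_entropy_binned(values: Sequence[float], bin_width_sd: float = 0.1) -> float:
    """Entropy (nats) of z-scored values binned at ``bin_width_sd`` SD.

    ``H = -sum p_i * ln(p_i + eps)`` over occupied-bin proportions.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero standard deviation: binning undefined")
    z = (x - x.mean()) / sd
    bins = np.floor(z / bin_width_sd).astype(int)
    counts = np.bincount(bins - bins.min())
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p + EPSILON)).sum())


def _tukey_mask(x: np.ndarray, k: float = 1.5) -> np.ndarray:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x >= q1 - k * iqr) & (x <= q3 + k * iqr)


def _weight_matrix(
    coords: np.ndarray,
    scheme: str,
    distance_cap: float,
    spacing: float | None,
    min_distance: float,
) -> np.ndarray:
    d = squareform(pdist(coords))
    if scheme == "inverse_distance_capped":
        d = np.minimum(d, distance_cap)
        d = np.maximum(d, min_distance)  # guard coincident centroids
        w = 1.0 / d
    elif scheme == "rook_adjacency":
        if spacing is None:
            off = d[~np.eye(len(d), dtype=bool)]
            spacing = float(off.min())
        w = (np.abs(d - spacing) < 1e-9 * max(spacing, 1.0)).astype(float)
    else:
        raise ValueError(f"unknown weight scheme: {scheme!r}")
    np.fill_diagonal(w, 0.0)
    return w


def morans_i(
    values: Sequence[float],
    coords: np.ndarray,
    scheme: str = "inverse_distance_capped",
    distance_cap: float = 2000.0,
    spacing: float | None = None,
    min_n: int = 100,
    outlier_rule: str | None = "tukey",
    min_distance: float = 1.0,
) -> float | None:
    """Moran's I spatial autocorrelation, or ``None`` below ``min_n`` cells.

    ``I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``
    with w_ij = 1 / min(d_ij, cap) by default, or binary rook adjacency for
    lattice patterns.  Outliers (Tukey fences, 1.5 IQR) are removed first;
    +1 marks spatial clustering/separation, 0 randomness, -1 perfect
    dispersion (checkerboard).
    """
    x = np.asarray(values, float)
    c = np.asarray(coords, float)
    if len(x) != len(c):
        raise ValueError("values and coords are misaligned")
    if outlier_rule == "tukey":
        keep = _tukey_mask(x)
        x, c = x[keep], c[keep]
    elif outlier_rule is not None:
        raise ValueError(f"unknown outlier rule: {outlier_rule!r}")
    n = len(x)
    if n < min_n:
        return None
    dev = x - x.mean()
    denom = float(dev @ dev)
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined")
    w = _weight_matrix(c, scheme, distance_cap, spacing, min_distance)
    W = w.sum()
    if W <= 0:
        raise ValueError("weight matrix sums to zero")
    num = float(dev @ w @ dev)
    return float(n / W * num / denom)


@dataclass(frozen=True)
class BootstrapResult:
    observed: float
    null: np.ndarray
    p_value: float
    n_reps: int


def bootstrap_composition_pairing(
    compositions: pd.DataFrame,
    patient_ids: Sequence[str],
    n_reps: int = 100_000,
    seed: int = 42,
    metric: str = "euclidean",
) -> BootstrapResult:
    """Are same-patient cores more alike in composition than random pairs?

    ``compositions`` holds one cell-type fraction vector per core (rows
    aligned with ``patient_ids``).  The observed statistic is the mean
    within-patient pairwise distance over patients with >= 2 cores; the
    null re-pairs cores at random (keeping group sizes), ``n_reps`` times,
    seeded.  The empirical p-value is the fraction of null statistics <=
    the observed one (small p: same-tumor cores are more similar).
    """
    X = compositions.to_numpy(float)
    pats = np.asarray(patient_ids)
    if len(X) != len(pats):
        raise ValueError("compositions and patient_ids are misaligned")
    if metric == "euclidean":
        D = squareform(pdist(X))
    elif metric == "jensenshannon":
        D = squareform(pdist(X, metric="jensenshannon"))
    else:
        raise ValueError(f"unknown metric: {metric!r}")

    # fixed group structure: within-group index pairs on a permuted order
    order = np.argsort(pats, kind="stable")
    sorted_pats = pats[order]
    start = 0
    pair_i, pair_j = [], []
    while start < len(sorted_pats):
        end = start
        while end < len(sorted_pats) and sorted_pats[end] == sorted_pats[start]:
            end += 1
        if end - start >= 2:
            for a in range(start, end):
                for b in range(a + 1, end):
                    pair_i.append(a)
                    pair_j.append(b)
        start = end
    if not pair_i:
        raise ValueError("no patient has >= 2 cores: nothing to pair")
    pair_i = np.asarray(pair_i)
    pair_j = np.asarray(pair_j)

    observed = float(D[order[pair_i], order[pair_j]].mean())

    rng = np.random.default_rng(seed)
    n = len(pats)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(n)
        null[r] = D[perm[pair_i], perm[pair_j]].mean()
    p = float((null <= observed).mean())
    return BootstrapResult(observed=observed, null=null, p_value=p, n_reps=n_reps)


def core_summary(
    cells: pd.DataFrame,
    markers: Sequence[str],
    min_n: int = 100,
    morans_markers: Sequence[str] | None = None,
    image_size: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-core, per-stratum heterogeneity summary.

    ``cells`` must carry ``core_id``, ``cell_type``, coordinates and the
    model readout columns ``momp_low`` (bool), ``caspase_high`` (bool) and
    ``quadrant``.  Strata are cancer / pooled immune / stroma.  For each
    core x stratum the summary reports cell count, low/high fractions for
    both models, the four quadrant fractions, binary entropies of both
    calls, quartile COD and binned entropy per marker, and Moran's I of
    the binary calls (inverse-distance weights).  Populations below
    ``min_n`` report NaN for the heterogeneity metrics.
    """
    from .panel import BROAD_STRATA

    morans_markers = list(morans_markers or [])
    rows = []
    for core_id, core in cells.groupby("core_id", observed=True):
        for stratum, types in BROAD_STRATA.items():
            sub = core[core["cell_type"].isin(types)]
            n = len(sub)
            row: dict = {"core_id": core_id, "stratum": stratum, "n_cells": n}
            if n > 0:
                momp_low = sub["momp_low"].to_numpy(bool)
                casp_high = sub["caspase_high"].to_numpy(bool)
                row["frac_momp_low"] = momp_low.mean()
                row["frac_momp_high"] = 1.0 - momp_low.mean()
                row["frac_caspase_high"] = casp_high.mean()
                row["frac_caspase_low"] = 1.0 - casp_high.mean()
                for q in ("both_high", "momp_only", "caspase_only", "both_low"):
                    row[f"frac_{q}"] = (sub["quadrant"] == q).mean()
            ok = n >= min_n
            coords = sub[["x", "y"]].to_numpy(float) if n else None
            if ok:
                row["entropy_momp_bits"] = shannon_entropy_binary(
                    sub["momp_low"].to_numpy(bool))
                row["entropy_caspase_bits"] = shannon_entropy_binary(
                    sub["caspase_high"].to_numpy(bool))
                for call, col in (("momp", "momp_low"), ("caspase", "caspase_high")):
                    vals = sub[col].to_numpy(float)
                    try:
                        row[f"morans_i_{call}"] = morans_i(
                            vals, coords, min_n=min_n, outlier_rule=None)
                    except ValueError:
                        row[f"morans_i_{call}"] = np.nan
                for m in markers:
                    vals = sub[m].to_numpy(float)
                    try:
                        row[f"cod_{m}"] = quartile_cod(vals)
                    except ValueError:
                        row[f"cod_{m}"] = np.nan
                    try:
                        row[f"entropy_{m}_nats"] = shannon_entropy_binned(vals)
                    except ValueError:
                        row[f"entropy_{m}_nats"] = np.nan
                for m in morans_markers:
                    try:
                        row[f"morans_i_{m}"] = morans_i(
                            sub[m].to_numpy(float), coords, min_n=min_n)
                    except ValueError:
                        row[f"morans_i_{m}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
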