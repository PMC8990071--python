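"""Batch correction: quantile normalization, rankit-affine fitting,
application, restoration, and ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apopsens.batch import (
    BatchModel,
    apply_batch_model,
    correct_batch,
    estimated_relative_gains,
    fit_rankit_affine,
    rankits,
    restore_intensity_scale,
    upper_quantile_normalize,
)
from apopsens.celltyping import annotate_per_slide
from apopsens.cohort import CohortTable
from apopsens.synthetic import inject_batch_effects

GAINS = {"S0": 1.0, "S1": 2.0, "S2": 0.5}
OFFSET = 5.0


@pytest.fixture(scope="module")
def distorted(medium_cohort):
    """Medium cohort with known slide gains/offsets and gate-based
    preliminary labels (the batch-correction entry state)."""
    table, truth = medium_cohort
    model = {s: {m: (g, OFFSET) for m in table.markers} for s, g in GAINS.items()}
    dist, factors = inject_batch_effects(table, model)
    ann = annotate_per_slide(dist, sample_frac=1.0, seed=0)
    prelim = dist.copy()
    prelim.cells.loc[ann.index, "cell_type"] = ann["gate_label"]
    return prelim, truth


class TestUpperQuantile:
    def test_single_slide_factors_unity(self, small_cohort):
        table, _ = small_cohort
        one = CohortTable(
            table.cells[table.cells.slide_id == "S0"].copy(), table.panel)
        out, model = upper_quantile_normalize(one)
        assert all(f == pytest.approx(1.0) for f in model.uq_factors.values())

    def test_doubled_slide_realigns_quantiles(self, small_cohort):
        table, _ = small_cohort
        dist, _ = inject_batch_effects(
            table, {"S1": {m: (2.0, 0.0) for m in table.markers}})
        out, _ = upper_quantile_normalize(dist)
        for m in ("BAK", "BCL2"):
            qs = out.cells.groupby("slide_id")[m].quantile(0.75)
            assert qs.max() / qs.min() == pytest.approx(1.0, rel=1e-9)

    def test_all_zero_group_errors(self, small_cohort):
        table, _ = small_cohort
        bad = table.copy()
        bad.cells.loc[bad.cells.slide_id == "S0", "BAK"] = 0.0
        with pytest.raises(ValueError, match="BAK"):
            upper_quantile_normalize(bad)


class TestRankitAffine:
    def test_recovers_normal_location_and_scale(self):
        # ordered quantiles of N(mu, sigma) regressed on rankits give
        # intercept ~ mu and slope ~ sigma
        rng = np.random.default_rng(0)
        mu, sigma, n = 40.0, 6.0, 4000
        vals = np.sort(rng.normal(mu, sigma, n))
        b, a = np.polyfit(rankits(n), vals, 1)
        assert a == pytest.approx(mu, abs=3 * sigma / np.sqrt(n))
        assert b == pytest.approx(sigma, rel=0.05)

    def test_identical_slides_get_identical_affine(self, small_cohort):
        table, _ = small_cohort
        cells = table.cells[table.cells.slide_id == "S0"].copy()
        dup = cells.copy()
        dup["slide_id"] = "S1"
        dup["cell_id"] = dup["cell_id"] + "_b"
        both = CohortTable(pd.concat([cells, dup], ignore_index=True), table.panel)
        ann = annotate_per_slide(both, seed=0)
        both.cells.loc[ann.index, "cell_type"] = ann["gate_label"]
        out, model = upper_quantile_normalize(both)
        model = fit_rankit_affine(out, model, min_ref=10)
        for m in both.markers:
            a0, b0 = model.affine[("S0", m)]
            a1, b1 = model.affine[("S1", m)]
            assert a0 == pytest.approx(a1) and b0 == pytest.approx(b1)

    def test_too_few_reference_cells_errors(self, small_cohort):
        table, _ = small_cohort
        t = table.copy()
        t.cells["cell_type"] = "cancer"  # no reference T cells at all
        out, model = upper_quantile_normalize(t)
        with pytest.raises(ValueError, match="reference cells"):
            fit_rankit_affine(out, model)


class TestApplyAndRestore:
    def test_identity_affine_changes_nothing(self, small_cohort):
        table, _ = small_cohort
        out, model = upper_quantile_normalize(table)
        for s in out.cells.slide_id.unique():
            for m in out.markers:
                model.affine[(s, m)] = (0.0, 1.0)
        applied = apply_batch_model(out, model)
        for m in out.markers:
            np.testing.assert_allclose(applied.cells[m], out.cells[m])

    def test_missing_model_entry_errors(self, small_cohort):
        table, _ = small_cohort
        out, model = upper_quantile_normalize(table)
        with pytest.raises(ValueError, match="missing entry"):
            apply_batch_model(out, model)

    def test_monotonicity_within_slide(self, distorted):
        prelim, _ = distorted
        corrected, _ = correct_batch(prelim, min_ref=20)
        for s in ("S0", "S1"):
            sub_in = prelim.cells[prelim.cells.slide_id == s]["BCL2"].to_numpy()
            sub_out = corrected.cells[corrected.cells.slide_id == s]["BCL2"].to_numpy()
            # floor at 0 may merge ties at the bottom; compare above floor
            positive = sub_out > 0
            assert (np.argsort(sub_in[positive], kind="stable")
                    == np.argsort(sub_out[positive], kind="stable")).all()

    def test_undistorted_cohort_round_trips(self, medium_cohort):
        # no batch distortion: correction must approximately return the
        # upper-quantile-normalized values
        table, _ = medium_cohort
        ann = annotate_per_slide(table, seed=0)
        prelim = table.copy()
        prelim.cells.loc[ann.index, "cell_type"] = ann["gate_label"]
        corrected, model = correct_batch(prelim, min_ref=20)
        for m in ("BAK", "BCL2"):
            uq = corrected.cells[f"{m}__uq"].to_numpy()
            rest = corrected.cells[m].to_numpy()
            # medians per slide agree within a few percent
            med_ratio = np.median(rest) / np.median(uq)
            assert med_ratio == pytest.approx(1.0, rel=0.10)

    def test_restore_degenerate_regression_errors(self, small_cohort):
        table, _ = small_cohort
        out, model = upper_quantile_normalize(table)
        out.cells["BAK"] = 1.0  # zero spread in z
        with pytest.raises(ValueError, match="zero spread|degenerate"):
            restore_intensity_scale(out, model)


class TestRecovery:
    def test_injected_gains_recovered_within_10pct(self, distorted):
        prelim, _ = distorted
        _, model = correct_batch(prelim, min_ref=20)
        rg = estimated_relative_gains(model)
        gmean = np.exp(np.mean(np.log(list(GAINS.values()))))
        true_norm = {s: g / gmean for s, g in GAINS.items()}
        rel_err = rg.apply(
            lambda r: abs(r.relative_gain / true_norm[r.slide_id] - 1.0), axis=1)
        assert rel_err.median() < 0.10

    def test_correction_reduces_reference_ks_distance(self, distorted):
        prelim, _ = distorted
        corrected, _ = correct_batch(prelim, min_ref=20)
        ref_types = ["regulatory_T", "helper_T"]
        before = prelim.cells[prelim.cells.cell_type.isin(ref_types)]
        after = corrected.cells[corrected.cells.cell_type.isin(ref_types)]
        improved = 0
        total = 0
        for m in prelim.markers:
            ks_b = stats.ks_2samp(
                before[before.slide_id == "S0"][m],
                before[before.slide_id == "S1"][m]).statistic
            ks_a = stats.ks_2samp(
                after[after.slide_id == "S0"][m],
                after[after.slide_id == "S1"][m]).statistic
            total += 1
            improved += ks_a < ks_b
        assert improved / total >= 0.8

    def test_model_yaml_round_trip(self, tmp_path, distorted):
        prelim, _ = distorted
        _, model = correct_batch(prelim, min_ref=20)
        path = tmp_path / "bm.yaml"
        model.to_yaml(path)
        back = BatchModel.from_yaml(path)
        assert back.q == model.q
        assert back.affine == {k: tuple(v) for k, v in model.affine.items()}
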