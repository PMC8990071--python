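"""Heterogeneity statistics against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apopsens.heterogeneity import (
    bootstrap_composition_pairing,
    core_summary,
    morans_i,
    quartile_cod,
    shannon_entropy_binary,
    shannon_entropy_binned,
)
from apopsens.synthetic import generate_spatial_pattern


class TestQuartileCod:
    def test_constant_values_zero(self):
        assert quartile_cod([5.0] * 10) == 0.0

    def test_linear_interpolation_quartiles(self):
        # {1..5}: Q1=2, Q3=4 -> (4-2)/(4+2) = 1/3
        assert quartile_cod([1, 2, 3, 4, 5]) == pytest.approx(1 / 3)

    def test_matches_direct_quartile_computation(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1, 0.8, 500)
        q1, q3 = np.percentile(x, [25, 75])
        assert quartile_cod(x) == pytest.approx((q3 - q1) / (q3 + q1))

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert quartile_cod(c * x) == pytest.approx(quartile_cod(x))

    def test_degenerate_zero_sum_errors(self):
        with pytest.raises(ValueError):
            quartile_cod([0.0, 0.0, 0.0, 0.0])


class TestBinaryEntropy:
    def test_even_split_one_bit(self):
        labels = [0, 1] * 50
        assert shannon_entropy_binary(labels) == pytest.approx(1.0, abs=1e-8)

    def test_single_class_near_zero(self):
        assert shannon_entropy_binary([1] * 40) == pytest.approx(0.0, abs=1e-8)

    def test_quarter_split_closed_form(self):
        labels = [1] * 25 + [0] * 75
        expected = -0.25 * np.log2(0.25) - 0.75 * np.log2(0.75)
        assert shannon_entropy_binary(labels) == pytest.approx(expected, abs=1e-8)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 200)
        h1 = shannon_entropy_binary(labels)
        h2 = shannon_entropy_binary(rng.permutation(labels))
        assert h1 == pytest.approx(h2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy_binary([])


class TestBinnedEntropy:
    def test_uniform_occupancy_gives_log_k(self):
        # values placed exactly one per bin after z-scoring is fragile;
        # instead: two equally occupied bins -> ln 2
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert shannon_entropy_binned(x) == pytest.approx(np.log(2), abs=1e-6)

    def test_matches_independent_histogram_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100_000)
        # oracle: explicit histogram on the same z-score bin edges
        z = (x - x.mean()) / x.std()
        lo = np.floor(z.min() / 0.1)
        hi = np.ceil(z.max() / 0.1)
        edges = np.arange(lo, hi + 1) * 0.1
        counts, _ = np.histogram(z, bins=edges)
        p = counts[counts > 0] / len(z)
        oracle = -(p * np.log(p + 1e-10)).sum()
        assert shannon_entropy_binned(x) == pytest.approx(oracle, abs=1e-6)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            shannon_entropy_binned(np.ones(10))


def brute_force_morans(values, w):
    """Double-loop Moran's I oracle."""
    x = np.asarray(values, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    W = 0.0
    for i in range(n):
        for j in range(n):
            num += w[i, j] * (x[i] - xbar) * (x[j] - xbar)
            W += w[i, j]
    return n / W * num / ((x - xbar) ** 2).sum()


class TestMoransI:
    def test_checkerboard_rook_is_minus_one(self):
        coords, labels = generate_spatial_pattern("checkerboard", 8)
        val = morans_i(labels, coords, scheme="rook_adjacency", spacing=1.0,
                       min_n=1, outlier_rule=None)
        assert val == pytest.approx(-1.0, abs=1e-12)

    def test_constant_field_errors(self):
        coords, _ = generate_spatial_pattern("checkerboard", 5)
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(25), coords, min_n=1, outlier_rule=None)

    def test_below_min_population_returns_sentinel(self):
        coords, labels = generate_spatial_pattern("checkerboard", 8)
        assert morans_i(labels, coords, min_n=100) is None

    def test_permutation_null_mean(self):
        # E[I] under random permutation is exactly -1/(N-1)
        rng = np.random.default_rng(4)
        coords, labels = generate_spatial_pattern("split", 8)
        vals = []
        for _ in range(300):
            perm = rng.permutation(labels)
            vals.append(morans_i(perm, coords, scheme="rook_adjacency",
                                 spacing=1.0, min_n=1, outlier_rule=None))
        n = len(labels)
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_pattern_ordering_split_random_checkerboard(self):
        n = 10
        _, split = generate_spatial_pattern("split", n)
        coords, checker = generate_spatial_pattern("checkerboard", n)
        _, rand = generate_spatial_pattern("random", n, seed=0)
        kw = dict(scheme="rook_adjacency", spacing=1.0, min_n=1, outlier_rule=None)
        i_split = morans_i(split, coords, **kw)
        i_rand = morans_i(rand, coords, **kw)
        i_check = morans_i(checker, coords, **kw)
        assert i_split > i_rand > i_check

    @pytest.mark.parametrize("scheme,kwargs", [
        ("inverse_distance_capped", {"distance_cap": 6.0}),
        ("rook_adjacency", {"spacing": 1.0}),
    ])
    def test_matches_brute_force_oracle(self, scheme, kwargs):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 30, size=(120, 2))
        if scheme == "rook_adjacency":
            coords, _ = generate_spatial_pattern("checkerboard", 11)
            coords = coords[:120]
        values = rng.normal(0, 1, 120)
        fast = morans_i(values, coords, scheme=scheme, min_n=1,
                        outlier_rule=None, **kwargs)
        # oracle weight matrix built independently
        from scipy.spatial.distance import cdist
        d = cdist(coords, coords)
        if scheme == "inverse_distance_capped":
            w = 1.0 / np.maximum(np.minimum(d, kwargs["distance_cap"]), 1.0)
        else:
            w = (np.abs(d - 1.0) < 1e-9).astype(float)
        np.fill_diagonal(w, 0.0)
        assert fast == pytest.approx(brute_force_morans(values, w), abs=1e-10)

    def test_outlier_removal_applied(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 100, size=(150, 2))
        values = rng.normal(10, 1, 150)
        values[0] = 1e6
        with_rule = morans_i(values, coords, min_n=10)
        without = morans_i(values, coords, min_n=10, outlier_rule=None)
        assert with_rule != without


class TestBootstrap:
    def _compositions(self, rng, n_patients=8, effect=0.3):
        rows, pats = [], []
        for p in range(n_patients):
            center = rng.dirichlet([5, 3, 2]) if effect == 0 else None
            base = rng.dirichlet([5, 3, 2])
            for c in range(2):
                comp = (1 - effect) * rng.dirichlet([5, 3, 2]) + effect * base
                rows.append(comp / comp.sum())
                pats.append(f"P{p}")
        return pd.DataFrame(rows), pats

    def test_identical_cores_give_zero_observed_high_p(self):
        comp = pd.DataFrame([[0.5, 0.3, 0.2]] * 8)
        pats = ["P0", "P0", "P1", "P1", "P2", "P2", "P3", "P3"]
        res = bootstrap_composition_pairing(comp, pats, n_reps=500, seed=42)
        assert res.observed == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_patient_effect_detected(self):
        rng = np.random.default_rng(7)
        comp, pats = self._compositions(rng, n_patients=12, effect=0.9)
        res = bootstrap_composition_pairing(comp, pats, n_reps=10_000, seed=42)
        assert res.p_value < 0.01

    def test_seed_reproduces_null(self):
        rng = np.random.default_rng(8)
        comp, pats = self._compositions(rng)
        r1 = bootstrap_composition_pairing(comp, pats, n_reps=300, seed=42)
        r2 = bootstrap_composition_pairing(comp, pats, n_reps=300, seed=42)
        np.testing.assert_array_equal(r1.null, r2.null)

    def test_no_multicore_patients_errors(self):
        comp = pd.DataFrame([[0.5, 0.5], [0.4, 0.6]])
        with pytest.raises(ValueError, match="nothing to pair"):
            bootstrap_composition_pairing(comp, ["P0", "P1"], n_reps=10)

    def test_default_protocol_constants(self):
        import inspect
        sig = inspect.signature(bootstrap_composition_pairing)
        assert sig.parameters["n_reps"].default == 100_000
        assert sig.parameters["seed"].default == 42


class TestCoreSummary:
    def _cells(self, n=150, frac_low=0.3, seed=0):
        rng = np.random.default_rng(seed)
        momp_low = rng.random(n) < frac_low
        return pd.DataFrame({
            "core_id": "C0",
            "cell_type": "cancer",
            "x": rng.uniform(0, 1000, n),
            "y": rng.uniform(0, 1000, n),
            "BAK": rng.lognormal(5, 0.5, n),
            "momp_low": momp_low,
            "caspase_high": True,
            "quadrant": np.where(momp_low, "caspase_only", "both_high"),
        })

    def test_homogeneous_core_zero_entropy_unit_fraction(self):
        cells = self._cells(frac_low=0.0)
        cells["quadrant"] = "both_high"
        out = core_summary(cells, markers=["BAK"], min_n=100)
        row = out[out.stratum == "cancer"].iloc[0]
        assert row["frac_both_high"] == 1.0
        assert row["entropy_momp_bits"] == pytest.approx(0.0, abs=1e-8)

    def test_quadrant_fractions_partition(self):
        out = core_summary(self._cells(), markers=["BAK"], min_n=100)
        row = out[out.stratum == "cancer"].iloc[0]
        total = sum(row[f"frac_{q}"] for q in
                    ("both_high", "momp_only", "caspase_only", "both_low"))
        assert total == pytest.approx(1.0)

    def test_constructed_low_fraction_recovered_within_3se(self):
        frac = 0.3
        n = 400
        out = core_summary(self._cells(n=n, frac_low=frac, seed=1),
                           markers=["BAK"], min_n=100)
        row = out[out.stratum == "cancer"].iloc[0]
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(row["frac_momp_low"] - frac) < 3 * se

    def test_small_population_reports_nan_metrics(self):
        out = core_summary(self._cells(n=50), markers=["BAK"], min_n=100)
        row = out[out.stratum == "cancer"].iloc[0]
        assert np.isnan(row.get("entropy_momp_bits", np.nan))
        assert row["n_cells"] == 50
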