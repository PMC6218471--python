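"""Normalization, state counting, Bhattacharyya machinery, bifurcation
grids, robustness reports, and embeddings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import circuitnoise as cn
from circuitnoise.analysis import (
    BD_CAP,
    ExpressionNormalizer,
    bhattacharyya_distance,
    cluster_spread,
    count_states,
    expression_bd,
    global_bifurcation,
    hierarchical_cluster,
    noise_robustness,
    normalize_expression,
    occupancy_from_labels,
    pca_embed,
    response_curve,
)


class TestBhattacharyya:
    def test_identical_histograms_have_zero_distance(self):
        p = np.array([0.2, 0.3, 0.5])
        assert bhattacharyya_distance(p, p) == 0.0

    def test_hand_computed_value(self):
        # -ln(sqrt(0.45) + sqrt(0.05)) = -ln(0.894427...) = 0.111572
        bd = bhattacharyya_distance(np.array([0.5, 0.5]), np.array([0.9, 0.1]))
        assert bd == pytest.approx(0.11157, abs=1e-4)

    def test_disjoint_support_hits_documented_cap(self):
        bd = bhattacharyya_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert bd == BD_CAP

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError, match="mismatched binning"):
            bhattacharyya_distance(np.ones(3), np.ones(4))

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20),
        q=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20),
    )
    @settings(max_examples=200, deadline=None)
    def test_axioms_on_random_histograms(self, p, q):
        n = min(len(p), len(q))
        p = np.asarray(p[:n]) + 1e-9
        q = np.asarray(q[:n]) + 1e-9
        d_pq = bhattacharyya_distance(p, q)
        assert d_pq >= 0.0
        assert d_pq == pytest.approx(bhattacharyya_distance(q, p), abs=1e-12)
        assert bhattacharyya_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_expression_bd_of_identical_samples_is_zero(self):
        x = np.random.default_rng(0).normal(size=(200, 2))
        assert expression_bd(x, x) == pytest.approx(0.0, abs=1e-12)


class TestNormalization:
    def test_reference_ensemble_normalizes_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        expr = rng.lognormal(3.0, 1.0, size=(500, 3))
        normed, _ = normalize_expression(expr)
        np.testing.assert_allclose(normed.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(normed.std(axis=0), 1.0, rtol=1e-12)

    def test_constant_gene_falls_back_to_zeros_with_warning(self):
        expr = np.column_stack([np.full(100, 7.0), np.random.default_rng(2).uniform(1, 9, 100)])
        with pytest.warns(UserWarning, match="zero-variance"):
            normed, _ = normalize_expression(expr)
        np.testing.assert_allclose(normed[:, 0], 0.0)

    def test_stored_transform_is_reusable_and_deterministic(self):
        rng = np.random.default_rng(3)
        ref = rng.lognormal(2.0, 0.5, size=(300, 2))
        other = rng.lognormal(2.5, 0.7, size=(50, 2))
        _, nz = normalize_expression(ref)
        a = nz.transform(other)
        b = nz.transform(other)
        np.testing.assert_array_equal(a, b)
        assert abs(a.mean()) > 0.01  # not re-centered on the new slice


class TestCountStates:
    def test_two_separated_clusters_detected(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(-3, 0.5, (150, 2)), rng.normal(3, 0.5, (100, 2))])
        prof = count_states(x, seed=0)
        assert prof.n_states == 2
        assert sorted(prof.counts.tolist()) == [100, 150]
        assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_replicated_single_point_is_one_state(self):
        x = np.tile([1.5, -2.0], (120, 1))
        prof = count_states(x, seed=0)
        assert prof.n_states == 1
        assert prof.counts.tolist() == [120]

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            count_states(np.zeros((10, 2)))

    def test_skewed_single_cloud_is_not_oversplit(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1.0, 400)
        x = np.column_stack([base + 0.3 * base**2, rng.normal(0, 1.0, 400)])
        assert count_states(x, seed=0).n_states == 1

    def test_occupancy_from_labels_counts(self):
        prof = occupancy_from_labels(["LL", "HH", "HH", "LH"])
        assert prof.states == ("HH", "LH", "LL")
        assert prof.counts.tolist() == [2, 1, 1]


class TestGlobalBifurcation:
    def test_constant_noise_collapses_into_one_bin(self, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 100, seed=6)
        res = cn.run_mic(ens, 2.0, 20.0, seed=7)
        table = global_bifurcation(res, 5, value_range=(0.0, 50.0), seed=0)
        assert len(table) == 5
        assert table["n_records"].sum() == 100
        assert table["empty"].sum() == 4
        assert (table.loc[~table["empty"], "n_records"] == 100).all()

    def test_parametric_variation_widens_clusters_on_shared_scale(self, ts):
        ref = cn.CircuitEnsemble.sample(ts, cn.ParameterRanges(), 1500, seed=8)
        ref_mic = cn.run_mic(ref, 1.0, 50.0, seed=9)
        nz = ExpressionNormalizer.fit(ref_mic.expression, ts.genes)
        spreads = []
        for p in (30.0, 100.0):
            ens = cn.CircuitEnsemble.sample(ts, cn.ParameterRanges().scaled(p), 1500, seed=8)
            mic = cn.run_mic(ens, 1.0, 50.0, seed=9)
            labels = (mic.expression[:, 0] > mic.expression[:, 1]).astype(int)
            spreads.append(cluster_spread(nz.transform(mic.expression), labels))
        assert spreads[1] > 2.0 * spreads[0]


class TestResponseAndRobustness:
    def test_zero_noise_curve_ends_at_zero_and_saturates(self, ts, default_ranges):
        rc = response_curve(ts, default_ranges, 2000, 0.0, list(range(1, 51)), seed=5)
        bd = rc["bd"].to_numpy()
        assert bd[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.all(bd[14:] < 0.02)  # relaxed well before the end of the run

    def test_noisy_ensembles_saturate_at_larger_plateau(self, ts, default_ranges):
        quiet = response_curve(ts, default_ranges, 2000, 0.0, [25.0, 50.0], seed=5)
        loud = response_curve(ts, default_ranges, 2000, 20.0, [25.0, 50.0], seed=5)
        assert loud["bd"].iloc[-1] > 0.02 > quiet["bd"].iloc[-1]
        # saturation: the noisy curve is flat between t=25 and t=50
        assert abs(loud["bd"].iloc[0] - loud["bd"].iloc[1]) < 0.3 * loud["bd"].iloc[-1]

    def test_robustness_curve_starts_at_zero_and_grows(self, ts, default_ranges):
        rep = noise_robustness(ts, default_ranges, 1500, seed=21)
        assert rep.bd[0] == 0.0
        assert rep.r_d > 0.0
        assert rep.bd[-1] == rep.bd.max()
        # non-decreasing up to sampling jitter
        assert np.all(np.diff(rep.bd) > -5e-3)
        assert rep.low_noise_slope >= 0.0


class TestEmbeddings:
    def test_two_gene_pca_is_a_rotation(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(200, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]])
        coords, comps, evr = pca_embed(x)
        np.testing.assert_allclose(comps @ comps.T, np.eye(2), atol=1e-10)
        assert coords.var(axis=0).sum() == pytest.approx(x.var(axis=0).sum(), rel=1e-9)
        assert evr.sum() == pytest.approx(1.0, rel=1e-9)

    def test_first_component_separates_toggle_states(self, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 1000, seed=10)
        res = cn.run_mic(ens, 0.0, 50.0, seed=11)
        normed, _ = normalize_expression(res)
        coords, _, _ = pca_embed(normed)
        labels = (res.expression[:, 0] > res.expression[:, 1]).astype(int)
        means = [coords[labels == v, 0].mean() for v in (0, 1)]
        pooled_sd = coords[:, 0].std()
        assert abs(means[0] - means[1]) > pooled_sd  # clear separation on PC1

    def test_pca_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(100, 3))
        a, comps_a, _ = pca_embed(x)
        b, comps_b, _ = pca_embed(x.copy())
        np.testing.assert_array_equal(a, b)
        for row in comps_a:
            assert row[np.argmax(np.abs(row))] > 0

    def test_duplicate_rows_cluster_together_at_height_zero(self):
        x = np.vstack([np.tile([1.0, 2.0], (3, 1)), np.tile([5.0, 6.0], (3, 1))])
        z, labels = hierarchical_cluster(x, n_clusters=2)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]
        assert z[0, 2] == 0.0  # first merge at zero distance
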