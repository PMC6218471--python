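"""Sampling protocols: SIC trapping, MIC basins, SA stability, and the
induction experiment on quadrastable switches."""

import numpy as np
import pandas as pd
import pytest

import circuitnoise as cn
from circuitnoise.analysis import bhattacharyya_distance
from circuitnoise.doublewell import NOISE_LEVELS, get_variant
from circuitnoise.schemes import label_state, state_thresholds


class TestNoiseLadder:
    def test_linear_ladder_shape(self):
        ladder = cn.NoiseLadder.linear(50.0, 30, 5.0)
        assert len(ladder.levels) == 30
        assert ladder.levels[0] == 50.0 and ladder.levels[-1] == 0.0

    @pytest.mark.parametrize(
        "levels, tau",
        [((50.0, 10.0), 5.0), ((10.0, 20.0, 0.0), 5.0), ((10.0, 0.0), 0.0), ((0.0, 0.0), 5.0)],
    )
    def test_invalid_ladders_rejected(self, levels, tau):
        with pytest.raises(ValueError):
            cn.NoiseLadder(levels, tau)


class TestDoubleWellSchemes:
    def test_sic_is_trapped_in_one_well_at_low_noise(self):
        well = get_variant("a")
        res = cn.run_sic(well, NOISE_LEVELS["low"], 2000.0, 2.0, seed=2, burn_in=20.0)
        sides = well.side(res.expression[:, 0])
        assert len(np.unique(sides)) == 1

    def test_sic_visits_both_wells_at_high_noise(self):
        well = get_variant("a")
        res = cn.run_sic(well, NOISE_LEVELS["high"], 2000.0, 2.0, seed=3, burn_in=20.0)
        frac_right = (well.side(res.expression[:, 0]) == 1).mean()
        assert 0.4 < frac_right < 0.6

    def test_mic_occupancy_tracks_basin_widths(self):
        # variant c: equal depths, basins 1:2 -> right fraction ~ 2/3
        well = get_variant("c")
        res = cn.run_mic(well, NOISE_LEVELS["low"], 10.0, seed=1, n_particles=2000)
        frac_right = (well.side(res.expression[:, 0]) == 1).mean()
        assert 0.60 < frac_right < 0.72

    @pytest.mark.parametrize("variant", ["b", "d"])
    def test_sa_concentrates_in_the_deeper_well(self, variant):
        well = get_variant(variant)
        deep = 0 if well.deeper_side == "left" else 1
        levels = cn.run_sa(well, cn.well_annealing_ladder(), seed=4, n_particles=1000)
        frac_deep = (well.side(levels[-1].expression[:, 0]) == deep).mean()
        assert frac_deep >= 0.95

    def test_sa_preserves_symmetry_at_every_level(self):
        well = get_variant("a")
        levels = cn.run_sa(well, cn.well_annealing_ladder(), seed=5, n_particles=2000)
        for lv in levels:
            frac_right = (well.side(lv.expression[:, 0]) == 1).mean()
            assert abs(frac_right - 0.5) < 0.06

    def test_all_schemes_agree_at_high_noise(self):
        well = get_variant("a")
        noise = NOISE_LEVELS["high"]
        sic = cn.run_sic(well, noise, 4000.0, 2.0, seed=2, burn_in=40.0)
        mic = cn.run_mic(well, noise, 20.0, seed=3, n_particles=2000)
        ladder = cn.NoiseLadder((noise, noise / 2, 0.0), 50.0)
        sa = cn.run_sa(well, ladder, seed=4, n_particles=2000)[0]
        edges = np.linspace(-2.5, 2.5, 101)
        hist = lambda r: np.histogram(r.expression[:, 0], bins=edges)[0].astype(float)
        for p, q in [(sic, mic), (mic, sa), (sic, sa)]:
            assert bhattacharyya_distance(hist(p), hist(q)) < 0.05


class TestCircuitSchemes:
    def test_mic_gives_one_terminal_record_per_model(self, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 100, seed=6)
        res = cn.run_mic(ens, 0.0, 50.0, seed=7)
        assert len(res.data) == 100
        assert list(res.data["model_id"]) == list(range(100))

    def test_low_noise_toggle_ensemble_has_bimodal_gene_a(self, ts, default_ranges):
        # the marginal distribution of one gene shows the two mutually
        # exclusive expression states at low noise
        from circuitnoise.analysis import count_states, normalize_expression

        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 1000, seed=8)
        res = cn.run_mic(ens, 0.5, 50.0, seed=9)
        normed, _ = normalize_expression(res)
        prof = count_states(normed[:, 0:1], seed=0)
        assert prof.n_states == 2
        assert prof.fractions.min() > 0.25  # both states well populated

    def test_single_level_zero_ladder_equals_deterministic_mic(self, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 200, seed=10)
        mic = cn.run_mic(ens, 0.0, 50.0, seed=11)
        sa = cn.run_sa(ens, cn.NoiseLadder((0.0,), tau=50.0), seed=11)
        assert len(sa) == 1
        pd.testing.assert_frame_equal(sa[0].data, mic.data)

    def test_protocols_are_reproducible_given_seed(self, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 100, seed=12)
        a = cn.run_mic(ens, 5.0, 20.0, seed=13)
        b = cn.run_mic(ens, 5.0, 20.0, seed=13)
        pd.testing.assert_frame_equal(a.data, b.data)
        sa_a = cn.run_sa(ens, cn.NoiseLadder.linear(10.0, 5, 2.0), seed=14)
        sa_b = cn.run_sa(ens, cn.NoiseLadder.linear(10.0, 5, 2.0), seed=14)
        for x, y in zip(sa_a, sa_b):
            pd.testing.assert_frame_equal(x.data, y.data)

    def test_randomized_noise_annotates_records_and_respects_range(self, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 500, seed=15)
        res = cn.run_noise_randomized_mic(ens, 50.0, 50.0, seed=16)
        assert res.noise.min() >= 0.0 and res.noise.max() < 50.0
        assert len(np.unique(res.noise)) == 500

    def test_vanishing_noise_range_reduces_to_deterministic_mic(self, ts, default_ranges):
        from circuitnoise.simulate import ensemble_drift

        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 300, seed=17)
        res = cn.run_noise_randomized_mic(ens, 1e-9, 50.0, seed=18)
        src, tgt, _ = ts.edge_arrays()
        rates = ensemble_drift(res.expression, ens.params, src, tgt)
        rel = (np.abs(rates) / (1.0 + np.abs(res.expression))).max(axis=1)
        assert np.median(rel) < 1e-6
        assert (rel < 1e-3).mean() >= 0.9

    def test_sic_on_ensemble_records_equidistant_times(self, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 10, seed=19)
        res = cn.run_sic(ens, 1.0, 100.0, 10.0, seed=20)
        assert len(res.data) == 10 * 10
        assert sorted(set(res.data["time"])) == [10.0 * i for i in range(1, 11)]

    def test_sa_enriches_stable_state_of_asymmetric_switch(self, ts_sa1, default_ranges):
        # one self-activating gene: SA (stability) moves occupancy toward the
        # self-activated state relative to MIC (basins) at low noise, while
        # the two agree at high noise
        ens = cn.CircuitEnsemble.sample(ts_sa1, default_ranges, 3000, seed=31)
        sa = cn.run_sa(ens, cn.NoiseLadder.linear(50.0, 30, 5.0), seed=32)
        frac_a = lambda r: (r.expression[:, 0] > r.expression[:, 1]).mean()
        mic_low = cn.run_mic(ens, 0.0, 50.0, seed=33)
        mic_high = cn.run_mic(ens, 50.0, 50.0, seed=33)
        diff_low = frac_a(sa[-1]) - frac_a(mic_low)
        diff_high = abs(frac_a(sa[0]) - frac_a(mic_high))
        assert diff_low > 0.02        # SA favors the stable A-high state
        assert diff_high < diff_low   # schemes agree once noise dominates


class TestEnsembleResultIO:
    def test_tsv_round_trip(self, tmp_path, ts, default_ranges):
        ens = cn.CircuitEnsemble.sample(ts, default_ranges, 20, seed=21)
        res = cn.run_mic(ens, 2.0, 10.0, seed=22)
        path = tmp_path / "res.tsv"
        res.to_tsv(path)
        back = cn.EnsembleResult.from_tsv(path)
        assert back.scheme == "MIC"
        assert back.genes == ts.genes
        np.testing.assert_allclose(back.expression, res.expression, rtol=1e-12)


class TestInduction:
    def test_state_enumeration_of_unregulated_gene(self):
        from circuitnoise.circuit import Circuit

        single = Circuit("single", ("A",), ())
        stack = cn.ParamStack(
            G=np.full((3, 1), 20.0), K=np.full((3, 1), 0.5),
            X0=np.zeros((3, 0)), N=np.zeros((3, 0)), LAM=np.zeros((3, 0)),
        )
        states = cn.enumerate_states(single, stack, seed=1, n_ic=10)
        for s in states:
            assert s.shape == (1, 1)
            assert s[0, 0] == pytest.approx(40.0, rel=1e-3)

    def test_quadrastable_states_carry_all_four_labels(self, quadrastable_10k):
        quad = quadrastable_10k
        assert quad.n_models > 0
        for i in range(min(quad.n_models, 20)):
            assert sorted(quad.labels(i)) == ["HH", "HL", "LH", "LL"]

    def test_identity_induction_keeps_every_model_in_place(self, quadrastable_10k):
        res = cn.induction_experiment(quadrastable_10k, [{"A": 1.0, "B": 1.0}], "LL")
        assert set(res[0].data["state"]) == {"LL"}

    def test_strong_simultaneous_induction_drives_low_low_to_high_high(self, quadrastable_10k):
        stages = [{"A": 15.0, "B": 15.0}, {"A": 1.0, "B": 1.0}]
        res = cn.induction_experiment(quadrastable_10k, stages, "LL")
        frac_hh = (res[0].data["state"] == "HH").mean()
        assert frac_hh > 0.9
        # hysteresis: removing the induction does not send models back to LL
        after = res[1].data["state"]
        assert (after == "HH").mean() > 0.9
        assert (after == "LL").sum() == 0

    def test_sequential_induction_passes_through_single_high_state(self, quadrastable_10k):
        res = cn.induction_experiment(
            quadrastable_10k, [{"B": 15.0}, {"A": 15.0, "B": 15.0}], "LL"
        )
        assert (res[0].data["state"] == "LH").mean() > 0.9
        assert (res[1].data["state"] == "HH").mean() > 0.9

    def test_unknown_state_label_rejected(self, quadrastable_10k):
        with pytest.raises(ValueError, match="unknown state label"):
            cn.induction_experiment(quadrastable_10k, [{"A": 2.0}], "XY")

    def test_empty_quadrastable_ensemble_rejected(self, ts_sa2):
        empty = cn.QuadrastableEnsemble(
            ts_sa2, cn.ParamStack(*(np.zeros((0, n)) for n in (2, 2, 4, 4, 4))),
            [], np.empty((0, 2)), np.array([]),
        )
        with pytest.raises(ValueError, match="no quadrastable models"):
            cn.induction_experiment(empty, [{"A": 2.0}], "LL")


def test_state_labeling_uses_geometric_midpoint():
    states = np.array([[1.0, 100.0], [100.0, 1.0], [1.0, 1.0], [100.0, 100.0]])
    thr = state_thresholds(states)
    np.testing.assert_allclose(thr, [10.0, 10.0])
    assert label_state(np.array([5.0, 50.0]), thr) == "LH"
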