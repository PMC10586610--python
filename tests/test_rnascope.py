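"""RNAscope quantification: thresholds, cluster resolution, scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from setscope.rnascope import (
    ClusterResolutionParams,
    animal_summary,
    cell_molecule_counts,
    classify_cells,
    derive_threshold,
    estimate_single_signal_intensity,
    fold_change,
    fold_change_classes,
    h_score,
    positives_per_1000,
    resolve_cluster,
)
from setscope.simulate import SpotSimConfig, simulate_spots


def _control(values, channel="Gal"):
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(values))],
            "channel": channel,
            "max_intensity": values,
        }
    )


class TestDeriveThreshold:
    def test_zero_spread_gives_the_constant(self):
        thr = derive_threshold(_control([7.0, 7.0, 7.0]), "Gal")
        assert thr.threshold == 7.0 and thr.sd_max == 0.0

    def test_mean_plus_three_sample_sd(self):
        thr = derive_threshold(_control([1.0, 2.0, 3.0]), "Gal")
        assert thr.mean_max == 2.0
        assert thr.sd_max == pytest.approx(1.0)
        assert thr.threshold == pytest.approx(5.0)
        assert thr.n_control_cells == 3

    def test_single_control_cell_rejected(self):
        with pytest.raises(ValueError, match="2 control cells"):
            derive_threshold(_control([4.0]), "Gal")


class TestResolveCluster:
    PARAMS = ClusterResolutionParams(
        channel="Gal", single_signal_mean_intensity=300.0, background=0.0
    )

    def test_exact_multiple(self):
        assert resolve_cluster(1500.0, self.PARAMS) == 5

    def test_background_subtracted(self):
        prm = ClusterResolutionParams("Gal", 300.0, background=100.0)
        assert resolve_cluster(1000.0, prm) == 3

    def test_round_half_up(self):
        prm = ClusterResolutionParams("Gal", 300.0, background=100.0)
        assert resolve_cluster(950.0, prm) == 3  # 2.833 -> 3
        assert resolve_cluster(850.0, prm) == 3  # 2.5 rounds up

    def test_threshold_passer_clamped_to_one(self, caplog):
        prm = ClusterResolutionParams("Gal", 300.0, background=500.0)
        with caplog.at_level("WARNING"):
            assert resolve_cluster(400.0, prm) == 1
        assert "clamping" in caplog.text


def _signals(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "section_id",
            "animal_id",
            "condition",
            "channel",
            "integral_intensity",
        ],
    )


class TestCellMoleculeCounts:
    THRESHOLDS = {"Gal": derive_threshold(_control([290.0, 300.0, 310.0]), "Gal")}
    PARAMS = {"Gal": ClusterResolutionParams("Gal", 300.0, 0.0)}

    def test_subthreshold_objects_discarded(self):
        thr = self.THRESHOLDS["Gal"].threshold
        sig = _signals(
            [
                ("c1", "S1", "A1", "x", "Gal", thr + 50.0),
                ("c1", "S1", "A1", "x", "Gal", thr - 10.0),
            ]
        )
        counts = cell_molecule_counts(sig, self.THRESHOLDS, self.PARAMS)
        assert counts.loc[0, "Gal"] == 1

    def test_cluster_resolved_to_multiple_molecules(self):
        sig = _signals([("c1", "S1", "A1", "x", "Gal", 900.0)])
        counts = cell_molecule_counts(sig, self.THRESHOLDS, self.PARAMS)
        assert counts.loc[0, "Gal"] == 3

    def test_cell_without_objects_gets_zero(self):
        sig = _signals([("c1", "S1", "A1", "x", "Gal", 900.0)])
        roster = pd.DataFrame(
            {
                "cell_id": ["c1", "c2"],
                "animal_id": "A1",
                "section_id": "S1",
                "condition": "x",
            }
        )
        counts = cell_molecule_counts(
            sig, self.THRESHOLDS, self.PARAMS, cells=roster
        ).set_index("cell_id")
        assert counts.loc["c2", "Gal"] == 0

    def test_missing_channel_calibration_is_key_error(self):
        sig = _signals([("c1", "S1", "A1", "x", "Fos", 900.0)])
        with pytest.raises(KeyError, match="Fos"):
            cell_molecule_counts(sig, self.THRESHOLDS, self.PARAMS)


class TestClassify:
    COUNTS = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "animal_id": "A1",
            "section_id": "S1",
            "condition": "x",
            "Gal": [2, 3, 0],
            "Calcr": [0, 2, 5],
            "Fos": [4, 5, 6],
        }
    )

    def test_minimum_molecule_rules(self):
        cls = classify_cells(self.COUNTS, {"Gal": 2, "Fos": 5})
        assert cls["Gal_pos"].tolist() == [True, True, False]
        assert cls["Fos_pos"].tolist() == [False, True, True]

    def test_composite_class_is_conjunction(self):
        cls = classify_cells(self.COUNTS, {"Gal": 2, "Calcr": 2})
        double = cls["Gal_pos"] & cls["Calcr_pos"]
        assert double.tolist() == [False, True, False]


class TestRates:
    def test_per_1000(self):
        assert positives_per_1000(50, 2000) == 25.0
        assert positives_per_1000(0, 10) == 0.0
        assert positives_per_1000(10, 10) == 1000.0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            positives_per_1000(0, 0)


class TestHScore:
    def test_bounds(self):
        assert h_score([0, 0, 0]) == 0.0
        assert h_score([16, 20, 100]) == 400.0

    def test_weighted_bins(self):
        assert h_score([2, 2, 5, 5]) == 150.0  # 50%*1 + 50%*2

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            h_score([])

    @given(
        st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=50),
        st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_range_order_invariance_and_mixture_linearity(self, pop1, pop2):
        h1, h2 = h_score(pop1), h_score(pop2)
        assert 0.0 <= h1 <= 400.0
        assert h_score(list(reversed(pop1))) == h1
        p = len(pop1) / (len(pop1) + len(pop2))
        assert h_score(pop1 + pop2) == pytest.approx(p * h1 + (1 - p) * h2)


class TestFoldChange:
    def test_identical_classes_give_unity(self):
        counts = TestClassify.COUNTS
        mask = np.array([True, True, False])
        assert fold_change_classes(counts, "Gal", mask, mask) == 1.0

    def test_reciprocal(self):
        counts = TestClassify.COUNTS
        a = np.array([True, False, False])
        b = np.array([False, True, True])
        fab = fold_change_classes(counts, "Fos", a, b)
        fba = fold_change_classes(counts, "Fos", b, a)
        assert fab * fba == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        counts = TestClassify.COUNTS
        with pytest.raises(ValueError):
            fold_change_classes(
                counts, "Gal", np.zeros(3, bool), np.ones(3, bool)
            )

    def test_zero_denominator_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change(2.0, 0.0)


class TestGroundTruthRecovery:
    def test_noise_free_counts_recovered_exactly(self):
        cfg = SpotSimConfig(
            n_cells=300, single_intensity_sd=0.0, cluster_prob=0.5, seed=4
        )
        signals, controls, truth = simulate_spots(cfg)
        channels = ["Calcr", "Gal", "Magel2"]
        thresholds = {ch: derive_threshold(controls, ch) for ch in channels}
        params = {
            ch: ClusterResolutionParams(
                ch, cfg.single_intensity_mean, cfg.background
            )
            for ch in channels
        }
        roster = truth[["cell_id", "animal_id", "section_id", "condition"]]
        counts = cell_molecule_counts(signals, thresholds, params, cells=roster)
        merged = counts.merge(truth, on="cell_id", suffixes=("", "_true"))
        for ch in channels:
            np.testing.assert_array_equal(merged[ch], merged[f"{ch}_true"])

    def test_ten_percent_noise_object_error_within_one_molecule(self):
        # Monte-Carlo: with sigma = 10% of the single-signal intensity,
        # at least 99% of resolved objects land within 1 molecule of truth.
        rng = np.random.default_rng(8)
        prm = ClusterResolutionParams("Gal", 300.0, background=20.0)
        true_k = rng.integers(1, 12, size=4000)
        errors = []
        for k in true_k:
            intensity = rng.normal(300.0, 30.0, size=k).sum() + 20.0
            errors.append(abs(resolve_cluster(intensity, prm) - k))
        assert np.mean(np.asarray(errors) <= 1) >= 0.99


def test_estimate_single_signal_intensity_sits_near_singles():
    rng = np.random.default_rng(12)
    singles = rng.normal(300, 15, size=300)
    clusters = rng.normal(1200, 100, size=100)
    sig = pd.DataFrame(
        {
            "cell_id": "c",
            "section_id": "S1",
            "animal_id": "A1",
            "condition": "x",
            "channel": "Gal",
            "integral_intensity": np.concatenate([singles, clusters]),
        }
    )
    est = estimate_single_signal_intensity(sig, "Gal")
    assert 250 < est < 350


def test_animal_summary_pools_sections_per_animal():
    counts = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "animal_id": ["A1"] * 4 + ["A2"] * 2,
            "section_id": ["S1", "S1", "S2", "S2", "S1", "S1"],
            "condition": ["exposed"] * 4 + ["control"] * 2,
            "Gal": [2, 0, 3, 0, 5, 0],
        }
    )
    summary = animal_summary(counts, {"Gal": 2}).set_index("animal_id")
    assert summary.loc["A1", "n_cells"] == 4
    assert summary.loc["A1", "Gal_positive"] == 2
    assert summary.loc["A1", "Gal_per_1000"] == 500.0
    assert summary.loc["A2", "Gal_per_1000"] == 500.0
    assert summary.loc["A1", "Gal_h_score"] == h_score([2, 0, 3, 0])
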