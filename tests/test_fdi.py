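"""FDi estimation: the reverse-correlation tensor, slice z-scoring,
split-half replicability and the permutation null."""

import numpy as np
import pandas as pd
import pytest

from featdiag.fdi import (
    FDiTensor,
    per_feature_accuracy,
    permutation_p,
    rt_fdi,
    split_half_replicability,
    zscore_fdi,
)
from featdiag.stimulus import TrialTable


def _toy_trials():
    """1 participant, 1 image, features {0:A,1:B,2:C,3:D}; trials
    (A,B) correct, (A,C) correct, (A,D) wrong."""
    df = pd.DataFrame({
        "trial_id": [0, 1, 2],
        "participant_id": ["p0"] * 3,
        "session": [1, 1, 1],
        "image_id": ["cat1"] * 3,
        "true_category": ["cat"] * 3,
        "response": ["cat", "cat", "dog"],
        "rt_ms": [500.0, 600.0, 700.0],
    })
    feats = np.array([[0, 1], [0, 2], [0, 3]])
    return TrialTable(df, feats)


def _noise_tensor(rng, P=12, I=2, F=200):
    vals = rng.normal(size=(P, I, F))
    vals = (vals - vals.mean(2, keepdims=True)) / vals.std(2, ddof=1,
                                                           keepdims=True)
    return FDiTensor(values=vals, participants=[f"p{i}" for i in range(P)],
                     images=[f"i{j}" for j in range(I)], zscored=True)


class TestPerFeatureAccuracy:
    def test_hand_enumerated_toy(self):
        raw = per_feature_accuracy(_toy_trials(), n_features=4)
        np.testing.assert_allclose(raw.values[0, 0],
                                   [2 / 3, 1.0, 1.0, 0.0])
        np.testing.assert_array_equal(raw.counts[0, 0], [3, 1, 1, 1])

    def test_never_shown_feature_is_missing(self):
        raw = per_feature_accuracy(_toy_trials(), n_features=5)
        assert np.isnan(raw.values[0, 0, 4])

    def test_all_correct_gives_ones(self):
        t = _toy_trials()
        t.df["response"] = "cat"
        raw = per_feature_accuracy(t, n_features=4)
        np.testing.assert_allclose(raw.values[0, 0], 1.0)

    def test_empty_table_rejected(self):
        t = _toy_trials()
        with pytest.raises(ValueError):
            per_feature_accuracy(TrialTable(t.df.iloc[:0], t.features[:0]))


class TestZscore:
    def test_toy_matches_hand_computation(self):
        fdi = zscore_fdi(per_feature_accuracy(_toy_trials(), n_features=4))
        expect = np.array([0.0, 0.70710678, 0.70710678, -1.41421356])
        np.testing.assert_allclose(fdi.values[0, 0], expect, atol=1e-8)

    def test_slice_normalization_and_imputation(self, small_cohort_run):
        trials, _, _ = small_cohort_run
        fdi = zscore_fdi(per_feature_accuracy(trials, n_features=300))
        assert not np.isnan(fdi.values).any()
        for p in range(fdi.values.shape[0]):
            for i in range(fdi.values.shape[1]):
                slc = fdi.values[p, i]
                obs = slc != 0.0
                if obs.sum() > 250:  # fully-observed slices
                    assert abs(slc.mean()) < 1e-9
                    assert abs(slc.std(ddof=1) - 1) < 1e-2

    def test_affine_invariance(self):
        raw = per_feature_accuracy(_toy_trials(), n_features=4)
        shifted = FDiTensor(values=0.25 + 3.0 * raw.values,
                            participants=raw.participants, images=raw.images,
                            counts=raw.counts)
        np.testing.assert_allclose(zscore_fdi(raw).values,
                                   zscore_fdi(shifted).values, atol=1e-9)

    def test_constant_slice_becomes_zeros(self):
        raw = FDiTensor(values=np.full((1, 1, 6), 0.4),
                        participants=["p0"], images=["i0"])
        assert not zscore_fdi(raw).values.any()


class TestSplitHalf:
    def test_identical_participants_give_r_one(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=(1, 2, 100))
        vals = np.repeat(row, 8, axis=0)
        fdi = FDiTensor(values=vals, participants=[f"p{i}" for i in range(8)],
                        images=["a", "b"])
        r = split_half_replicability(fdi, 20, np.random.default_rng(1))
        assert r == pytest.approx(1.0)

    def test_noise_gives_near_zero_r(self):
        fdi = _noise_tensor(np.random.default_rng(2), P=20, F=500)
        r = split_half_replicability(fdi, 50, np.random.default_rng(3))
        assert abs(r) < 3 * 3 / np.sqrt(2 * 500)

    def test_seeded_determinism(self):
        fdi = _noise_tensor(np.random.default_rng(4))
        a = split_half_replicability(fdi, 30, np.random.default_rng(9))
        b = split_half_replicability(fdi, 30, np.random.default_rng(9))
        assert a == b

    def test_too_few_participants_rejected(self):
        fdi = _noise_tensor(np.random.default_rng(5), P=3)
        with pytest.raises(ValueError):
            split_half_replicability(fdi, 10, np.random.default_rng(0))


class TestPermutationP:
    def test_perfect_replication_gives_minimal_p(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=(1, 1, 400))
        vals = np.repeat(row, 10, axis=0)
        fdi = FDiTensor(values=vals,
                        participants=[f"p{i}" for i in range(10)],
                        images=["a"])
        res = permutation_p(fdi, 20, 200, np.random.default_rng(1))
        assert res.observed_r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 201)

    def test_p_in_unit_interval_and_null_calibration(self):
        # on pure-noise FDi the p-value should be roughly uniform: over
        # repeated null cohorts the rejection fraction stays modest
        ps = []
        for seed in range(40):
            fdi = _noise_tensor(np.random.default_rng(100 + seed))
            res = permutation_p(fdi, 30, 199,
                                np.random.default_rng(300 + seed))
            assert 0 < res.p_value <= 1
            ps.append(res.p_value)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert frac <= 0.15
        assert 0.3 <= np.mean(ps) <= 0.7


class TestRtFdi:
    def test_constant_rt_gives_zero_slices(self):
        t = _toy_trials()
        t.df["rt_ms"] = 500.0
        fdi = rt_fdi(t, n_features=4)
        assert not fdi.values.any()

    def test_rt_pipeline_null_vs_planted(self, small_banks):
        # RT carries no feature information by default; the planted flag
        # makes the RT-FDi pattern replicable
        from featdiag.cohort import (CohortConfig, ObserverModel,
                                     simulate_experiment)

        null_ps, planted_ps = [], []
        for seed in range(6):
            for coupling, acc in ((0.0, null_ps), (400.0, planted_ps)):
                cfg = CohortConfig(
                    n_participants=12, rng_seed=900 + seed, fixed_sessions=2,
                    observer=ObserverModel(rt_evidence_coupling_ms=coupling))
                rng = np.random.default_rng(900 + seed)
                trials, _, _ = simulate_experiment(cfg, small_banks, rng)
                fdi = rt_fdi(trials, 300)
                acc.append(permutation_p(fdi, 40, 199, rng).p_value)
        assert sum(p > 0.05 for p in null_ps) >= 5
        assert sum(p < 0.05 for p in planted_ps) >= 5

    def test_missing_rt_column_rejected(self):
        t = _toy_trials()
        t.df.drop(columns="rt_ms", inplace=True)
        with pytest.raises(ValueError):
            rt_fdi(t)


def test_fdi_csv_round_trip(tmp_path):
    fdi = _noise_tensor(np.random.default_rng(8), P=5, I=2, F=10)
    fdi.to_csv(tmp_path / "fdi.csv")
    back = FDiTensor.from_csv(tmp_path / "fdi.csv")
    np.testing.assert_allclose(back.values, fdi.values)
    assert back.participants == fdi.participants
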