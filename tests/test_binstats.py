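"""Feature binning, distances and the bin-by-group ANOVA machinery."""

import numpy as np
import pandas as pd
import pytest

from featdiag.binstats import (
    Landmarks,
    assign_bins,
    feature_distances,
    highest_bin_contrast,
    participant_bin_means,
    two_way_anova,
)
from featdiag.fdi import FDiTensor


class TestAssignBins:
    def test_equal_sizes_and_ascending_boundaries(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.24, 2.07, size=(10, 1000))
        spec = assign_bins(values, [f"i{k}" for k in range(10)], 5)
        assert (spec.counts() == 2000).all()
        lows = [b[0] for b in spec.boundaries]
        highs = [b[1] for b in spec.boundaries]
        assert lows == sorted(lows) and highs == sorted(highs)
        # every feature assigned exactly once
        assert spec.bin_index.shape == values.shape

    def test_sorted_input_gives_rank_blocks(self):
        values = np.arange(100.0).reshape(1, 100)
        spec = assign_bins(values, ["a"], 5)
        np.testing.assert_array_equal(spec.bin_index[0],
                                      np.repeat(np.arange(5), 20))

    def test_ties_break_deterministically(self):
        values = np.zeros((2, 50))
        s1 = assign_bins(values, ["a", "b"], 5)
        s2 = assign_bins(values, ["a", "b"], 5)
        np.testing.assert_array_equal(s1.bin_index, s2.bin_index)
        assert (s1.counts() == 20).all()

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            assign_bins(np.zeros((1, 3)), ["a"], 5)


class TestFeatureDistances:
    def test_center_corner_geometry(self, small_banks):
        # a feature at the corner of the default 250 px / 22.5 dva image sits
        # sqrt(2) * 11.25 ~ 15.9 dva from the centre; scale-free check here
        bank = small_banks["cat1"]
        d = feature_distances(small_banks, "center_distance")
        geom = bank.geometry
        corner = np.hypot((geom.side_px - 1) / 2, (geom.side_px - 1) / 2) \
            / geom.px_per_dva
        assert d.max() <= corner + 1e-9

    def test_feature_at_eye_point_has_zero_distance(self, small_banks):
        bank = small_banks["cat1"]
        w = bank.wavelets[0]
        lm = Landmarks({"cat1": [(w.x_px, w.y_px)], "dog1": [(0.0, 0.0)]})
        d = feature_distances(small_banks, "eye_distance", lm)
        assert d[0, 0] == 0.0

    def test_missing_landmarks_named_in_error(self, small_banks):
        with pytest.raises(ValueError, match="dog1"):
            feature_distances(small_banks, "eye_distance",
                              Landmarks({"cat1": [(1.0, 1.0)]}))

    def test_landmarks_json_round_trip(self, tmp_path):
        lm = Landmarks({"cat1": [(10.0, 20.0), (30.0, 20.0)]})
        lm.to_json(tmp_path / "lm.json")
        back = Landmarks.from_json(tmp_path / "lm.json")
        assert back.eye_points == lm.eye_points


class TestParticipantBinMeans:
    def _fdi_and_spec(self, P=4, I=2, F=10):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(P, I, F))
        vals -= vals.mean(2, keepdims=True)
        vals /= vals.std(2, ddof=1, keepdims=True)
        fdi = FDiTensor(values=vals,
                        participants=[f"p{i}" for i in range(P)],
                        images=["a", "b"], zscored=True)
        spec = assign_bins(rng.uniform(size=(I, F)), ["a", "b"], 5)
        return fdi, spec

    def test_toy_two_bin_hand_computation(self):
        vals = np.array([[[1.0, 2.0, 3.0, 4.0]]])
        fdi = FDiTensor(values=vals, participants=["p0"], images=["a"])
        spec = assign_bins(np.array([[0.1, 0.2, 0.3, 0.4]]), ["a"], 2)
        means = participant_bin_means(fdi, spec)
        np.testing.assert_allclose(means["value"], [1.5, 3.5])

    def test_zero_fdi_gives_zero_means(self):
        fdi = FDiTensor(values=np.zeros((3, 1, 10)),
                        participants=["p0", "p1", "p2"], images=["a"])
        spec = assign_bins(np.arange(10.0).reshape(1, 10), ["a"], 5)
        assert not participant_bin_means(fdi, spec)["value"].any()

    def test_bin_means_average_to_zero_per_participant(self):
        # z-scored slices partition into equal bins, so the per-participant
        # mean across bins vanishes
        fdi, spec = self._fdi_and_spec()
        means = participant_bin_means(fdi, spec)
        per_part = means.groupby("participant_id")["value"].mean()
        np.testing.assert_allclose(per_part, 0.0, atol=1e-12)


def _balanced_table(rng, n_per_group=26, n_bins=5, bin_effect=0.0,
                    interaction=0.0, noise=1.0):
    rows = []
    for g, gname in enumerate(["high", "low"]):
        for s in range(n_per_group):
            pid = f"{gname}{s}"
            for b in range(1, n_bins + 1):
                mu = bin_effect * b + (interaction * b if g == 0 else 0.0)
                rows.append((pid, gname, b, mu + noise * rng.normal()))
    return pd.DataFrame(rows, columns=["participant_id", "group", "bin",
                                       "value"])


def _ss_oracle(df):
    """Explicit sums-of-squares decomposition for the balanced flat
    two-way layout (independent oracle for two_way_anova)."""
    grand = df["value"].mean()
    cells = df.groupby(["bin", "group"])["value"].mean()
    a_means = df.groupby("bin")["value"].mean()
    b_means = df.groupby("group")["value"].mean()
    n_rep = len(df) / len(cells)
    a, b = len(a_means), len(b_means)
    ss_a = n_rep * b * ((a_means - grand) ** 2).sum()
    ss_b = n_rep * a * ((b_means - grand) ** 2).sum()
    ss_cells = n_rep * ((cells - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    merged = df.merge(cells.rename("cell"), on=["bin", "group"])
    ss_err = ((merged["value"] - merged["cell"]) ** 2).sum()
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = len(df) - a * b
    return {
        "bin": (ss_a / df_a) / (ss_err / df_err),
        "group": (ss_b / df_b) / (ss_err / df_err),
        "interaction": (ss_ab / df_ab) / (ss_err / df_err),
        "df_err": df_err,
    }


class TestTwoWayAnova:
    def test_matches_explicit_ss_oracle_on_balanced_table(self):
        rng = np.random.default_rng(3)
        df = _balanced_table(rng, bin_effect=0.3, interaction=0.2)
        res = two_way_anova(df, model="flat")
        oracle = _ss_oracle(df)
        for eff in ("bin", "group", "interaction"):
            assert res.effects[eff]["F"] == pytest.approx(oracle[eff])
        assert res.effects["interaction"]["df2"] == oracle["df_err"]

    def test_printed_df_patterns(self):
        rng = np.random.default_rng(4)
        # 52 participants (25/27), 5 bins -> interaction df (4, 250)
        df = _balanced_table(rng, n_per_group=26)
        df = df[~df["participant_id"].isin(["high25"])]  # 25 vs 26... keep 52
        df52 = _balanced_table(rng, n_per_group=26)
        res = two_way_anova(df52, model="flat")
        assert (res.effects["interaction"]["df1"],
                res.effects["interaction"]["df2"]) == (4, 250)
        # 52 participants x 2 categories -> error df 100
        df2x2 = _balanced_table(rng, n_per_group=26, n_bins=2)
        res2 = two_way_anova(df2x2, model="flat")
        assert res2.effects["interaction"]["df2"] == 100

    def test_rm_model_df_pattern(self):
        rng = np.random.default_rng(5)
        df52 = _balanced_table(rng, n_per_group=26)
        res = two_way_anova(df52, model="rm")
        assert (res.effects["interaction"]["df1"],
                res.effects["interaction"]["df2"]) == (4, 200)

    def test_constant_data_reports_zero_f(self):
        df = _balanced_table(np.random.default_rng(0), noise=0.0)
        df["value"] = 1.0
        res = two_way_anova(df, model="flat")
        assert res.effects["interaction"]["F"] == 0.0
        assert res.effects["interaction"]["p"] == 1.0

    def test_reduces_to_one_way_when_group_constant(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        df = _balanced_table(rng, bin_effect=0.2)
        df["group"] = "all"
        # with a single group level the bin effect must match one-way ANOVA
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = two_way_anova(df, model="flat")
        groups = [g["value"].to_numpy() for _, g in df.groupby("bin")]
        F, p = stats.f_oneway(*groups)
        assert res.effects["bin"]["F"] == pytest.approx(F)


class TestHighestBinContrast:
    def test_df_pattern_25_vs_27(self):
        rng = np.random.default_rng(7)
        rows = []
        groups = {}
        for i in range(52):
            g = "high" if i < 25 else "low"
            pid = f"p{i:02d}"
            groups[pid] = g
            for b in range(1, 6):
                rows.append((pid, b, rng.normal()))
        df = pd.DataFrame(rows, columns=["participant_id", "bin", "value"])
        t, dof, p = highest_bin_contrast(df, groups)
        assert dof == 50

    def test_identical_groups_give_t_zero(self):
        rows = [(f"p{i}", 5, 1.0) for i in range(10)]
        df = pd.DataFrame(rows, columns=["participant_id", "bin", "value"])
        groups = {f"p{i}": ("high" if i < 5 else "low") for i in range(10)}
        t, dof, p = highest_bin_contrast(df, groups)
        assert t == 0.0 and p == 1.0

    def test_power_for_one_sd_shift(self):
        # planted 1 SD group shift at n = 26/26 rejects >90% of the time
        rng = np.random.default_rng(8)
        rejections = 0
        groups = {f"p{i}": ("high" if i < 26 else "low") for i in range(52)}
        for _ in range(100):
            rows = []
            for i in range(52):
                shift = 1.0 if i < 26 else 0.0
                rows.append((f"p{i}", 5, shift + rng.normal()))
            df = pd.DataFrame(rows, columns=["participant_id", "bin",
                                             "value"])
            _, _, p = highest_bin_contrast(df, groups)
            rejections += p < 0.05
        assert rejections > 90

    def test_tiny_group_rejected(self):
        df = pd.DataFrame([("a", 5, 1.0), ("b", 5, 2.0), ("c", 5, 3.0)],
                          columns=["participant_id", "bin", "value"])
        groups = {"a": "high", "b": "low", "c": "low"}
        with pytest.raises(ValueError):
            highest_bin_contrast(df, groups)
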