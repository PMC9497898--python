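"""CV/RPD/ICC statistics, exclusion rule, planted-effect studies, study driver."""

import numpy as np
import pandas as pd
import pytest

import _oracles
from texphan import repstats as rs
from texphan import texturex, virtual_mr


class TestCV:
    def test_identical_repetitions_zero(self):
        assert rs.cv([10, 10, 10]) == 0.0

    def test_hand_example(self):
        assert rs.cv([1, 2, 3]) == pytest.approx(50.0)  # sample std 1, mean 2

    def test_zero_mean_undefined(self):
        assert np.isnan(rs.cv([0, 0, 0]))
        assert np.isnan(rs.cv([-1, 1]))

    def test_scale_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, 5)
        assert rs.cv(x) == pytest.approx(rs.cv(3.7 * x))

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            rs.cv([5.0])


class TestRPD:
    def test_signed_asymmetric(self):
        assert rs.rpd(2, 1) == pytest.approx(50.0)
        assert rs.rpd(1, 2) == pytest.approx(-100.0)

    def test_equal_means_zero(self):
        assert rs.rpd(3.3, 3.3) == 0.0

    def test_zero_denominator_flagged(self):
        assert np.isnan(rs.rpd(0.0, 1.0))


class TestComparisonPairs:
    def test_fourteen_pairs_seven_per_weighting(self):
        pairs = rs.comparison_pairs()
        assert len(pairs) == 14
        assert sum("T1" in lbl for lbl, _, _ in pairs) == 7
        assert sum("T2" in lbl for lbl, _, _ in pairs) == 7

    def test_first_pair_is_resolution_comparison(self):
        lbl, r1, r2 = rs.comparison_pairs()[0]
        assert lbl == "1.5T_T1_6ch_1mm-2mm" and (r1, r2) == (1, 3)

    def test_indices_reference_real_setups(self):
        setups = virtual_mr.enumerate_setups()
        for lbl, r1, r2 in rs.comparison_pairs():
            for r in (r1, r2):
                assert 1 <= r <= 24
            # weighting in the label matches the referenced setups
            assert setups[r1 - 1].weighting in lbl
            assert setups[r1 - 1].weighting == setups[r2 - 1].weighting

    def test_t2_pairs_mirror_t1_rows(self):
        pairs = rs.comparison_pairs()
        for (l1, a1, b1), (l2, a2, b2) in zip(pairs[:7], pairs[7:]):
            assert (a2, b2) == (a1 + 12, b1 + 12)
            assert l2 == l1.replace("T1", "T2")


class TestICC:
    def test_perfect_absolute_agreement(self):
        res = rs.icc([[1, 1], [2, 2], [3, 3]])
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_hand_anova_example(self):
        res = rs.icc([[1, 2], [3, 4], [5, 6]])
        assert (res.MSR, res.MSC, res.MSE) == (8.0, 1.5, 0.0)
        assert res.icc == pytest.approx(8 / 9)
        assert res.category == "good"

    @pytest.mark.parametrize("value,cat", [
        (0.92, "excellent"), (0.8, "good"), (0.6, "moderate"), (0.3, "poor")])
    def test_categories(self, value, cat):
        res = rs.ICCResult(icc=value, MSR=0, MSC=0, MSE=0, n=3, k=2)
        assert res.category == cat

    def test_constant_offset_column_lowers_icc(self):
        base = np.array([[1.0, 1], [2, 2], [3, 3]])
        shifted = base.copy()
        shifted[:, 1] += 1.0
        assert rs.icc(shifted).icc < 1.0

    def test_zero_variance_undefined(self):
        assert np.isnan(rs.icc([[5.0, 5], [5, 5]]).icc)

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(3, 10))
            k = int(rng.integers(2, 6))
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            assert rs.icc(x).icc == pytest.approx(_oracles.anova_icc2(x),
                                                  abs=1e-12)

    def test_matches_pingouin(self):
        """ICC2 (absolute agreement, single rater) from an external package."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.normal(10, 2, (6, 3))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(6), 3),
            "raters": np.tile(np.arange(3), 6),
            "scores": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, "targets", "raters", "scores")
        typ = ref["Type"].astype(str)
        sel = ref.loc[typ.isin(["ICC2", "ICC(A,1)"]), "ICC"]
        ref_icc2 = float(sel.iloc[0])
        assert rs.icc(x).icc == pytest.approx(ref_icc2, abs=1e-10)


class TestExclusion:
    def test_planted_unstable_features_flagged_exactly(self):
        table = rs.synthetic_repeat_table(seed=3)
        cvs = rs.cv_table(table)
        retained, excluded = rs.exclude_unstable(cvs, threshold=10.0)
        planted = {"Jmax", "Energy", "ClusterShade", "HGRE", "SRHGE", "LRHGE",
                   "LZE", "LZLGE", "LZHGE"}
        assert set(excluded) == planted
        assert len(retained) == 45 - 9

    def test_stable_feature_retained(self):
        df = pd.DataFrame({"object": ["a"] * 3, "setup": ["s"] * 3,
                           "repetition": [1, 2, 3], "f": [5.0, 5.0, 5.0]})
        retained, excluded = rs.exclude_unstable(rs.cv_table(df))
        assert retained == ["f"] and not excluded

    def test_any_aggregation_stricter_than_mean(self):
        table = rs.synthetic_repeat_table(seed=4)
        cvs = rs.cv_table(table)
        _, exc_mean = rs.exclude_unstable(cvs, aggregation="mean")
        _, exc_any = rs.exclude_unstable(cvs, aggregation="any")
        assert set(exc_mean) <= set(exc_any)


class TestSummaries:
    def test_single_group_mean(self):
        df = pd.DataFrame({"object": ["a"] * 2, "setup": ["1.5T_T1_6ch_1mm_FBS"] * 2,
                           "feature": ["f", "g"], "cv": [1.0, 3.0]})
        out = rs.summarize_cv(df, group_by="field")
        assert out.loc["a", "1.5T"] == pytest.approx(2.0)

    def test_partition_recombines_to_global_mean(self):
        table = rs.synthetic_repeat_table(seed=5)
        cvs = rs.cv_table(table).dropna(subset=["cv"])
        out = rs.summarize_cv(cvs, group_by="voxel")
        # weighted recombination of group means == global mean per object
        for obj, grp in cvs.groupby("object"):
            weights = grp.groupby(
                grp["setup"].str.contains("2mm").map({True: "2mm", False: "1mm"})
            )["cv"].count()
            recomb = (out.loc[obj] * weights / weights.sum()).sum()
            assert recomb == pytest.approx(grp["cv"].mean())

    def test_planted_coarse_noise_raises_2mm_cv(self):
        table = rs.synthetic_repeat_table(seed=6)
        out = rs.summarize_cv(rs.cv_table(table), group_by="voxel")
        assert (out["2mm"] > out["1mm"]).all()

    def test_normalization_lowers_cv(self):
        norm = rs.synthetic_repeat_table(seed=7, normalized=True)
        raw = rs.synthetic_repeat_table(seed=7, normalized=False)
        cv_n = rs.cv_table(norm)["cv"].mean()
        cv_r = rs.cv_table(raw)["cv"].mean()
        assert cv_n < cv_r


@pytest.fixture(scope="module")
def tiny_config():
    from texphan import phantom_forge as pf

    setups = [virtual_mr.parse_setup_label(s) for s in
              ("1.5T_T1_6ch_2mm_FBS", "1.5T_T1_6ch_2mm_FBN",
               "3T_T1_8ch_2mm_FBS", "3T_T1_8ch_2mm_FBN")]
    return rs.StudyConfig(
        phantoms={
            "onion": lambda: pf.make_bio_phantom(
                "onion", (32, 32, 32), 1, pitch_mm=1.0),
            "tomato": lambda: pf.make_bio_phantom(
                "tomato", (32, 32, 32), 2, pitch_mm=1.0),
        },
        vois={"onion": ("cubic", 16.0), "tomato": ("cubic", 16.0)},
        setups=setups, n_rep=3, master_seed=11)


class TestStudyDriver:
    def test_cardinality_and_determinism(self, tiny_config, tmp_path):
        b1 = rs.run_study(tiny_config, tmp_path / "run1")
        assert len(b1["features"]) == 2 * 4 * 3  # objects x setups x reps
        b2 = rs.run_study(tiny_config, tmp_path / "run2")
        assert (tmp_path / "run1" / "features.csv").read_bytes() \
            == (tmp_path / "run2" / "features.csv").read_bytes()
        assert (tmp_path / "run1" / "cv_heatmap.png").exists()

    def test_heatmap_cells_trace_to_csv(self, tiny_config, tmp_path):
        bundle = rs.run_study(tiny_config)
        grid = rs.plot_cv_heatmap(bundle["cv"], tmp_path / "hm.png")
        cvs = bundle["cv"]
        for feat in grid.index[:5]:
            for setup in grid.columns:
                expected = cvs[(cvs["feature"] == feat)
                               & (cvs["setup"] == setup)]["cv"].mean()
                assert grid.loc[feat, setup] == pytest.approx(expected, nan_ok=True)

    def test_feature_columns_complete(self, tiny_config):
        bundle = rs.run_study(tiny_config)
        cols = [c for c in bundle["features"].columns
                if c not in rs.META_COLUMNS]
        assert set(cols) == set(texturex.ALL_FEATURE_NAMES)
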