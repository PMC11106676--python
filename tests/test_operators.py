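"""Moving-average, cross and balance PTOs; feature assembly and scaling."""

import numpy as np
import pandas as pd
import pytest

from ifptml.operators import (
    FeatureDef,
    FeatureMatrix,
    FeatureSpec,
    assemble_features,
    cross_deviation,
    default_feature_spec,
    group_means,
    ma_deviation,
    mab_operator,
    standardize,
)
from ifptml.records import PartitionSpec


class TestGroupMeans:
    def test_single_group_mean(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
        mt = group_means(df, "x", ("g",))
        assert mt.means[("a",)] == 2.0
        assert mt.global_mean == 2.0

    def test_two_groups(self):
        df = pd.DataFrame({"x": [1.0, 3.0, 10.0], "g": ["a", "a", "b"]})
        mt = group_means(df, "x", ("g",))
        assert mt.means == {("a",): 2.0, ("b",): 10.0}

    def test_matches_brute_force_double_loop(self, random_paired_frame):
        df = random_paired_frame
        partition = ("c_d0", "c_d1")
        mt = group_means(df, "logp", partition)
        combos = df[list(partition)].drop_duplicates().itertuples(index=False)
        for combo in combos:
            key = tuple(combo)
            rows = [v for v, a, b in zip(df["logp"], df["c_d0"], df["c_d1"])
                    if (a, b) == key]
            assert mt.means[key] == pytest.approx(np.mean(rows))

    def test_absent_descriptor_rejected(self, random_paired_frame):
        with pytest.raises(KeyError):
            group_means(random_paired_frame, "nope", ("c_d0",))

    def test_training_rows_only(self, random_paired_frame, rng):
        """Leakage guard: permuting validation descriptors changes nothing."""
        df = random_paired_frame.copy()
        tmask = np.zeros(len(df), bool)
        tmask[:700] = True
        mt = group_means(df, "psa", ("c_d0",), tmask)
        df.loc[~tmask, "psa"] = rng.permutation(df.loc[~tmask, "psa"]) + 1e3
        mt2 = group_means(df, "psa", ("c_d0",), tmask)
        assert mt.means == mt2.means
        assert mt.global_mean == mt2.global_mean


class TestMADeviation:
    def test_mean_centering(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "g": ["a"] * 3})
        mt = group_means(df, "x", ("g",))
        np.testing.assert_allclose(ma_deviation(df, mt), [-1, 0, 1])

    def test_zero_sum_within_groups(self, random_paired_frame):
        df = random_paired_frame
        mt = group_means(df, "d_n02", ("c_n0", "c_n1"))
        dev = ma_deviation(df, mt)
        sums = pd.Series(dev).groupby(
            [df["c_n0"], df["c_n1"]], observed=True).sum()
        scale = np.abs(df["d_n02"]).sum()
        assert (np.abs(sums) < 1e-8 * scale).all()

    def test_matches_brute_force_subtraction(self, random_paired_frame):
        df = random_paired_frame
        mt = group_means(df, "logp", ("c_d0",))
        dev = ma_deviation(df, mt)
        for i in range(0, len(df), 97):
            group = df[df["c_d0"] == df["c_d0"].iloc[i]]["logp"]
            assert dev[i] == pytest.approx(df["logp"].iloc[i] - group.mean())

    def test_idempotence_of_means_on_centered_column(self, random_paired_frame):
        df = random_paired_frame.copy()
        mt = group_means(df, "psa", ("c_d0",))
        df["psa"] = ma_deviation(df, mt)
        mt2 = group_means(df, "psa", ("c_d0",))
        assert all(abs(v) < 1e-9 for v in mt2.means.values())

    def test_unseen_group_uses_global_mean(self):
        df = pd.DataFrame({"x": [1.0, 3.0], "g": ["a", "a"]})
        mt = group_means(df, "x", ("g",))
        new = pd.DataFrame({"x": [5.0], "g": ["zzz"]})
        np.testing.assert_allclose(ma_deviation(new, mt), [5.0 - 2.0])


class TestCrossDeviation:
    def test_constant_within_other_side_groups_is_zero(self):
        df = pd.DataFrame({
            "logp": [2.0, 2.0, 7.0, 7.0],
            "c_n0": ["x", "x", "y", "y"],
        })
        dev, _ = cross_deviation(df, "logp", ("c_n0",))
        np.testing.assert_allclose(dev, 0.0)

    def test_coincides_with_ma_on_own_partition(self, random_paired_frame):
        df = random_paired_frame
        dev_cross, _ = cross_deviation(df, "logp", ("c_d0",))
        mt = group_means(df, "logp", ("c_d0",))
        np.testing.assert_allclose(dev_cross, ma_deviation(df, mt))

    def test_matches_paired_group_by_oracle(self, random_paired_frame):
        df = random_paired_frame.head(500)
        dev, _ = cross_deviation(df, "psa", ("c_n0", "c_n1"))
        for i in range(0, 500, 83):
            key = (df["c_n0"].iloc[i], df["c_n1"].iloc[i])
            rows = df[(df["c_n0"] == key[0]) & (df["c_n1"] == key[1])]["psa"]
            assert dev[i] == pytest.approx(df["psa"].iloc[i] - rows.mean())


class TestMABOperator:
    def test_adopted_balance_form(self):
        # one row per c_I group and c_III group would zero everything, so
        # craft deviations directly: drug dev 0.5, coating devs 0.2, 0.2
        df = pd.DataFrame({
            "logp": [2.0, 3.0], "d_n12": [1.0, 1.4], "d_n13": [4.0, 4.4],
            **{k: ["u"] * 2 for k in
               ("c_d0", "c_d1", "c_d2", "c_d3", "c_n0", "c_n1", "c_n2",
                "c_n3", "c_n4")},
        })
        col, _ = mab_operator(df, "logp", "d_n12", "d_n13", PartitionSpec())
        # dD(logp) = [-0.5, 0.5]; dD(ca) = [-0.2, 0.2] each
        np.testing.assert_allclose(col, [-0.3, 0.3])

    def test_zero_deviations_give_zero(self):
        df = pd.DataFrame({
            "logp": [2.0], "d_n12": [1.0], "d_n13": [4.0],
            **{k: ["u"] for k in
               ("c_d0", "c_d1", "c_d2", "c_d3", "c_n0", "c_n1", "c_n2",
                "c_n3", "c_n4")},
        })
        col, _ = mab_operator(df, "logp", "d_n12", "d_n13", PartitionSpec())
        np.testing.assert_allclose(col, 0.0)

    def test_matches_direct_formula_on_random_pairs(self, random_paired_frame):
        df = random_paired_frame.copy()
        for k in ("c_d2", "c_d3", "c_n2", "c_n3", "c_n4"):
            df[k] = "z"
        parts = PartitionSpec()
        col, _ = mab_operator(df, "psa", "d_n10", "d_n11", parts)
        d_psa = ma_deviation(df, group_means(df, "psa", parts.c_I))
        d_1 = ma_deviation(df, group_means(df, "d_n10", parts.c_III))
        d_2 = ma_deviation(df, group_means(df, "d_n11", parts.c_III))
        np.testing.assert_allclose(col, d_psa - 0.5 * (d_1 + d_2))

    def test_alias_names_accepted(self, random_paired_frame):
        df = random_paired_frame.copy()
        for k in ("c_d2", "c_d3", "c_n2", "c_n3", "c_n4"):
            df[k] = "z"
        col, _ = mab_operator(df, "PSA", "TPSA(NO)coat", "TPSA(Tot)coat",
                              PartitionSpec())
        assert np.isfinite(col).all()


class TestAssembleFeatures:
    def test_default_spec_has_seven_named_columns_in_order(
            self, random_paired_frame):
        df = random_paired_frame.copy()
        for k in ("c_d2", "c_d3", "c_n2", "c_n3", "c_n4"):
            df[k] = "z"
        for k in ("d_n03", "d_n17", "d_n18"):
            df[k] = np.arange(len(df), dtype=float)
        df["f_ref_fused"] = 0.25
        spec = default_feature_spec()
        fm = assemble_features(df, spec)
        assert list(fm.X.columns) == [
            "f(cd0,cn0)_ref", "dD_psa(c_I)", "dD_t(c_III)", "dD_lnp(c_III)",
            "dD_vnu(c_III)", "dD_vxcoat(c_III)", "dD_vvdwmgcoat(c_III)"]
        # absent assay_time column -> zero column, flagged
        assert (fm.X["dD_t(c_III)"] == 0).all()
        assert "dD_t(c_III)" in fm.constant_features

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            FeatureSpec(())

    def test_columns_equal_individual_operators(self, random_paired_frame):
        df = random_paired_frame.copy()
        df["f_ref_fused"] = 0.5
        spec = FeatureSpec((
            FeatureDef("reference", "ref"),
            FeatureDef("ma", "dlogp", "logp", ("c_d0",)),
            FeatureDef("cross_ma", "dlogp_x", "logp", ("c_n0",)),
        ))
        fm = assemble_features(df, spec)
        np.testing.assert_allclose(fm.X["ref"], 0.5)
        np.testing.assert_allclose(
            fm.X["dlogp"], ma_deviation(df, group_means(df, "logp", ("c_d0",))))
        np.testing.assert_allclose(
            fm.X["dlogp_x"], cross_deviation(df, "logp", ("c_n0",))[0])

    def test_unknown_feature_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            FeatureDef("fancy", "x", "logp", ("c_d0",))

    def test_transform_reproduces_training_columns(self, random_paired_frame):
        df = random_paired_frame.copy()
        df["f_ref_fused"] = 0.3
        spec = FeatureSpec((
            FeatureDef("reference", "ref"),
            FeatureDef("ma", "dpsa", "psa", ("c_d0",)),
        ))
        fm = assemble_features(df, spec)
        again = fm.transform(df, np.full(len(df), 0.3))
        pd.testing.assert_frame_equal(again, fm.X)

    def test_state_json_round_trip(self, random_paired_frame, tmp_path):
        df = random_paired_frame.copy()
        df["f_ref_fused"] = 0.3
        spec = FeatureSpec((
            FeatureDef("reference", "ref"),
            FeatureDef("ma", "dpsa", "psa", ("c_d0",)),
        ))
        fm = standardize(assemble_features(df, spec),
                         np.ones(len(df), bool))
        fm.state_to_json(tmp_path / "state.json")
        fm2 = FeatureMatrix.state_from_json(tmp_path / "state.json")
        out1 = fm.transform(df.head(50), np.full(50, 0.3))
        out2 = fm2.transform(df.head(50), np.full(50, 0.3))
        pd.testing.assert_frame_equal(out1, out2)

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = default_feature_spec()
        spec.to_yaml(tmp_path / "spec.yaml")
        back = FeatureSpec.from_yaml(tmp_path / "spec.yaml")
        assert back.names == spec.names
        assert [f.kind for f in back.features] == [f.kind for f in spec.features]


class TestStandardize:
    def _fm(self, df):
        spec = FeatureSpec((FeatureDef("ma", "dx", "logp", ("c_d0",)),))
        df = df.copy()
        return assemble_features(df, spec)

    def test_sample_sd_scaling(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        fm = FeatureMatrix(X=df.rename(columns={"x": "f"}),
                           spec=FeatureSpec((FeatureDef("reference", "f"),)),
                           mean_tables={"f": None})
        out = standardize(fm, np.ones(3, bool))
        np.testing.assert_allclose(out.X["f"], [-1.0, 0.0, 1.0])

    def test_training_columns_zero_mean_unit_sd(self, random_paired_frame):
        fm = self._fm(random_paired_frame)
        tmask = np.zeros(len(random_paired_frame), bool)
        tmask[:750] = True
        out = standardize(fm, tmask)
        assert abs(out.X.loc[tmask, "dx"].mean()) < 1e-9
        assert abs(out.X.loc[tmask, "dx"].std(ddof=1) - 1.0) < 1e-9

    def test_constant_column_zeroed_and_flagged(self):
        X = pd.DataFrame({"f": [2.0, 2.0, 2.0, 2.0]})
        fm = FeatureMatrix(X=X,
                           spec=FeatureSpec((FeatureDef("reference", "f"),)),
                           mean_tables={"f": None})
        out = standardize(fm, np.ones(4, bool))
        assert (out.X["f"] == 0).all()
        assert "f" in out.constant_features

    def test_validation_rows_use_training_stats(self, random_paired_frame):
        fm = self._fm(random_paired_frame)
        tmask = np.zeros(len(random_paired_frame), bool)
        tmask[:750] = True
        out = standardize(fm, tmask)
        mu = fm.X.loc[tmask, "dx"].mean()
        sd = fm.X.loc[tmask, "dx"].std(ddof=1)
        expected = (fm.X.loc[~tmask, "dx"] - mu) / sd
        np.testing.assert_allclose(out.X.loc[~tmask, "dx"], expected)
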