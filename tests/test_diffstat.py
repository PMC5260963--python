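import math

import numpy as np
import pandas as pd
import pytest

from lfqdiff import (
    DifferentialAbundanceModel,
    ModeratedTestParams,
    StudyDesign,
    generate_study,
    impute_downshifted,
    filter_by_detection,
    load_significant_table_fixture,
    log2_transform,
    moderated_welch_t,
    patient_level_matrix,
    permutation_fdr,
    signed_fold_change,
    summarize_significant,
)
from lfqdiff.preprocess import ImputationParams
from conftest import make_matrix
from _oracles import enumerate_permutation_q


def _prepared(n_proteins=400, seed=0, **sim):
    m, d, truth = generate_study(n_proteins=n_proteins, seed=seed, **sim)
    f = filter_by_detection(m)
    imp = impute_downshifted(log2_transform(f), ImputationParams(seed=seed))
    return imp, d, truth


class TestPatientCollapse:
    def test_replicates_average_on_log2(self, small_design):
        vals = np.tile([10.0, 12.0], 15)[None, :]
        m = make_matrix(vals, samples=small_design.samples, scale="log2")
        collapsed, groups = patient_level_matrix(m, small_design)
        np.testing.assert_allclose(collapsed.values, 11.0)
        assert collapsed.n_samples == 15

    def test_group_sizes(self, small_design):
        m = make_matrix(np.ones((3, 30)), samples=small_design.samples, scale="log2")
        collapsed, groups = patient_level_matrix(m, small_design)
        assert (groups == "treated").sum() == 8
        assert (groups == "control").sum() == 7

    def test_single_replicate_passthrough(self, tiny_design):
        vals = np.arange(7, dtype=float)[None, :]
        m = make_matrix(vals, samples=tiny_design.samples, scale="log2")
        collapsed, _ = patient_level_matrix(m, tiny_design)
        np.testing.assert_array_equal(collapsed.values, vals)

    def test_unmatched_sample_rejected(self, small_design):
        m = make_matrix(np.ones((1, 2)), samples=["T01_r1", "stray"], scale="log2")
        with pytest.raises(Exception, match="stray"):
            patient_level_matrix(m, small_design)


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "delta,expected",
        [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (math.log2(3.40), 3.40)],
    )
    def test_values(self, delta, expected):
        assert signed_fold_change(delta) == pytest.approx(expected)

    def test_antisymmetry_and_magnitude(self):
        # antisymmetric away from 0 (delta = 0 maps to +1 by convention)
        deltas = np.concatenate([np.linspace(-4, -0.1, 20), np.linspace(0.1, 4, 20)])
        fc = signed_fold_change(deltas)
        np.testing.assert_allclose(fc, -signed_fold_change(-deltas))
        assert (np.abs(fc) >= 1).all()


class TestModeratedWelch:
    def test_identical_groups(self):
        d, p, df, se, delta = moderated_welch_t([5, 5, 5], [5, 5, 5], s0=0.1)
        assert d == 0 and p == 1 and delta == 0

    def test_matches_hand_computed_welch(self):
        d, p, df, se, delta = moderated_welch_t([1, 2, 3], [2, 3, 4], s0=0.0)
        assert d == pytest.approx(-1.224744871, rel=1e-9)
        assert df == pytest.approx(4.0)
        from scipy import stats

        ref = stats.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=False)
        assert d == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_d_strictly_decreasing_in_s0(self):
        a, b = [3.0, 4.0, 5.0], [1.0, 1.5, 2.0]
        ds = [moderated_welch_t(a, b, s0)[0] for s0 in (0.0, 0.1, 0.5, 1.0)]
        assert all(x > y > 0 for x, y in zip(ds, ds[1:]))

    def test_p_unaffected_by_s0(self):
        a, b = [3.0, 4.0, 5.0], [1.0, 1.5, 2.0]
        ps = {moderated_welch_t(a, b, s0)[1] for s0 in (0.0, 0.3)}
        assert len(ps) == 1

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            moderated_welch_t([1.0], [2.0, 3.0], 0.0)


class TestPermutationFdr:
    def test_distinct_assignment_count(self):
        assert math.comb(15, 8) == 6435  # 5000 runs are a proper subsample

    @pytest.mark.parametrize("s0", [0.0, 0.1])
    def test_exact_agrees_with_enumeration(self, tiny_design, s0):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(12, 7))
        values[:3, :4] += 2.0  # a few shifted proteins
        treated = np.array([True] * 4 + [False] * 3)
        params = ModeratedTestParams(s0=s0, n_permutations=10_000, seed=0)
        q = permutation_fdr(values, np.where(treated, "treated", "control"), params)
        expected = enumerate_permutation_q(values, treated, s0)
        np.testing.assert_allclose(q, expected, rtol=1e-10)

    def test_seed_determinism_when_subsampling(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 15))
        groups = np.array(["treated"] * 8 + ["control"] * 7)
        p = ModeratedTestParams(n_permutations=200, seed=5)
        q1 = permutation_fdr(values, groups, p)
        q2 = permutation_fdr(values, groups, p)
        np.testing.assert_array_equal(q1, q2)

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(50, 15))
        values[:5, :8] += 1.5
        groups = np.array(["treated"] * 8 + ["control"] * 7)
        q = permutation_fdr(values, groups, ModeratedTestParams(n_permutations=300, seed=1))
        from lfqdiff.diffstat import _d_statistic

        d = np.abs(_d_statistic(values, groups == "treated", 0.05))
        order = np.argsort(-d)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_small_groups_rejected(self):
        values = np.ones((2, 3))
        with pytest.raises(ValueError):
            permutation_fdr(
                values, np.array(["treated", "control", "control"]),
                ModeratedTestParams(n_permutations=10),
            )


class TestRunDifferentialTest:
    def test_null_type_one_calibration(self):
        imp, design, _ = _prepared(n_proteins=600, seed=3, planted_fraction=0.0)
        fit = DifferentialAbundanceModel(
            imp, design, ModeratedTestParams(n_permutations=300, seed=3)
        ).fit()
        frac = (fit.frame["welch_p"] < 0.05).mean()
        assert 0.02 < frac < 0.09  # ~5% within binomial slack

    def test_strong_planted_recovery(self):
        imp, design, truth = _prepared(
            n_proteins=500, seed=4, planted_fraction=0.02, planted_delta=3.0
        )
        fit = DifferentialAbundanceModel(
            imp, design, ModeratedTestParams(n_permutations=400, seed=4)
        ).fit()
        frame = fit.frame.set_index("protein_id")
        planted = [p for p in truth.planted_ids if p in frame.index]
        assert frame.loc[planted, "significant"].all()
        # false calls stay consistent with 5% FDR control (rate, not zero)
        nulls = frame.drop(index=planted)
        assert nulls["significant"].sum() <= 2

    def test_s0_demotes_small_fold_changes(self, small_design):
        # the moderation constant exists to drop proteins whose fold change
        # is tiny even though their variance (hence Welch p) is tiny too,
        # while large-fold-change proteins stay significant
        rng = np.random.default_rng(6)
        n_null = 120
        vals = 20.0 + rng.normal(0, 0.3, size=(n_null + 2, 30))
        vals[0] = 20.0 + 0.005 * rng.normal(size=30)
        vals[0, :16] += 0.12  # protein 0: minute shift, near-zero noise
        vals[1, :16] += 2.0  # protein 1: large shift
        m = make_matrix(vals, samples=small_design.samples, scale="log2")
        out = {}
        for s0 in (0.0, 0.5):
            fit = DifferentialAbundanceModel(
                m, small_design, ModeratedTestParams(s0=s0, n_permutations=300, seed=6)
            ).fit()
            out[s0] = fit.frame.set_index("protein_id")["significant"]
        assert out[0.0]["P000"] and out[0.0]["P001"]
        assert not out[0.5]["P000"]  # small fold change demoted
        assert out[0.5]["P001"]  # large fold change kept

    def test_order_invariance(self):
        imp, design, _ = _prepared(n_proteins=120, seed=7, planted_fraction=0.05)
        params = ModeratedTestParams(n_permutations=150, seed=7)
        base = DifferentialAbundanceModel(imp, design, params).fit().frame

        rng = np.random.default_rng(0)
        perm = rng.permutation(imp.n_proteins)
        shuffled = imp.select_proteins(perm)
        out = DifferentialAbundanceModel(shuffled, design, params).fit().frame
        merged = base.set_index("protein_id").join(
            out.set_index("protein_id"), rsuffix="_shuf"
        )
        assert (merged["significant"] == merged["significant_shuf"]).all()
        np.testing.assert_allclose(merged["q"], merged["q_shuf"], atol=1e-12)

    def test_sd_percentile_mode(self):
        imp, design, _ = _prepared(n_proteins=150, seed=8)
        fit = DifferentialAbundanceModel(
            imp, design,
            ModeratedTestParams(s0=0.5, s0_mode="sd_percentile", n_permutations=100, seed=8),
        ).fit()
        se = fit.frame["se"].to_numpy()
        assert fit.s0_constant == pytest.approx(np.quantile(se, 0.5))

    def test_significance_implies_both_thresholds(self):
        imp, design, _ = _prepared(n_proteins=300, seed=9, planted_fraction=0.05)
        fr = DifferentialAbundanceModel(
            imp, design, ModeratedTestParams(n_permutations=200, seed=9)
        ).fit().frame
        sig = fr[fr["significant"]]
        assert (sig["welch_p"] < 0.05).all() and (sig["q"] < 0.05).all()
        assert (np.sign(fr["fold_change"]) == np.sign(fr["delta_log2"]).replace(0, 1)).all()


class TestSummarize:
    def test_reference_table_summary(self):
        s = summarize_significant(load_significant_table_fixture())
        up = s[s["direction"] == "up"].iloc[0]
        down = s[s["direction"] == "down"].iloc[0]
        assert up["n"] == 21 and up["median_fc"] == 2.4
        assert down["n"] == 34 and down["median_fc"] == -2.4

    def test_single_protein(self):
        s = summarize_significant(pd.DataFrame({"fold_change": [3.0]}))
        assert s.iloc[0]["n"] == 1 and s.iloc[0]["median_fc"] == 3.0

    def test_sign_flip_antisymmetry(self):
        t = load_significant_table_fixture()
        flipped = t.assign(fold_change=-t["fold_change"])
        s, sf = summarize_significant(t), summarize_significant(flipped)
        up, down = s.set_index("direction"), sf.set_index("direction")
        assert up.loc["up", "n"] == down.loc["down", "n"]
        assert up.loc["up", "median_fc"] == -down.loc["down", "median_fc"]

    def test_empty_input(self):
        assert summarize_significant(pd.DataFrame(columns=["fold_change"])).empty
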