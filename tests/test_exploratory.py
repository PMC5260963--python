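import numpy as np
import pytest

from lfqdiff import (
    StudyDesign,
    generate_study,
    hierarchical_cluster,
    log2_transform,
    pca,
    replicate_shift_and_subtract,
    technical_pair_concordance,
    zscore_rows,
)
from conftest import make_matrix
from _oracles import upgma_heights


def _paired_design(n_patients):
    records = []
    for i in range(n_patients):
        g = "treated" if i % 2 == 0 else "control"
        p = f"pt{i}"
        records += [(f"{p}a", p, g, 1), (f"{p}b", p, g, 2)]
    return StudyDesign.from_records(records)


class TestHierarchicalCluster:
    def test_identical_pair_merges_first(self):
        vals = np.array([[0.0, 0.0, 10.0], [1.0, 1.0, -10.0]])
        d = hierarchical_cluster(make_matrix(vals, scale="log2"))
        first = d.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    @pytest.mark.parametrize("n_samples", [4, 5, 6])
    def test_heights_match_bruteforce(self, n_samples):
        rng = np.random.default_rng(n_samples)
        vals = rng.normal(size=(7, n_samples))
        d = hierarchical_cluster(make_matrix(vals, scale="log2"))
        expected = upgma_heights(vals.T)
        np.testing.assert_allclose(sorted(d.heights), expected, rtol=1e-10)

    def test_rectangle_hand_computed(self):
        # corners of a 1 x 3 rectangle: pairs at distance 1 merge first at
        # height 1, then the two pairs merge at mean distance (3+sqrt(10))/2
        pts = np.array([[0, 0], [0, 1], [3, 0], [3, 1]], dtype=float).T
        d = hierarchical_cluster(make_matrix(pts, scale="log2"))
        np.testing.assert_allclose(
            sorted(d.heights), [1.0, 1.0, (3 + np.sqrt(10)) / 2], rtol=1e-12
        )

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 6))
        d1 = hierarchical_cluster(make_matrix(vals, scale="log2"))
        perm = rng.permutation(6)
        d2 = hierarchical_cluster(
            make_matrix(vals[:, perm], samples=[f"S{j:02d}" for j in perm], scale="log2")
        )
        np.testing.assert_allclose(sorted(d1.heights), sorted(d2.heights), rtol=1e-10)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(make_matrix([[1.0, np.nan]], scale="log2"))

    def test_newick_contains_all_leaves(self):
        vals = np.random.default_rng(1).normal(size=(5, 4))
        d = hierarchical_cluster(make_matrix(vals, scale="log2"))
        nwk = d.to_newick()
        for s in d.samples:
            assert s in nwk


class TestConcordance:
    def test_exact_copies_fully_concordant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(30, 4))
        vals = np.repeat(base, 2, axis=1)  # a,b copies adjacent
        design = _paired_design(4)
        m = make_matrix(vals, samples=[s for p in range(4) for s in (f"pt{p}a", f"pt{p}b")], scale="log2")
        frac, flags = technical_pair_concordance(hierarchical_cluster(m), design)
        assert frac == 1.0
        assert all(flags.values())

    def test_wrong_replicate_count_raises(self, small_design):
        vals = np.random.default_rng(0).normal(size=(5, 3))
        m = make_matrix(vals, samples=["T01_r1", "T01_r2", "T02_r1"], scale="log2")
        d = hierarchical_cluster(m)
        with pytest.raises(ValueError, match="T02"):
            technical_pair_concordance(d, small_design)

    def test_pure_noise_concordance_near_chance(self):
        # replicate noise >> patient differences: pairing carries no signal
        m, design, _ = generate_study(
            n_proteins=150, patient_sd=0.0, replicate_sd=1.0, dropout_slope=0.0,
            planted_fraction=0.0, seed=4,
        )
        z = zscore_rows(log2_transform(m))
        frac, _ = technical_pair_concordance(hierarchical_cluster(z), design)
        # under exchangeability a pair is rarely a mutual first merge
        assert frac < 0.5


class TestPca:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 3))
        vals = np.repeat(base, 2, axis=1)
        res = pca(make_matrix(vals, scale="log2"))
        for k in range(0, 6, 2):
            np.testing.assert_allclose(res.scores[k], res.scores[k + 1], atol=1e-10)

    def test_two_samples_single_component(self):
        res = pca(make_matrix(np.random.default_rng(0).normal(size=(10, 2)), scale="log2"))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 8))
        res = pca(make_matrix(vals, scale="log2"))
        X = vals.T
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(res.scores @ res.loadings, Xc, atol=1e-8)

    def test_variance_fractions(self):
        res = pca(make_matrix(np.random.default_rng(4).normal(size=(30, 7)), scale="log2"))
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() == pytest.approx(1.0)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-10

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca(make_matrix([[1.0]], scale="log2"))


class TestReplicateShift:
    def _constructed(self, delta):
        # pairs separated by delta exactly along the dominant direction
        rng = np.random.default_rng(0)
        n_pat, n_prot = 6, 200
        centers = rng.normal(0, 1.0, size=(n_pat, n_prot))
        direction = np.zeros(n_prot)
        direction[0] = 1.0
        rows = []
        samples = []
        for p in range(n_pat):
            rows += [centers[p] + delta / 2 * direction, centers[p] - delta / 2 * direction]
            samples += [f"pt{p}a", f"pt{p}b"]
        vals = np.array(rows).T
        return make_matrix(vals, samples=samples, scale="log2"), _paired_design(n_pat)

    def test_constructed_offset_recovered_on_first_component(self):
        delta = 60.0  # dominates the centre spread, so PC1 is the pair offset
        m, design = self._constructed(delta)
        res = pca(m)
        shift = replicate_shift_and_subtract(res, design, component=0)
        assert shift.mean_abs_shift[0] == pytest.approx(delta, rel=0.05)
        assert shift.mean_abs_shift[0] > 10 * shift.mean_abs_shift[1:].max()
        # removing that component kills the intraindividual displacement
        assert shift.intra_inter_ratio_after < 0.2 * shift.intra_inter_ratio_before

    def test_zero_delta_leaves_distances(self):
        m, design = self._constructed(0.0)
        res = pca(m)
        shift = replicate_shift_and_subtract(res, design, component=0)
        assert shift.intra_inter_ratio_before == pytest.approx(
            shift.intra_inter_ratio_after, rel=0.05
        )

    def test_batch_effect_ratio_decreases(self):
        m, design, _ = generate_study(
            n_proteins=300, replicate_batch_sd=0.8, dropout_slope=0.0,
            planted_fraction=0.0, seed=5,
        )
        z = zscore_rows(log2_transform(m))
        res = pca(z)
        shift = replicate_shift_and_subtract(res, design, component=0)
        assert shift.intra_inter_ratio_after < shift.intra_inter_ratio_before
        assert shift.per_pair.shape == (15, res.n_components)

    def test_component_out_of_range(self):
        m, design = self._constructed(1.0)
        res = pca(m)
        with pytest.raises(IndexError):
            replicate_shift_and_subtract(res, design, component=res.n_components)
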