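"""Feature building, WPGMA linkage, cophenetic analysis, cutting, Newick."""

import numpy as np
import pytest

from efcpipe._validation import ValidationError
from efcpipe.clustering import (
    Dendrogram,
    ROIFeatureVector,
    build_features,
    cophenetic,
    correlation_distance_matrix,
    cut,
    inter_roi_corr,
    to_newick,
    wpgma,
)
from efcpipe.hrf_glm import CycleAverage, TwoGammaFit


def make_fit(amp1=1.0, amp2=0.2, lag1=1.0, lag2=9.0):
    return TwoGammaFit(amp1=amp1, amp2=amp2, lag1=lag1, lag2=lag2,
                       k1=6.0, theta1=1.0, k2=6.0, theta2=1.5, rss=0.0, converged=True)


def make_cycle(y):
    y = np.asarray(y, float)
    return CycleAverage(window_times=np.arange(len(y)) * 2.0, mean_psc=y,
                        se_psc=np.zeros_like(y), n_cycles=7, condition="heat")


from _oracles import brute_force_wpgma


class TestBuildFeatures:
    def _inputs(self, n=4, scale=1.0):
        rng = np.random.default_rng(0)
        rois = [f"r{i}" for i in range(n)]
        fits = {r: make_fit(amp1=1.0 + 0.1 * i) for i, r in enumerate(rois)}
        betas = {r: 0.5 * i for i, r in enumerate(rois)}
        cycles = {r: make_cycle(scale * (np.sin(np.arange(23) / 3.0) + 0.1 * i)) for i, r in enumerate(rois)}
        return fits, betas, cycles

    def test_identical_inputs_identical_vectors(self):
        fits = {"a": make_fit(), "b": make_fit(), "c": make_fit(amp1=9.0)}
        betas = {"a": 1.0, "b": 1.0, "c": 0.0}
        cyc = make_cycle(np.sin(np.arange(23)))
        cycles = {"a": cyc, "b": cyc, "c": make_cycle(np.cos(np.arange(23)))}
        feats = {f.roi: f.features for f in build_features(fits, betas, cycles)}
        np.testing.assert_allclose(feats["a"], feats["b"], atol=1e-12)

    def test_zscore_columns(self):
        fits, betas, cycles = self._inputs()
        X = np.array([f.features for f in build_features(fits, betas, cycles)])
        live = X.std(axis=0) > 0
        np.testing.assert_allclose(X[:, live].mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(X[:, live].std(axis=0), 1.0, atol=1e-10)

    def test_psc_scale_invariance(self):
        fits, betas, cycles1 = self._inputs(scale=1.0)
        _, _, cycles10 = self._inputs(scale=10.0)
        X1 = np.array([f.features for f in build_features(fits, betas, cycles1)])
        X10 = np.array([f.features for f in build_features(fits, betas, cycles10)])
        np.testing.assert_allclose(X1, X10, atol=1e-10)

    def test_missing_roi_rejected(self):
        fits, betas, cycles = self._inputs()
        del betas["r1"]
        with pytest.raises(ValidationError, match="r1"):
            build_features(fits, betas, cycles)


class TestWPGMA:
    def test_identical_vectors_merge_at_zero(self):
        v = np.sin(np.arange(30) / 2)
        feats = [
            ROIFeatureVector("a", v.copy(), "heat"),
            ROIFeatureVector("b", v.copy(), "heat"),
            ROIFeatureVector("c", -v, "heat"),
        ]
        dendro = wpgma(feats)
        assert dendro.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_height_two(self):
        v = np.sin(np.arange(30) / 2)
        feats = [ROIFeatureVector("a", v, "heat"), ROIFeatureVector("b", -v, "heat")]
        dendro = wpgma(feats)
        assert dendro.merges[0][2] == pytest.approx(2.0)

    def test_four_point_pencil_and_paper(self):
        # hand-executed WPGMA:
        # d(A,B)=.2 merges first; d(AB,C)=(.9+.8)/2=.85, d(AB,D)=(1+.95)/2=.975
        # d(C,D)=.3 merges next; d(AB,CD)=(.85+.975)/2=.9125
        names = ["A", "B", "C", "D"]
        D = np.array([
            [0.0, 0.2, 0.9, 1.0],
            [0.2, 0.0, 0.8, 0.95],
            [0.9, 0.8, 0.0, 0.3],
            [1.0, 0.95, 0.3, 0.0],
        ])
        dendro = wpgma(D, leaf_names=names)
        assert dendro.merges[0] == (0, 1, pytest.approx(0.2))
        assert dendro.merges[1] == (2, 3, pytest.approx(0.3))
        assert dendro.merges[2][2] == pytest.approx(0.9125)

    def test_constant_vector_rejected_by_name(self):
        feats = [
            ROIFeatureVector("flat", np.zeros(10), "heat"),
            ROIFeatureVector("b", np.sin(np.arange(10.0)), "heat"),
        ]
        with pytest.raises(ValidationError, match="flat"):
            wpgma(feats)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        names = [f"x{i}" for i in range(n)]
        for _ in range(25):
            A = rng.uniform(0, 2, size=(n, n))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0)
            mine = wpgma(D, leaf_names=names).merges
            oracle = brute_force_wpgma(names, D)
            assert len(mine) == len(oracle)
            for (a1, b1, h1), (a2, b2, h2) in zip(mine, oracle):
                assert {a1, b1} == {a2, b2}
                assert h1 == pytest.approx(h2, abs=1e-12)

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            A = rng.uniform(0, 2, size=(7, 7))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0)
            dendro = wpgma(D, leaf_names=[f"l{i}" for i in range(7)])
            heights = [h for _, _, h in dendro.merges]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_leaf_order_invariance_of_partition(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        v1 = rng.normal(size=20)
        v2 = rng.normal(size=20)
        feats = [ROIFeatureVector(f"r{i}", (v1 if i < 3 else v2) + 0.01 * rng.normal(size=20), "heat")
                 for i in range(6)]
        d1 = wpgma(feats)
        d2 = wpgma(feats[::-1])
        p1 = cut(d1, 0.7).labels
        p2 = cut(d2, 0.7).labels
        rois = sorted(p1)
        assert adjusted_rand_score([p1[r] for r in rois], [p2[r] for r in rois]) == 1.0


class TestCophenetic:
    def test_two_leaves_degenerate_flag(self):
        dendro = Dendrogram(leaves=["a", "b"], merges=[(0, 1, 0.5)])
        res = cophenetic(dendro, np.array([[0, 0.5], [0.5, 0]]))
        assert res.defined is False
        assert res.correlation is None

    def test_ultrametric_input_perfect_correlation(self):
        # construct an ultrametric: pairs (a,b)=.2, (c,d)=.4, across=1.0
        names = list("abcd")
        D = np.array([
            [0, 0.2, 1.0, 1.0],
            [0.2, 0, 1.0, 1.0],
            [1.0, 1.0, 0, 0.4],
            [1.0, 1.0, 0.4, 0],
        ])
        dendro = wpgma(D, leaf_names=names)
        res = cophenetic(dendro, D)
        assert res.correlation == pytest.approx(1.0)
        np.testing.assert_allclose(res.matrix, D, atol=1e-12)

    def test_max_ultrametricity_of_cophenetic_matrix(self):
        rng = np.random.default_rng(12)
        A = rng.uniform(0, 2, size=(6, 6))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        C = cophenetic(wpgma(D, leaf_names=list("abcdef"))).matrix
        n = 6
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert C[i, k] <= max(C[i, j], C[j, k]) + 1e-12

    def test_agrees_with_scipy(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(13)
        X = rng.normal(size=(7, 5))
        from scipy.spatial.distance import pdist

        d = pdist(X)
        D = squareform(d)
        mine = wpgma(D, leaf_names=[f"l{i}" for i in range(7)])
        C = cophenetic(mine, D)
        Z = linkage(d, method="weighted")
        c_scipy, coph_scipy = cophenet(Z, d)
        np.testing.assert_allclose(squareform(C.matrix), coph_scipy, atol=1e-10)
        assert C.correlation == pytest.approx(c_scipy)


class TestCut:
    def _dendro(self):
        names = ["A", "B", "C", "D"]
        D = np.array([
            [0.0, 0.2, 0.9, 1.0],
            [0.2, 0.0, 0.8, 0.95],
            [0.9, 0.8, 0.0, 0.3],
            [1.0, 0.95, 0.3, 0.0],
        ])
        return wpgma(D, leaf_names=names)

    def test_above_root_single_cluster(self):
        part = cut(self._dendro(), 5.0)
        assert part.n_subnetworks == 1

    def test_zero_height_singletons(self):
        part = cut(self._dendro(), 0.0)
        assert part.n_subnetworks == 4

    def test_mid_height_two_clusters(self):
        part = cut(self._dendro(), 0.7)
        assert part.n_subnetworks == 2
        assert set(part.members(part.labels["A"])) == {"A", "B"}
        assert set(part.members(part.labels["C"])) == {"C", "D"}


class TestInterROICorr:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(1)
        V = rng.normal(size=(30, 3))
        c = inter_roi_corr(V, ["a", "b", "c"])
        np.testing.assert_allclose(np.diag(c.r), 1.0)

    def test_identical_series_correlation_one(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        c = inter_roi_corr(np.column_stack([y, y]), ["a", "b"])
        assert c.r[0, 1] == pytest.approx(1.0)

    def test_hand_pearson_six_points(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 7, 5])
        # hand Pearson: r = cov/(sx sy)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        c = inter_roi_corr(np.column_stack([x, y]), ["a", "b"])
        assert c.r[0, 1] == pytest.approx(r_hand)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError, match="b"):
            inter_roi_corr(np.column_stack([np.arange(10.0), np.ones(10)]), ["a", "b"])

    def test_condition_mask_restricts_rows(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(40, 2))
        mask = np.zeros(40, bool)
        mask[:20] = True
        c = inter_roi_corr(V, ["a", "b"], condition_mask=mask)
        expected = np.corrcoef(V[:20].T)[0, 1]
        assert c.r[0, 1] == pytest.approx(expected)


class TestNewick:
    def test_two_leaf_convention(self):
        dendro = Dendrogram(leaves=["A", "B"], merges=[(0, 1, 0.8)])
        assert to_newick(dendro) == "(A:0.4,B:0.4);"

    def test_four_leaf_hand_example(self):
        names = ["A", "B", "C", "D"]
        D = np.array([
            [0.0, 0.2, 0.9, 1.0],
            [0.2, 0.0, 0.8, 0.95],
            [0.9, 0.8, 0.0, 0.3],
            [1.0, 0.95, 0.3, 0.0],
        ])
        nwk = to_newick(wpgma(D, leaf_names=names))
        assert nwk == "((A:0.1,B:0.1):0.35625,(C:0.15,D:0.15):0.30625);"

    def test_round_trip_preserves_cophenetic_matrix(self):
        import dendropy

        rng = np.random.default_rng(17)
        A = rng.uniform(0.1, 2, size=(6, 6))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        names = [f"t{i}" for i in range(6)]
        dendro = wpgma(D, leaf_names=names)
        C = cophenetic(dendro).matrix
        tree = dendropy.Tree.get(data=to_newick(dendro), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in range(6):
            for j in range(i + 1, 6):
                d = pdm.distance(taxa[names[i]], taxa[names[j]])
                assert d == pytest.approx(C[i, j], abs=1e-6)
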