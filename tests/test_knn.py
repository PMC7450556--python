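import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neo3dgenome.epitopes import LabeledEpitope
from neo3dgenome.genome_grid import make_bin_table
from neo3dgenome.knn import (
    DEFAULT_K,
    EnsembleDistances,
    Genome3DNNClassifier,
    combine_scores,
    knn_score,
    mean_distance_matrix,
    pairwise_model_distance,
    rescale_baseline,
)
from neo3dgenome.polymer import Conformation, ConformationEnsemble, RestraintSet


def ensemble_from_coords(coords_list, bins):
    """Build an ensemble directly from per-replica coordinate arrays."""
    rs = RestraintSet(radial_targets=np.full(coords_list[0].shape[0], 5.0))
    replicas = [
        Conformation(coords=c, chain_breaks=bins.chain_breaks(), energy=0.0, seed=i)
        for i, c in enumerate(coords_list)
    ]
    return ConformationEnsemble(replicas=replicas, restraints=rs, bins=bins)


def located(peptide, bin_index, label, bins):
    return LabeledEpitope(
        peptide=peptide, mhc_allele="HLA-A*02:01",
        positive_rate=1.0 if label == "positive" else 0.0,
        label=label, chrom=bins.chrom_of_bin(bin_index),
        position=0, bin_index=bin_index,
    )


def brute_force_knn(target, training, ensemble, k):
    """Exhaustive sort-and-count oracle mirroring the scoring contract."""
    bins = ensemble.bins
    chrom = bins.chrom_of_bin(target.bin_index)
    cands = []
    for t in training:
        if not t.located or bins.chrom_of_bin(t.bin_index) != chrom:
            continue
        if t.peptide == target.peptide and t.mhc_allele == target.mhc_allele:
            continue
        ds = [
            float(np.linalg.norm(c.coords[target.bin_index] - c.coords[t.bin_index]))
            for c in ensemble.replicas
        ]
        cands.append((sum(ds) / len(ds), t.bin_index, t.peptide, t.is_positive))
    if not cands:
        return float(np.mean([t.is_positive for t in training if t.located])), 0
    cands.sort()
    top = cands[: min(k, len(cands))]
    return sum(c[3] for c in top) / len(top), len(top)


@pytest.fixture
def line_bins():
    return make_bin_table([("chr1", 10 * 500_000)])


class TestPairwiseDistance:
    def test_same_bead_zero(self, line_bins):
        ens = ensemble_from_coords([np.random.default_rng(0).normal(size=(10, 3))], line_bins)
        assert pairwise_model_distance(3, 3, ens) == 0.0

    def test_three_four_five_triangle(self, line_bins):
        coords = np.zeros((10, 3))
        coords[1] = [3.0, 4.0, 0.0]
        ens = ensemble_from_coords([coords], line_bins)
        assert pairwise_model_distance(0, 1, ens) == 5.0

    def test_mean_over_replicas_matches_per_replica_oracle(self, line_bins):
        rng = np.random.default_rng(1)
        coords = [rng.normal(size=(10, 3)) for _ in range(5)]
        ens = ensemble_from_coords(coords, line_bins)
        expected = np.mean(
            [np.linalg.norm(c[2] - c[7]) for c in coords]
        )
        assert pairwise_model_distance(2, 7, ens) == pytest.approx(expected, abs=1e-12)

    def test_empty_ensemble_rejected(self, line_bins):
        rs = RestraintSet(radial_targets=np.full(10, 5.0))
        ens = ConformationEnsemble(replicas=[], restraints=rs, bins=line_bins)
        with pytest.raises(ValueError, match="empty"):
            pairwise_model_distance(0, 1, ens)

    def test_distance_matrix_consistent(self, line_bins):
        rng = np.random.default_rng(2)
        ens = ensemble_from_coords([rng.normal(size=(10, 3)) for _ in range(3)], line_bins)
        mat = mean_distance_matrix(ens)
        for a, b in [(0, 1), (2, 9), (4, 4)]:
            assert mat[a, b] == pytest.approx(pairwise_model_distance(a, b, ens), abs=1e-12)


class TestKnnScore:
    def test_default_k_is_10(self):
        assert DEFAULT_K == 10

    def test_unanimous_votes(self, line_bins):
        rng = np.random.default_rng(3)
        ens = ensemble_from_coords([rng.normal(size=(10, 3))], line_bins)
        target = located("TARGETPEP", 0, "negative", line_bins)
        all_pos = [located(f"P{i}AAAAAAA", i, "positive", line_bins) for i in range(1, 6)]
        all_neg = [located(f"N{i}AAAAAAA", i, "negative", line_bins) for i in range(1, 6)]
        assert knn_score(target, all_pos, ens, k=5)[0] == 1.0
        assert knn_score(target, all_neg, ens, k=5)[0] == 0.0

    def test_matches_exhaustive_oracle_with_ties(self):
        """Random instances (<= 20 training epitopes, tie-prone integer
        coordinates) match the brute-force oracle for k in 1..5."""
        bins = make_bin_table([("chr1", 10 * 500_000), ("chr2", 10 * 500_000)])
        rng = np.random.default_rng(4)
        for trial in range(30):
            coords = [
                rng.integers(0, 3, size=(20, 3)).astype(float) for _ in range(2)
            ]
            ens = ensemble_from_coords(coords, bins)
            n_train = int(rng.integers(3, 21))
            training = [
                located(
                    f"PEP{trial}X{i}", int(rng.integers(0, 20)),
                    "positive" if rng.random() < 0.5 else "negative", bins,
                )
                for i in range(n_train)
            ]
            target = located("TARGETPEP", int(rng.integers(0, 20)), "negative", bins)
            for k in (1, 2, 3, 4, 5):
                assert knn_score(target, training, ens, k=k) == brute_force_knn(
                    target, training, ens, k
                )

    def test_global_prior_fallback_when_no_same_chrom_neighbors(self):
        bins = make_bin_table([("chr1", 5 * 500_000), ("chr2", 5 * 500_000)])
        rng = np.random.default_rng(5)
        ens = ensemble_from_coords([rng.normal(size=(10, 3))], bins)
        target = located("TARGETPEP", 0, "negative", bins)  # chr1
        training = [
            located(f"N{i}AAAAAAA", 5 + i, "positive" if i < 2 else "negative", bins)
            for i in range(4)  # all on chr2
        ]
        score, n_used = knn_score(target, training, ens)
        assert n_used == 0
        assert score == pytest.approx(0.5)  # 2/4 positives globally

    def test_rigid_motion_invariance(self, line_bins):
        """Per-replica rotation/reflection leaves the score unchanged."""
        rng = np.random.default_rng(6)
        coords = [rng.normal(size=(10, 3)) for _ in range(3)]
        ens = ensemble_from_coords(coords, line_bins)
        target = located("TARGETPEP", 0, "negative", line_bins)
        training = [
            located(f"P{i}AAAAAAA", i, "positive" if i % 2 else "negative", line_bins)
            for i in range(1, 8)
        ]
        before = knn_score(target, training, ens, k=3)
        rotated = []
        for c in coords:
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            rotated.append(c @ q.T)
        ens_rot = ensemble_from_coords(rotated, line_bins)
        assert knn_score(target, training, ens_rot, k=3) == pytest.approx(before)

    def test_unlocated_target_rejected(self, line_bins):
        rng = np.random.default_rng(7)
        ens = ensemble_from_coords([rng.normal(size=(10, 3))], line_bins)
        target = LabeledEpitope("TARGETPEP", "HLA-A*02:01", 0.0, "negative")
        with pytest.raises(ValueError, match="TARGETPEP"):
            knn_score(target, [located("A" * 9, 1, "positive", line_bins)], ens)


class TestCombineScores:
    def test_zero_knn_is_pure_baseline(self):
        assert combine_scores(0.4, 0.0) == pytest.approx(0.4)

    def test_higher_knn_ranks_better_at_equal_baseline(self):
        assert combine_scores(0.5, 0.9) < combine_scores(0.5, 0.1)

    def test_stated_arithmetic(self):
        assert combine_scores(0.3, 0.8) == pytest.approx(-0.5)

    def test_out_of_range_baseline_rejected(self):
        with pytest.raises(ValueError, match="rescale"):
            combine_scores(1.5, 0.2)

    @given(
        b=st.floats(0, 1), k1=st.floats(0, 1), k2=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotonicity_property(self, b, k1, k2):
        lo, hi = sorted([k1, k2])
        assert combine_scores(b, hi) <= combine_scores(b, lo)


class TestRescaleBaseline:
    def test_fractional_ranks(self):
        np.testing.assert_allclose(
            rescale_baseline([10.0, 20.0, 30.0]), [0.0, 0.5, 1.0]
        )

    def test_constant_list_maps_to_half(self):
        np.testing.assert_allclose(rescale_baseline([5.0, 5.0, 5.0]), 0.5)

    def test_invert_flag(self):
        np.testing.assert_allclose(
            rescale_baseline([10.0, 20.0, 30.0], invert=True), [1.0, 0.5, 0.0]
        )

    def test_affinity_mode_strong_binder_low_score(self):
        out = rescale_baseline([1.0, 50.0, 50_000.0], mode="affinity")
        assert out[0] == 0.0 and out[2] == 1.0 and 0 < out[1] < 1

    @given(
        st.lists(st.integers(-100, 100), min_size=2, max_size=20, unique=True),
        st.sampled_from([lambda x: 2 * x + 3, np.exp, lambda x: x**3]),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_transform_invariance(self, raw, f):
        raw = np.asarray(raw, dtype=float)
        np.testing.assert_allclose(
            rescale_baseline(raw), rescale_baseline(f(raw / 20.0)), atol=1e-12
        )


class TestEstimator:
    @pytest.fixture
    def fitted(self, line_bins):
        rng = np.random.default_rng(8)
        ens = ensemble_from_coords([rng.normal(size=(10, 3)) for _ in range(3)], line_bins)
        X = np.column_stack([rng.integers(0, 10, size=30), rng.uniform(0, 1, size=30)])
        y = rng.integers(0, 2, size=30)
        return Genome3DNNClassifier(ensemble=ens, k=3).fit(X, y), X, y

    def test_sklearn_params_round_trip(self, fitted):
        clf, _, _ = fitted
        params = clf.get_params()
        assert params["k"] == 3
        clf.set_params(k=5)
        assert clf.k == 5

    def test_decision_matches_module_functions(self, fitted, line_bins):
        clf, X, y = fitted
        d = clf.decision_function(X[:5])
        for i in range(5):
            target = located(f"target_{i}", int(X[i, 0]), "negative", line_bins)
            kscore, _ = knn_score(target, clf._training_, clf.ensemble, k=3)
            assert d[i] == pytest.approx(kscore - X[i, 1])

    def test_predict_proba_shape_and_range(self, fitted):
        clf, X, _ = fitted
        proba = clf.predict_proba(X)
        assert proba.shape == (30, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_requires_two_feature_columns(self, fitted):
        clf, _, y = fitted
        with pytest.raises(ValueError, match="2 columns"):
            Genome3DNNClassifier(ensemble=clf.ensemble).fit(np.zeros((30, 3)), y)
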