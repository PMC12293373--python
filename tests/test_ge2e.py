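"""GE2E loss: oracle equivalence, analytic gradient, geometry properties."""

import numpy as np
import pytest

import protovol as pv
from protovol.errors import ConfigurationError, DataError
from conftest import naive_ge2e_loss


def _batch(n, m, d, seed=0):
    return pv.EmbeddingBatch(np.random.default_rng(seed).normal(size=(n, m, d)),
                             label_ids=list(range(n)))


class TestCentroids:
    def test_identical_vectors_give_that_vector(self):
        u = np.array([1.0, 2.0, 3.0])
        e = np.stack([np.stack([u, u]), np.stack([u + 1, u - 1])])
        c = pv.centroids(pv.EmbeddingBatch(e, [0, 1]))
        assert np.array_equal(c.centroids[0], u)

    def test_simple_arithmetic_mean(self):
        e = np.array([[[1.0, 0.0], [0.0, 1.0]], [[2.0, 2.0], [4.0, 4.0]]])
        c = pv.centroids(pv.EmbeddingBatch(e, [0, 1]))
        assert np.array_equal(c.centroids[0], [0.5, 0.5])
        assert np.array_equal(c.centroids[1], [3.0, 3.0])

    def test_matches_explicit_loop_means(self):
        b = _batch(3, 4, 8, seed=1)
        c = pv.centroids(b)
        for i in range(3):
            loop = sum(b.embeddings[i, j] for j in range(4)) / 4
            assert np.allclose(c.centroids[i], loop, atol=1e-12)

    def test_self_exclusion_needs_m_of_two(self):
        with pytest.raises(ConfigurationError):
            pv.centroids(_batch(2, 1, 4), pv.GE2EConfig(self_exclusion=True))


class TestSimilarity:
    def test_colinear_gives_one(self):
        e = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        c = pv.CentroidSet(np.array([[2.0, 0.0], [0.0, 3.0]]))
        s = pv.similarity(pv.EmbeddingBatch(e, [0, 1]), c).values
        assert s[0, 0, 0] == pytest.approx(1.0)
        assert s[0, 0, 1] == pytest.approx(0.0)
        assert s[1, 0, 1] == pytest.approx(1.0)

    def test_matches_loop_cosines(self):
        b = _batch(3, 4, 6, seed=2)
        cfg = pv.GE2EConfig(scale=2.0, bias=-0.5)
        c = pv.centroids(b, cfg)
        s = pv.similarity(b, c, cfg).values
        for i in range(3):
            for j in range(4):
                for k in range(3):
                    f, ck = b.embeddings[i, j], c.centroids[k]
                    cos = f @ ck / (np.linalg.norm(f) * np.linalg.norm(ck))
                    assert abs(s[i, j, k] - (2.0 * cos - 0.5)) < 1e-10

    def test_bounded_by_scale_and_bias(self):
        s = pv.similarity(_batch(4, 5, 3, seed=3)).values
        assert np.all(s >= -1 - 1e-12) and np.all(s <= 1 + 1e-12)

    def test_zero_vector_rejected_not_nan(self):
        e = np.ones((2, 2, 3))
        b = pv.EmbeddingBatch(e, [0, 1])
        c = pv.CentroidSet(np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]))
        with pytest.raises(DataError):
            pv.similarity(b, c)


class TestLoss:
    def test_single_label_collapses_to_zero(self):
        for m in (1, 3, 5):
            assert pv.ge2e_loss(_batch(1, m, 4, seed=m)) == pytest.approx(0.0)

    def test_hand_computed_two_singleton_labels(self):
        # f_0 = (1,0), f_1 = (0,1): own-similarity 1, cross-similarity 0
        e = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        loss = pv.ge2e_loss(pv.EmbeddingBatch(e, [0, 1]))
        expected = 2 * (-1.0 + np.log(np.e + 1.0))
        assert loss == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("self_exclusion", [False, True])
    def test_matches_naive_loop_oracle(self, self_exclusion):
        rng = np.random.default_rng(4)
        for rep in range(25):
            n = rng.integers(2, 5)
            m = rng.integers(2, 6)
            d = rng.integers(2, 9)
            e = rng.normal(size=(n, m, d))
            w, bias = rng.uniform(0.5, 3.0), rng.uniform(-1, 1)
            cfg = pv.GE2EConfig(self_exclusion=self_exclusion, scale=w,
                                bias=bias)
            got = pv.ge2e_loss(pv.EmbeddingBatch(e, list(range(n))), cfg)
            want = naive_ge2e_loss(e, w, bias, self_exclusion)
            assert got == pytest.approx(want, abs=1e-6)

    def test_mean_reduction_divides_by_batch_terms(self):
        b = _batch(3, 4, 5, seed=5)
        total = pv.ge2e_loss(b, pv.GE2EConfig(reduction="sum"))
        mean = pv.ge2e_loss(b, pv.GE2EConfig(reduction="mean"))
        assert mean == pytest.approx(total / 12)

    def test_permutation_of_labels_and_samples_preserves_loss(self):
        rng = np.random.default_rng(6)
        e = rng.normal(size=(4, 3, 5))
        base = pv.ge2e_loss(pv.EmbeddingBatch(e, [0, 1, 2, 3]))
        perm_n = rng.permutation(4)
        shuffled = e[perm_n][:, rng.permutation(3)]
        assert pv.ge2e_loss(pv.EmbeddingBatch(shuffled, list(perm_n))) \
            == pytest.approx(base, abs=1e-10)

    def test_cosine_scale_invariance(self):
        e = np.random.default_rng(7).normal(size=(3, 4, 6))
        a = pv.ge2e_loss(pv.EmbeddingBatch(e, [0, 1, 2]))
        b = pv.ge2e_loss(pv.EmbeddingBatch(3.0 * e, [0, 1, 2]))
        assert a == pytest.approx(b, abs=1e-8)

    @pytest.mark.parametrize("self_exclusion", [False, True])
    def test_analytic_gradient_matches_finite_differences(self, self_exclusion):
        rng = np.random.default_rng(8)
        e = rng.normal(size=(3, 3, 4))
        cfg = pv.GE2EConfig(self_exclusion=self_exclusion, scale=1.5, bias=0.2)
        _, grad = pv.ge2e_loss(pv.EmbeddingBatch(e.copy(), [0, 1, 2]), cfg,
                               return_grad=True)
        h = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (2, 1, 1), (0, 2, 2)]:
            ep, em = e.copy(), e.copy()
            ep[idx] += h
            em[idx] -= h
            num = (pv.ge2e_loss(pv.EmbeddingBatch(ep, [0, 1, 2]), cfg)
                   - pv.ge2e_loss(pv.EmbeddingBatch(em, [0, 1, 2]), cfg)) / (2 * h)
            assert grad[idx] == pytest.approx(num, abs=1e-6)

    def test_gradient_step_decreases_loss_on_separated_labels(self):
        rng = np.random.default_rng(9)
        e = np.stack([rng.normal([3, 0, 0], 0.5, size=(4, 3)),
                      rng.normal([0, 3, 0], 0.5, size=(4, 3))])
        cfg = pv.GE2EConfig()
        loss0, grad = pv.ge2e_loss(pv.EmbeddingBatch(e.copy(), [0, 1]), cfg,
                                   return_grad=True)
        stepped = e - 1e-3 * grad
        loss1 = pv.ge2e_loss(pv.EmbeddingBatch(stepped, [0, 1]), cfg)
        assert loss1 < loss0


class TestTrainGE2E:
    def test_insufficient_samples_fails_before_training(self, tiny_spec):
        pool = pv.simulate_dataset(pv.SyntheticConfig(
            n_patients=4, volume_shape=(4, 8, 8), lesion_radius_voxels=2.0,
            seed=0))
        enc = pv.build_encoder(tiny_spec, seed=0)
        with pytest.raises(DataError, match="samples"):
            pv.train_ge2e(enc, pool, sched=pv.TrainSchedule(m_per_label=10,
                                                            steps=5))

    def test_training_improves_class_separation(self, tiny_spec):
        """After GE2E training, intra-label cosine similarity exceeds
        inter-label similarity on held-out samples (the pull/push claim)."""
        cfg = pv.SyntheticConfig(n_patients=60, volume_shape=(4, 8, 8),
                                 lesion_contrast=4.0, lesion_radius_voxels=2.0,
                                 seed=1)
        data = pv.simulate_dataset(cfg)
        train, test = pv.split_by_patient(data, (0.7, 0.3), seed=2)
        enc = pv.build_encoder(tiny_spec, seed=3)
        pv.train_ge2e(enc, train, sched=pv.TrainSchedule(steps=120, seed=4))
        emb = pv.embed_batch(enc, test)
        vecs = np.stack([ev.values for ev, _, _ in emb])
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        labels = np.array([label for _, label, _ in emb])
        sim = vecs @ vecs.T
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        intra = sim[same & off_diag].mean()
        inter = sim[~same].mean()
        assert intra > inter

    def test_loss_curve_logged(self, tiny_spec, tiny_pool, tmp_path):
        enc = pv.build_encoder(tiny_spec, seed=0)
        curve = tmp_path / "curve.csv"
        pv.train_ge2e(enc, tiny_pool, sched=pv.TrainSchedule(steps=5, seed=1),
                      curve_path=curve)
        lines = curve.read_text().strip().splitlines()
        assert lines[0] == "step,loss"
        assert len(lines) == 6
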