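"""Episode sampling, prototypes and nearest-prototype classification."""

import numpy as np
import pytest

import protovol as pv
from protovol.errors import ConfigurationError, EpisodeError
from conftest import pairwise_auc


def _pool(n_per_class=50, seed=0):
    """Balanced pool; one exam per patient by construction."""
    return pv.simulate_dataset(pv.SyntheticConfig(
        n_patients=2 * n_per_class, volume_shape=(4, 8, 8),
        lesion_radius_voxels=2.0, seed=seed))


def _ev(values, exam_id="q"):
    return pv.EmbeddingVector(np.asarray(values, dtype=float), exam_id)


class TestBuildEpisode:
    def test_counts_with_all_remaining_queries(self):
        ep = pv.build_episode(_pool(50), pv.EpisodeConfig(k_shot=40, seed=0))
        assert ep.support.class_counts() == {0: 40, 1: 40}
        assert len(ep.query) == 20

    def test_insufficient_class_named_in_error(self):
        pool = _pool(50)
        few_pos = pv.SampleSet(
            [s for s in pool if s.label == 0][:30]
            + [s for s in pool if s.label == 1][:5], name="few")
        with pytest.raises(EpisodeError, match="class 1 has 5"):
            pv.build_episode(few_pos, pv.EpisodeConfig(k_shot=20))

    def test_same_seed_reproduces_episode_exactly(self):
        pool = _pool(30)
        a = pv.build_episode(pool, pv.EpisodeConfig(k_shot=5, seed=11))
        b = pv.build_episode(pool, pv.EpisodeConfig(k_shot=5, seed=11))
        assert a.support.exam_ids == b.support.exam_ids
        assert a.query.exam_ids == b.query.exam_ids

    @pytest.mark.parametrize("seed", range(10))
    def test_support_query_disjointness(self, seed):
        pool = _pool(25)
        ep = pv.build_episode(pool, pv.EpisodeConfig(k_shot=10, seed=seed))
        assert not set(ep.support.exam_ids) & set(ep.query.exam_ids)
        assert not set(ep.support.patient_ids) & set(ep.query.patient_ids)

    def test_fixed_n_query(self):
        ep = pv.build_episode(_pool(30),
                              pv.EpisodeConfig(k_shot=5, n_query=8, seed=1))
        assert len(ep.query) == 8

    def test_n_way_fixed_at_two(self):
        with pytest.raises(ConfigurationError):
            pv.EpisodeConfig(k_shot=2, n_way=3)


class TestPrototypes:
    def test_single_support_embedding_is_the_prototype(self):
        p = pv.prototypes([(_ev([1.0, 2.0]), 0), (_ev([5.0, 5.0]), 1)])
        assert np.array_equal(p.prototypes[0], [1.0, 2.0])

    def test_arithmetic_mean(self):
        p = pv.prototypes([(_ev([0.0, 0.0]), 0), (_ev([2.0, 2.0]), 0),
                           (_ev([1.0, 0.0]), 1)])
        assert np.array_equal(p.prototypes[0], [1.0, 1.0])

    def test_matches_loop_mean_at_k40(self):
        rng = np.random.default_rng(0)
        sup = [(_ev(rng.normal(size=16)), label)
               for label in (0, 1) for _ in range(40)]
        p = pv.prototypes(sup)
        for label in (0, 1):
            vecs = [ev.values for ev, l in sup if l == label]
            loop = sum(vecs) / len(vecs)
            assert np.allclose(p.prototypes[label], loop, atol=1e-12)

    def test_l2_normalize_option_averages_unit_vectors(self):
        sup = [(_ev([2.0, 0.0]), 0), (_ev([0.0, 4.0]), 0), (_ev([1.0, 1.0]), 1)]
        p = pv.prototypes(sup, l2_normalize=True)
        assert np.allclose(p.prototypes[0], [0.5, 0.5])


class TestClassifyQuery:
    def test_query_at_positive_prototype(self):
        p = pv.PrototypeSet({0: np.array([0.0, 0.0]), 1: np.array([3.0, 4.0])})
        r = pv.classify_query(_ev([3.0, 4.0]), p)
        assert r.predicted_label == 1
        assert r.distances[1] == 0.0
        assert r.score == pytest.approx(5.0)

    def test_equidistant_tie_goes_to_negative(self):
        p = pv.PrototypeSet({0: np.array([-1.0, 0.0]), 1: np.array([1.0, 0.0])})
        r = pv.classify_query(_ev([0.0, 5.0]), p)
        assert r.predicted_label == 0
        assert r.score == pytest.approx(0.0)

    def test_agrees_with_brute_force_nearest(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            d = rng.integers(2, 12)
            q = _ev(rng.normal(size=d))
            p = pv.PrototypeSet({0: rng.normal(size=d), 1: rng.normal(size=d)})
            r = pv.classify_query(q, p)
            d0 = np.sqrt(((q.values - p.prototypes[0]) ** 2).sum())
            d1 = np.sqrt(((q.values - p.prototypes[1]) ** 2).sum())
            assert r.predicted_label == (1 if d1 < d0 else 0)

    def test_dimension_mismatch(self):
        p = pv.PrototypeSet({0: np.zeros(3), 1: np.ones(3)})
        with pytest.raises(pv.DataError):
            pv.classify_query(_ev([1.0, 2.0]), p)


class TestEpisodeEvaluation:
    def test_oracle_embedding_auc_tracks_contrast(self):
        """With the generator's own lesion statistic as a 1-D embedding,
        episode AUC approaches 1 at high contrast and 0.5 at contrast 0."""
        for contrast, lo, hi in [(0.0, 0.3, 0.7), (6.0, 0.95, 1.0)]:
            cfg = pv.SyntheticConfig(n_patients=80, volume_shape=(4, 8, 8),
                                     lesion_contrast=contrast,
                                     lesion_radius_voxels=2.0, seed=3)
            sset = pv.simulate_dataset(cfg)
            ref = pv.lesion_mask(cfg, tuple(d / 2 for d in cfg.volume_shape))
            ep = pv.build_episode(sset, pv.EpisodeConfig(k_shot=10, seed=0))
            sup = [( _ev([s.volume.voxels[ref].mean()], s.exam_id), s.label)
                   for s in ep.support]
            proto = pv.prototypes(sup)
            scores, labels = [], []
            for s in ep.query:
                r = pv.classify_query(
                    _ev([s.volume.voxels[ref].mean()], s.exam_id), proto)
                scores.append(r.score)
                labels.append(s.label)
            auc = pairwise_auc(scores, labels)
            assert lo <= auc <= hi, f"contrast {contrast}: AUC {auc}"

    def test_support_relabeling_flips_predictions_and_auc(self, tiny_spec):
        pool = _pool(20, seed=5)
        enc = pv.build_encoder(tiny_spec, seed=6)
        ep = pv.build_episode(pool, pv.EpisodeConfig(k_shot=8, seed=7))
        results = pv.evaluate_episode(enc, ep)
        flipped_support = pv.SampleSet(
            [pv.LabeledSample(label=1 - s.label, exam_id=s.exam_id,
                              patient_id=s.patient_id, _volume=s.volume)
             for s in ep.support], name="flipped")
        flipped = pv.evaluate_episode(
            enc, pv.Episode(flipped_support, ep.query, ep.config))
        for r, f in zip(results, flipped):
            assert f.predicted_label == 1 - r.predicted_label
            assert f.score == pytest.approx(-r.score, abs=1e-9)
        labels = [r.true_label for r in results]
        auc = pv.roc_auc([r.score for r in results], labels)
        auc_flipped = pv.roc_auc([f.score for f in flipped], labels)
        assert auc_flipped == pytest.approx(1.0 - auc, abs=1e-12)

    def test_evaluate_many_uses_distinct_seeds_and_aggregates(self, tiny_spec):
        pool = _pool(15, seed=8)
        enc = pv.build_encoder(tiny_spec, seed=9)
        reports, agg = pv.evaluate_many(enc, pool, pv.EpisodeConfig(k_shot=4),
                                        n_episodes=5, base_seed=0)
        assert len(reports) == 5
        assert agg["auc_mean"] == pytest.approx(
            np.mean([r.auc for r in reports]))
        # different base seeds give different episodes
        reports2, _ = pv.evaluate_many(enc, pool, pv.EpisodeConfig(k_shot=4),
                                       n_episodes=5, base_seed=100)
        assert any(a.to_dict() != b.to_dict()
                   for a, b in zip(reports, reports2))
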