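"""Prediction, RSA, uniqueness, and validation-experiment statistics."""

import numpy as np
import pytest
from scipy import stats

from semvis.evaluation import (
    RDM,
    build_rdm,
    dice_coefficient,
    embed_2d,
    label_agreement_metrics,
    predict_semantic_content,
    predict_stimuli_family,
    predict_stimuli_for_concept,
    procrustes_align,
    real_vs_null_comparison,
    rsa_compare,
    rsa_difference,
    twoafc_validation,
    uniqueness_analysis,
)
from semvis.mapping import fit_pipeline
from semvis.semantics import EmbeddingModel


@pytest.fixture(scope="module")
def embedding():
    gen = np.random.default_rng(1)
    words = ["dog", "cat", "grass", "sky", "tree", "water", "bird", "dogs"]
    return EmbeddingModel({w: gen.standard_normal(6) for w in words})


class TestDice:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2}, {1, 2}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2, 3}, {2, 3, 4}, 2 * 2 / 6),
            (set(), set(), 0.0),
        ],
    )
    def test_values(self, a, b, expected):
        assert dice_coefficient(a, b) == pytest.approx(expected)

    def test_symmetric_bounded_and_one_iff_equal(self, rng):
        for _ in range(20):
            a = set(rng.integers(0, 10, rng.integers(1, 6)).tolist())
            b = set(rng.integers(0, 10, rng.integers(1, 6)).tolist())
            d = dice_coefficient(a, b)
            assert d == dice_coefficient(b, a)
            assert 0.0 <= d <= 1.0
            assert (d == 1.0) == (a == b)


class TestPredictStimuli:
    def test_perfect_ranking_gives_dice_one(self, rng):
        concept = rng.standard_normal(8)
        pos = np.stack([concept + 0.01 * rng.standard_normal(8) for _ in range(3)])
        neg = -np.stack([concept + 0.01 * rng.standard_normal(8) for _ in range(5)])
        feats = np.vstack([pos, neg])
        truth = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        out = predict_stimuli_for_concept(concept, feats, truth, n_perm=50, seed=0)
        assert out.statistic == pytest.approx(1.0)

    def test_hand_case_two_positives_one_hit(self):
        # correlations rank stimuli (0, 1, 2, 3); truth marks {0, 3}: the top-2
        # prediction {0, 1} hits one of two -> Dice = 2*1/4 = 0.5
        base = np.array([1.0, -1.0, 0.5, -0.5])
        feats = np.stack([base * s + np.array([0.0, 0.1, -0.1, 0.2]) for s in
                          (1.0, 0.8, 0.6, 0.4)])
        concept = base
        truth = np.array([1, 0, 0, 1])
        out = predict_stimuli_for_concept(concept, feats, truth, n_perm=20, seed=0)
        assert out.statistic == pytest.approx(0.5)

    def test_random_truth_gives_small_z(self, rng):
        feats = rng.standard_normal((40, 6))
        concept = rng.standard_normal(6)
        zs = []
        for rep in range(10):
            truth = np.zeros(40, int)
            truth[rng.permutation(40)[:10]] = 1
            out = predict_stimuli_for_concept(concept, feats, truth,
                                              n_perm=200, seed=rep)
            zs.append(out.z)
        assert np.max(np.abs(zs)) < 3.0

    def test_degenerate_truth_rejected(self, rng):
        feats = rng.standard_normal((5, 4))
        with pytest.raises(ValueError):
            predict_stimuli_for_concept(np.ones(4), feats, np.ones(5, int))

    def test_family_correction_is_conservative(self, rng):
        feats = rng.standard_normal((30, 6))
        from semvis.mapping import ConceptRepresentation

        concepts = [
            ConceptRepresentation(label=f"c{j}", features=rng.standard_normal(6))
            for j in range(4)
        ]
        truth = np.zeros((30, 4), int)
        for j in range(4):
            truth[rng.permutation(30)[:8], j] = 1
        outs = predict_stimuli_family(concepts, feats, truth, n_perm=100, seed=3)
        for o in outs:
            assert o.p_fwe >= o.p


class TestRDM:
    def test_duplicate_vectors_distance_zero(self, rng):
        v = rng.standard_normal(5)
        rdm = build_rdm(np.stack([v, v, rng.standard_normal(5)]), ["a", "b", "c"])
        assert rdm.distances[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_distance_two(self, rng):
        v = rng.standard_normal(5)
        rdm = build_rdm(np.stack([v, -v, rng.standard_normal(5)]), ["a", "b", "c"])
        assert rdm.distances[0, 1] == pytest.approx(2.0)

    def test_matches_bruteforce_pairwise(self, rng):
        x = rng.standard_normal((3, 6))
        rdm = build_rdm(x, ["a", "b", "c"])
        for i in range(3):
            for j in range(3):
                expected = 1 - stats.pearsonr(x[i], x[j]).statistic
                assert rdm.distances[i, j] == pytest.approx(expected)

    def test_constant_vector_rejected(self, rng):
        x = np.vstack([np.ones(4), rng.standard_normal((2, 4))])
        with pytest.raises(ValueError, match="constant"):
            build_rdm(x, ["a", "b", "c"])

    def test_entries_in_range(self, rng):
        rdm = build_rdm(rng.standard_normal((6, 10)), list("abcdef"))
        assert rdm.distances.min() >= 0.0 and rdm.distances.max() <= 2.0


class TestRSA:
    def test_self_correlation_is_one(self, rng):
        rdm = build_rdm(rng.standard_normal((6, 8)), list("abcdef"))
        res = rsa_compare(rdm, rdm, n_perm=50, n_boot=50, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal((6, 8))
        rdm1 = build_rdm(x, list("abcdef"))
        beh = build_rdm(rng.standard_normal((6, 8)), list("abcdef"))
        transformed = RDM(distances=np.sqrt(rdm1.distances), labels=rdm1.labels)
        r1 = rsa_compare(rdm1, beh, n_perm=10, n_boot=10, seed=1)
        r2 = rsa_compare(transformed, beh, n_perm=10, n_boot=10, seed=1)
        assert r1.rho == pytest.approx(r2.rho)

    def test_null_p_values_roughly_uniform(self):
        # independent random RDMs: permutation p should be ~Uniform(0, 1)
        gen = np.random.default_rng(2)
        ps = []
        labels = [f"i{k}" for k in range(10)]
        for _ in range(60):
            a = build_rdm(gen.standard_normal((10, 6)), labels)
            b = build_rdm(gen.standard_normal((10, 6)), labels)
            ps.append(rsa_compare(a, b, n_perm=99, n_boot=1, seed=gen).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_label_mismatch_rejected(self, rng):
        a = build_rdm(rng.standard_normal((3, 5)), ["a", "b", "c"])
        b = build_rdm(rng.standard_normal((3, 5)), ["x", "y", "z"])
        with pytest.raises(ValueError):
            rsa_compare(a, b)

    def test_difference_test_detects_better_model(self, rng):
        base = rng.standard_normal((8, 10))
        labels = [f"i{k}" for k in range(8)]
        beh = build_rdm(base, labels)
        good = build_rdm(base + 0.1 * rng.standard_normal((8, 10)), labels)
        bad = build_rdm(rng.standard_normal((8, 10)), labels)
        diff, p = rsa_difference(good, bad, beh, n_perm=200, seed=4)
        assert diff > 0
        assert p < 0.05


class TestUniqueness:
    def test_identical_groups_and_halves_saturate_correlations(self, rng, embedding):
        # both groups carry the same data and the two halves are duplicates,
        # so every representation vector is identical: within = between = 1
        words = list(embedding.vocabulary)[:6]
        base_f = rng.standard_normal((30, 6))
        base_s = np.stack([embedding[words[i % 6]] for i in range(30)])
        feats = np.vstack([base_f, base_f])
        sems = np.vstack([base_s, base_s])
        res = uniqueness_analysis(
            feats, sems, feats.copy(), sems.copy(), words, embedding,
            n_perm=20, n_boot=20, seed=0,
        )
        assert res.within == pytest.approx(1.0)
        assert res.between == pytest.approx(1.0)
        assert res.difference == pytest.approx(0.0, abs=1e-10)

    def test_distinct_worlds_within_exceeds_between(self, small_feature_model):
        from semvis.simulation import make_standard_world, simulate_experiment

        wa = make_standard_world(m=16, d=12, v=24, n_clusters=4, noise_sd=0.2, seed=21)
        wb = make_standard_world(m=16, d=12, v=24, n_clusters=4, noise_sd=0.2, seed=22)
        # same lexicon/embedding, different ground-truth mappings
        wb.lexicon = wa.lexicon
        wb.embedding = wa.embedding
        ta = simulate_experiment(wa, small_feature_model, t=300, seed=31)
        tb = simulate_experiment(wb, small_feature_model, t=300, seed=32)
        res = uniqueness_analysis(
            ta.features, ta.trial_vectors(wa.embedding),
            tb.features, tb.trial_vectors(wa.embedding),
            wa.lexicon, wa.embedding, n_perm=40, n_boot=10, seed=1,
        )
        assert res.within > res.between
        assert res.p < 0.05


class TestTwoAFC:
    def test_all_correct_concept_significant(self):
        r = np.ones((20, 3))
        r[:, 1] = np.random.default_rng(0).integers(0, 2, 20)
        res = twoafc_validation(r, n_boot=2000, seed=1)
        assert res.accuracies[0] == 1.0 and res.significant[0]
        assert res.accuracies[2] == 1.0 and res.significant[2]

    def test_binary_input_enforced(self):
        with pytest.raises(ValueError):
            twoafc_validation(np.full((4, 2), 0.5))

    def test_fair_coin_rarely_significant(self):
        gen = np.random.default_rng(3)
        r = gen.integers(0, 2, size=(50, 60)).astype(float)
        res = twoafc_validation(r, n_boot=4000, seed=4)
        # Sidak-corrected one-sided level over 60 concepts ~ 0.00085
        assert res.significant.sum() <= 1

    def test_subset_mean_permutation_p(self):
        gen = np.random.default_rng(5)
        r = gen.integers(0, 2, size=(30, 10)).astype(float)
        r[:, :3] = 1.0  # strong subset
        res = twoafc_validation(r, n_boot=500, subset=np.arange(3),
                                n_perm=500, seed=6)
        assert res.mean_accuracy == 1.0
        assert res.mean_p < 0.05

    def test_default_resample_count_matches_procedure(self):
        r = np.ones((3, 2))
        res = twoafc_validation(r, seed=0)
        assert res.n_boot == 50_000


class TestLabelAgreement:
    def test_unanimous_responses(self, embedding):
        m = label_agreement_metrics(["dog"] * 10, "dog", embedding)
        assert m.most_common_correct
        assert m.entropy == pytest.approx(0.0)
        assert m.dispersion_trace == pytest.approx(0.0)

    def test_plural_counts_as_correct(self, embedding):
        m = label_agreement_metrics(["dogs", "dogs", "cat"], "dog", embedding)
        assert m.most_common_correct

    def test_uniform_entropy_is_log_k(self, embedding):
        words = ["dog", "cat", "grass", "sky"]
        m = label_agreement_metrics(words, "dog", embedding)
        assert m.entropy == pytest.approx(np.log(4))

    def test_slope_matches_normal_equations(self):
        # engineered embeddings: cosines 0.9, 0.5, 0.1 to the true label
        def on_circle(c):
            return np.array([c, np.sqrt(1 - c * c)])

        emb = EmbeddingModel(
            {
                "true": np.array([1.0, 0.0]),
                "near": on_circle(0.9),
                "mid": on_circle(0.5),
                "far": on_circle(0.1),
            }
        )
        responses = ["near"] * 10 + ["mid"] * 5 + ["far"] * 1
        m = label_agreement_metrics(responses, "true", emb)
        x = np.array([0.1, 0.5, 0.9])  # distances 1 - cosine
        y = np.array([10.0, 5.0, 1.0])
        slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        assert m.slope == pytest.approx(slope)
        assert slope == pytest.approx(-11.25)

    def test_out_of_vocabulary_label_rejected(self, embedding):
        with pytest.raises(KeyError):
            label_agreement_metrics(["dog"], "zebra", embedding)


class TestRealVsNull:
    def test_clear_separation_all_flags_true(self, embedding):
        real = {"dog": ["dog"] * 8, "cat": ["cat"] * 8}
        null = {
            "dog": [["sky", "grass", "tree", "water"] * 2 for _ in range(3)],
            "cat": [["sky", "grass", "tree", "water"] * 2 for _ in range(3)],
        }
        res = real_vs_null_comparison(real, null, embedding, n_perm=50,
                                      n_boot=50, seed=0)
        assert all(v.all() for v in res.flags.values())
        assert all(c == 2 for c in res.counts.values())

    def test_identical_distributions_tie_fails(self, embedding):
        words = ["dog", "cat", "sky"]
        real = {"dog": list(words)}
        null = {"dog": [list(words), list(words)]}
        res = real_vs_null_comparison(real, null, embedding, n_perm=20,
                                      n_boot=20, seed=0)
        assert not any(v.any() for v in res.flags.values())

    def test_exchangeable_responses_counts_within_null_band(self, embedding):
        gen = np.random.default_rng(7)
        vocab = ["dog", "cat", "grass", "sky", "tree", "water"]
        concepts = ["dog", "cat", "grass", "sky"]
        real = {c: [vocab[i] for i in gen.integers(0, 6, 10)] for c in concepts}
        null = {
            c: [[vocab[i] for i in gen.integers(0, 6, 10)] for _ in range(3)]
            for c in concepts
        }
        res = real_vs_null_comparison(real, null, embedding, n_perm=200,
                                      n_boot=50, seed=8)
        # under exchangeability no metric should be significant
        assert all(p > 0.05 for p in res.p.values())

    def test_missing_nulls_rejected(self, embedding):
        with pytest.raises(ValueError, match="no null responses"):
            real_vs_null_comparison({"dog": ["dog"]}, {"dog": []}, embedding)


class TestEmbed2D:
    def test_seeded_rerun_identical(self, rng):
        x = rng.standard_normal((12, 8))
        a = embed_2d(x, seed=5)
        b = embed_2d(x, seed=5)
        assert np.array_equal(a, b)

    def test_procrustes_identity(self, rng):
        layout = rng.standard_normal((10, 2))
        aligned = procrustes_align(layout, layout)
        assert np.allclose(aligned, layout, atol=1e-8)

    def test_procrustes_recovers_rotation(self, rng):
        layout = rng.standard_normal((10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        rotated = layout @ rot.T
        aligned = procrustes_align(rotated, layout)
        assert np.max(np.abs(aligned - layout)) < 1e-6

    def test_too_few_items_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_2d(rng.standard_normal((2, 4)))


class TestPredictSemanticContent:
    def test_cosine_extremes(self, rng, embedding):
        feats = rng.standard_normal((20, 6))
        sems = rng.standard_normal((20, 4))
        matrix = fit_pipeline(feats, sems)
        from semvis.mapping import features_to_semantics

        preds = np.stack([features_to_semantics(f, matrix) for f in feats[:3]])
        per, mean = predict_semantic_content(feats[:3], preds, matrix)
        for o in per:
            assert o.statistic == pytest.approx(1.0)
        orth = np.stack([_orthogonal_to(p, rng) for p in preds])
        per2, _ = predict_semantic_content(feats[:3], orth, matrix)
        for o in per2:
            assert abs(o.statistic) < 1e-8

    def test_recovers_structure_against_label_null(self, small_world,
                                                   small_feature_model,
                                                   small_trials):
        sems = small_trials.trial_vectors(small_world.embedding)
        hold = 5
        matrix = fit_pipeline(small_trials.features[hold:], sems[hold:])
        pool = [w for ws in small_trials.word_lists[:hold] for w in ws]
        counts = [len(ws) for ws in small_trials.word_lists[:hold]]
        _, mean = predict_semantic_content(
            small_trials.features[:hold], sems[:hold], matrix,
            label_pool=pool, label_counts=counts,
            embedding=small_world.embedding, n_null=200, seed=2,
        )
        assert mean.statistic > np.quantile(
            np.array([mean.null_mean]), 0.0
        )  # sanity: null summary present
        assert mean.p < 0.05


def _orthogonal_to(v, rng):
    x = rng.standard_normal(v.shape[0])
    x -= (x @ v) / (v @ v) * v
    return x
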