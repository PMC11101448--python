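"""Downstream evaluation: semantic-content prediction, stimulus prediction,
and representational similarity analysis on a simulated experiment."""

import numpy as np

from semvis.evaluation import (
    build_rdm,
    predict_semantic_content,
    predict_stimuli_family,
    rsa_compare,
)
from semvis.mapping import concept_to_features, fit_pipeline
from semvis.simulation import (
    make_standard_feature_model,
    make_standard_world,
    simulate_experiment,
)

world = make_standard_world(seed=0)
feature_model = make_standard_feature_model(seed=0)
trials = simulate_experiment(world, feature_model, t=2000, seed=9)
sems = trials.trial_vectors(world.embedding)

# hold out 5 stimuli, fit on the rest
hold = 5
matrix = fit_pipeline(trials.features[hold:], sems[hold:])

pool = [w for ws in trials.word_lists[:hold] for w in ws]
counts = [len(ws) for ws in trials.word_lists[:hold]]
per_image, mean_out = predict_semantic_content(
    trials.features[:hold], sems[:hold], matrix,
    label_pool=pool, label_counts=counts, embedding=world.embedding,
    n_null=200, seed=1,
)
print(f"semantic-content prediction on {hold} held-out stimuli: "
      f"mean cosine {mean_out.statistic:.3f} "
      f"(null mean {mean_out.null_mean:.3f}, p = {mean_out.p:.3f})")

# which stimuli contain a concept?
concepts = [concept_to_features(w, world.embedding, matrix)
            for w in world.lexicon[:5]]
truth = np.zeros((500, 5), int)
for j, w in enumerate(world.lexicon[:5]):
    truth[:, j] = [w in ws for ws in trials.word_lists[:500]]
outs = predict_stimuli_family(concepts, trials.features[:500], truth,
                              n_perm=200, seed=2)
for w, o in zip(world.lexicon[:5], outs):
    print(f"stimulus prediction for {w!r}: Dice {o.statistic:.2f}, "
          f"Z {o.z:.1f}, familywise p {o.p_fwe:.3f}")

# second-order similarity: do recovered representations mirror the embedding?
rec = np.stack([
    concept_to_features(w, world.embedding, matrix).features
    for w in world.lexicon
])
emb = np.stack([world.embedding[w] for w in world.lexicon])
rdm_visual = build_rdm(rec, world.lexicon)
rdm_semantic = build_rdm(emb, world.lexicon)
res = rsa_compare(rdm_visual, rdm_semantic, n_perm=500, n_boot=500, seed=3)
print(f"RSA: Spearman rho {res.rho:.2f} "
      f"(95% CI {res.ci[0]:.2f}-{res.ci[1]:.2f}, p = {res.p:.3f})")
print("a positive rho says concepts similar in the embedding also have")
print("similar recovered visual representations.")
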