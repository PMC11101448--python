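# semvis — reverse correlation in deep feature space

Classical reverse correlation infers an observer's internal template by
correlating random pixel noise with their responses — workable for a letter
or a facial expression, but hopeless for abstract natural concepts whose
appearance varies across thousands of images. `semvis` generalizes the
paradigm to an abstract feature space: stimuli are images optimized to carry
*pseudo-random values of deep network features* ("feature noise"), observers
answer with free-text labels, and a word embedding turns those labels into
vectors, so a single linear map can relate the entire visual feature space to
the entire semantic space. The toolkit is for cognitive scientists and
psychophysicists who want to recover, visualize, and validate mental
representations of arbitrary visual concepts from open-ended behavior.

## The model

Let `x_i ∈ R^v` be the channel-mean activations (one scalar per channel of a
chosen layer) of the stimulus on trial `i`, and `y_i ∈ R^d` the mean embedding
vector of the observer's labels. Both sides are reduced by whitened PCA,
keeping the minimum number of components explaining 90% of variance. With
whitened trial-score matrices `X (t × k_v)` and `Y (t × k_s)`, the
**visual–semantic matrix** is the scaled outer product

    B = XᵀY / (t − 1),

which equals the multivariate least-squares coefficient matrix (scores are
uncorrelated with unit variance), so each cell reads as a correlation between
a visual and a semantic principal component. Coefficients are tested with a
**permutation max-statistic**: semantic rows are shuffled across trials, `B`
refitted, every cell z-scored, and each observed |Z| compared with the null
distribution of the familywise maximum |Z| (exact familywise error control).

Projecting through `B` runs in both directions:

* **concept → features**: embed a word, apply the semantic PCA, multiply by
  `B`, invert the visual PCA — the concept's feature vector `y`;
* **features → semantics**: the transpose route predicts the semantic content
  of a new image.

A concept is visualized by optimizing an image `p` (Fourier-parameterized,
1/f-scaled, color-decorrelated) to maximize the **caricature objective**

    ⟨y, φ(p)⟩ · ( ⟨y, φ(p)⟩ / (‖y‖·‖φ(p)‖) )^α ,      α = 4,

which pushes the image's features `φ(p)` far along the concept direction
while the cosine factor keeps the direction true; small random
rotations/translations/scalings per step suppress adversarial high-frequency
artifacts. Stimuli themselves are synthesized the same way but by minimizing
the MSE to a target vector sampled from a whitened kernel-density model of
the feature space (Adam with decoupled weight decay; lr 0.05, wd 0.1, β₁ 0.9,
β₂ 0.999).

Everything downstream of these primitives — Dice-based stimulus prediction,
cosine prediction of semantic content, Spearman RSA with permutation and
bootstrap inference, split-half uniqueness analysis, 2AFC validation with
participant bootstrap and Šidák correction, open-label agreement metrics —
is in `semvis.evaluation`, and `semvis.simulation` provides synthetic worlds
with known ground truth for parameter-recovery testing.

## Worked example

```bash
python examples/fit_visual_semantic_map.py
```

prints (numbers from an actual run):

```
simulated 2000 trials, mean labels/trial = 2.19
retained 38 visual PCs and 17 semantic PCs (90% variance each)
72 of 646 coefficients significant (familywise alpha 0.05, critical |Z| = 3.91)
```

2000 simulated trials of observers labeling feature-noise stimuli suffice to
expose dozens of familywise-significant visual–semantic associations; under
shuffled data the expected number of flagged families is 5%. The other
example scripts cover stimulus synthesis (`synthesize_stimuli.py`, final MSE
≈ 4% of initial in 300 iterations, R² ≈ 0.999), concept reconstruction with
bootstrap CIs (`reconstruct_concepts.py`), prediction and RSA
(`evaluate_predictions.py`, ρ ≈ 0.68 between recovered-representation and
embedding RDMs), and observer comparison (`compare_observers.py`, within-
vs between-group r = 0.93 vs 0.78, p = 0.01).

A thin CLI wraps the same workflows:

```bash
semvis simulate --t 2000 --seed 7 --out simulated
semvis fit-map --trials simulated/trials.csv --features simulated/features.npz \
       --embedding simulated/embedding.txt --out fitted
semvis reconstruct --matrix fitted/matrix.npz --embedding simulated/embedding.txt \
       --concept waa --out reconstructions
```

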