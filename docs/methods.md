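# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite shows. Units: images are H × W × 3 float
arrays in [0, 1]; feature vectors are channel-mean activations (arbitrary
activation units); entropies are in nats.

## Feature-space model (`semvis.feature_space`)

Channel activations collected over an image corpus are standardized per
channel (corpus mean and ddof-1 sd — the statistics always come from the
fitting corpus, never from a sampled batch). The covariance of the
standardized features is estimated with analytic shrinkage toward its
diagonal. Because standardization makes the diagonal the identity, the
Ledoit–Wolf estimator applies unchanged; its analytically chosen intensity is
stored on the model and can be overridden (`shrinkage=` in `[0, 1]`).
Whitening is the symmetric (ZCA / Mahalanobis) inverse square root
`W = Σ^(-1/2)`; coloring is its exact inverse. ZCA is used rather than PCA
whitening because it stays maximally close to the original channel basis, so
whitened coordinates remain interpretable as channels.

Each whitened feature gets a 1-D Gaussian kernel density (Scott's rule
`sd · n^(-1/5)` per feature; absolute bandwidth override available). Sampling
draws a training point uniformly and adds Gaussian noise at the bandwidth
scale — exact for Gaussian kernels. Independent per-feature draws are then
colored and unstandardized. Note the sampler's asymptotic covariance is
`C · diag(var_j + h_j²) · Cᵀ` on the standardized scale — the shrunk
covariance inflated by the bandwidth — which the tests account for.

## Synthesis (`semvis.synthesis`)

Images are parameterized by complex Fourier coefficients per color channel,
initialized from a Gaussian with sd 0.01. Rendering: (i) 1/f scaling by
frequency magnitude, with the DC term given the minimum nonzero frequency's
scale to avoid division by zero; (ii) inverse FFT, real part; (iii) color
decorrelation by a 3 × 3 matrix supplied as model metadata (identity default
for toy work); (iv) a logistic sigmoid into [0, 1]. The sigmoid was chosen
over clamping because it is smooth and invertible on the open interval, so
gradients never die at the display-range boundary.

No autodiff framework is used: every stage carries an analytic
vector-Jacobian product (the adjoint of `real ∘ ifft2` is `fft2 / N`;
the random rotation/translation/homothecy of transformation robustness is
applied as an explicit sparse bilinear-interpolation matrix whose transpose
is the exact adjoint). The `FeatureExtractor` protocol therefore requires
`features(image)` plus `vjp(image, upstream)`; any differentiable backend can
implement it.

Optimization is Adam with *decoupled* weight decay on the coefficients
(defaults: 1500 iterations, lr 0.05, weight decay 0.1, β₁ 0.9, β₂ 0.999 for
MSE stimulus synthesis; 2000 iterations and α = 4 for caricature
reconstruction). Robustness-transform ranges default to ±5° rotation, ±4 px
translation, scale 0.95–1.05, sampled uniformly each iteration with bilinear
interpolation and edge padding; all ranges are config-exposed. The default
image size is 224; the test fixtures use 32.

The caricature objective `⟨y, φ⟩ (⟨y, φ⟩ / (‖y‖‖φ‖))^α` is positively
homogeneous of degree 1 in each argument, so the magnitude of the target
direction is irrelevant. For integer α (the default regime) a negative
cosine poses no problem; for non-integer α the code requires a positive
cosine and raises otherwise. `SynthesisResult.r_squared` is `1 − SSE/SStot`
between achieved and target feature values.

## Response cleaning and embedding (`semvis.semantics`)

Cleaning lowercases, removes stopwords (a compact built-in English list by
default; any list can be supplied), single characters, and numerals (tokens
containing a digit or parseable as a number). Words the embedding does not
recognize are spell-corrected within edit distance 2 (edlib); ties prefer the
priority lexicon of visual words, then lexicographic order. Multiword labels
recognized whole by the embedding embed as one token, otherwise they are
split. Every token's fate (kept / corrected / dropped, with reason) is
logged exactly once. Trial vectors are plain means of word vectors, giving
every trial equal weight regardless of label count.

Participant screening follows the concreteness rule: exclude when strictly
more than 25% of a participant's rated words score below 4; unrated words are
ignored. Singular/plural equivalence strips a trailing "s" when the stripped
form is in vocabulary — a documented shortcut, not full lemmatization.

## Mapping and inference (`semvis.mapping`)

PCA keeps the minimum component count whose cumulative explained variance
reaches 90%, with whitened scores. `B = XᵀY/(t−1)`; the `1/(t−1)` scale makes
whitened-score coefficients read as correlations and is irrelevant to ranks,
significance, and (direction-only) reconstruction. The reverse projection
uses `Bᵀ`, making the two directions exact adjoints.

The permutation test z-scores observed and null matrices with **pooled**
per-cell moments (the observed matrix included alongside the permutations).
Studentizing by the null-only moments — the textbook description — lets each
null matrix shrink its own z through its contribution to the sd and
measurably inflates the familywise error at small permutation counts
(12% at nominal 5% with 200 matrices of 100 cells); pooling restores
exchangeability and makes the test exact (measured 5.0%). At 1000
permutations the two conventions differ negligibly. Significance is decided
by `p ≤ α` with `p = (1 + #{null max ≥ |Z|}) / (n_perm + 1)`; cells with a
degenerate null sd are flagged untestable. For a 213 × 127 family with
Gaussian-like nulls the familywise 5% critical value computes to |Z| ≈ 4.72,
matching the max-of-Gaussians approximation Φ⁻¹(1 − 0.025/27051) = 4.76.

Bootstrap concept CIs resample trials with replacement and refit the full
pipeline per resample (both PCAs and B); a fast mode keeps the PCAs fixed.
Degenerate resamples are redrawn and counted. Leave-concept-out removes
individual response words equal to the concept or its singular/plural form,
drops a trial only when emptied, and refits everything.

## Synthetic worlds (`semvis.simulation`)

The generator emulates the experiment's structure: a lexicon of m words with
a clustered unit-sphere embedding; a ground-truth linear map `W* (v × d)`
with entries `N(0, 1/v)` so the semantic image `s = W*ᵀ x̃` of standardized
features has unit-scale components; observer noise added to `s` (sd 0.5 by
default — "moderate" in the sense that recovery is clearly degraded relative
to noiseless but far from chance); labels drawn without replacement from a
softmax (temperature 0.1) over cosine similarities between `s` and the
lexicon; 1–3 labels per trial with probabilities (0.2, 0.43, 0.37), matching
the observed mean of 2.17 labels per stimulus. The standard world is m = 40,
d = 32, v = 64. The toy extractor is a frozen random convolution (wrap
boundary, so its adjoint is exact) with softplus nonlinearity and spatial
mean; kernels are scaled so pre-activations are O(1) over [0, 1] images,
i.e. channels genuinely respond to content.

What the generator does **not** emulate: real images and a real trained
network (features come from the toy extractor or are sampled directly in
feature space), lexical structure of natural language (the toy embedding has
cluster geometry but no syntax or frequency effects), participant
heterogeneity, lapses, response times, or memory effects. Passing tests
therefore demonstrate that the estimator and inference machinery recover a
linear visual–semantic structure from softmax-quantized labels under noise —
not that the pipeline's assumptions hold for human data.

One consequence of the observer model worth stating: the label rule is a
near-argmax quantization of the linear semantic image, and the best *linear*
read-out of a quantized rule is intrinsically imperfect — top-1 label
prediction from `features_to_semantics` plateaus near 0.5–0.6 even with
noiseless labels and many trials (an oracle using the true nonlinear rule
reaches ≈ 0.9 on the same data). Recovery of concept *feature vectors* is
unaffected by this ceiling (mean recovered-vs-true correlation ≈ 0.6 at
t = 2000 under standard conditions, every concept beating its label-permuted
null), because it aggregates over trials rather than ranking single ones.

## Evaluation (`semvis.evaluation`)

Dice is `2|A∩B|/(|A|+|B|)` with the empty–empty case defined as 0. Stimulus
prediction thresholds the per-stimulus correlations so the predicted-positive
count matches the true count, ties broken by stimulus index; the family-level
correction uses the max of z-scored null Dice values. RDMs are correlation
distances; RSA uses Spearman correlation of upper triangles, permutation by
joint row/column shuffling of the behavioral RDM, bootstrap by resampling
items and dropping off-diagonal zero entries from duplicates. The uniqueness
analysis splits trials into deterministic first/second halves (trial order is
randomized by design; a fixed split keeps reruns identical).

2AFC validation bootstraps participants (multinomial weights, default 50,000
resamples); a concept is significant when the one-sided Šidák-level
(`1 − (1−α)^(1/m)`) lower quantile of its bootstrap distribution exceeds 0.5.
The Šidák level is config-exposed because more than one convention is in use;
an opt-in refinement pass reruns borderline concepts (lower bound in
[0.4, 0.6]) with 500,000 resamples. The mean-level permutation shuffles
correctness entries across concepts, which is informative only for a proper
subset of the family; for the full family (where any permutation preserves
the mean) the code substitutes an exact binomial test against chance.
Real-vs-null comparisons require strict improvement on each of the four
metrics (correct-label frequency, semantic distance, entropy, dispersion
trace); ties count as failures. Entropy uses natural log; dispersion is the
trace of the ddof-1 covariance of response embeddings, defined as 0 for
single-response sets (a warning is emitted).

2-D layouts delegate to t-SNE with correlation distance (perplexity 15,
reduced to `(n−1)/3` for small item sets) and can be aligned to a reference
layout by orthogonal Procrustes (rotation + isotropic scale + translation).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 500 simulated null families
(10 × 10 coefficients, 200 permutations) for familywise-error calibration;
10 fair-coin 2AFC families of 50 participants × 350 concepts at 50,000
bootstrap resamples; 20 replicates of the standard synthetic world at
t = 2000 (and 20 at t = 200) with 40-permutation recovery nulls; 300/200
iteration synthesis runs at 32 × 32 with the 16-channel toy extractor. These
sizes give stable Monte-Carlo estimates while keeping a full run in the
minutes range on one CPU. Every stochastic routine takes a seed and is
bit-reproducible on one platform given (seed, config, extractor).

## Known limitations

* The linear map cannot represent context-dependent or compositional
  label use; the simulator's quantization ceiling (above) is the visible
  symptom.
* Spell correction scans the vocabulary per unknown word — fine for the
  tens-of-thousands-word vocabularies used here, but a real-time application
  would want a prefix index.
* The color-decorrelation matrix ships as near-identity metadata; realistic
  color statistics must be estimated from a natural-image corpus and passed
  in.
* `features_to_semantics` inverts through the retained PCA subspaces only;
  feature components outside the retained visual subspace are invisible to
  the semantic prediction.
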