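"""Synthetic worlds and simulated observers for end-to-end testing.

The generator emulates the experiment's structure: stimulus feature vectors
are drawn from a fitted feature-space model; an observer's semantic percept is
a noisy linear image of the standardized stimulus features under a
ground-truth visual-semantic mapping W* (v x d); labels (1-3 per trial, with
the label-count distribution matched to the observed mean of 2.17 labels per
stimulus) are drawn from a softmax over cosine similarities between the
percept and the lexicon's embedding vectors.

By default the simulation operates directly in feature space (no pixel
synthesis), so full parameter-recovery suites run quickly; pixel-mode tests
route targets through :func:`semvis.synthesis.synthesize_stimulus` with the
toy extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .extractors import FeatureExtractor
from .feature_space import FeatureSpaceModel, fit_feature_space, sample_target_features
from .mapping import VisualSemanticMatrix, concept_to_features, fit_pipeline
from .semantics import EmbeddingModel, RawResponse, embed_trial

__all__ = [
    "SyntheticWorld",
    "SimulatedTrialSet",
    "ConvToyExtractor",
    "make_toy_extractor",
    "make_toy_embedding",
    "make_standard_world",
    "simulate_experiment",
    "model_observer_responses",
    "recovery_correlations",
]


# ---------------------------------------------------------------------------
# toy extractor

def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ConvToyExtractor(FeatureExtractor):
    """Frozen random convolution + softplus + spatial mean, per channel.

    Circular (wrap) boundary handling makes the convolution's adjoint exact,
    so pixel gradients are analytic.  Deterministic given the seed.
    """

    def __init__(self, channels: int, image_size: int, seed: int | None = None,
                 kernel_size: int = 5, layer: str = "conv"):
        if channels < 1:
            raise ValueError("channels must be >= 1")
        rng = np.random.default_rng(seed)
        # scaled so pre-activations are O(1) over [0, 1] images, i.e. the
        # channels actually respond to image content
        scale = 4.0 / np.sqrt(3 * kernel_size**2)
        self.kernels = rng.normal(0.0, scale, size=(channels, 3, kernel_size, kernel_size))
        self.bias = rng.normal(0.0, 0.3, size=channels)
        self.image_size = image_size
        self.sampled_layer = layer
        self.layer_channels = {layer: channels}

    def _preactivations(self, image: np.ndarray) -> np.ndarray:
        acts = np.empty((self.kernels.shape[0], self.image_size, self.image_size))
        for c in range(self.kernels.shape[0]):
            a = np.zeros((self.image_size, self.image_size))
            for i in range(3):
                a += ndimage.correlate(image[:, :, i], self.kernels[c, i], mode="wrap")
            acts[c] = a + self.bias[c]
        return acts

    def layer_features(self, image: np.ndarray, layer: str) -> np.ndarray:
        self._check(image, layer)
        return _softplus(self._preactivations(image)).mean(axis=(1, 2))

    def layer_vjp(self, image: np.ndarray, layer: str, upstream: np.ndarray) -> np.ndarray:
        self._check(image, layer)
        acts = self._preactivations(image)
        n = self.image_size**2
        grad = np.zeros_like(image, dtype=float)
        for c in range(self.kernels.shape[0]):
            g_act = upstream[c] / n * _sigmoid(acts[c])
            for i in range(3):
                # adjoint of wrap-mode correlation is wrap-mode convolution
                grad[:, :, i] += ndimage.convolve(g_act, self.kernels[c, i], mode="wrap")
        return grad

    def _check(self, image: np.ndarray, layer: str) -> None:
        if layer not in self.layer_channels:
            raise KeyError(f"unknown layer {layer!r}")
        expect = (self.image_size, self.image_size, 3)
        if image.shape != expect:
            raise ValueError(f"image shape {image.shape} != {expect}")


def make_toy_extractor(
    channels: int, image_size: int, seed: int | None = None
) -> ConvToyExtractor:
    """A small fixed-parameter differentiable image-to-channel map."""
    return ConvToyExtractor(channels, image_size, seed)


# ---------------------------------------------------------------------------
# toy embedding

def make_toy_embedding(
    m: int, d: int, n_clusters: int, seed: int | None = None,
    spread: float = 0.35,
) -> tuple[EmbeddingModel, list[str]]:
    """Clustered unit-sphere embedding over a synthetic lexicon.

    Cluster centers are random directions; members are perturbed copies, so
    within-cluster cosine similarity exceeds between-cluster similarity on
    average.
    """
    if not m >= n_clusters >= 1:
        raise ValueError("need m >= n_clusters >= 1")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_clusters, d))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    # letter-only tokens so synthetic labels survive numeral filtering
    lexicon = [
        "w" + chr(ord("a") + i // 26) + chr(ord("a") + i % 26) for i in range(m)
    ]
    vectors: dict[str, np.ndarray] = {}
    for i, word in enumerate(lexicon):
        c = centers[i % n_clusters]
        v = c + spread * rng.standard_normal(d)
        vectors[word] = v / np.linalg.norm(v)
    return EmbeddingModel(vectors), lexicon


# ---------------------------------------------------------------------------
# synthetic world

@dataclass
class SyntheticWorld:
    """Ground-truth lexicon, embedding and mapping for simulated observers."""

    lexicon: list[str]
    embedding: EmbeddingModel
    mapping: np.ndarray  # W*, v x d
    noise_sd: float = 0.5
    label_count_probs: tuple[float, float, float] = (0.2, 0.43, 0.37)
    temperature: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.lexicon) < 2:
            raise ValueError("lexicon needs at least 2 words")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not np.isclose(sum(self.label_count_probs), 1.0):
            raise ValueError("label count probabilities must sum to 1")

    @property
    def n_visual(self) -> int:
        return self.mapping.shape[0]

    def true_concept_features(self) -> np.ndarray:
        """m x v ground-truth feature patterns (standardized feature space)."""
        E = np.stack([self.embedding[w] for w in self.lexicon])
        return E @ self.mapping.T


@dataclass
class SimulatedTrialSet:
    features: np.ndarray  # t x v, channel space
    responses: list[RawResponse]
    word_lists: list[list[str]] = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def trial_vectors(self, embedding: EmbeddingModel) -> np.ndarray:
        return np.stack([embed_trial(w, embedding) for w in self.word_lists])


def make_standard_world(
    m: int = 40, d: int = 32, v: int = 64, n_clusters: int = 8,
    noise_sd: float = 0.5, seed: int | None = 0,
) -> SyntheticWorld:
    """The standard synthetic world used across the recovery suites."""
    rng = np.random.default_rng(seed)
    emb_seed = int(rng.integers(2**31))
    embedding, lexicon = make_toy_embedding(m, d, n_clusters, seed=emb_seed)
    mapping = rng.normal(0.0, 1.0 / np.sqrt(v), size=(v, d))
    return SyntheticWorld(
        lexicon=lexicon, embedding=embedding, mapping=mapping,
        noise_sd=noise_sd, seed=seed,
    )


def make_standard_feature_model(
    v: int = 64, n_corpus: int = 500, seed: int | None = 0
) -> FeatureSpaceModel:
    """A feature-space model fitted on a synthetic activation corpus."""
    rng = np.random.default_rng(seed)
    # mild correlation structure + heterogeneous scales, like channel data
    mix = np.eye(v) + 0.15 * rng.standard_normal((v, v))
    scales = np.exp(0.2 * rng.standard_normal(v))
    corpus = rng.standard_normal((n_corpus, v)) @ mix.T * scales + rng.normal(0, 1, v)
    return fit_feature_space(corpus)


def simulate_experiment(
    world: SyntheticWorld,
    feature_model: FeatureSpaceModel,
    t: int,
    seed: int | np.random.Generator | None = None,
) -> SimulatedTrialSet:
    """Simulate t trials: sampled stimulus features + observer labels."""
    if feature_model.n_features != world.n_visual:
        raise ValueError(
            f"feature model has {feature_model.n_features} channels, "
            f"world expects {world.n_visual}"
        )
    rng = np.random.default_rng(seed)
    X = sample_target_features(feature_model, t, rng)
    Xs = (X - feature_model.mean) / feature_model.std
    S = Xs @ world.mapping + world.noise_sd * rng.standard_normal((t, world.mapping.shape[1]))

    E = np.stack([world.embedding[w] for w in world.lexicon])
    En = E / np.linalg.norm(E, axis=1, keepdims=True)
    Sn = S / np.maximum(np.linalg.norm(S, axis=1, keepdims=True), 1e-12)
    sims = Sn @ En.T  # t x m

    counts = rng.choice([1, 2, 3], size=t, p=world.label_count_probs)
    m = len(world.lexicon)
    responses, word_lists = [], []
    for i in range(t):
        k = int(counts[i])
        if world.temperature == 0:
            chosen = np.argsort(-sims[i], kind="stable")[:k]
        else:
            logits = sims[i] / world.temperature
            p = np.exp(logits - logits.max())
            p /= p.sum()
            chosen = rng.choice(m, size=k, replace=False, p=p)
        labels = [world.lexicon[j] for j in chosen]
        responses.append(
            RawResponse(trial_id=str(i), participant_id="sim", labels=labels)
        )
        word_lists.append(labels)
    return SimulatedTrialSet(
        features=X, responses=responses, word_lists=word_lists,
        provenance={"t": t, "noise_sd": world.noise_sd},
    )


def model_observer_responses(
    class_probabilities: np.ndarray,
    class_labels: list[str],
    stimulus_ids: list[str] | None = None,
    top_k: int = 3,
    embedding: EmbeddingModel | None = None,
    resolver=None,
) -> tuple[list[RawResponse], list[dict]]:
    """Top-k class labels per stimulus as a model observer's responses.

    ``class_probabilities`` is an n_stimuli x n_classes table.  Labels with
    several comma-separated synonyms contribute their first synonym.  When an
    embedding is given, labels it rejects are passed to ``resolver(label)``
    (e.g., a hypernym lookup); unresolved labels are dropped and logged.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    probs = np.asarray(class_probabilities, float)
    n, c = probs.shape
    if c != len(class_labels):
        raise ValueError("probability columns must match class labels")
    ids = [str(i) for i in range(n)] if stimulus_ids is None else stimulus_ids
    responses, log = [], []
    for i in range(n):
        order = np.argsort(-probs[i], kind="stable")[:top_k]
        labels = []
        for j in order:
            label = class_labels[j].split(",")[0].strip().lower()
            if embedding is not None and label not in embedding:
                fixed = resolver(label) if resolver is not None else None
                if fixed is None or fixed not in embedding:
                    log.append({"stimulus": ids[i], "label": label, "action": "dropped"})
                    continue
                log.append({"stimulus": ids[i], "label": label,
                            "action": "resolved", "replacement": fixed})
                label = fixed
            labels.append(label)
        if labels:
            responses.append(
                RawResponse(trial_id=ids[i], participant_id="model", labels=labels)
            )
    return responses, log


def permuted_recovery_correlations(
    world: SyntheticWorld,
    trials: SimulatedTrialSet,
    feature_model: FeatureSpaceModel,
    n_perm: int = 40,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Null recovery: refit with semantic rows permuted across trials.

    Returns an n_perm x m array of recovered-vs-true correlations under the
    broken trial alignment, the reference distribution for judging real
    recovery quality.
    """
    rng = np.random.default_rng(seed)
    sems = trials.trial_vectors(world.embedding)
    out = np.empty((n_perm, len(world.lexicon)))
    for i in range(n_perm):
        perm = rng.permutation(sems.shape[0])
        matrix = fit_pipeline(trials.features, sems[perm])
        out[i] = recovery_correlations(world, trials, feature_model, matrix)
    return out


def recovery_correlations(
    world: SyntheticWorld,
    trials: SimulatedTrialSet,
    feature_model: FeatureSpaceModel,
    matrix: VisualSemanticMatrix | None = None,
) -> np.ndarray:
    """Pearson correlation of each recovered concept vector with ground truth.

    Recovered channel-space vectors are standardized with the feature model's
    statistics before correlation against the world's true (standardized
    space) concept patterns.
    """
    if matrix is None:
        matrix = fit_pipeline(trials.features, trials.trial_vectors(world.embedding))
    truth = world.true_concept_features()
    out = np.empty(len(world.lexicon))
    for j, word in enumerate(world.lexicon):
        rec = concept_to_features(word, world.embedding, matrix).features
        rec_std = (rec - feature_model.mean) / feature_model.std
        out[j] = np.corrcoef(rec_std, truth[j])[0, 1]
    return out
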