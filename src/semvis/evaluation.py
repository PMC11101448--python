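"""Downstream statistics: prediction, RSA, uniqueness, and validation analyses.

All permutation and bootstrap routines are seeded and deterministic, and all
permutation p-values floor at 1/(n_perm + 1).  Entropies are reported in nats.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from sklearn.manifold import TSNE

from .mapping import ConceptRepresentation, VisualSemanticMatrix, features_to_semantics
from .semantics import EmbeddingModel, embed_trial, singular_plural_equivalent

__all__ = [
    "RDM",
    "PredictionOutcome",
    "AgreementMetrics",
    "predict_semantic_content",
    "dice_coefficient",
    "predict_stimuli_for_concept",
    "predict_stimuli_family",
    "build_rdm",
    "rsa_compare",
    "rsa_difference",
    "uniqueness_analysis",
    "twoafc_validation",
    "label_agreement_metrics",
    "real_vs_null_comparison",
    "embed_2d",
    "procrustes_align",
]


# ---------------------------------------------------------------------------
# basic containers

@dataclass
class RDM:
    """Representational dissimilarity matrix (correlation distances)."""

    distances: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValueError("distance matrix and labels must agree")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(d), 0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.distances.shape[0], k=1)
        return self.distances[iu]


@dataclass
class PredictionOutcome:
    statistic: float  # cosine or Dice
    null_mean: float
    null_sd: float
    n_null: int
    z: float
    p: float
    p_fwe: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class AgreementMetrics:
    most_common_correct: bool
    slope: float
    slope_t: float
    slope_p: float  # one-tailed (negative slope)
    entropy: float  # nats
    dispersion_trace: float


def _perm_p(null: np.ndarray, observed: float, tail: str = "greater") -> float:
    n = null.shape[0]
    if tail == "greater":
        exceed = np.sum(null >= observed)
    elif tail == "less":
        exceed = np.sum(null <= observed)
    else:  # two-sided around 0
        exceed = np.sum(np.abs(null) >= abs(observed))
    return float((1 + exceed) / (n + 1))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm vector in cosine similarity")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# prediction of semantic content

def predict_semantic_content(
    image_features: np.ndarray,
    true_vectors: np.ndarray,
    matrix: VisualSemanticMatrix,
    label_pool: list[str] | None = None,
    label_counts: list[int] | None = None,
    embedding: EmbeddingModel | None = None,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[PredictionOutcome], PredictionOutcome]:
    """Cosine similarity between predicted and true semantic vectors.

    The null for the mean cosine re-draws each image's labels (with
    replacement) from ``label_pool`` and recomputes; requires ``label_pool``,
    per-image ``label_counts`` and the ``embedding``.
    """
    feats = np.asarray(image_features, float)
    truth = np.asarray(true_vectors, float)
    if feats.shape[0] != truth.shape[0]:
        raise ValueError("feature and semantic lists must align")
    preds = np.stack([features_to_semantics(f, matrix) for f in feats])
    cosines = np.array([_cosine(p, s) for p, s in zip(preds, truth)])

    null_means = np.empty(0)
    if label_pool is not None:
        if embedding is None or label_counts is None:
            raise ValueError("null model needs label_pool, label_counts, embedding")
        rng = np.random.default_rng(seed)
        pool = list(label_pool)
        null_means = np.empty(n_null)
        for b in range(n_null):
            cs = []
            for i in range(feats.shape[0]):
                words = [pool[j] for j in rng.integers(0, len(pool), label_counts[i])]
                cs.append(_cosine(preds[i], embed_trial(words, embedding)))
            null_means[b] = np.mean(cs)

    per_image = [
        PredictionOutcome(
            statistic=float(c), null_mean=float("nan"), null_sd=float("nan"),
            n_null=0, z=float("nan"), p=float("nan"),
        )
        for c in cosines
    ]
    mean_c = float(cosines.mean())
    if null_means.size:
        mu, sd = null_means.mean(), null_means.std(ddof=1)
        mean_out = PredictionOutcome(
            statistic=mean_c, null_mean=float(mu), null_sd=float(sd),
            n_null=n_null, z=float((mean_c - mu) / sd) if sd > 0 else float("nan"),
            p=_perm_p(null_means, mean_c),
        )
    else:
        mean_out = PredictionOutcome(
            statistic=mean_c, null_mean=float("nan"), null_sd=float("nan"),
            n_null=0, z=float("nan"), p=float("nan"),
        )
    return per_image, mean_out


# ---------------------------------------------------------------------------
# prediction of stimuli

def dice_coefficient(set_a, set_b) -> float:
    """2|A n B| / (|A| + |B|); two empty sets give 0 by convention."""
    a, b = set(set_a), set(set_b)
    denom = len(a) + len(b)
    if denom == 0:
        return 0.0
    return 2.0 * len(a & b) / denom


def _dice_for_truth(corr: np.ndarray, truth: np.ndarray) -> float:
    m_pos = int(truth.sum())
    order = np.argsort(-corr, kind="stable")  # ties broken by stimulus index
    predicted = set(order[:m_pos].tolist())
    actual = set(np.flatnonzero(truth).tolist())
    return dice_coefficient(predicted, actual)


def predict_stimuli_for_concept(
    concept: ConceptRepresentation | np.ndarray,
    stimulus_features: np.ndarray,
    truth: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PredictionOutcome:
    """Dice overlap between predicted and actual stimuli for one concept.

    Stimuli are ranked by Pearson correlation of their feature vectors with
    the concept's; the top m (m = number of positives) are predicted.  The
    null permutes the truth assignment across stimuli.
    """
    vec = concept.features if isinstance(concept, ConceptRepresentation) else np.asarray(concept)
    feats = np.asarray(stimulus_features, float)
    truth = np.asarray(truth).astype(int)
    if truth.sum() == 0 or truth.sum() == truth.shape[0]:
        raise ValueError("truth must contain both positives and negatives")
    corr = _rowwise_pearson(feats, vec)
    observed = _dice_for_truth(corr, truth)
    rng = np.random.default_rng(seed)
    null = np.array([
        _dice_for_truth(corr, truth[rng.permutation(truth.shape[0])])
        for _ in range(n_perm)
    ])
    mu, sd = null.mean(), null.std(ddof=1)
    z = (observed - mu) / sd if sd > 0 else float("nan")
    return PredictionOutcome(
        statistic=observed, null_mean=float(mu), null_sd=float(sd), n_null=n_perm,
        z=float(z), p=_perm_p(null, observed),
        extra={"null": null, "correlations": corr},
    )


def predict_stimuli_family(
    concepts: list[ConceptRepresentation],
    stimulus_features: np.ndarray,
    truth_matrix: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> list[PredictionOutcome]:
    """Family of stimulus predictions with max-statistic FWER correction.

    Observed and null Dice values are z-scored per concept by the null
    mean/sd; the per-permutation maximum of the z-scored nulls across the
    family calibrates the corrected p-values.
    """
    rng = np.random.default_rng(seed)
    outcomes = [
        predict_stimuli_for_concept(
            c, stimulus_features, truth_matrix[:, j], n_perm, rng
        )
        for j, c in enumerate(concepts)
    ]
    null_z = np.stack([
        (o.extra["null"] - o.null_mean) / (o.null_sd if o.null_sd > 0 else 1.0)
        for o in outcomes
    ])  # concepts x n_perm
    max_z = null_z.max(axis=0)
    for o in outcomes:
        o.p_fwe = _perm_p(max_z, o.z)
        o.extra.pop("null", None)
    return outcomes


def _rowwise_pearson(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.linalg.norm(rc, axis=1) * np.linalg.norm(vc)
    return rc @ vc / denom


# ---------------------------------------------------------------------------
# RSA

def build_rdm(vectors: np.ndarray, labels: list[str]) -> RDM:
    """Pairwise correlation distances (1 - Pearson r) between row vectors."""
    x = np.asarray(vectors, float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 items")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant vector cannot enter a correlation distance")
    d = 1.0 - np.corrcoef(x)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RDM(distances=d, labels=list(labels))


@dataclass
class RSAResult:
    rho: float
    p: float
    ci: tuple[float, float]
    n_perm: int
    n_boot: int


def rsa_compare(
    rdm_model: RDM,
    rdm_behavior: RDM,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> RSAResult:
    """Spearman correlation between vectorized upper triangles.

    Permutation p: joint row/column shuffling of the behavioral RDM
    (one-tailed, positive).  Bootstrap CI: items resampled with replacement,
    off-diagonal zero entries from duplicated items removed.
    """
    if rdm_model.labels != rdm_behavior.labels:
        raise ValueError("RDM label mismatch")
    rng = np.random.default_rng(seed)
    rho = _upper_spearman(rdm_model.distances, rdm_behavior.distances)
    n = rdm_model.distances.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = _upper_spearman(
            rdm_model.distances, rdm_behavior.distances[perm][:, perm]
        )
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _bootstrap_rho(rdm_model.distances, rdm_behavior.distances, rng)
    ci = (float(np.nanpercentile(boots, 2.5)), float(np.nanpercentile(boots, 97.5)))
    return RSAResult(rho=float(rho), p=_perm_p(null, rho), ci=ci,
                     n_perm=n_perm, n_boot=n_boot)


def rsa_difference(
    rdm_a: RDM,
    rdm_b: RDM,
    rdm_behavior: RDM,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Paired difference rho_A - rho_B with a two-tailed permutation test."""
    rng = np.random.default_rng(seed)
    beh = rdm_behavior.distances
    diff = _upper_spearman(rdm_a.distances, beh) - _upper_spearman(rdm_b.distances, beh)
    n = beh.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        bp = beh[perm][:, perm]
        null[i] = _upper_spearman(rdm_a.distances, bp) - _upper_spearman(
            rdm_b.distances, bp
        )
    return float(diff), _perm_p(null, diff, tail="two")


def _upper_spearman(a: np.ndarray, b: np.ndarray) -> float:
    iu = np.triu_indices(a.shape[0], k=1)
    return float(stats.spearmanr(a[iu], b[iu]).statistic)


def _bootstrap_rho(a: np.ndarray, b: np.ndarray, rng) -> float:
    n = a.shape[0]
    idx = rng.integers(0, n, n)
    sa, sb = a[idx][:, idx], b[idx][:, idx]
    iu = np.triu_indices(n, k=1)
    ua, ub = sa[iu], sb[iu]
    keep = ~((idx[iu[0]] == idx[iu[1]]))  # duplicated item -> zero distance
    if keep.sum() < 3 or np.ptp(ua[keep]) == 0 or np.ptp(ub[keep]) == 0:
        return float("nan")
    return float(stats.spearmanr(ua[keep], ub[keep]).statistic)


# ---------------------------------------------------------------------------
# uniqueness (split-half within vs between groups)

@dataclass
class UniquenessResult:
    within: float
    between: float
    difference: float
    p: float
    within_ci: tuple[float, float]
    between_ci: tuple[float, float]
    detail: dict = field(default_factory=dict)


def uniqueness_analysis(
    feats_a: np.ndarray,
    sems_a: np.ndarray,
    feats_b: np.ndarray,
    sems_b: np.ndarray,
    reference: list[str],
    embedding: EmbeddingModel,
    n_perm: int = 200,
    n_boot: int = 200,
    seed: int | np.random.Generator | None = None,
    variance_threshold: float = 0.9,
) -> UniquenessResult:
    """Split-half within- vs between-group correlation of representations.

    Each group's trials are split in half; per half a visual-semantic matrix
    is fitted and the reference concepts' feature vectors are concatenated
    into one long vector per half and group.  ``within`` averages corr(A1,A2)
    and corr(B1,B2); ``between`` averages corr(A1,B2) and corr(A2,B1).  The
    two-tailed p for the difference comes from refitting with semantic rows
    permuted across trials; CIs from resampling trials with replacement.
    """
    from .mapping import concept_to_features, fit_pipeline  # local, avoids cycle noise

    rng = np.random.default_rng(seed)

    # deterministic first/second-half split (trial order is already random
    # by experimental design; a fixed split keeps the analysis reproducible
    # and makes identical inputs give identical halves)
    def halves(n):
        idx = np.arange(n)
        return idx[: n // 2], idx[n // 2 :]

    a1, a2 = halves(feats_a.shape[0])
    b1, b2 = halves(feats_b.shape[0])

    def rep_vector(feats, sems):
        m = fit_pipeline(feats, sems, variance_threshold)
        return np.concatenate(
            [concept_to_features(w, embedding, m).features for w in reference]
        )

    def within_between(fa, sa, fb, sb, shuffle=False):
        parts = []
        for f, s, idx in ((fa, sa, (a1, a2)), (fb, sb, (b1, b2))):
            for half in idx:
                s_half = s[half]
                if shuffle:
                    s_half = s_half[rng.permutation(s_half.shape[0])]
                parts.append(rep_vector(f[half], s_half))
        va1, va2, vb1, vb2 = parts
        within = (np.corrcoef(va1, va2)[0, 1] + np.corrcoef(vb1, vb2)[0, 1]) / 2
        between = (np.corrcoef(va1, vb2)[0, 1] + np.corrcoef(va2, vb1)[0, 1]) / 2
        return within, between

    w_obs, b_obs = within_between(feats_a, sems_a, feats_b, sems_b)
    diff = w_obs - b_obs

    null = np.empty(n_perm)
    for i in range(n_perm):
        w_n, b_n = within_between(feats_a, sems_a, feats_b, sems_b, shuffle=True)
        null[i] = w_n - b_n
    p = _perm_p(null - null.mean(), diff - null.mean(), tail="two")

    w_boot = np.empty(n_boot)
    b_boot = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, feats_a.shape[0], feats_a.shape[0])
        ib = rng.integers(0, feats_b.shape[0], feats_b.shape[0])
        w_boot[i], b_boot[i] = within_between(
            feats_a[ia], sems_a[ia], feats_b[ib], sems_b[ib]
        )
    return UniquenessResult(
        within=float(w_obs), between=float(b_obs), difference=float(diff), p=p,
        within_ci=(float(np.percentile(w_boot, 2.5)), float(np.percentile(w_boot, 97.5))),
        between_ci=(float(np.percentile(b_boot, 2.5)), float(np.percentile(b_boot, 97.5))),
        detail={"null_sd": float(null.std(ddof=1))},
    )


# ---------------------------------------------------------------------------
# validation experiment 1: 2AFC

@dataclass
class TwoAFCResult:
    accuracies: np.ndarray
    significant: np.ndarray
    sidak_level: float
    mean_accuracy: float
    mean_p: float
    n_boot: int


def twoafc_validation(
    responses: np.ndarray,
    n_boot: int = 50_000,
    alpha: float = 0.05,
    subset: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    refine: bool = False,
    n_refine: int = 500_000,
    sidak_alpha: float | None = None,
) -> TwoAFCResult:
    """Per-concept 2AFC accuracy with participant-bootstrap Šidák inference.

    ``responses`` is a participants x concepts 0/1 correctness table.  A
    concept is significant when the Šidák-corrected lower percentile of its
    participant-bootstrap accuracy distribution exceeds the 0.5 chance level
    (one-sided level 1 - (1 - alpha)^(1/m); override via ``sidak_alpha``).
    ``refine`` repeats borderline concepts (lower bound in [0.4, 0.6]) with
    ``n_refine`` resamples.  The mean-level p permutes correctness entries
    across concepts when ``subset`` is a proper subset; for the full family
    (where that permutation is degenerate) it falls back to an exact binomial
    test against chance.
    """
    r = np.asarray(responses, float)
    if not np.isin(r, (0.0, 1.0)).all():
        raise ValueError("responses must be binary")
    n_part, m = r.shape
    rng = np.random.default_rng(seed)
    level = sidak_alpha if sidak_alpha is not None else 1.0 - (1.0 - alpha) ** (1.0 / m)

    acc = r.mean(axis=0)

    def boot_quantiles(cols: np.ndarray, n: int) -> np.ndarray:
        counts = rng.multinomial(n_part, np.full(n_part, 1.0 / n_part), size=n)
        boot = counts @ r[:, cols] / n_part  # n x len(cols)
        return np.quantile(boot, level, axis=0)

    lower = boot_quantiles(np.arange(m), n_boot)
    if refine:
        border = np.flatnonzero((lower >= 0.4) & (lower <= 0.6))
        if border.size:
            lower[border] = boot_quantiles(border, n_refine)
    significant = lower > 0.5

    cols = np.arange(m) if subset is None else np.asarray(subset, int)
    mean_acc = float(acc[cols].mean())
    if cols.shape[0] < m:
        null = np.empty(n_perm)
        flat = r.ravel()
        for i in range(n_perm):
            shuffled = flat[rng.permutation(flat.shape[0])].reshape(r.shape)
            null[i] = shuffled[:, cols].mean()
        mean_p = _perm_p(null, mean_acc)
    else:
        total = int(r.sum())
        mean_p = float(stats.binomtest(total, r.size, 0.5, alternative="greater").pvalue)

    return TwoAFCResult(
        accuracies=acc, significant=significant, sidak_level=float(level),
        mean_accuracy=mean_acc, mean_p=mean_p, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# validation experiments 2-3: open labeling

def _response_embeddings(words: list[str], embedding: EmbeddingModel) -> np.ndarray:
    return np.stack([embedding[w] for w in words])


def _entropy_nats(words: list[str]) -> float:
    counts = np.array(list(Counter(words).values()), float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _dispersion_trace(words: list[str], embedding: EmbeddingModel) -> float:
    if len(words) < 2:
        warnings.warn("dispersion trace of a single response is defined as 0",
                      stacklevel=2)
        return 0.0
    return float(np.trace(np.cov(_response_embeddings(words, embedding), rowvar=False)))


def _mean_distance_to_label(
    words: list[str], true_label: str, embedding: EmbeddingModel
) -> float:
    e = embedding[true_label]
    return float(
        np.mean([1.0 - _cosine(embedding[w], e) for w in words])
    )


def label_agreement_metrics(
    responses: list[str], true_label: str, embedding: EmbeddingModel
) -> AgreementMetrics:
    """Agreement of open-ended responses with a concept's true label.

    The slope is the least-squares coefficient of unique-response frequency
    on semantic distance to the true label (negative when close responses are
    more frequent), with its t statistic and one-tailed p (caller applies any
    across-concept correction).  Entropy of the empirical response
    distribution is in nats; dispersion is the trace of the response-embedding
    covariance.
    """
    if not responses:
        raise ValueError("need at least one response")
    if true_label not in embedding:
        raise KeyError(f"true label {true_label!r} not in embedding")
    counts = Counter(responses)
    top, top_n = counts.most_common(1)[0]
    # singular/plural forms count as the same answer
    mcc = singular_plural_equivalent(top, true_label, embedding)

    uniq = sorted(counts)
    dists = np.array([1.0 - _cosine(embedding[w], embedding[true_label]) for w in uniq])
    freqs = np.array([counts[w] for w in uniq], float)
    if len(uniq) >= 3 and np.std(dists) > 0:
        fit = stats.linregress(dists, freqs)
        slope, t = fit.slope, fit.slope / fit.stderr if fit.stderr > 0 else np.inf
        slope_p = float(stats.t.cdf(t, len(uniq) - 2))  # one-tailed, negative slope
    else:
        slope, t, slope_p = float("nan"), float("nan"), float("nan")
    return AgreementMetrics(
        most_common_correct=bool(mcc),
        slope=float(slope),
        slope_t=float(t),
        slope_p=slope_p,
        entropy=_entropy_nats(responses),
        dispersion_trace=_dispersion_trace(responses, embedding),
    )


@dataclass
class RealVsNullResult:
    flags: dict[str, np.ndarray]  # metric -> per-concept booleans
    counts: dict[str, int]
    p: dict[str, float]
    ci: dict[str, tuple[int, int]]


def real_vs_null_comparison(
    real_responses: dict[str, list[str]],
    null_responses: dict[str, list[list[str]]],
    embedding: EmbeddingModel,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> RealVsNullResult:
    """Compare real reconstructions with null reconstructions on four metrics.

    Per concept (keys of the two dicts; each concept's key is its true
    label): (1) correct-label frequency higher for the real image than the
    null average, (2) mean semantic distance to the true label lower,
    (3) response entropy lower, (4) semantic-dispersion trace smaller.
    Strictly-better comparisons; ties count as failures.  Significance of the
    summed counts: metrics 1-2 permute the concept/true-label assignment,
    metrics 3-4 permute all responses across images.  CIs resample the
    per-concept flag vectors.
    """
    concepts = sorted(real_responses)
    if sorted(null_responses) != concepts:
        raise ValueError("real and null responses must cover the same concepts")
    for c in concepts:
        if not null_responses[c]:
            raise ValueError(f"concept {c!r} has no null responses")
    rng = np.random.default_rng(seed)

    def correct_freq(words: list[str], label: str) -> float:
        return np.mean([singular_plural_equivalent(w, label, embedding) for w in words])

    def flags_for(assignment: dict[str, str]) -> dict[str, np.ndarray]:
        out = {k: np.zeros(len(concepts), bool) for k in
               ("correct_label", "semantic_distance", "entropy", "dispersion")}
        for j, c in enumerate(concepts):
            label = assignment[c]
            real, nulls = real_responses[c], null_responses[c]
            out["correct_label"][j] = correct_freq(real, label) > np.mean(
                [correct_freq(nw, label) for nw in nulls]
            )
            out["semantic_distance"][j] = _mean_distance_to_label(
                real, label, embedding
            ) < np.mean([_mean_distance_to_label(nw, label, embedding) for nw in nulls])
            out["entropy"][j] = _entropy_nats(real) < np.mean(
                [_entropy_nats(nw) for nw in nulls]
            )
            out["dispersion"][j] = _dispersion_trace(real, embedding) < np.mean(
                [_dispersion_trace(nw, embedding) for nw in nulls]
            )
        return out

    identity = {c: c for c in concepts}
    flags = flags_for(identity)
    counts = {k: int(v.sum()) for k, v in flags.items()}

    # permutation nulls
    p: dict[str, float] = {}
    null_counts = {k: np.empty(n_perm) for k in ("correct_label", "semantic_distance")}
    for i in range(n_perm):
        perm = rng.permutation(len(concepts))
        assignment = {c: concepts[perm[j]] for j, c in enumerate(concepts)}
        f = _label_metric_flags(
            concepts, assignment, real_responses, null_responses, embedding
        )
        null_counts["correct_label"][i] = f[0].sum()
        null_counts["semantic_distance"][i] = f[1].sum()
    for k in null_counts:
        p[k] = _perm_p(null_counts[k], counts[k])

    # metrics 3-4: permute all responses across all images
    all_words, sizes = [], []
    for c in concepts:
        sizes.append(("real", c, len(real_responses[c])))
        all_words.extend(real_responses[c])
        for nw in null_responses[c]:
            sizes.append(("null", c, len(nw)))
            all_words.extend(nw)
    null34 = {"entropy": np.empty(n_perm), "dispersion": np.empty(n_perm)}
    words_arr = np.array(all_words, dtype=object)
    for i in range(n_perm):
        shuffled = words_arr[rng.permutation(words_arr.shape[0])]
        sr, sn = _split_shuffled(shuffled, sizes)
        ce = cd = 0
        for j, c in enumerate(concepts):
            ce += _entropy_nats(sr[c]) < np.mean([_entropy_nats(x) for x in sn[c]])
            cd += _dispersion_trace(sr[c], embedding) < np.mean(
                [_dispersion_trace(x, embedding) for x in sn[c]]
            )
        null34["entropy"][i] = ce
        null34["dispersion"][i] = cd
    for k in null34:
        p[k] = _perm_p(null34[k], counts[k])

    ci = {}
    for k, v in flags.items():
        boots = rng.integers(0, len(concepts), size=(n_boot, len(concepts)))
        sums = v[boots].sum(axis=1)
        ci[k] = (int(np.percentile(sums, 2.5)), int(np.percentile(sums, 97.5)))
    return RealVsNullResult(flags=flags, counts=counts, p=p, ci=ci)


def _label_metric_flags(concepts, assignment, real_responses, null_responses, embedding):
    f1 = np.zeros(len(concepts), bool)
    f2 = np.zeros(len(concepts), bool)
    for j, c in enumerate(concepts):
        label = assignment[c]
        real, nulls = real_responses[c], null_responses[c]
        rf = np.mean([singular_plural_equivalent(w, label, embedding) for w in real])
        nf = np.mean([
            np.mean([singular_plural_equivalent(w, label, embedding) for w in nw])
            for nw in nulls
        ])
        f1[j] = rf > nf
        f2[j] = _mean_distance_to_label(real, label, embedding) < np.mean(
            [_mean_distance_to_label(nw, label, embedding) for nw in nulls]
        )
    return f1, f2


def _split_shuffled(shuffled, sizes):
    sr: dict[str, list[str]] = {}
    sn: dict[str, list[list[str]]] = {}
    pos = 0
    for kind, c, n in sizes:
        chunk = list(shuffled[pos : pos + n])
        pos += n
        if kind == "real":
            sr[c] = chunk
        else:
            sn.setdefault(c, []).append(chunk)
    return sr, sn


# ---------------------------------------------------------------------------
# 2-D embedding

def embed_2d(
    vectors: np.ndarray,
    perplexity: float = 15.0,
    seed: int | None = 0,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """t-SNE layout with correlation distance; optional Procrustes alignment."""
    x = np.asarray(vectors, float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items")
    perp = min(perplexity, (n - 1) / 3.0)
    layout = TSNE(
        n_components=2, metric="correlation", perplexity=perp,
        init="random", random_state=seed,
    ).fit_transform(x)
    if reference is not None:
        layout = procrustes_align(layout, np.asarray(reference, float))
    return layout


def procrustes_align(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes: rotate/scale/translate source onto target."""
    mu_s, mu_t = source.mean(axis=0), target.mean(axis=0)
    s0, t0 = source - mu_s, target - mu_t
    R, scale = orthogonal_procrustes(s0, t0)
    norm2 = (s0**2).sum()
    factor = scale / norm2 if norm2 > 0 else 1.0
    return s0 @ R * factor + mu_t
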