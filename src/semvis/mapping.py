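"""Visual-semantic mapping: dual PCA, the coefficient matrix, and inference.

Trial feature vectors (visual space) and trial semantic vectors are each
reduced by a whitened PCA keeping the minimum number of components that
explains 90% of the variance.  The visual-semantic matrix B is the scaled
outer product of the two trial x PC score matrices,

    B = X^T Y / (t - 1),

which for whitened scores (X^T X = (t-1) I) equals the least-squares
coefficient matrix of the multivariate regression of Y on X; with whitening
its entries read as correlations.  Significance of the coefficients is
assessed with a permutation max-statistic test: semantic rows are shuffled
across trials, B refitted, each cell z-scored by its null mean/sd, and the
observed |Z| compared to the null distribution of the per-permutation maximum
|Z| (familywise-corrected, two-tailed).

Concept projections run the matrix in both directions:
word -> semantic PCA -> B -> inverse visual PCA -> channel features, and
features -> visual PCA -> B^T -> inverse semantic PCA -> semantic vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .semantics import EmbeddingModel, embed_trial, singular_plural_equivalent

__all__ = [
    "PCAModel",
    "VisualSemanticMatrix",
    "NullEnsemble",
    "ConceptRepresentation",
    "fit_pca",
    "fit_visual_semantic",
    "fit_pipeline",
    "build_null_ensemble",
    "test_coefficients",
    "concept_to_features",
    "features_to_semantics",
    "bootstrap_concept_ci",
    "leave_concept_out_matrix",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Centered PCA truncated at a cumulative-explained-variance threshold."""

    mean: np.ndarray
    components: np.ndarray  # k x n, orthonormal rows
    variances: np.ndarray  # k
    whiten: bool
    explained_fraction: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        scores = (np.asarray(x, float) - self.mean) @ self.components.T
        if self.whiten:
            scores = scores / np.sqrt(self.variances)
        return scores

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, float)
        if self.whiten:
            scores = scores * np.sqrt(self.variances)
        return scores @ self.components + self.mean


def fit_pca(
    data: np.ndarray, variance_threshold: float = 0.9, whiten: bool = True
) -> PCAModel:
    """Fit a centered PCA keeping the minimum k with cumvar >= threshold."""
    x = np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    if np.all(x == x[0]):
        raise ValueError("zero total variance")
    full = _SkPCA(n_components=None).fit(x)
    total = full.explained_variance_.sum()
    if total <= 0:
        raise ValueError("zero total variance")
    cum = np.cumsum(full.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, full.components_.shape[0])
    return PCAModel(
        mean=full.mean_,
        components=full.components_[:k],
        variances=full.explained_variance_[:k],
        whiten=whiten,
        explained_fraction=float(cum[k - 1]),
    )


# ---------------------------------------------------------------------------
# visual-semantic matrix

@dataclass
class VisualSemanticMatrix:
    B: np.ndarray  # k_v x k_s
    visual_pca: PCAModel
    semantic_pca: PCAModel
    t: int
    provenance: dict = field(default_factory=dict)

    def save(self, path) -> None:
        np.savez(
            path,
            B=self.B,
            t=self.t,
            v_mean=self.visual_pca.mean,
            v_components=self.visual_pca.components,
            v_variances=self.visual_pca.variances,
            v_whiten=self.visual_pca.whiten,
            v_explained=self.visual_pca.explained_fraction,
            s_mean=self.semantic_pca.mean,
            s_components=self.semantic_pca.components,
            s_variances=self.semantic_pca.variances,
            s_whiten=self.semantic_pca.whiten,
            s_explained=self.semantic_pca.explained_fraction,
        )

    @classmethod
    def load(cls, path) -> "VisualSemanticMatrix":
        with np.load(path) as z:
            vp = PCAModel(
                z["v_mean"], z["v_components"], z["v_variances"],
                bool(z["v_whiten"]), float(z["v_explained"]),
            )
            sp = PCAModel(
                z["s_mean"], z["s_components"], z["s_variances"],
                bool(z["s_whiten"]), float(z["s_explained"]),
            )
            return cls(B=z["B"], visual_pca=vp, semantic_pca=sp, t=int(z["t"]))


@dataclass
class NullEnsemble:
    matrices: np.ndarray  # n_perm x k_v x k_s
    seed: int | None
    mean: np.ndarray = field(init=False)
    sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.matrices.shape[0] < 1:
            raise ValueError("n_perm must be >= 1")
        self.mean = self.matrices.mean(axis=0)
        self.sd = self.matrices.std(axis=0, ddof=1) if self.matrices.shape[0] > 1 \
            else np.zeros_like(self.mean)


@dataclass
class ConceptRepresentation:
    label: str
    features: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)


def fit_visual_semantic(
    visual_scores: np.ndarray, semantic_scores: np.ndarray, **provenance
) -> np.ndarray:
    """B = X^T Y / (t - 1) for aligned trial x PC score matrices."""
    x = np.asarray(visual_scores, float)
    y = np.asarray(semantic_scores, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"row-count mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    return x.T @ y / (x.shape[0] - 1)


def fit_pipeline(
    stimulus_features: np.ndarray,
    trial_vectors: np.ndarray,
    variance_threshold: float = 0.9,
    whiten: bool = True,
    **provenance,
) -> VisualSemanticMatrix:
    """Full fit: both PCAs on the trial data, then the coefficient matrix."""
    feats = np.asarray(stimulus_features, float)
    sems = np.asarray(trial_vectors, float)
    if feats.shape[0] != sems.shape[0]:
        raise ValueError("stimulus features and trial vectors must align")
    vp = fit_pca(feats, variance_threshold, whiten)
    sp = fit_pca(sems, variance_threshold, whiten)
    B = fit_visual_semantic(vp.transform(feats), sp.transform(sems))
    return VisualSemanticMatrix(
        B=B, visual_pca=vp, semantic_pca=sp, t=feats.shape[0],
        provenance=dict(provenance),
    )


def build_null_ensemble(
    visual_scores: np.ndarray,
    semantic_scores: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> NullEnsemble:
    """Null matrices from shuffling semantic rows across trials."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(visual_scores, float)
    y = np.asarray(semantic_scores, float)
    rng = np.random.default_rng(seed)
    t = x.shape[0]
    mats = np.empty((n_perm, x.shape[1], y.shape[1]))
    for i in range(n_perm):
        mats[i] = fit_visual_semantic(x, y[rng.permutation(t)])
    return NullEnsemble(matrices=mats, seed=None if isinstance(seed, np.random.Generator) else seed)


@dataclass
class CoefficientTest:
    z: np.ndarray
    significant: np.ndarray  # boolean mask
    p: np.ndarray
    critical_value: float
    untestable: np.ndarray  # boolean mask of zero-null-sd cells


def test_coefficients(
    B: np.ndarray, ensemble: NullEnsemble, alpha: float = 0.05
) -> CoefficientTest:
    """Two-tailed permutation max-statistic test on every coefficient.

    Each cell is z-scored by its null mean/sd; the per-permutation maximum
    |Z| across the family forms the null; a cell is significant at familywise
    ``alpha`` when its |Z| exceeds the (1 - alpha) quantile of that null.
    P-values floor at 1/(n_perm + 1).
    """
    B = np.asarray(B, float)
    if ensemble.mean.shape != B.shape:
        raise ValueError("ensemble shape does not match B")
    # studentize observed and null matrices with POOLED per-cell mean/sd
    # (observed included): under the null all n_perm + 1 matrices are then
    # exchangeable and the max-statistic test is exact.  Studentizing by the
    # null-only moments lets each null matrix shrink its own z through its
    # contribution to the sd, which inflates the familywise error.
    pooled = np.concatenate([ensemble.matrices, B[None]], axis=0)
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1)
    # a cell whose null distribution is degenerate carries no information
    untestable = (ensemble.sd == 0) | (sd == 0)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (B - mu) / safe_sd
    z[untestable] = np.nan
    null_z = (ensemble.matrices - mu) / safe_sd
    null_z[:, untestable] = 0.0
    null_max = np.max(np.abs(null_z), axis=(1, 2))
    n_perm = null_max.shape[0]
    crit = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
    absz = np.abs(z)
    p = (1.0 + (null_max[:, None, None] >= absz[None]).sum(axis=0)) / (n_perm + 1.0)
    p[untestable] = np.nan
    # exact permutation decision: p <= alpha (the interpolated quantile rule
    # is anti-conservative at small n_perm)
    sig = p <= alpha
    sig[untestable] = False
    return CoefficientTest(z=z, significant=sig, p=p, critical_value=crit,
                           untestable=untestable)


# ---------------------------------------------------------------------------
# projections

def concept_to_features(
    word: str, embedding: EmbeddingModel, matrix: VisualSemanticMatrix
) -> ConceptRepresentation:
    """Channel-space feature vector associated with a concept label."""
    sem = embedding[word]  # raises on out-of-vocabulary
    s = matrix.semantic_pca.transform(sem[None, :])[0]
    u = matrix.B @ s
    feats = matrix.visual_pca.inverse_transform(u[None, :])[0]
    return ConceptRepresentation(label=word, features=feats)


def features_to_semantics(
    features: np.ndarray, matrix: VisualSemanticMatrix
) -> np.ndarray:
    """Semantic vector predicted from channel-space feature values."""
    feats = np.asarray(features, float)
    if feats.shape != matrix.visual_pca.mean.shape:
        raise ValueError(
            f"feature length {feats.shape} != {matrix.visual_pca.mean.shape}"
        )
    u = matrix.visual_pca.transform(feats[None, :])[0]
    s = matrix.B.T @ u
    return matrix.semantic_pca.inverse_transform(s[None, :])[0]


# ---------------------------------------------------------------------------
# resampling analyses

def bootstrap_concept_ci(
    stimulus_features: np.ndarray,
    trial_vectors: np.ndarray,
    word: str,
    embedding: EmbeddingModel,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    refit_pca: bool = True,
    percentiles: tuple[float, float] = (2.5, 97.5),
    variance_threshold: float = 0.9,
) -> ConceptRepresentation:
    """Percentile bootstrap CI on a concept's feature vector.

    Trials are resampled with replacement (visual and semantic rows
    together); by default the full pipeline (both PCAs and B) is refitted per
    resample.  ``refit_pca=False`` is a fast mode that keeps the original
    PCAs and refits only B.  Degenerate resamples (zero variance) are redrawn
    and counted in the provenance.
    """
    feats = np.asarray(stimulus_features, float)
    sems = np.asarray(trial_vectors, float)
    t = feats.shape[0]
    if t < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    base = fit_pipeline(feats, sems, variance_threshold)
    point = concept_to_features(word, embedding, base)
    boots = np.empty((n_boot, feats.shape[1]))
    redraws = 0
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, t, size=t)
            try:
                if refit_pca:
                    m = fit_pipeline(feats[idx], sems[idx], variance_threshold)
                else:
                    B = fit_visual_semantic(
                        base.visual_pca.transform(feats[idx]),
                        base.semantic_pca.transform(sems[idx]),
                    )
                    m = VisualSemanticMatrix(
                        B=B, visual_pca=base.visual_pca,
                        semantic_pca=base.semantic_pca, t=t,
                    )
                break
            except ValueError:
                redraws += 1  # degenerate resample; redraw
        boots[i] = concept_to_features(word, embedding, m).features
    lo = np.percentile(boots, percentiles[0], axis=0)
    hi = np.percentile(boots, percentiles[1], axis=0)
    return ConceptRepresentation(
        label=word, features=point.features, ci_lower=lo, ci_upper=hi,
        provenance={"n_boot": n_boot, "redraws": redraws, "refit_pca": refit_pca},
    )


def leave_concept_out_matrix(
    stimulus_features: np.ndarray,
    word_lists: list[list[str]],
    word: str,
    embedding: EmbeddingModel,
    variance_threshold: float = 0.9,
) -> VisualSemanticMatrix:
    """Refit the matrix ignoring responses containing the concept's name.

    Individual response words equal to the concept (or its singular/plural
    form) are removed; a trial is dropped only when no valid word remains.
    """
    feats = np.asarray(stimulus_features, float)
    if feats.shape[0] != len(word_lists):
        raise ValueError("features and word lists must align")
    kept_rows, kept_sems = [], []
    for i, words in enumerate(word_lists):
        remaining = [
            w for w in words if not singular_plural_equivalent(w, word, embedding)
        ]
        if remaining:
            kept_rows.append(i)
            kept_sems.append(embed_trial(remaining, embedding))
    if len(kept_rows) < 2:
        raise ValueError("fewer than 2 usable trials remain after removal")
    return fit_pipeline(
        feats[kept_rows], np.asarray(kept_sems), variance_threshold,
        left_out=word,
    )
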