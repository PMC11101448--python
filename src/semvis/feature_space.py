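"""Statistical model of a feature extractor's channel space.

Channel-mean activations collected over an image corpus are standardized,
their correlation structure is estimated with analytic shrinkage toward the
diagonal, and a symmetric (ZCA / Mahalanobis) whitening transform is derived.
Per-feature Gaussian kernel densities fitted in the whitened space provide the
sampling distribution for pseudo-random target feature vectors: independent
draws per whitened feature are "colored" (inverse whitening) and
unstandardized back to the channel space.

Because columns are standardized before covariance estimation, the shrinkage
target (the covariance's own diagonal) coincides with the identity matrix, so
the Ledoit-Wolf analytic intensity applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.covariance import LedoitWolf

__all__ = ["FeatureSpaceModel", "fit_feature_space", "sample_target_features"]


def _zca_transforms(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric inverse square root (whitening) and square root (coloring)."""
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise np.linalg.LinAlgError("shrunk covariance is not positive definite")
    whiten = (evecs * (evals**-0.5)) @ evecs.T
    color = (evecs * (evals**0.5)) @ evecs.T
    return whiten, color


def _scott_bandwidth(data: np.ndarray) -> float:
    # Scott's rule for a 1-D Gaussian KDE: sd * n^(-1/5), as in scipy.
    return float(np.std(data, ddof=1) * data.shape[0] ** (-1.0 / 5.0))


@dataclass
class FeatureSpaceModel:
    """Fitted channel-space model: standardization + ZCA + per-feature KDEs.

    The kernel density of whitened feature j is the equally weighted mixture
    of Gaussians centered on ``kde_points[j]`` with scale ``kde_bandwidths[j]``.
    """

    mean: np.ndarray
    std: np.ndarray
    covariance: np.ndarray  # shrunk covariance of the standardized features
    whitening: np.ndarray
    coloring: np.ndarray
    shrinkage: float
    kde_points: np.ndarray  # v x t
    kde_bandwidths: np.ndarray  # v

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]

    def whiten(self, activations: np.ndarray) -> np.ndarray:
        """Standardize and whiten raw channel activations (rows = samples)."""
        z = (np.asarray(activations, dtype=float) - self.mean) / self.std
        return z @ self.whitening.T

    def color(self, whitened: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`whiten`: color and unstandardize."""
        z = np.asarray(whitened, dtype=float) @ self.coloring.T
        return z * self.std + self.mean

    def density(self, j: int) -> stats.gaussian_kde:
        """The fitted kernel density of whitened feature j as a scipy KDE."""
        pts = self.kde_points[j]
        factor = self.kde_bandwidths[j] / max(np.std(pts, ddof=1), 1e-300)
        return stats.gaussian_kde(pts, bw_method=factor)

    def density_cdf(self, j: int, x: np.ndarray) -> np.ndarray:
        """CDF of the fitted kernel density of whitened feature j."""
        pts = self.kde_points[j]
        bw = self.kde_bandwidths[j]
        if bw == 0:
            return np.mean(np.asarray(x)[..., None] >= pts, axis=-1)
        return stats.norm.cdf((np.asarray(x)[..., None] - pts) / bw).mean(axis=-1)

    def save(self, path) -> None:
        np.savez(
            path,
            mean=self.mean,
            std=self.std,
            covariance=self.covariance,
            shrinkage=self.shrinkage,
            kde_points=self.kde_points,
            kde_bandwidths=self.kde_bandwidths,
        )

    @classmethod
    def load(cls, path) -> "FeatureSpaceModel":
        with np.load(path) as z:
            cov = z["covariance"]
            whiten, color = _zca_transforms(cov)
            return cls(
                mean=z["mean"],
                std=z["std"],
                covariance=cov,
                whitening=whiten,
                coloring=color,
                shrinkage=float(z["shrinkage"]),
                kde_points=z["kde_points"],
                kde_bandwidths=z["kde_bandwidths"],
            )


def fit_feature_space(
    activations: np.ndarray,
    shrinkage: float | None = None,
    bandwidth: float | None = None,
) -> FeatureSpaceModel:
    """Fit the channel-space model on a t x v activation table.

    Parameters
    ----------
    activations
        One row per corpus image, one column per channel.
    shrinkage
        Optional override of the analytic (Ledoit-Wolf) shrinkage intensity
        toward the diagonal target, in [0, 1].
    bandwidth
        Optional KDE bandwidth override (absolute scale, same for all
        whitened features); default is Scott's rule per feature.
    """
    x = np.asarray(activations, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    if np.any(std <= 0):
        bad = np.flatnonzero(std <= 0)
        raise ValueError(f"constant column(s) at indices {bad.tolist()}")
    z = (x - mean) / std

    if shrinkage is None:
        lw = LedoitWolf(assume_centered=False).fit(z)
        cov, intensity = lw.covariance_, float(lw.shrinkage_)
    else:
        if not 0.0 <= shrinkage <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")
        emp = np.cov(z, rowvar=False, ddof=0)
        target = np.diag(np.diag(emp))
        cov, intensity = (1 - shrinkage) * emp + shrinkage * target, shrinkage
    cov = (cov + cov.T) / 2.0  # symmetrize against round-off

    whiten, color = _zca_transforms(cov)
    white = z @ whiten.T
    if bandwidth is None:
        bws = np.array([_scott_bandwidth(white[:, j]) for j in range(x.shape[1])])
    else:
        if bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")
        bws = np.full(x.shape[1], float(bandwidth))
    return FeatureSpaceModel(
        mean=mean,
        std=std,
        covariance=cov,
        whitening=whiten,
        coloring=color,
        shrinkage=intensity,
        kde_points=np.ascontiguousarray(white.T),
        kde_bandwidths=bws,
    )


def sample_target_features(
    model: FeatureSpaceModel, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw n pseudo-random target feature vectors (n x v, channel space).

    Each whitened feature is sampled independently from its fitted kernel
    density (a uniformly chosen training point plus Gaussian noise at the
    bandwidth scale), then colored and unstandardized.  Draws are reproducible
    given ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty((0, model.n_features))
    rng = np.random.default_rng(seed)
    white = np.empty((n, model.n_features))
    for j in range(model.n_features):
        data = model.kde_points[j]
        idx = rng.integers(0, data.shape[0], size=n)
        white[:, j] = data[idx] + rng.standard_normal(n) * model.kde_bandwidths[j]
    return model.color(white)
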