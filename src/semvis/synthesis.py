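"""Image synthesis by first-order optimization in a Fourier parameterization.

Images are parameterized by complex 2-D Fourier coefficients per color
channel.  Rendering applies, in order: frequency-dependent (1/f) scaling,
inverse Fourier transform, color decorrelation by a 3 x 3 matrix, and a
smooth sigmoid map into the [0, 1] display range.  Every stage is linear
except the final sigmoid, and the whole pipeline carries an analytic
vector-Jacobian product, so gradients of any scalar feature objective flow
back to the coefficients without an autodiff framework.

Two objectives are supported:

* ``mse`` — match a target feature vector (stimulus synthesis);
* ``caricature`` — maximize ``<y, phi> * (<y, phi> / (|y| |phi|))**alpha``,
  pushing features along a target direction while the cosine term keeps the
  direction close (concept reconstruction and PC visualization).  During
  caricature optimization the rendered image is subjected to a small random
  rotation/translation/homothecy each iteration before feature extraction
  (transformation robustness), which suppresses high-frequency artifacts.

Optimization uses Adam with decoupled weight decay on the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .extractors import FeatureExtractor

__all__ = [
    "FourierImageParam",
    "SynthesisConfig",
    "SynthesisResult",
    "init_fourier_params",
    "render_image",
    "render_preimage",
    "caricature_objective",
    "synthesize_stimulus",
    "reconstruct_image",
    "visualize_pc",
]


# ---------------------------------------------------------------------------
# parameterization and rendering

@dataclass
class FourierImageParam:
    """Complex Fourier coefficients, shape (3, size, size)."""

    coeffs: np.ndarray
    scale: float = 0.01

    @property
    def size(self) -> int:
        return self.coeffs.shape[-1]


@dataclass
class SynthesisConfig:
    """Optimization settings; defaults follow the published procedure."""

    iterations: int = 1500
    learning_rate: float = 0.05
    weight_decay: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    alpha: float = 4.0  # caricature exponent
    objective: str = "mse"  # or "caricature"
    image_size: int = 224
    init_scale: float = 0.01
    seed: int | None = None
    # transformation-robustness ranges (caricature only)
    use_robustness: bool = True
    max_rotation_deg: float = 5.0
    max_translation_px: float = 4.0
    scale_range: tuple[float, float] = (0.95, 1.05)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.objective not in ("mse", "caricature"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class SynthesisResult:
    image: np.ndarray  # H x W x 3 in [0, 1]
    achieved: np.ndarray  # feature vector of the final image
    trace: np.ndarray  # objective per iteration
    r_squared: float
    params: FourierImageParam = field(repr=False)


def init_fourier_params(
    size: int, seed: int | np.random.Generator | None = None, scale: float = 0.01
) -> FourierImageParam:
    """Seeded complex Gaussian coefficients (sd = ``scale`` per component)."""
    if size <= 0:
        raise ValueError("size must be > 0")
    rng = np.random.default_rng(seed)
    re = rng.normal(0.0, 1.0, size=(3, size, size)) * scale
    im = rng.normal(0.0, 1.0, size=(3, size, size)) * scale
    return FourierImageParam(coeffs=re + 1j * im, scale=scale)


def _freq_scale(size: int) -> np.ndarray:
    """1/f scaling per 2-D frequency; DC uses the minimum nonzero frequency."""
    fx = np.fft.fftfreq(size)[:, None]
    fy = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    f_min = 1.0 / size
    return 1.0 / np.maximum(f, f_min)


DEFAULT_COLOR_MATRIX = np.eye(3)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def render_image(
    params: FourierImageParam, color_matrix: np.ndarray | None = None
) -> np.ndarray:
    """Render an H x W x 3 image in [0, 1] from Fourier coefficients."""
    img, _ = _render_with_cache(params, color_matrix)
    return img


def render_preimage(
    params: FourierImageParam, color_matrix: np.ndarray | None = None
) -> np.ndarray:
    """The image before the display-range map (linear in the coefficients)."""
    _, cache = _render_with_cache(params, color_matrix)
    return cache["decor"]


def _render_with_cache(
    params: FourierImageParam, color_matrix: np.ndarray | None
) -> tuple[np.ndarray, dict]:
    L = DEFAULT_COLOR_MATRIX if color_matrix is None else np.asarray(color_matrix, float)
    if L.shape != (3, 3):
        raise ValueError("color decorrelation matrix must be 3 x 3")
    size = params.size
    fscale = _freq_scale(size)
    spatial = np.fft.ifft2(params.coeffs * fscale, axes=(-2, -1))
    # ifft2 of an unconstrained spectrum has an imaginary part; only the real
    # part is rendered, and the backward pass accounts for that exactly
    pre = np.moveaxis(spatial.real, 0, -1)  # H x W x 3
    decor = pre @ L.T
    img = _sigmoid(decor)
    cache = {"fscale": fscale, "L": L, "decor": decor, "img": img}
    return img, cache


def _render_vjp(g_img: np.ndarray, cache: dict, size: int) -> np.ndarray:
    """Backpropagate an image-space gradient to complex coefficients."""
    sig = cache["img"]
    g_decor = g_img * sig * (1.0 - sig)
    g_pre = g_decor @ cache["L"]
    g_spatial = np.moveaxis(g_pre, -1, 0)  # 3 x H x W
    # adjoint of real(ifft2(.)): fft2(.) / N, then the frequency scaling
    g_coeffs = np.fft.fft2(g_spatial, axes=(-2, -1)) / (size * size)
    return g_coeffs * cache["fscale"]


# ---------------------------------------------------------------------------
# robustness transform (linear in pixels -> exact sparse adjoint)

def _affine_matrix(
    size: int, angle_deg: float, tx: float, ty: float, zoom: float
) -> sparse.csr_matrix:
    """Bilinear-interpolation matrix of a rotation/translation/homothecy.

    Output pixel (r, c) samples the input at the inverse-transformed
    location; coordinates are clamped to the image (edge padding).
    """
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    center = (size - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    r0, c0 = rr.ravel() - center, cc.ravel() - center
    # inverse map: undo translation, rotation, zoom
    src_r = (cos_t * (r0 - ty) + sin_t * (c0 - tx)) / zoom + center
    src_c = (-sin_t * (r0 - ty) + cos_t * (c0 - tx)) / zoom + center
    src_r = np.clip(src_r, 0, size - 1)
    src_c = np.clip(src_c, 0, size - 1)
    r_lo = np.floor(src_r).astype(int)
    c_lo = np.floor(src_c).astype(int)
    r_hi = np.minimum(r_lo + 1, size - 1)
    c_hi = np.minimum(c_lo + 1, size - 1)
    wr = src_r - r_lo
    wc = src_c - c_lo
    n = size * size
    rows = np.repeat(np.arange(n), 4)
    cols = np.stack(
        [r_lo * size + c_lo, r_lo * size + c_hi, r_hi * size + c_lo, r_hi * size + c_hi],
        axis=1,
    ).ravel()
    weights = np.stack(
        [(1 - wr) * (1 - wc), (1 - wr) * wc, wr * (1 - wc), wr * wc], axis=1
    ).ravel()
    return sparse.csr_matrix((weights, (rows, cols)), shape=(n, n))


def _sample_transform(rng: np.random.Generator, config: SynthesisConfig, size: int):
    angle = rng.uniform(-config.max_rotation_deg, config.max_rotation_deg)
    tx = rng.uniform(-config.max_translation_px, config.max_translation_px)
    ty = rng.uniform(-config.max_translation_px, config.max_translation_px)
    zoom = rng.uniform(*config.scale_range)
    return _affine_matrix(size, angle, tx, ty, zoom)


def _apply_transform(mat: sparse.csr_matrix, img: np.ndarray) -> np.ndarray:
    size = img.shape[0]
    flat = img.reshape(size * size, 3)
    return (mat @ flat).reshape(size, size, 3)


def _transform_vjp(mat: sparse.csr_matrix, g: np.ndarray) -> np.ndarray:
    size = g.shape[0]
    flat = g.reshape(size * size, 3)
    return (mat.T @ flat).reshape(size, size, 3)


# ---------------------------------------------------------------------------
# objectives

def caricature_objective(y: np.ndarray, phi: np.ndarray, alpha: float) -> float:
    """``<y, phi> * (<y, phi> / (|y| |phi|))**alpha``.

    Positively homogeneous of degree 1 in each argument.  For non-integer
    ``alpha`` the cosine must be positive (a negative base under a fractional
    power is undefined); integer ``alpha`` (the default regime, alpha = 4)
    has no such restriction.
    """
    y = np.asarray(y, float)
    phi = np.asarray(phi, float)
    if y.shape != phi.shape:
        raise ValueError("y and phi must have equal length")
    ny, nphi = np.linalg.norm(y), np.linalg.norm(phi)
    if ny == 0 or nphi == 0:
        raise ValueError("zero-norm input")
    dot = float(y @ phi)
    cos = dot / (ny * nphi)
    if alpha == int(alpha):
        cos_pow = cos ** int(alpha)
    else:
        if cos <= 0:
            raise ValueError("non-integer alpha requires positive cosine")
        cos_pow = cos**alpha
    return dot * cos_pow


def _caricature_grad(y: np.ndarray, phi: np.ndarray, alpha: float) -> np.ndarray:
    """Gradient of the caricature objective with respect to ``phi``.

    d/dphi [ D^(a+1) |y|^-a |phi|^-a ]
      = (a+1) D^a |y|^-a |phi|^-a y  -  a D^(a+1) |y|^-a |phi|^-(a+2) phi
    with D = <y, phi>.
    """
    ny, nphi = np.linalg.norm(y), np.linalg.norm(phi)
    dot = float(y @ phi)
    a = alpha
    k = ny ** (-a) * nphi ** (-a)
    if a == int(a):
        d_a = dot ** int(a)
    else:
        d_a = dot**a
    return (a + 1) * d_a * k * y - a * d_a * dot * k / nphi**2 * phi


# ---------------------------------------------------------------------------
# optimization driver

class _AdamW:
    """Adam with decoupled weight decay on a complex coefficient array."""

    def __init__(self, shape, lr, wd, beta1, beta2, eps=1e-8):
        self.lr, self.wd = lr, wd
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = np.zeros(shape + (2,))
        self.v = np.zeros(shape + (2,))
        self.t = 0

    def step(self, coeffs: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        g = np.stack([grad.real, grad.imag], axis=-1)
        p = np.stack([coeffs.real, coeffs.imag], axis=-1)
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g**2
        m_hat = self.m / (1 - self.b1**self.t)
        v_hat = self.v / (1 - self.b2**self.t)
        p = p - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.wd * p)
        return p[..., 0] + 1j * p[..., 1]


def _optimize(
    target: np.ndarray,
    extractor: FeatureExtractor,
    config: SynthesisConfig,
    color_matrix: np.ndarray | None,
    layers: list[str] | None,
) -> SynthesisResult:
    target = np.asarray(target, float)
    rng = np.random.default_rng(config.seed)
    params = init_fourier_params(config.image_size, rng, config.init_scale)
    opt = _AdamW(
        params.coeffs.shape,
        config.learning_rate,
        config.weight_decay,
        config.beta1,
        config.beta2,
    )
    caricature = config.objective == "caricature"
    robust = caricature and config.use_robustness
    trace = np.empty(config.iterations)
    v = target.shape[0]

    for it in range(config.iterations):
        img, cache = _render_with_cache(params, color_matrix)
        if robust:
            mat = _sample_transform(rng, config, config.image_size)
            fed = _apply_transform(mat, img)
        else:
            fed = img
        phi = extractor.features(fed, layers)
        if caricature:
            obj = caricature_objective(target, phi, config.alpha)
            g_phi = -_caricature_grad(target, phi, config.alpha)  # ascent
        else:
            obj = float(np.mean((phi - target) ** 2))
            g_phi = 2.0 * (phi - target) / v
        if not np.isfinite(obj):
            raise RuntimeError(
                f"objective diverged (non-finite) at iteration {it}; "
                f"|phi| = {np.linalg.norm(phi):.3g}"
            )
        trace[it] = obj
        g_img = extractor.vjp(fed, g_phi, layers)
        if robust:
            g_img = _transform_vjp(mat, g_img)
        g_coeffs = _render_vjp(g_img, cache, config.image_size)
        params.coeffs = opt.step(params.coeffs, g_coeffs)

    final_img = render_image(params, color_matrix)
    achieved = extractor.features(final_img, layers)
    ss_res = float(np.sum((achieved - target) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return SynthesisResult(
        image=final_img, achieved=achieved, trace=trace, r_squared=r2, params=params
    )


def synthesize_stimulus(
    target: np.ndarray,
    extractor: FeatureExtractor,
    config: SynthesisConfig | None = None,
    color_matrix: np.ndarray | None = None,
    layers: list[str] | None = None,
) -> SynthesisResult:
    """Optimize an image whose feature values match ``target`` (MSE loss)."""
    config = config or SynthesisConfig()
    if config.objective != "mse":
        raise ValueError("synthesize_stimulus requires objective='mse'")
    _check_target(target, extractor, layers)
    return _optimize(target, extractor, config, color_matrix, layers)


def reconstruct_image(
    direction: np.ndarray,
    extractor: FeatureExtractor,
    config: SynthesisConfig | None = None,
    color_matrix: np.ndarray | None = None,
    layers: list[str] | None = None,
) -> SynthesisResult:
    """Maximize the caricature objective along ``direction``.

    A random small rotation/translation/homothecy is applied to the rendered
    image before feature extraction on every iteration (seeded).
    """
    if config is None:
        config = SynthesisConfig(objective="caricature", iterations=2000)
    if config.objective != "caricature":
        raise ValueError("reconstruct_image requires objective='caricature'")
    _check_target(direction, extractor, layers)
    if np.linalg.norm(direction) == 0:
        raise ValueError("direction must have nonzero norm")
    return _optimize(direction, extractor, config, color_matrix, layers)


def visualize_pc(
    pc_index: int,
    pca,
    extractor: FeatureExtractor,
    config: SynthesisConfig | None = None,
    color_matrix: np.ndarray | None = None,
    negative: bool = False,
) -> SynthesisResult:
    """Caricature of a principal component's loading direction.

    ``pca`` is a fitted :class:`semvis.mapping.PCAModel`; the PC's unit
    loading vector in channel space is handed to :func:`reconstruct_image`.
    """
    if not 0 <= pc_index < pca.n_components:
        raise IndexError(f"pc_index {pc_index} out of range ({pca.n_components})")
    direction = pca.components[pc_index].copy()
    if negative:
        direction = -direction
    return reconstruct_image(direction, extractor, config, color_matrix)


def _check_target(target, extractor, layers):
    target = np.asarray(target)
    expect = sum(
        extractor.layer_channels[lay]
        for lay in (layers or [extractor.sampled_layer])
    )
    if target.shape != (expect,):
        raise ValueError(f"target length {target.shape} != {expect} channels")
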