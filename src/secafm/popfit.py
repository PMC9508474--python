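"""Population models for particle height/volume samples.

AFM protrusion heights and volumes are strictly positive and right-skewed,
so subpopulations are modelled as a finite mixture of gamma densities

    f(x) = sum_k w_k * Gamma(x; alpha_k, theta_k),

fitted by expectation-maximisation, with the number of components chosen
by the Bayesian information criterion BIC = p*ln(n) - 2*lnL (minimised),
p = 3K - 1 free parameters (K shapes, K scales, K-1 weights).  Smoothed
empirical densities use an Epanechnikov kernel normalised to unit area.

Heights are fitted in Å; volumes should be rescaled to ~O(1-100) units
(e.g. 1e6 Å³) before fitting so the digamma/Newton shape solver stays in
a well-conditioned range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, polygamma
from sklearn.neighbors import KernelDensity

__all__ = [
    "GammaMixture",
    "Density",
    "kde_density",
    "fit_gamma_mixture_em",
    "select_components_bic",
    "mixture_peaks",
    "summed_density",
]

# Gaussian -> Epanechnikov canonical-bandwidth conversion:
# delta_0 = (R(K)/mu2(K)^2)^(1/5); 15^(1/5) / (1/(2 sqrt(pi)))^(1/5).
_EPA_OVER_GAUSS = 15.0 ** 0.2 / (1.0 / (2.0 * np.sqrt(np.pi))) ** 0.2  # ~2.2138


@dataclass
class GammaMixture:
    """A weighted gamma mixture, optionally carrying its fit statistics.

    ``weights`` must sum to 1; ``shapes`` (alpha) and ``scales`` (theta)
    are per-component and strictly positive.  The component mode, used as
    the reported "peak", is (alpha-1)*theta for alpha > 1 and 0 otherwise.
    """

    weights: np.ndarray
    shapes: np.ndarray
    scales: np.ndarray
    log_likelihood: float | None = None
    bic: float | None = None
    n: int | None = None
    collapsed: bool = False
    bic_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        self.shapes = np.atleast_1d(np.asarray(self.shapes, float))
        self.scales = np.atleast_1d(np.asarray(self.scales, float))
        if not (len(self.weights) == len(self.shapes) == len(self.scales)):
            raise ValueError("component arrays must share one length")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.shapes <= 0) or np.any(self.scales <= 0):
            raise ValueError("gamma shapes and scales must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @classmethod
    def from_modes(
        cls,
        modes: np.ndarray,
        weights: np.ndarray,
        shape: float | np.ndarray = 25.0,
    ) -> "GammaMixture":
        """Build a mixture from target component modes.

        The mode of Gamma(alpha, theta) is (alpha-1)*theta, so
        theta = mode / (alpha - 1).  ``shape`` (> 1) sets the relative
        width of each component: sd/mode = sqrt(alpha)/(alpha-1).  The
        default (25, i.e. SD ~ 21% of the mode) keeps neighbouring
        conformational-state modes separated by at least ~2 component
        SDs, the regime in which subpopulations are identifiable at all.
        """
        modes = np.atleast_1d(np.asarray(modes, float))
        shapes = np.broadcast_to(np.asarray(shape, float), modes.shape).copy()
        if np.any(shapes <= 1):
            raise ValueError("shape must exceed 1 for a positive mode")
        return cls(np.asarray(weights, float), shapes, modes / (shapes - 1.0))

    def component_logpdf(self, x: np.ndarray) -> np.ndarray:
        """log pdf of each component at x; shape (len(x), K)."""
        x = np.asarray(x, float)[:, None]
        a = self.shapes[None, :]
        th = self.scales[None, :]
        return (a - 1.0) * np.log(x) - x / th - a * np.log(th) - gammaln(a)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return logsumexp(
            self.component_logpdf(x) + np.log(self.weights)[None, :], axis=1
        )

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def means(self) -> np.ndarray:
        return self.shapes * self.scales

    def modes(self) -> np.ndarray:
        return np.where(self.shapes > 1.0, (self.shapes - 1.0) * self.scales, 0.0)


@dataclass
class Density:
    """A smoothed probability density on a uniform grid (unit area)."""

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float
    kernel: str = "epanechnikov"

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


def silverman_bandwidth(samples: np.ndarray, kernel: str = "epanechnikov") -> float:
    """Silverman's rule of thumb, rescaled to the Epanechnikov kernel."""
    samples = np.asarray(samples, float)
    n = samples.size
    sd = samples.std(ddof=1)
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = max(abs(samples[0]), 1.0) * 0.01
    h = 0.9 * spread * n ** (-1.0 / 5.0)
    if kernel == "epanechnikov":
        h *= _EPA_OVER_GAUSS
    return float(h)


def kde_density(
    samples: np.ndarray,
    bandwidth: float | str = "auto",
    grid_points: int = 512,
) -> Density:
    """Epanechnikov kernel density estimate on [0, max + 3h].

    The estimate is renormalised to unit trapezoid area (mass smoothed
    below 0 by the kernel is folded back by the renormalisation).
    """
    samples = np.asarray(samples, float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples for a density estimate")
    if bandwidth == "auto":
        h = silverman_bandwidth(samples)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(0.0, samples.max() + 3.0 * h, grid_points)
    kde = KernelDensity(kernel="epanechnikov", bandwidth=h)
    kde.fit(samples[:, None])
    values = np.exp(kde.score_samples(grid[:, None]))
    area = np.trapezoid(values, grid)
    if area <= 0:
        raise ValueError("degenerate density (zero area)")
    return Density(grid, values / area, h)


def _weighted_gamma_mle(
    x: np.ndarray, logx: np.ndarray, resp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component MLE of (shape, scale) under responsibilities.

    ``resp`` has shape (n, K).  Solves ln(alpha) - digamma(alpha) =
    ln(mean) - mean(ln x) by Newton iteration (vectorised over
    components) from Minka's closed-form starting point; the scale
    follows as mean/alpha.
    """
    w = resp.sum(axis=0)
    m = (x @ resp) / w
    ml = (logx @ resp) / w
    s = np.maximum(np.log(m) - ml, 1e-12)  # s -> 0 for degenerate data
    alpha = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(25):
        f = np.log(alpha) - digamma(alpha) - s
        fp = 1.0 / alpha - polygamma(1, alpha)
        new = alpha - f / fp
        new = np.where(new <= 0, alpha / 2.0, new)
        if np.all(np.abs(new - alpha) < 1e-12 * alpha):
            alpha = new
            break
        alpha = new
    alpha = np.clip(alpha, 1e-3, 1e6)
    return alpha, m / alpha


def _quantile_init(
    x_sorted: np.ndarray, K: int, rng: np.random.Generator, jitter: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Initial parameters from K contiguous quantile blocks (optionally
    with randomly perturbed block boundaries)."""
    n = x_sorted.size
    edges = np.linspace(0, n, K + 1)
    if jitter and K > 1:
        edges[1:-1] += rng.uniform(-0.5, 0.5, K - 1) * (n / K) * 0.8
        edges = np.sort(edges)
    idx = np.clip(edges.round().astype(int), 0, n)
    w, a, th = np.empty(K), np.empty(K), np.empty(K)
    for k in range(K):
        lo, hi = idx[k], max(idx[k + 1], idx[k] + 2)
        hi = min(hi, n)
        lo = min(lo, hi - 2) if hi >= 2 else 0
        blk = x_sorted[lo:hi]
        m, v = blk.mean(), blk.var() + 1e-12
        a[k] = np.clip(m * m / v, 0.1, 1e4)
        th[k] = m / a[k]
        w[k] = (hi - lo) / n
    w /= w.sum()
    return w, a, th


def _em_once(
    x: np.ndarray,
    logx: np.ndarray,
    w: np.ndarray,
    a: np.ndarray,
    th: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One EM run; returns parameters and final log-likelihood.

    The log-likelihood is asserted non-decreasing every iteration (up to
    a small numerical slack).
    """
    n = x.size
    prev = -np.inf
    for _ in range(max_iter):
        logp = (
            (a - 1.0)[None, :] * logx[:, None]
            - x[:, None] / th[None, :]
            - (a * np.log(th) + gammaln(a))[None, :]
            + np.log(w)[None, :]
        )
        norm = logsumexp(logp, axis=1)
        lnL = float(norm.sum())
        if not lnL >= prev - 1e-7 * max(1.0, abs(prev)):
            raise AssertionError("EM log-likelihood decreased")
        if lnL - prev < tol * max(1.0, abs(lnL)):
            prev = lnL
            break
        prev = lnL
        resp = np.exp(logp - norm[:, None])
        w = resp.sum(axis=0) / n
        w = np.clip(w, 1e-300, None)
        w /= w.sum()
        a, th = _weighted_gamma_mle(x, logx, resp)
    return w, a, th, prev


def fit_gamma_mixture_em(
    samples: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GammaMixture:
    """Fit a K-component gamma mixture by EM.

    Runs ``n_restarts`` EM fits from quantile-split initialisations and
    keeps the best log-likelihood.  A component whose weight collapses
    below 1e-4 is dropped and the fit is redone with K-1 components
    (``collapsed`` flag set on the result).
    """
    x = np.asarray(samples, float)
    if np.any(x <= 0):
        raise ValueError("gamma mixtures require strictly positive samples")
    if K < 1:
        raise ValueError("K must be >= 1")
    if x.size < 10 * K:
        raise ValueError(f"need at least {10 * K} samples for K={K}")
    rng = np.random.default_rng(seed)
    logx = np.log(x)
    x_sorted = np.sort(x)

    # short-run prescreen of all restarts, then full convergence from the
    # best start (the usual emEM economy; the polished run re-asserts
    # log-likelihood monotonicity throughout)
    screen_iter = min(60, max_iter)
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for r in range(n_restarts):
        w0, a0, th0 = _quantile_init(x_sorted, K, rng, jitter=(r > 0))
        try:
            w, a, th, lnL = _em_once(
                x, logx, w0.copy(), a0.copy(), th0.copy(), screen_iter, tol
            )
        except (FloatingPointError, AssertionError):  # pragma: no cover
            continue
        if best is None or lnL > best[0]:
            best = (lnL, w, a, th)
    if best is None:
        raise RuntimeError("all EM restarts failed")
    _, w, a, th = best
    w, a, th, lnL = _em_once(x, logx, w, a, th, max_iter, tol)

    if K > 1 and np.any(w < 1e-4):
        warnings.warn(f"component collapse at K={K}; refitting with K={K - 1}")
        sub = fit_gamma_mixture_em(
            samples, K - 1, seed=seed, n_restarts=n_restarts,
            max_iter=max_iter, tol=tol,
        )
        sub.collapsed = True
        return sub

    order = np.argsort(a * th)  # sort components by mean
    n = x.size
    p = 3 * K - 1
    return GammaMixture(
        weights=w[order],
        shapes=a[order],
        scales=th[order],
        log_likelihood=lnL,
        bic=p * np.log(n) - 2.0 * lnL,
        n=n,
    )


def select_components_bic(
    samples: np.ndarray,
    K_max: int = 6,
    seed: int = 0,
    n_restarts: int = 10,
) -> GammaMixture:
    """Fit K = 1..K_max gamma mixtures and return the minimum-BIC model.

    Ties (within 1e-9) break toward smaller K.  The BIC of every
    candidate is recorded on the returned model (``bic_by_k``).
    """
    best: GammaMixture | None = None
    bic_by_k: dict[int, float] = {}
    for K in range(1, K_max + 1):
        try:
            fit = fit_gamma_mixture_em(samples, K, seed=seed, n_restarts=n_restarts)
        except ValueError:
            break  # not enough samples for this K
        bic_by_k[K] = fit.bic
        if best is None or fit.bic < best.bic - 1e-9:
            best = fit
    assert best is not None
    best.bic_by_k = bic_by_k
    return best


def mixture_peaks(model: GammaMixture) -> list[tuple[float, float]]:
    """(peak position, weight) per component, sorted by peak position.

    The peak is the gamma mode (alpha-1)*theta for alpha > 1, else 0
    (density maximal at the origin).
    """
    peaks = model.modes()
    order = np.argsort(peaks)
    return [(float(peaks[i]), float(model.weights[i])) for i in order]


def summed_density(d1: Density, d2: Density, w1: float) -> Density:
    """Pointwise weighted sum w1*d1 + (1-w1)*d2 on a common grid.

    Used to compare a co-assembled sample's distribution against the
    normalised summation of the isolated samples' distributions.  When
    the grids differ the densities are linearly resampled (zero outside
    their support) with a warning.
    """
    if not 0.0 <= w1 <= 1.0:
        raise ValueError("w1 must be a fraction in [0, 1]")
    if d1.grid.shape == d2.grid.shape and np.allclose(d1.grid, d2.grid):
        grid = d1.grid
        v1, v2 = d1.values, d2.values
    else:
        warnings.warn("density grids differ; resampling to a common grid")
        lo = min(d1.grid[0], d2.grid[0])
        hi = max(d1.grid[-1], d2.grid[-1])
        grid = np.linspace(lo, hi, max(len(d1.grid), len(d2.grid)))
        v1 = np.interp(grid, d1.grid, d1.values, left=0.0, right=0.0)
        v2 = np.interp(grid, d2.grid, d2.values, left=0.0, right=0.0)
    values = w1 * v1 + (1.0 - w1) * v2
    area = np.trapezoid(values, grid)
    return Density(grid, values / area, max(d1.bandwidth, d2.bandwidth), d1.kernel)
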