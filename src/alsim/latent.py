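"""Simulation-based inference of the latent calcium-behavior correlation.

Observed calcium-behavior model R^2 values are attenuated by measurement
noise in both variables.  Assuming latent states X_c, X_b with
corr(X_c, X_b) = r_latent, and noisy readouts X_c', X_b' with
corr(X_c, X_c') = r_c and corr(X_b, X_b') = r_b (set from the test-retest
repeatabilities via r = (R^2)^(1/4), so that corr(X', X'')^2 = R^2), the
observed corr(X_c', X_b') concentrates around r_latent * r_c * r_b at
finite sample size N.  Simulating the forward process on a grid of
r_latent values and inverting yields a posterior over R^2_latent given the
observed model R^2 and the bootstrap uncertainty of the repeatabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import pca_responses

__all__ = [
    "RepeatabilityEstimate",
    "LatentInferenceResult",
    "pca_repeatability",
    "retest_repeatability",
    "simulate_observed_r2",
    "infer_latent",
]


@dataclass
class RepeatabilityEstimate:
    """Point repeatability R^2 plus bootstrap samples, all in [0, 1]."""

    value: float
    bootstrap: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.bootstrap = np.asarray(self.bootstrap, dtype=float)
        samples = np.append(self.bootstrap, self.value)
        if np.any((samples < 0) | (samples > 1)):
            raise ValueError("repeatability R^2 values must lie in [0, 1]")

    @classmethod
    def point_mass(cls, value: float, source: str = "") -> "RepeatabilityEstimate":
        return cls(value=value, bootstrap=np.array([value]), source=source)


@dataclass
class LatentInferenceResult:
    """Posterior over R^2_latent from the grid inversion."""

    grid_r_latent: np.ndarray
    posterior: np.ndarray         # weights over grid points, sum to 1
    median: float                 # median R^2_latent
    ci90: tuple[float, float]     # 5th-95th quantiles of R^2_latent
    observed_r2_samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    def quantile(self, q: float) -> float:
        """Quantile of R^2_latent (r_latent quantile, squared)."""
        cdf = np.cumsum(self.posterior)
        k = int(np.searchsorted(cdf, q))
        k = min(k, len(self.grid_r_latent) - 1)
        return float(self.grid_r_latent[k] ** 2)


def _shuffle_within_rows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = X.copy()
    for i in range(out.shape[0]):
        rng.shuffle(out[i])
    return out


def _signal_variance_fraction(X: np.ndarray, n_shuffles: int, rng: np.random.Generator) -> float:
    """Cumulative variance of leading PCs whose eigenvalue beats the
    rank-matched mean shuffled eigenvalue."""
    pca = pca_responses(X)
    eig = pca.variance_fraction * np.sum(
        np.linalg.svd(X - X.mean(axis=0), compute_uv=False) ** 2
    )
    shuf = np.zeros_like(eig)
    for _ in range(n_shuffles):
        Xs = _shuffle_within_rows(X, rng)
        s = np.linalg.svd(Xs - Xs.mean(axis=0), compute_uv=False) ** 2
        shuf[: len(s)] += s[: len(shuf)]
    shuf /= n_shuffles
    above = eig > shuf
    k = int(np.argmin(above)) if not above.all() else len(above)
    if k == 0:
        return 0.0
    return float(pca.variance_fraction[:k].sum())


def pca_repeatability(
    features: np.ndarray,
    n_shuffles: int = 20,
    n_bootstrap: int = 200,
    seed: int | np.random.Generator = 0,
) -> RepeatabilityEstimate:
    """Repeatability R^2 of a multidimensional measure via PCA vs. shuffle.

    Feature values are permuted independently within each individual (row)
    to build a noise spectrum; R^2 is the summed variance fraction of the
    leading PCs whose eigenvalue exceeds the rank-matched mean shuffled
    eigenvalue.  Bootstrapping individuals yields the uncertainty samples.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    value = _signal_variance_fraction(X, n_shuffles, rng)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        take = rng.integers(0, X.shape[0], size=X.shape[0])
        boot[b] = _signal_variance_fraction(X[take], n_shuffles, rng)
    return RepeatabilityEstimate(value=value, bootstrap=boot, source="calcium-PCA")


def retest_repeatability(
    first: np.ndarray,
    second: np.ndarray,
    n_bootstrap: int = 200,
    seed: int | np.random.Generator = 0,
) -> RepeatabilityEstimate:
    """Test-retest repeatability R^2 of a scalar measure, with bootstrap.

    ``first`` and ``second`` are paired measurements of the same
    individuals (e.g. odor preference scored hours apart); R^2 is the
    squared correlation, bootstrapped over individuals.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of >= 3 paired measurements")
    value = min(_corr(a, b) ** 2, 1.0)
    boot = np.empty(n_bootstrap)
    for k in range(n_bootstrap):
        take = rng.integers(0, len(a), size=len(a))
        if np.std(a[take]) == 0 or np.std(b[take]) == 0:
            boot[k] = 0.0
        else:
            boot[k] = min(_corr(a[take], b[take]) ** 2, 1.0)
    return RepeatabilityEstimate(value=value, bootstrap=boot, source="behavior-retest")


def _mix_to_correlation(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """y = r x + sqrt(1 - r^2) z with z independent standard normal."""
    return r * x + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(x.shape)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def simulate_observed_r2(
    r_latent: float,
    r_c: float,
    r_b: float,
    N: int,
    seed: int | np.random.Generator = 0,
) -> float:
    """One simulated observed calcium-behavior R^2 at sample size N."""
    for name, v in (("r_latent", r_latent), ("r_c", r_c), ("r_b", r_b)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if N < 3:
        raise ValueError("need N >= 3")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x_c = rng.standard_normal(N)
    x_b = _mix_to_correlation(x_c, r_latent, rng)
    x_c_obs = _mix_to_correlation(x_c, r_c, rng)
    x_b_obs = _mix_to_correlation(x_b, r_b, rng)
    return _corr(x_c_obs, x_b_obs) ** 2


def _simulate_r2_batch(
    r_latent: float, r_c: np.ndarray, r_b: np.ndarray, N: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized batch of simulated observed R^2 (one per (r_c, r_b) pair)."""
    m = len(r_c)
    x_c = rng.standard_normal((m, N))
    x_b = r_latent * x_c + np.sqrt(1.0 - r_latent**2) * rng.standard_normal((m, N))
    x_c_obs = r_c[:, None] * x_c + np.sqrt(1.0 - r_c[:, None] ** 2) * rng.standard_normal((m, N))
    x_b_obs = r_b[:, None] * x_b + np.sqrt(1.0 - r_b[:, None] ** 2) * rng.standard_normal((m, N))
    a = x_c_obs - x_c_obs.mean(axis=1, keepdims=True)
    b = x_b_obs - x_b_obs.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a**2, axis=1) * np.sum(b**2, axis=1))
    return (num / den) ** 2


def infer_latent(
    observed_r2: np.ndarray | float,
    calcium: RepeatabilityEstimate,
    behavior: RepeatabilityEstimate,
    N: int = 69,
    grid_step: float = 0.01,
    n_sims: int = 10_000,
    n_bins: int = 50,
    seed: int | np.random.Generator = 0,
) -> LatentInferenceResult:
    """Grid inversion of the forward simulation.

    For each grid value of r_latent (0 to 1 in steps of ``grid_step``) and
    each of ``n_sims`` simulations, (r_c, r_b) are drawn from the bootstrap
    repeatability samples via the quarter-power transform r = (R^2)^(1/4)
    and an observed R^2 is simulated at sample size N.  For each observed
    R^2 draw, the marginal distribution of r_latent values consistent with
    it (equal prior weight per grid point) is accumulated; quantiles of the
    resulting r_latent posterior are squared to give R^2_latent (quantile
    matching P(r_latent <= q) = P(R^2_latent <= q^2)).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs = np.atleast_1d(np.asarray(observed_r2, dtype=float))
    if np.any(obs > 1.0) or np.any(obs < 0.0):
        raise ValueError("observed R^2 must lie in [0, 1]")
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # bootstrap draws of (r_c, r_b), index-cycled across simulations
    rc_pool = np.asarray(calcium.bootstrap, dtype=float) ** 0.25
    rb_pool = np.asarray(behavior.bootstrap, dtype=float) ** 0.25
    rc = rc_pool[np.arange(n_sims) % len(rc_pool)]
    rb = rb_pool[np.arange(n_sims) % len(rb_pool)]

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # hist[g, k]: fraction of simulations at grid point g whose observed R^2
    # fell in bin k
    hist = np.empty((len(grid), n_bins))
    for gi, r in enumerate(grid):
        sims = _simulate_r2_batch(r, rc, rb, N, rng)
        h, _ = np.histogram(np.clip(sims, 0, 1), bins=edges)
        hist[gi] = h / n_sims

    posterior = np.zeros(len(grid))
    bin_of = np.clip(np.searchsorted(edges, obs, side="right") - 1, 0, n_bins - 1)
    for k in bin_of:
        lik = hist[:, k]
        tot = lik.sum()
        if tot > 0:
            posterior += lik / tot
    if posterior.sum() == 0:
        raise ValueError("observed R^2 lies outside the support of every grid simulation")
    posterior /= posterior.sum()

    cdf = np.cumsum(posterior)

    def r_quant(q: float) -> float:
        k = min(int(np.searchsorted(cdf, q)), len(grid) - 1)
        return float(grid[k])

    median = r_quant(0.5) ** 2
    ci90 = (r_quant(0.05) ** 2, r_quant(0.95) ** 2)
    return LatentInferenceResult(
        grid_r_latent=grid,
        posterior=posterior,
        median=median,
        ci90=ci90,
        observed_r2_samples=obs,
    )
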