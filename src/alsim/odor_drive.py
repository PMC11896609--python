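"""ORN odor drive: response matrix -> firing-rate profiles -> spike times.

Odor drive is parameterized by a glomerulus-by-odor response matrix with
entries in [0, 1] (DoOR-style).  An ORN of glomerulus g stimulated with odor
o fires as an inhomogeneous Poisson process at

    FR(t) = FR_max * D[g, o] * (f_a + (1 - f_a) * exp(-t / t_a))

with t the time since odor onset, so the rate adapts from FR_max*D down to
f_a*FR_max*D with timescale t_a.  Off odor (and for D = 0) ORNs fire as a
homogeneous Poisson process at the spontaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DriveParams",
    "StimulusProtocol",
    "impute_missing_responses",
    "odor_firing_rate",
    "sample_orn_spike_times",
    "orn_rate_profiles",
]


@dataclass(frozen=True)
class DriveParams:
    """ORN drive parameters (Hz, ms, pA)."""

    fr_max: float = 400.0          # peak ORN rate at D = 1, odor onset
    f_a: float = 0.75              # adapted fraction of the initial rate
    t_a: float = 110.0             # adaptation timescale, ms
    spontaneous_rate: float = 10.0  # off-odor Poisson rate, Hz
    kick_current: float = 1e6      # current forcing a scheduled ORN spike, pA

    def __post_init__(self) -> None:
        if not (0 < self.f_a <= 1):
            raise ValueError("adapted fraction f_a must lie in (0, 1]")
        if min(self.fr_max, self.t_a, self.spontaneous_rate, self.kick_current) <= 0:
            raise ValueError("rates, timescales and kick current must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered odor panel with on/gap durations (ms)."""

    odors: tuple[str, ...]
    on_duration: float = 400.0
    gap_duration: float = 300.0
    lead_in: float = 300.0

    def __post_init__(self) -> None:
        if min(self.on_duration, self.gap_duration, self.lead_in) < 0:
            raise ValueError("durations must be nonnegative")
        object.__setattr__(self, "odors", tuple(self.odors))

    @property
    def total_duration(self) -> float:
        n = len(self.odors)
        if n == 0:
            return self.lead_in
        return self.lead_in + n * self.on_duration + (n - 1) * self.gap_duration

    def odor_windows(self) -> list[tuple[str, float, float]]:
        """(odor, onset_ms, offset_ms) for each presentation."""
        out = []
        t = self.lead_in
        for odor in self.odors:
            out.append((odor, t, t + self.on_duration))
            t += self.on_duration + self.gap_duration
        return out


def odor_firing_rate(D, t_since_onset, params: DriveParams | None = None):
    """Evaluate the adapting ORN rate formula (Hz). Vectorized in both args."""
    p = params or DriveParams()
    D = np.asarray(D, dtype=float)
    t = np.asarray(t_since_onset, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since odor onset must be nonnegative")
    if np.any((D < 0) | (D > 1)):
        raise ValueError("response values D must lie in [0, 1]")
    rate = p.fr_max * D * (p.f_a + (1.0 - p.f_a) * np.exp(-t / p.t_a))
    return float(rate) if rate.ndim == 0 else rate


def impute_missing_responses(
    matrix: pd.DataFrame,
    n_repeats: int = 1000,
    seed: int | np.random.Generator = 0,
    rank: int | None = None,
    variance_retained: float = 0.75,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Complete a response matrix by repeated alternating-least-squares infill.

    Each repeat runs a low-rank ALS completion from a random start; the
    result is the elementwise mean of the repeats, clamped to [0, 1].
    Observed entries are never altered.  The rank is chosen per repeat as the
    number of components explaining ``variance_retained`` of the variance of
    the current infill (unless fixed via ``rank``).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = matrix.to_numpy(dtype=float)
    mask = np.isfinite(X)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix to impute")
    if mask.all():
        return matrix.copy()
    if (~mask).all(axis=1).any() or (~mask).all(axis=0).any():
        raise ValueError("a fully-missing row or column cannot be imputed")

    acc = np.zeros_like(X)
    for _ in range(n_repeats):
        acc += _als_complete_once(X, mask, rng, rank, variance_retained, tol, max_iter)
    filled = acc / n_repeats
    out = X.copy()
    out[~mask] = np.clip(filled[~mask], 0.0, 1.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _als_complete_once(X, mask, rng, rank, variance_retained, tol, max_iter):
    n, m = X.shape
    col_mean = np.nanmean(np.where(mask, X, np.nan), axis=0)
    Z = np.where(mask, X, col_mean[None, :] + 0.05 * rng.standard_normal((n, m)))
    if rank is None:
        mu = Z.mean(axis=0)
        s = np.linalg.svd(Z - mu, compute_uv=False)
        var = s**2 / max((s**2).sum(), 1e-30)
        k = int(np.searchsorted(np.cumsum(var), variance_retained) + 1)
    else:
        k = rank
    k = max(1, min(k, min(n, m) - 1)) if min(n, m) > 1 else 1

    prev = Z.copy()
    for _ in range(max_iter):
        mu = Z.mean(axis=0)
        U, s, Vt = np.linalg.svd(Z - mu, full_matrices=False)
        approx = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        Z = np.where(mask, X, approx)
        denom = max(np.linalg.norm(prev), 1e-30)
        if np.linalg.norm(Z - prev) / denom < tol:
            break
        prev = Z.copy()
    return Z


def sample_orn_spike_times(
    rate_profile: np.ndarray,
    duration: float,
    dt: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample spike times (ms) by Bernoulli thinning of a Poisson process.

    ``rate_profile`` gives the rate in Hz per time step of width ``dt`` ms;
    a spike occurs in step k with probability rate[k] * dt / 1000.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rate = np.asarray(rate_profile, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rates must be nonnegative")
    n_steps = int(round(duration / dt))
    if len(rate) < n_steps:
        raise ValueError("rate profile shorter than requested duration")
    p = rate[:n_steps] * dt / 1000.0
    if np.any(p >= 1.0):
        raise ValueError("rate * dt >= 1: discretization too coarse for this rate")
    hits = rng.random(n_steps) < p
    return np.flatnonzero(hits) * dt


def orn_rate_profiles(
    D_matrix: pd.DataFrame,
    protocol: StimulusProtocol,
    dt: float,
    params: DriveParams | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-glomerulus ORN rate profiles (Hz) over the whole protocol.

    Returns an array of shape (n_glomeruli, n_steps) and the glomerulus
    order.  During an odor window a glomerulus with D > 0 follows the
    adapting evoked rate (the evoked process replaces the spontaneous one);
    glomeruli with D = 0, and all glomeruli during gaps, stay at the
    spontaneous rate.  Adaptation resets at each odor onset.
    """
    p = params or DriveParams()
    for odor in protocol.odors:
        if odor not in D_matrix.columns:
            raise KeyError(f"odor {odor!r} absent from the response matrix")
    if not np.isfinite(D_matrix[list(protocol.odors)].to_numpy(dtype=float)).all():
        raise ValueError("response matrix contains missing values; impute first")
    gloms = list(D_matrix.index)
    n_steps = int(round(protocol.total_duration / dt))
    t_grid = np.arange(n_steps) * dt
    rates = np.full((len(gloms), n_steps), p.spontaneous_rate, dtype=float)
    for odor, on, off in protocol.odor_windows():
        sel = (t_grid >= on) & (t_grid < off)
        tt = t_grid[sel] - on
        D = D_matrix[odor].to_numpy(dtype=float)
        evoked = p.fr_max * D[:, None] * (p.f_a + (1 - p.f_a) * np.exp(-tt[None, :] / p.t_a))
        rows = D > 0
        rates[np.ix_(rows, sel)] = evoked[rows]
    return rates, gloms
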