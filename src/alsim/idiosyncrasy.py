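"""Generators of idiosyncratic antennal lobes.

Two sources of developmental stochasticity are modeled by resampling the
reference circuit: (1) bootstrapping cell populations — ORNs (and uPNs)
with replacement within each glomerulus pool, LNs from the single pool of
all LNs — and (2) resampling each glomerulus's total PN-input synapse count
from the empirical log-normal power law linking it to glomerular volume,

    log S_g = log(a * V_g^d) + eps_g,   eps_g ~ Normal(0, sigma^2),

then scaling all synapses onto that glomerulus's PNs by a single scalar to
match the drawn total.  The reference fit for the hemibrain relationship is
(a = 8.98, d = 0.73, sigma = 0.38).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit_model import NeuronRoster

__all__ = [
    "VolumeSynapseModel",
    "HEMIBRAIN_VOLUME_SYNAPSE_MODEL",
    "bootstrap_population",
    "fit_volume_synapse_model",
    "pn_input_totals",
    "resample_synapse_density",
    "make_idiosyncratic",
]


@dataclass(frozen=True)
class VolumeSynapseModel:
    """Log-normal power law S = a * V^d * exp(eps), sd(eps) = sigma."""

    a: float
    d: float
    sigma: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale factor a must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def mean_log_count(self, volume) -> np.ndarray:
        return np.log(self.a) + self.d * np.log(np.asarray(volume, dtype=float))

    def sample_counts(self, volumes, rng: np.random.Generator) -> np.ndarray:
        v = np.asarray(volumes, dtype=float)
        eps = rng.normal(0.0, self.sigma, size=v.shape)
        return np.exp(self.mean_log_count(v) + eps)


#: Maximum-likelihood fit of the hemibrain volume vs. PN-input-synapse relation.
HEMIBRAIN_VOLUME_SYNAPSE_MODEL = VolumeSynapseModel(a=8.98, d=0.73, sigma=0.38)


def bootstrap_population(
    roster: NeuronRoster,
    raw_counts: np.ndarray,
    cell_class: str,
    seed: int | np.random.Generator = 0,
) -> tuple[NeuronRoster, np.ndarray]:
    """Resample one cell population with replacement.

    ORNs and uPNs are resampled within each glomerulus pool (pool sizes
    preserved); LNs are resampled from the single pool of all LNs.  A
    sampled neuron keeps its original synapse rows/columns, so duplicated
    neurons become distinct instances with identical connectivity; no new
    neuron pairs are ever connected.
    """
    if cell_class not in ("ORN", "PN", "uPN", "LN"):
        raise ValueError(f"cannot bootstrap class {cell_class!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    target = "uPN" if cell_class == "PN" else cell_class

    mapping = np.arange(len(roster))
    if target == "LN":
        pool = roster.index_of("LN")
        if len(pool) == 0:
            raise ValueError("empty LN pool")
        mapping[pool] = rng.choice(pool, size=len(pool), replace=True)
    else:
        for g in roster.glomeruli:
            pool = roster.index_of(target, g)
            if len(pool) == 0:
                continue
            mapping[pool] = rng.choice(pool, size=len(pool), replace=True)
        if not any(len(roster.index_of(target, g)) for g in roster.glomeruli):
            raise ValueError(f"no {target}s to bootstrap")

    tab = roster.table.iloc[mapping].copy()
    # make duplicated instances distinct while recording their origin
    seen: dict[str, int] = {}
    new_ids = []
    for nid in tab["id"]:
        k = seen.get(nid, 0)
        seen[nid] = k + 1
        new_ids.append(nid if k == 0 else f"{nid}#{k}")
    tab["id"] = new_ids
    new_counts = raw_counts[np.ix_(mapping, mapping)].copy()
    return NeuronRoster(tab), new_counts


def fit_volume_synapse_model(volumes, pn_input_counts) -> VolumeSynapseModel:
    """Maximum-likelihood fit of the log-normal power law.

    Equivalent to ordinary least squares of log S on log V, with the biased
    MLE form of sigma (RMS residual, divisor n).
    """
    v = np.asarray(volumes, dtype=float)
    s = np.asarray(pn_input_counts, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 glomeruli to fit")
    if np.any(v <= 0) or np.any(s <= 0):
        raise ValueError("volumes and synapse counts must be positive")
    X = np.column_stack([np.ones_like(v), np.log(v)])
    y = np.log(s)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma = float(np.sqrt(np.mean(resid**2)))
    return VolumeSynapseModel(a=float(np.exp(beta[0])), d=float(beta[1]), sigma=sigma)


def pn_input_totals(roster: NeuronRoster, counts: np.ndarray) -> pd.Series:
    """Total synapse count onto each glomerulus's PNs (any presynaptic class)."""
    totals = {}
    for g in roster.glomeruli:
        pn_cols = roster.index_of("uPN", g)
        totals[g] = float(counts[:, pn_cols].sum()) if len(pn_cols) else 0.0
    return pd.Series(totals)


def resample_synapse_density(
    roster: NeuronRoster,
    raw_counts: np.ndarray,
    volumes: pd.Series,
    model: VolumeSynapseModel = HEMIBRAIN_VOLUME_SYNAPSE_MODEL,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rescale PN-input synapses per glomerulus to a draw from the power law.

    For each glomerulus g a target total S_g is drawn from the model at that
    glomerulus's volume, and every synapse onto g's PNs is multiplied by the
    single scalar S_g / (current total); within-glomerulus ratios between PN
    inputs are therefore unchanged and weights become real-valued.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    new_counts = np.asarray(raw_counts, dtype=float).copy()
    for g in roster.glomeruli:
        pn_cols = roster.index_of("uPN", g)
        if len(pn_cols) == 0:
            continue
        if g not in volumes.index:
            raise KeyError(f"no volume recorded for glomerulus {g!r}")
        current = new_counts[:, pn_cols].sum()
        if current <= 0:
            raise ValueError(f"glomerulus {g!r} has no PN-input synapses to rescale")
        target = float(model.sample_counts(volumes[g], rng))
        new_counts[:, pn_cols] *= target / current
    return new_counts


def make_idiosyncratic(
    roster: NeuronRoster,
    raw_counts: np.ndarray,
    mode: str,
    volumes: pd.Series | None = None,
    model: VolumeSynapseModel = HEMIBRAIN_VOLUME_SYNAPSE_MODEL,
    seed: int | np.random.Generator = 0,
) -> tuple[NeuronRoster, np.ndarray]:
    """One idiosyncratic circuit under a named variation mode.

    Modes: ``poisson`` (identity — variation comes only from input spike
    timing), ``orn`` / ``pn`` / ``ln`` (population bootstrap), ``density``
    (PN-input synapse density resampling), and combinations joined with
    ``+`` (bootstrap applied before density rescaling).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r, c = roster, np.asarray(raw_counts, dtype=float)
    parts = [p.strip().lower() for p in mode.split("+")]
    order = [p for p in parts if p in ("orn", "pn", "ln")] + [
        p for p in parts if p == "density"
    ]
    unknown = set(parts) - {"poisson", "orn", "pn", "ln", "density"}
    if unknown:
        raise ValueError(f"unknown idiosyncrasy mode(s): {sorted(unknown)}")
    for part in order:
        if part == "density":
            if volumes is None:
                raise ValueError("density resampling requires glomerular volumes")
            c = resample_synapse_density(r, c, volumes, model, rng)
        else:
            r, c = bootstrap_population(r, c, part.upper() if part != "pn" else "PN", rng)
    return r, c
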