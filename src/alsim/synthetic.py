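"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a glomerularly
organized connectome (ORNs and uPNs grouped into glomerulus blocks, LNs
innervating broadly, volumes obeying a chosen volume-synapse power law), a
bounded odor-response matrix with missing entries, and paired trial-level
calcium / behavior datasets with a known latent correlation and known
test-retest repeatabilities.  All generators are deterministic given their
spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit_model import NeuronRoster
from .idiosyncrasy import VolumeSynapseModel, HEMIBRAIN_VOLUME_SYNAPSE_MODEL

__all__ = [
    "SyntheticALSpec",
    "PairedDatasetSpec",
    "generate_connectome",
    "generate_door_matrix",
    "generate_paired_dataset",
    "write_connectome",
]


@dataclass(frozen=True)
class SyntheticALSpec:
    """Layout of a synthetic antennal lobe.

    Edge-count scales are expressed through the volume-synapse model (PN
    input totals) and per-edge means; LN innervation breadth is drawn
    uniformly between the given bounds.
    """

    n_glomeruli: int = 8
    orns_per_glomerulus: int = 5
    upns_per_glomerulus: int = 2
    n_mpns: int = 4
    n_lns: int = 20
    eln_iln_ratio: float = 5.4
    volume_range: tuple[float, float] = (7e4, 1.5e5)
    volume_synapse_model: VolumeSynapseModel = HEMIBRAIN_VOLUME_SYNAPSE_MODEL
    orn_share_of_pn_input: float = 0.95   # rest comes from LNs
    ln_breadth: tuple[int, int] = (4, 8)  # glomeruli innervated per LN (inclusive)
    mean_orn_ln_synapses: float = 600.0
    mean_pn_ln_synapses: float = 40.0
    mean_mpn_input_synapses: float = 40.0
    connection_probability: float = 1.0   # ORN->uPN within glomerulus

    def __post_init__(self) -> None:
        if min(self.n_glomeruli, self.orns_per_glomerulus, self.upns_per_glomerulus) < 1:
            raise ValueError("need at least one glomerulus with ORNs and uPNs")
        if not (0.0 <= self.connection_probability <= 1.0):
            raise ValueError("connection probability must lie in [0, 1]")
        if not (0.0 < self.orn_share_of_pn_input <= 1.0):
            raise ValueError("ORN share of PN input must lie in (0, 1]")
        lo, hi = self.ln_breadth
        if not (1 <= lo <= hi <= self.n_glomeruli):
            raise ValueError("LN breadth bounds must satisfy 1 <= lo <= hi <= n_glomeruli")


@dataclass(frozen=True)
class PairedDatasetSpec:
    """Ground truth for a paired calcium/behavior population."""

    n_individuals: int = 69
    r2_latent: float = 0.5
    r2_calcium: float = 0.77   # test-retest repeatability of the calcium measure
    r2_behavior: float = 0.12  # test-retest repeatability of the behavior score
    n_glomeruli: int = 5
    n_odors: int = 13
    trials_per_individual: int = 4
    signal_amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r2_latent", "r2_calcium", "r2_behavior"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.trials_per_individual < 2:
            raise ValueError("repeatability calibration needs at least 2 trials")


def _dirichlet_counts(total: float, n: int, rng: np.random.Generator, conc: float = 5.0) -> np.ndarray:
    """Split ``total`` synapses over n edges with moderate spread, min 1."""
    if n == 0:
        return np.zeros(0)
    w = rng.gamma(conc, 1.0, size=n)
    counts = np.maximum(np.round(total * w / w.sum()), 1.0)
    return counts


def generate_connectome(
    spec: SyntheticALSpec, seed: int | np.random.Generator = 0
) -> tuple[NeuronRoster, np.ndarray, pd.Series]:
    """Build a synthetic roster, synapse-count matrix, and volume table.

    ORN->uPN edges are confined within glomerulus blocks; each LN innervates
    a random subset of glomeruli (breadth uniform within the spec bounds),
    receiving ORN and uPN input there and synapsing onto that glomerulus's
    uPNs; mPNs receive input from random ORNs.  Per-glomerulus PN-input
    totals follow the spec's volume-synapse model at volumes drawn
    log-uniformly, so refitting the model on (volume, PN-input) pairs
    recovers its parameters.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gloms = [f"G{k + 1:02d}" for k in range(spec.n_glomeruli)]

    rows = []
    for g in gloms:
        for k in range(spec.orns_per_glomerulus):
            rows.append((f"{g}-ORN{k}", "ORN", g, 1.0))
    for g in gloms:
        for k in range(spec.upns_per_glomerulus):
            rows.append((f"{g}-uPN{k}", "uPN", g, np.nan))
    for k in range(spec.n_mpns):
        rows.append((f"mPN{k}", "mPN", None, np.nan))
    for k in range(spec.n_lns):
        rows.append((f"LN{k:02d}", "LN", None, np.nan))
    roster = NeuronRoster(
        pd.DataFrame(rows, columns=["id", "cell_class", "glomerulus", "polarity"])
    )

    lo, hi = spec.volume_range
    volumes = pd.Series(
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(gloms))), index=gloms
    )
    pn_totals = spec.volume_synapse_model.sample_counts(volumes.to_numpy(), rng)

    # LN innervation sets
    ln_idx = roster.index_of("LN")
    ln_gloms: list[list[str]] = []
    for _ in ln_idx:
        breadth = int(rng.integers(spec.ln_breadth[0], spec.ln_breadth[1] + 1))
        ln_gloms.append(list(rng.choice(gloms, size=breadth, replace=False)))

    n = len(roster)
    counts = np.zeros((n, n))

    for gi, g in enumerate(gloms):
        orns = roster.index_of("ORN", g)
        upns = roster.index_of("uPN", g)
        lns_here = [ln_idx[k] for k, gs in enumerate(ln_gloms) if g in gs]

        orn_budget = pn_totals[gi] * spec.orn_share_of_pn_input
        ln_budget = pn_totals[gi] - orn_budget if lns_here else 0.0
        if not lns_here:
            orn_budget = pn_totals[gi]

        pairs = [
            (o, p)
            for o in orns
            for p in upns
            if rng.random() < spec.connection_probability
        ]
        if not pairs:  # guarantee the glomerulus is wired
            pairs = [(orns[0], upns[0])]
        for (o, p), c in zip(pairs, _dirichlet_counts(orn_budget, len(pairs), rng)):
            counts[o, p] += c
        if lns_here:
            ln_pairs = [(l, p) for l in lns_here for p in upns]
            for (l, p), c in zip(ln_pairs, _dirichlet_counts(ln_budget, len(ln_pairs), rng)):
                counts[l, p] += c
        # drive onto LNs from this glomerulus
        for l in lns_here:
            for o in orns:
                counts[o, l] += max(1.0, np.round(rng.poisson(spec.mean_orn_ln_synapses)))
            for p in upns:
                counts[p, l] += max(1.0, np.round(rng.poisson(spec.mean_pn_ln_synapses)))

    # mPNs: diffuse ORN input
    for m in roster.index_of("mPN"):
        srcs = rng.choice(roster.index_of("ORN"), size=8, replace=False)
        for o, c in zip(srcs, _dirichlet_counts(spec.mean_mpn_input_synapses, len(srcs), rng)):
            counts[o, m] += c

    return roster, counts, volumes


def write_connectome(
    roster: NeuronRoster, counts: np.ndarray, volumes: pd.Series, out_dir
) -> dict[str, Path]:
    """Write roster/edges/volumes in the loader schemas (TSV/TSV/CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / "roster.tsv",
        "edges": out / "edges.tsv",
        "volumes": out / "volumes.csv",
    }
    roster.to_tsv(paths["roster"])
    pre, post = np.nonzero(counts)
    pd.DataFrame(
        {
            "pre_id": roster.ids[pre],
            "post_id": roster.ids[post],
            "synapse_count": counts[pre, post],
        }
    ).to_csv(paths["edges"], sep="\t", index=False)
    volumes.rename("volume_um3").rename_axis("glomerulus").to_csv(paths["volumes"])
    return paths


def generate_door_matrix(
    n_glomeruli: int,
    n_odors: int,
    missing_fraction: float = 0.4,
    seed: int | np.random.Generator = 0,
    glomeruli: list[str] | None = None,
    odors: list[str] | None = None,
    rank: int = 2,
) -> pd.DataFrame:
    """Low-rank-plus-noise response matrix squashed to [0, 1], with holes.

    Emulates a receptor-response database: smooth structure across
    glomeruli and odors, bounded entries, and a uniformly random missing
    mask (default 40% missing).
    """
    if not (0.0 <= missing_fraction <= 0.9):
        raise ValueError("missing fraction must lie in [0, 0.9]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    G = glomeruli or [f"G{k + 1:02d}" for k in range(n_glomeruli)]
    O = odors or [f"odor{k + 1}" for k in range(n_odors)]
    L = rng.normal(0.0, 1.0, size=(n_glomeruli, rank))
    R = rng.normal(0.0, 1.0, size=(rank, n_odors))
    raw = L @ R + 0.3 * rng.standard_normal((n_glomeruli, n_odors))
    X = 1.0 / (1.0 + np.exp(-raw))  # squash into (0, 1)
    mask = rng.random(X.shape) < missing_fraction
    X = X.copy()
    X[mask] = np.nan
    return pd.DataFrame(X, index=G, columns=O)


def generate_paired_dataset(
    spec: PairedDatasetSpec, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Trial-level calcium table + two behavior measurements per individual.

    Latent states X_c, X_b are standard normal with corr = sqrt(r2_latent).
    The observed per-individual calcium state mixes X_c at r_c =
    (r2_calcium)^(1/4); trials embed it along a fixed unit loading vector
    plus isotropic noise whose SD is calibrated by bisection so that the
    PCA-vs-shuffle repeatability estimator recovers r2_calcium.  Behavior is
    measured twice at r_b = (r2_behavior)^(1/4), giving test-retest
    R^2 = r2_behavior in expectation.

    Returns (calcium_trials, behavior, truth) where truth records the latent
    states, the loading vector, and the calibrated noise SD.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    N = spec.n_individuals
    p = spec.n_glomeruli * spec.n_odors
    r_lat = np.sqrt(spec.r2_latent)
    r_c = spec.r2_calcium**0.25
    r_b = spec.r2_behavior**0.25

    x_c = rng.standard_normal(N)
    x_b = r_lat * x_c + np.sqrt(1.0 - spec.r2_latent) * rng.standard_normal(N)
    x_c_obs = r_c * x_c + np.sqrt(1.0 - r_c**2) * rng.standard_normal(N)
    beh1 = r_b * x_b + np.sqrt(1.0 - r_b**2) * rng.standard_normal(N)
    beh2 = r_b * x_b + np.sqrt(1.0 - r_b**2) * rng.standard_normal(N)

    loading = rng.standard_normal(p)
    loading /= np.linalg.norm(loading)

    noise_sd = _calibrate_noise_sd(spec, x_c_obs, loading, rng)

    gloms = [f"G{k + 1:02d}" for k in range(spec.n_glomeruli)]
    odors = [f"odor{k + 1}" for k in range(spec.n_odors)]
    feat_cols = [f"{g}:{o}" for g in gloms for o in odors]
    rows = []
    for i in range(N):
        for t in range(spec.trials_per_individual):
            y = spec.signal_amplitude * x_c_obs[i] * loading + noise_sd * rng.standard_normal(p)
            rows.append([f"fly{i:03d}", t, "L" if t % 2 == 0 else "R", *y])
    calcium = pd.DataFrame(rows, columns=["individual", "trial", "hemisphere", *feat_cols])
    behavior = pd.DataFrame(
        {
            "individual": [f"fly{i:03d}" for i in range(N)],
            "preference_1": beh1,
            "preference_2": beh2,
        }
    )
    truth = {
        "x_c": x_c,
        "x_b": x_b,
        "x_c_obs": x_c_obs,
        "loading": loading,
        "noise_sd": noise_sd,
        "spec": spec,
    }
    return calcium, behavior, truth


def _calibrate_noise_sd(
    spec: PairedDatasetSpec,
    x_c_obs: np.ndarray,
    loading: np.ndarray,
    rng: np.random.Generator,
    n_iter: int = 12,
) -> float:
    """Bisection on the trial-noise SD against the repeatability estimator."""
    from .latent import pca_repeatability

    p = len(loading)
    target = spec.r2_calcium

    def estimate(sd: float) -> float:
        local = np.random.default_rng(12345)
        rows = np.repeat(spec.signal_amplitude * x_c_obs[:, None] * loading[None, :],
                         spec.trials_per_individual, axis=0)
        rows = rows + sd * local.standard_normal(rows.shape)
        est = pca_repeatability(rows, n_shuffles=5, n_bootstrap=1, seed=local)
        return est.value

    lo, hi = 1e-3, 5.0
    if estimate(lo) < target:
        return lo
    for _ in range(n_iter):
        mid = np.sqrt(lo * hi)
        if estimate(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
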