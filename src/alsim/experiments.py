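"""Idiosyncratic-population experiments.

Drivers that combine the simulator with the idiosyncrasy generators:
simulate a population of individually resampled antennal lobes, collect
their PN glomerulus-odor response vectors, and quantify how strongly each
source of developmental stochasticity organizes population variation at the
glomerular level (GOI), and whether it supports decoding of a simulated
odor preference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circuit_model import NeuronRoster, SensitivityConfig, build_weight_matrix
from .idiosyncrasy import (
    VolumeSynapseModel,
    fit_volume_synapse_model,
    make_idiosyncratic,
    pn_input_totals,
)
from .lif_engine import run_odor_panel
from .odor_drive import DriveParams, StimulusProtocol
from .population import (
    LinearPreferenceModel,
    PN_PC2_OCT_MCH_MODEL,
    apply_preference_model,
    classify_individuals,
    glomerular_organization_index,
    pca_responses,
)

__all__ = [
    "simulate_population",
    "glomerulus_blocks",
    "population_goi",
    "specialist_contrast_loading",
    "preference_decoding",
]

VARIATION_MODES = ("poisson", "density", "orn", "ln", "pn")


def simulate_population(
    roster: NeuronRoster,
    raw_counts: np.ndarray,
    D_matrix: pd.DataFrame,
    protocol: StimulusProtocol,
    mode: str,
    n_individuals: int,
    volumes: pd.Series | None = None,
    model: VolumeSynapseModel | None = None,
    sensitivities: SensitivityConfig | None = None,
    drive: DriveParams | None = None,
    seed: int = 0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """PN glomerulus-odor response vectors for a population of individuals.

    Each individual is an independently resampled circuit under ``mode``
    (every mode also carries independent input-spike Poisson timing), run
    through the full odor panel.  For density resampling the volume-synapse
    model defaults to the one fitted from the source circuit itself, so the
    resampled totals are statistically matched to the source.  Returns a
    DataFrame with one row per individual and glomerulus-major
    ``glom:odor`` feature columns.
    """
    if model is None and "density" in mode:
        totals = pn_input_totals(roster, raw_counts)
        model = fit_volume_synapse_model(
            volumes.loc[totals.index].to_numpy(), totals.to_numpy()
        )
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_individuals):
        r_k, c_k = make_idiosyncratic(
            roster, raw_counts, mode, volumes=volumes, model=model, seed=rng
        ) if mode != "poisson" else (roster, raw_counts)
        w = build_weight_matrix(r_k, c_k, sensitivities or SensitivityConfig())
        resp = run_odor_panel(
            w, D_matrix, protocol, drive=drive, seed=rng, dt=dt,
            readout_classes=("uPN",),
        )["uPN"]
        rows.append(resp.as_vector())
        labels = resp.feature_labels
    return pd.DataFrame(
        rows, index=[f"al{k:03d}" for k in range(n_individuals)], columns=labels
    )


def glomerulus_blocks(feature_labels: list[str]) -> dict[str, np.ndarray]:
    """Group glomerulus-major ``glom:odor`` columns into index blocks."""
    gloms = {}
    for j, lab in enumerate(feature_labels):
        g = lab.split(":")[0]
        gloms.setdefault(g, []).append(j)
    return {g: np.array(idx) for g, idx in gloms.items()}


def population_goi(
    features: pd.DataFrame,
    n_pcs: int = 5,
    n_bootstrap: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """GOI of a population's PN response variation, with a bootstrap SE.

    The point estimate is the GOI of the PCA over individuals; the SE is the
    SD of the GOI over bootstrap resamples of individuals.
    """
    rng = np.random.default_rng(seed)
    blocks = glomerulus_blocks(list(features.columns))
    X = features.to_numpy(dtype=float)
    point = glomerular_organization_index(pca_responses(X), blocks, n_pcs)
    boots = np.empty(n_bootstrap)
    n = X.shape[0]
    for b in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        boots[b] = glomerular_organization_index(pca_responses(X[take]), blocks, n_pcs)
    return point, float(boots.std(ddof=1))


def specialist_contrast_loading(
    feature_labels: list[str], plus_glom: str, minus_glom: str
) -> np.ndarray:
    """Unit loading contrasting two glomeruli's responses across all odors.

    Plays the role of an empirically fitted principal-component direction
    (the DM2-minus-DC2-style axis): +1 on every feature of ``plus_glom``,
    -1 on every feature of ``minus_glom``, 0 elsewhere, normalized.
    """
    v = np.zeros(len(feature_labels))
    for j, lab in enumerate(feature_labels):
        g = lab.split(":")[0]
        if g == plus_glom:
            v[j] = 1.0
        elif g == minus_glom:
            v[j] = -1.0
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("neither contrast glomerulus found in the feature labels")
    return v / norm


def preference_decoding(
    features: pd.DataFrame,
    preference_loading: np.ndarray,
    model: LinearPreferenceModel = PN_PC2_OCT_MCH_MODEL,
    n_pcs: int = 3,
    n_shuffles: int = 200,
    seed: int = 0,
) -> dict:
    """Decode simulated odor preference from the population's top PCs.

    A 'behavioral preference' is assigned to each individual by projecting
    its mean-centered response vector onto ``preference_loading`` and
    applying the linear preference model; individuals are labeled OCT- vs
    MCH-preferring by median split.  A linear-logistic classifier in the
    space of the population's first ``n_pcs`` PCs is scored by twofold
    cross-validation and compared with a shuffled-label null.
    """
    rng = np.random.default_rng(seed)
    X = features.to_numpy(dtype=float)
    scores_on_loading = (X - X.mean(axis=0)) @ preference_loading
    pref = apply_preference_model(model, scores_on_loading)
    labels = (pref > np.median(pref)).astype(int)
    pca = pca_responses(X)
    pcs = pca.scores[:, :n_pcs]
    acc = classify_individuals(pcs, labels, seed=rng)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = classify_individuals(pcs, rng.permutation(labels), seed=rng)
    return {
        "accuracy": acc,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "null_p": float((np.sum(null >= acc) + 1) / (n_shuffles + 1)),
        "labels": labels,
        "preference": pref,
    }
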