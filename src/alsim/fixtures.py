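"""The shipped synthetic fixture: a small tuned antennal lobe.

An 8-glomerulus, ~120-neuron circuit with a 4-odor panel (including an
OCT-like and an MCH-like odor) sized so that a full idiosyncratic-population
experiment runs in minutes.  The wiring scales were calibrated once so that
the canonical-computation battery passes at the standard sensitivity
multipliers (0.1, 0.04, 0.02, 0.4); see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circuit_model import (
    NeuronRoster,
    SensitivityConfig,
    SignedWeightMatrix,
    assign_ln_polarity,
    assign_pn_polarity,
    build_weight_matrix,
)
from .odor_drive import DriveParams, StimulusProtocol
from .synthetic import SyntheticALSpec, generate_connectome

__all__ = [
    "FIXTURE_ODORS",
    "fixture_spec",
    "fixture_circuit",
    "fixture_door_matrix",
    "fixture_protocol",
]

FIXTURE_ODORS = ("OCT", "MCH", "EA", "BENZ")

#: Master seed for the shipped reference fixture.
FIXTURE_SEED = 2024


def fixture_spec() -> SyntheticALSpec:
    return SyntheticALSpec()


def fixture_circuit(
    seed: int = FIXTURE_SEED,
    sensitivities: SensitivityConfig | None = None,
) -> tuple[SignedWeightMatrix, pd.Series]:
    """Fully assembled weight matrix plus glomerular volumes."""
    roster, counts, volumes = generate_connectome(fixture_spec(), seed=seed)
    roster, counts = _assign_polarities(roster, counts, seed)
    w = build_weight_matrix(roster, counts, sensitivities or SensitivityConfig())
    return w, volumes


def _assign_polarities(roster: NeuronRoster, counts, seed: int):
    rng = np.random.default_rng(seed + 1)
    roster = assign_ln_polarity(roster, counts, eln_iln_ratio=5.4, seed=rng)
    mpns = roster.ids[roster.index_of("mPN")]
    upns = roster.ids[roster.index_of("uPN")]
    known = {}
    if len(mpns) >= 2:  # a subset annotated: one cholinergic, one GABAergic
        known[mpns[0]] = "cholinergic"
        known[mpns[1]] = "GABAergic"
    if len(upns) >= 1:  # uPNs are overwhelmingly cholinergic
        known[upns[0]] = "cholinergic"
    roster = assign_pn_polarity(roster, known, seed=rng)
    return roster, counts


def fixture_door_matrix(seed: int = FIXTURE_SEED, n_glomeruli: int = 8) -> pd.DataFrame:
    """Complete 8-glomerulus x 4-odor response matrix in [0, 1].

    Odor tuning mimics a generalist/specialist structure: two broadly tuned
    glomeruli respond strongly to every odor, one moderately tuned
    specialist glomerulus responds to each single odor, and the remaining
    glomeruli are silent (ORNs there stay at the spontaneous rate).  The
    specialist contrast between the OCT- and MCH-like odors plays the role
    of a DM2/DC2-style axis.
    """
    rng = np.random.default_rng(seed + 2)
    gloms = [f"G{k + 1:02d}" for k in range(n_glomeruli)]
    D = np.zeros((n_glomeruli, len(FIXTURE_ODORS)))
    generalists = (0, 1)
    specialist = {"OCT": 2, "MCH": 3, "EA": 4, "BENZ": 5}
    for j, odor in enumerate(FIXTURE_ODORS):
        for g in generalists:
            D[g, j] = 0.75 + 0.25 * rng.random()
        D[specialist[odor], j] = 0.3 + 0.2 * rng.random()
    return pd.DataFrame(D, index=gloms, columns=list(FIXTURE_ODORS))


def fixture_protocol(odors=FIXTURE_ODORS) -> StimulusProtocol:
    return StimulusProtocol(odors=tuple(odors), on_duration=400.0, gap_duration=300.0, lead_in=300.0)
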