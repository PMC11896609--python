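"""Antennal-lobe circuit representation.

The circuit is a roster of neurons (ORNs, uniglomerular PNs, multiglomerular
PNs, and local neurons) plus a synapse-count matrix taken from a connectome
export.  ORNs and uPNs carry a glomerulus label; LNs innervate many glomeruli
and carry none.  Polarities are +1 (excitatory, cholinergic) or -1
(inhibitory, GABAergic).  The effective weight matrix used by the simulator is
the raw synapse-count matrix with presynaptic rows signed by polarity and
postsynaptic columns scaled by a class-specific sensitivity multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellClassParams",
    "SensitivityConfig",
    "NeuronRoster",
    "SignedWeightMatrix",
    "TABLE_CELL_PARAMS",
    "DEFAULT_EXCLUDED_GLOMERULI",
    "load_circuit",
    "ln_innervation_counts",
    "assign_ln_polarity",
    "assign_pn_polarity",
    "build_weight_matrix",
]

#: Non-olfactory (hygro-/thermosensory) glomeruli dropped on load.
DEFAULT_EXCLUDED_GLOMERULI = ("VP1d", "VP1l", "VP1m", "VP2", "VP3", "VP4", "VP5")

CELL_CLASSES = ("ORN", "uPN", "mPN", "LN")


@dataclass(frozen=True)
class CellClassParams:
    """Electrophysiology of one cell class (mV, ms, pF, GOhm)."""

    resting_potential: float
    threshold: float
    ap_min: float
    ap_max: float
    ap_duration: float
    capacitance: float
    resistance: float

    def __post_init__(self) -> None:
        if not (self.ap_min <= self.resting_potential < self.threshold < self.ap_max):
            raise ValueError("require ap_min <= V_0 < V_thr < ap_max")
        if self.capacitance <= 0 or self.resistance <= 0:
            raise ValueError("capacitance and resistance must be positive")

    @property
    def tau_membrane(self) -> float:
        """Membrane time constant R*C in ms."""
        return self.resistance * self.capacitance


#: Published electrophysiology per cell class. PN values are shared by uPNs
#: and mPNs; ORN capacitance is assumed equal to PNs.
TABLE_CELL_PARAMS: dict[str, CellClassParams] = {
    "ORN": CellClassParams(-70.0, -50.0, -70.0, 0.0, 2.0, 73.0, 1.8),
    "LN": CellClassParams(-50.0, -40.0, -60.0, 0.0, 4.0, 64.0, 1.0),
    "PN": CellClassParams(-55.0, -40.0, -55.0, -30.0, 2.0, 73.0, 0.3),
}


@dataclass(frozen=True)
class SensitivityConfig:
    """Class-specific postsynaptic sensitivity multipliers a_i.

    Defaults are the hand-tuned working point: ORN columns of the
    connectivity matrix scaled by 0.1, eLN columns by 0.04, iLN columns by
    0.02, and PN columns (both subtypes) by 0.4.
    """

    a_orn: float = 0.1
    a_eln: float = 0.04
    a_iln: float = 0.02
    a_pn: float = 0.4

    def __post_init__(self) -> None:
        if min(self.a_orn, self.a_eln, self.a_iln, self.a_pn) <= 0:
            raise ValueError("sensitivity multipliers must be strictly positive")

    def scaled(self, factors: dict[str, float]) -> "SensitivityConfig":
        """Return a copy with named multipliers scaled (for sensitivity runs)."""
        vals = {
            "a_orn": self.a_orn,
            "a_eln": self.a_eln,
            "a_iln": self.a_iln,
            "a_pn": self.a_pn,
        }
        for name, f in factors.items():
            vals[name] = vals[name] * f
        return SensitivityConfig(**vals)


@dataclass
class NeuronRoster:
    """Ordered table of neurons with class, glomerulus, and polarity.

    ``table`` columns: id (str), cell_class (ORN/uPN/mPN/LN), glomerulus
    (str or None), polarity (+1/-1, NaN when unassigned).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.table["id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate neuron ids in roster: {dupes[:5]}")
        bad = set(self.table["cell_class"]) - set(CELL_CLASSES)
        if bad:
            raise ValueError(f"unknown cell classes: {sorted(bad)}")
        glom = self.table["glomerulus"]
        needs_glom = self.table["cell_class"].isin(["ORN", "uPN"])
        if glom[needs_glom].isna().any():
            raise ValueError("every ORN and uPN must carry a glomerulus label")
        orn = self.table["cell_class"] == "ORN"
        pol = self.table["polarity"]
        if (pol[orn].dropna() != 1).any():
            raise ValueError("ORN polarity must be +1")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def cell_class(self) -> np.ndarray:
        return self.table["cell_class"].to_numpy()

    @property
    def glomerulus(self) -> np.ndarray:
        return self.table["glomerulus"].to_numpy()

    @property
    def polarity(self) -> np.ndarray:
        return self.table["polarity"].to_numpy(dtype=float)

    @property
    def glomeruli(self) -> list[str]:
        """Sorted list of glomerulus labels present."""
        return sorted(self.table["glomerulus"].dropna().unique())

    def index_of(self, cell_class: str | None = None, glomerulus: str | None = None) -> np.ndarray:
        mask = np.ones(len(self.table), dtype=bool)
        if cell_class is not None:
            mask &= self.table["cell_class"].to_numpy() == cell_class
        if glomerulus is not None:
            mask &= self.table["glomerulus"].to_numpy() == glomerulus
        return np.flatnonzero(mask)

    def class_counts(self) -> dict[str, int]:
        return self.table["cell_class"].value_counts().to_dict()

    def with_polarity(self, indices: np.ndarray, polarity: np.ndarray | int) -> "NeuronRoster":
        tab = self.table.copy()
        tab.loc[tab.index[indices], "polarity"] = polarity
        return NeuronRoster(tab)

    def to_tsv(self, path) -> None:
        tab = self.table.copy()
        tab["polarity"] = tab["polarity"].map(
            lambda p: "" if pd.isna(p) else str(int(p))
        )
        tab["glomerulus"] = tab["glomerulus"].fillna("")
        tab.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NeuronRoster":
        tab = pd.read_csv(path, sep="\t", dtype={"id": str})
        return cls(_normalize_roster_table(tab))


def _normalize_roster_table(tab: pd.DataFrame) -> pd.DataFrame:
    tab = tab.copy()
    required = {"id", "cell_class", "glomerulus", "polarity"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"roster missing columns: {sorted(missing)}")
    tab["id"] = tab["id"].astype(str)
    tab["glomerulus"] = tab["glomerulus"].replace("", np.nan)
    tab["glomerulus"] = tab["glomerulus"].where(pd.notna(tab["glomerulus"]), None)
    tab["polarity"] = pd.to_numeric(tab["polarity"], errors="coerce")
    return tab[["id", "cell_class", "glomerulus", "polarity"]]


@dataclass
class SignedWeightMatrix:
    """Synapse counts and signed, sensitivity-scaled effective weights.

    Convention: ``raw_counts[j, i]`` is the synapse count from presynaptic
    neuron j (row) onto postsynaptic neuron i (column), ordered as in the
    roster.  ``effective_weights[j, i] = polarity(j) * raw_counts[j, i] *
    a_class(i)`` where the column multiplier depends on the postsynaptic
    neuron's class (eLN vs iLN distinguished by polarity).
    """

    roster: NeuronRoster
    raw_counts: np.ndarray
    effective_weights: np.ndarray
    sensitivities: SensitivityConfig


def load_circuit(
    roster_table,
    edge_table,
    excluded_glomeruli: tuple[str, ...] = DEFAULT_EXCLUDED_GLOMERULI,
) -> tuple[NeuronRoster, np.ndarray]:
    """Load a roster and synapse-count edge list from delimited tables.

    Parameters are file paths, file-like objects, or DataFrames.  Roster
    schema: ``id  cell_class  glomerulus  polarity`` (tab-separated);
    edges: ``pre_id  post_id  synapse_count``.  Neurons of non-olfactory
    glomeruli (default VP*) are dropped, together with their edges.

    Returns the roster and the count matrix aligned to roster order.
    """
    roster_df = _read_table(roster_table)
    edges = _read_table(edge_table)

    roster_df = _normalize_roster_table(roster_df)
    keep = ~roster_df["glomerulus"].isin(list(excluded_glomeruli))
    roster = NeuronRoster(roster_df[keep])

    required = {"pre_id", "post_id", "synapse_count"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table missing columns: {sorted(required - set(edges.columns))}")

    n = len(roster)
    counts = np.zeros((n, n), dtype=float)
    if len(edges):
        edges = edges.copy()
        edges["pre_id"] = edges["pre_id"].astype(str)
        edges["post_id"] = edges["post_id"].astype(str)
        dropped_ids = set(roster_df.loc[~keep, "id"])
        known = set(roster.ids)
        # edges touching excluded neurons vanish with them; anything else
        # unknown is a schema error worth naming
        for col in ("pre_id", "post_id"):
            bad = set(edges[col]) - known - dropped_ids
            if bad:
                raise ValueError(f"edge table references unknown neuron id(s): {sorted(bad)[:5]}")
        edges = edges[edges["pre_id"].isin(known) & edges["post_id"].isin(known)]
        if (edges["synapse_count"] < 0).any():
            raise ValueError("synapse counts must be nonnegative")
        pos = {nid: k for k, nid in enumerate(roster.ids)}
        rows = edges["pre_id"].map(pos).to_numpy()
        cols = edges["post_id"].map(pos).to_numpy()
        np.add.at(counts, (rows, cols), edges["synapse_count"].to_numpy(dtype=float))
    return roster, counts


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t")


def ln_innervation_counts(roster: NeuronRoster, raw_counts: np.ndarray) -> pd.Series:
    """Number of glomeruli each LN innervates.

    A glomerulus counts as innervated if the LN has at least one synapse, in
    either direction, with any glomerulus-labeled neuron (ORN or uPN) of that
    glomerulus.
    """
    ln_idx = roster.index_of("LN")
    glom = roster.glomerulus
    labeled = np.flatnonzero(pd.notna(glom))
    out = {}
    for i in ln_idx:
        touched = np.flatnonzero(raw_counts[i, labeled] + raw_counts[labeled, i] > 0)
        out[roster.ids[i]] = len(set(glom[labeled[touched]]))
    return pd.Series(out, dtype=int)


def assign_ln_polarity(
    roster: NeuronRoster,
    raw_counts: np.ndarray,
    eln_iln_ratio: float = 5.4,
    seed: int | np.random.Generator = 0,
) -> NeuronRoster:
    """Assign LN polarities: a minority of excitatory LNs among inhibitory ones.

    The eLN count is round-half-up of n_LN / (1 + ratio), matching the
    estimated 1:5.4 eLN:iLN ratio (197 LNs -> 31 eLNs).  Because eLNs broadly
    innervate the antennal lobe, candidates are restricted to the top half of
    LNs ranked by innervated-glomerulus count (ties broken by id), and the
    eLNs are drawn uniformly without replacement from that pool.
    """
    if eln_iln_ratio <= 0:
        raise ValueError("eLN:iLN ratio must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ln_idx = roster.index_of("LN")
    n_ln = len(ln_idx)
    if n_ln == 0:
        return roster
    n_eln = int(np.floor(n_ln / (1.0 + eln_iln_ratio) + 0.5))
    counts = ln_innervation_counts(roster, raw_counts)
    ln_ids = roster.ids[ln_idx]
    order = sorted(range(n_ln), key=lambda k: (-counts[ln_ids[k]], ln_ids[k]))
    n_top = int(np.ceil(n_ln / 2))
    candidates = np.array(order[:n_top])
    if n_eln > n_top:
        raise ValueError(f"{n_eln} eLNs requested but only {n_top} broadly-innervating candidates")
    chosen = rng.choice(candidates, size=n_eln, replace=False) if n_eln else np.array([], dtype=int)
    pol = np.full(n_ln, -1.0)
    pol[chosen.astype(int)] = 1.0
    return roster.with_polarity(ln_idx, pol)


def assign_pn_polarity(
    roster: NeuronRoster,
    known_transmitter: dict[str, str] | pd.Series | None,
    seed: int | np.random.Generator = 0,
    default_cholinergic_fraction: dict[str, float] | None = None,
) -> NeuronRoster:
    """Assign PN polarities from neurotransmitter annotations.

    Annotated PNs take their annotated polarity (cholinergic -> +1,
    GABAergic -> -1).  Each unannotated mPN (resp. uPN) is independently
    assigned excitatory with probability equal to the cholinergic fraction
    among annotated mPNs (resp. uPNs).  The draw is made once per roster and
    should be serialized with it; reloading a serialized roster never
    re-randomizes.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    known = dict(known_transmitter) if known_transmitter is not None else {}
    for nid, label in known.items():
        if label not in ("cholinergic", "GABAergic"):
            raise ValueError(f"unknown transmitter label {label!r} for {nid}")
    out = roster
    for pn_class in ("mPN", "uPN"):
        idx = out.index_of(pn_class)
        if len(idx) == 0:
            continue
        ids = out.ids[idx]
        annotated = np.array([known.get(i) is not None for i in ids])
        pol = np.full(len(idx), np.nan)
        pol[annotated] = [1.0 if known[i] == "cholinergic" else -1.0 for i in ids[annotated]]
        n_unknown = int((~annotated).sum())
        if n_unknown:
            if annotated.any():
                frac = float(np.mean(pol[annotated] == 1.0))
            elif default_cholinergic_fraction and pn_class in default_cholinergic_fraction:
                frac = float(default_cholinergic_fraction[pn_class])
            else:
                raise ValueError(
                    f"no annotated {pn_class}s to estimate a cholinergic fraction; "
                    "supply default_cholinergic_fraction explicitly"
                )
            draw = rng.random(n_unknown) < frac
            pol[~annotated] = np.where(draw, 1.0, -1.0)
        out = out.with_polarity(idx, pol)
    return out


def build_weight_matrix(
    roster: NeuronRoster,
    raw_counts: np.ndarray,
    sensitivities: SensitivityConfig | None = None,
) -> SignedWeightMatrix:
    """Sign rows by presynaptic polarity and scale columns by a_class(post)."""
    sens = sensitivities or SensitivityConfig()
    pol = roster.polarity
    if np.isnan(pol).any():
        missing = roster.ids[np.isnan(pol)]
        raise ValueError(f"unassigned polarity for {len(missing)} neurons, e.g. {missing[:3]}")
    cls = roster.cell_class
    col_scale = np.empty(len(roster))
    col_scale[cls == "ORN"] = sens.a_orn
    col_scale[(cls == "uPN") | (cls == "mPN")] = sens.a_pn
    is_ln = cls == "LN"
    col_scale[is_ln & (pol > 0)] = sens.a_eln
    col_scale[is_ln & (pol < 0)] = sens.a_iln
    eff = pol[:, None] * raw_counts * col_scale[None, :]
    return SignedWeightMatrix(roster, np.asarray(raw_counts, dtype=float), eff, sens)
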