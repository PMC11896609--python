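"""Leaky integrate-and-fire network engine.

All neurons are single-compartment LIF units.  Below threshold, neuron i
obeys forward-Euler dynamics of

    C_i dV_i/dt = (V_{i,0} - V_i) / R_i + I_odor,i(t) + sum_j a_i W_ji I_j(t)

(units mV, ms, pF, GOhm, pA; the class sensitivity a_i and the presynaptic
sign are folded into the effective weight matrix).  When V_i crosses its
class threshold, a templated action potential is written into the voltage
trace — integration is suspended for the template's duration, which acts as
the refractory period — and the neuron's output current jumps by one unit
and then decays exponentially with timescale tau_syn; downstream neurons
receive that current scaled by the effective weight, starting the step after
the spike.  Scheduled ORN input spikes are forced by injecting a large kick
current for a single time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .circuit_model import (
    CellClassParams,
    NeuronRoster,
    SignedWeightMatrix,
    TABLE_CELL_PARAMS,
)
from .odor_drive import DriveParams, StimulusProtocol, orn_rate_profiles

__all__ = [
    "SimulationResult",
    "ResponseMatrix",
    "simulate",
    "compute_firing_rates",
    "run_odor_panel",
]

DEFAULT_DT = 0.1      # ms
DEFAULT_TAU_SYN = 2.0  # ms, postsynaptic-current decay


@dataclass
class SimulationResult:
    """Spike times per neuron plus protocol metadata."""

    neuron_ids: np.ndarray
    spike_neurons: np.ndarray   # index into neuron_ids, one entry per spike
    spike_steps: np.ndarray     # time step of each spike
    dt: float
    duration: float
    protocol: StimulusProtocol | None = None
    voltage_traces: np.ndarray | None = None  # (n_steps, n) if stored

    @property
    def spike_times(self) -> np.ndarray:
        """Spike times in ms, aligned with ``spike_neurons``."""
        return self.spike_steps * self.dt

    def spikes_of(self, neuron_index: int) -> np.ndarray:
        return np.sort(self.spike_times[self.spike_neurons == neuron_index])

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dt"] = self.dt
            f.attrs["duration"] = self.duration
            g = f.create_group("spikes")
            for k, nid in enumerate(self.neuron_ids):
                g.create_dataset(str(nid), data=self.spikes_of(k))


@dataclass
class ResponseMatrix:
    """Glomerulus-by-odor mean firing rates (Hz) for one cell class."""

    rates: pd.DataFrame                 # glomerulus rows x odor columns
    per_neuron: pd.DataFrame | None = None  # neuron rows x odor columns
    cell_class: str = "uPN"

    def as_vector(self) -> np.ndarray:
        """Flatten glomerulus-major (all odors of glom 1, then glom 2, ...)."""
        return self.rates.to_numpy().ravel()

    @property
    def feature_labels(self) -> list[str]:
        return [f"{g}:{o}" for g in self.rates.index for o in self.rates.columns]


@njit(cache=True)
def _lif_kernel(
    n_steps,
    dt,
    V_rest,
    R,
    C,
    V_thr,
    cls_idx,
    templates,
    tmpl_len,
    W_T,
    kick_steps,
    kick_neurons,
    kick_amp,
    syn_decay,
    store_v,
    I_ext,
    V_init,
):
    n = V_rest.shape[0]
    V = V_init.copy()
    I_out = np.zeros(n)
    phase = np.full(n, -1, np.int64)
    cap = 0
    for i in range(n):
        cap += n_steps // tmpl_len[cls_idx[i]] + 1
    spk_n = np.empty(cap, np.int64)
    spk_t = np.empty(cap, np.int64)
    n_spk = 0
    trace = np.empty((n_steps if store_v else 1, n))
    kick = np.zeros(n)
    kp = 0
    for t in range(n_steps):
        I_in = np.dot(W_T, I_out)
        for j in range(n):
            I_out[j] *= syn_decay
        while kp < kick_steps.size and kick_steps[kp] == t:
            kick[kick_neurons[kp]] += kick_amp
            kp += 1
        for i in range(n):
            c = cls_idx[i]
            if phase[i] >= 0:
                V[i] = templates[c, phase[i]]
                phase[i] += 1
                if phase[i] >= tmpl_len[c]:
                    phase[i] = -1
            else:
                I_tot = I_in[i] + kick[i] + I_ext[i]
                V[i] += dt * ((V_rest[i] - V[i]) / R[i] + I_tot) / C[i]
                if not np.isfinite(V[i]):
                    return spk_n[:n_spk], spk_t[:n_spk], trace, i, t
                if V[i] >= V_thr[i]:
                    spk_n[n_spk] = i
                    spk_t[n_spk] = t
                    n_spk += 1
                    V[i] = templates[c, 0]
                    phase[i] = 1
                    if tmpl_len[c] <= 1:
                        phase[i] = -1
                    I_out[i] += 1.0
            kick[i] = 0.0
        if store_v:
            for i in range(n):
                trace[t, i] = V[i]
    return spk_n[:n_spk], spk_t[:n_spk], trace, -1, -1


def _ap_template(params: CellClassParams, dt: float) -> np.ndarray:
    """Piecewise-linear AP waveform sampled at dt: V_thr -> ap_max -> ap_min."""
    L = params.ap_duration / dt
    if abs(L - round(L)) > 1e-9:
        raise ValueError(
            f"dt={dt} ms does not divide the {params.ap_duration} ms action-potential template"
        )
    L = int(round(L))
    t = np.arange(1, L + 1) * dt
    half = params.ap_duration / 2.0
    rise = params.threshold + (params.ap_max - params.threshold) * (t / half)
    fall = params.ap_max + (params.ap_min - params.ap_max) * ((t - half) / half)
    return np.where(t <= half, rise, fall)


def _class_param_lookup(
    roster: NeuronRoster, cell_params: dict[str, CellClassParams]
) -> tuple[np.ndarray, dict[str, int]]:
    """Map each neuron to its parameter record (uPN/mPN share 'PN')."""
    key_of = {"ORN": "ORN", "LN": "LN", "uPN": "PN", "mPN": "PN"}
    keys = sorted(set(key_of.values()))
    key_index = {k: i for i, k in enumerate(keys)}
    cls_idx = np.array([key_index[key_of[c]] for c in roster.cell_class], dtype=np.int64)
    return cls_idx, key_index


def simulate(
    weights: SignedWeightMatrix,
    orn_spike_schedules: dict[int, np.ndarray],
    duration: float,
    dt: float = DEFAULT_DT,
    cell_params: dict[str, CellClassParams] | None = None,
    drive: DriveParams | None = None,
    tau_syn: float = DEFAULT_TAU_SYN,
    store_voltages: bool = False,
    protocol: StimulusProtocol | None = None,
    external_current: np.ndarray | None = None,
    initial_voltage: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the network for ``duration`` ms.

    ``orn_spike_schedules`` maps neuron index -> array of scheduled spike
    times (ms); each is forced by a one-step kick current.
    ``external_current`` (pA, per neuron) is a constant injected current;
    ``initial_voltage`` overrides the resting-potential initial condition.
    """
    cp = cell_params or TABLE_CELL_PARAMS
    dp = drive or DriveParams()
    roster = weights.roster
    n = len(roster)
    n_steps = int(round(duration / dt))

    cls_idx, key_index = _class_param_lookup(roster, cp)
    n_cls = len(key_index)
    tmpls = [_ap_template(cp[k], dt) for k in sorted(key_index, key=key_index.get)]
    max_len = max(len(t) for t in tmpls)
    templates = np.zeros((n_cls, max_len))
    tmpl_len = np.zeros(n_cls, dtype=np.int64)
    for k, t in enumerate(tmpls):
        templates[k, : len(t)] = t
        tmpl_len[k] = len(t)

    V_rest = np.empty(n)
    R = np.empty(n)
    C = np.empty(n)
    V_thr = np.empty(n)
    for k, key in enumerate(sorted(key_index, key=key_index.get)):
        sel = cls_idx == k
        V_rest[sel] = cp[key].resting_potential
        R[sel] = cp[key].resistance
        C[sel] = cp[key].capacitance
        V_thr[sel] = cp[key].threshold

    events = []
    for idx, times in orn_spike_schedules.items():
        steps = np.asarray(np.round(np.asarray(times) / dt), dtype=np.int64)
        if np.any((steps < 0) | (steps >= n_steps)):
            raise ValueError("scheduled spike outside the simulated duration")
        for s in steps:
            events.append((s, idx))
    if events:
        events.sort()
        kick_steps = np.array([e[0] for e in events], dtype=np.int64)
        kick_neurons = np.array([e[1] for e in events], dtype=np.int64)
    else:
        kick_steps = np.empty(0, dtype=np.int64)
        kick_neurons = np.empty(0, dtype=np.int64)

    W_T = np.ascontiguousarray(weights.effective_weights.T)
    syn_decay = float(np.exp(-dt / tau_syn))
    spk_n, spk_t, trace, bad_i, bad_t = _lif_kernel(
        n_steps,
        dt,
        V_rest,
        R,
        C,
        V_thr,
        cls_idx,
        templates,
        tmpl_len,
        W_T,
        kick_steps,
        kick_neurons,
        float(dp.kick_current),
        syn_decay,
        store_voltages,
        np.zeros(n) if external_current is None else np.asarray(external_current, dtype=float),
        V_rest if initial_voltage is None else np.asarray(initial_voltage, dtype=float),
    )
    if bad_i >= 0:
        raise FloatingPointError(
            f"non-finite voltage for neuron {roster.ids[bad_i]!r} at t={bad_t * dt:.3f} ms"
        )
    return SimulationResult(
        neuron_ids=roster.ids,
        spike_neurons=spk_n,
        spike_steps=spk_t,
        dt=dt,
        duration=duration,
        protocol=protocol,
        voltage_traces=trace if store_voltages else None,
    )


def compute_firing_rates(result: SimulationResult, window: tuple[float, float]) -> np.ndarray:
    """Per-neuron rate (Hz) from spike counts in the half-open window [start, end)."""
    start, end = window
    if end <= start:
        raise ValueError("window must have positive length")
    if start < 0 or end > result.duration + 1e-9:
        raise ValueError("window outside the simulated duration")
    t = result.spike_times
    sel = (t >= start) & (t < end)
    counts = np.bincount(result.spike_neurons[sel], minlength=len(result.neuron_ids))
    return counts / ((end - start) / 1000.0)


def run_odor_panel(
    weights: SignedWeightMatrix,
    D_matrix: pd.DataFrame,
    protocol: StimulusProtocol,
    drive: DriveParams | None = None,
    seed: int | np.random.Generator = 0,
    dt: float = DEFAULT_DT,
    cell_params: dict[str, CellClassParams] | None = None,
    tau_syn: float = DEFAULT_TAU_SYN,
    baseline_subtract: bool = False,
    readout_classes: tuple[str, ...] = ("uPN", "ORN"),
) -> dict[str, ResponseMatrix]:
    """Simulate one continuous run over the odor panel and reduce to responses.

    Each odor is presented for ``protocol.on_duration`` ms with odor-free
    gaps; per-odor rates are computed over the odor window; the glomerular
    response is the mean rate over that glomerulus's neurons of the readout
    class.  Returns one ResponseMatrix per requested class.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dp = drive or DriveParams()
    roster = weights.roster
    rates, gloms = orn_rate_profiles(D_matrix, protocol, dt, dp)
    glom_row = {g: k for k, g in enumerate(gloms)}
    n_steps = rates.shape[1]

    schedules: dict[int, np.ndarray] = {}
    for idx in roster.index_of("ORN"):
        g = roster.glomerulus[idx]
        if g not in glom_row:
            # glomerulus absent from the response matrix: spontaneous only
            profile = np.full(n_steps, dp.spontaneous_rate)
        else:
            profile = rates[glom_row[g]]
        p = profile * dt / 1000.0
        hits = rng.random(n_steps) < p
        schedules[int(idx)] = np.flatnonzero(hits) * dt

    result = simulate(
        weights,
        schedules,
        duration=protocol.total_duration,
        dt=dt,
        cell_params=cell_params,
        drive=dp,
        tau_syn=tau_syn,
        protocol=protocol,
    )

    out: dict[str, ResponseMatrix] = {}
    windows = protocol.odor_windows()
    baseline = None
    if baseline_subtract and protocol.lead_in > 0:
        baseline = compute_firing_rates(result, (0.0, protocol.lead_in))
    roster_gloms = roster.glomeruli
    for cls in readout_classes:
        idx = roster.index_of(cls)
        per_odor = np.empty((len(idx), len(windows)))
        for k, (_, on, off) in enumerate(windows):
            r = compute_firing_rates(result, (on, off))
            if baseline is not None:
                r = r - baseline
            per_odor[:, k] = r[idx]
        odor_names = [w[0] for w in windows]
        per_neuron = pd.DataFrame(per_odor, index=roster.ids[idx], columns=odor_names)
        glom_rates = np.full((len(roster_gloms), len(windows)), np.nan)
        neuron_gloms = roster.glomerulus[idx]
        for gi, g in enumerate(roster_gloms):
            members = neuron_gloms == g
            if members.any():
                glom_rates[gi] = per_odor[members].mean(axis=0)
        rates_df = pd.DataFrame(glom_rates, index=roster_gloms, columns=odor_names)
        out[cls] = ResponseMatrix(rates=rates_df, per_neuron=per_neuron, cell_class=cls)
    return out
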