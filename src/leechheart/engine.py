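"""Fixed-step integration of the bilateral motor neuron ensemble.

The four seven-compartment neurons are integrated with a semi-implicit
scheme: gating variables advance by exponential Euler using tabulated
steady-state and time-constant curves evaluated at the pre-step voltage,
and the compartmental cable equation is then solved implicitly (trapezoid
rule, theta = 1/2) with the channel conductances frozen over the step.
Synaptic input enters as precomputed playback conductance waveforms at the
synaptic compartment; bilateral electrical coupling is applied explicitly
from the pre-step voltages, which makes the two coupling currents exactly
equal and opposite at every step.

All quantities are held internally in mV / nS / nF / pA / s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .circuit import COMPARTMENTS, PARENT, EnsembleCircuit
from .errors import ConfigurationError, InputError, SimulationInstabilityError
from .synapses import conduction_delay, synaptic_conductance_waveform

__all__ = ["SimulationResult", "simulate"]

_COMP_INDEX = {name: i for i, name in enumerate(COMPARTMENTS)}
_SYN_COMP = _COMP_INDEX["synaptic"]

# voltage table grid
_VMIN, _VMAX, _DV = -150.0, 100.0, 0.05
_NV = int(round((_VMAX - _VMIN) / _DV)) + 1


def _sigmoid(v, vhalf, k):
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / k))


def _tau_curve(v, tau0, tau1, vhalf, k):
    s = _sigmoid(v, vhalf, abs(k))
    return tau0 + 4.0 * tau1 * s * (1.0 - s)


@dataclass
class _Packed:
    """Flat array view of one circuit for the numba kernel."""

    cm: np.ndarray
    gl: np.ndarray
    el: np.ndarray
    edge_child: np.ndarray
    edge_parent: np.ndarray
    edge_w: np.ndarray
    elim_child: np.ndarray
    elim_parent: np.ndarray
    elim_w: np.ndarray
    inst_comp: np.ndarray
    inst_gbar: np.ndarray
    inst_erev: np.ndarray
    inst_pexp: np.ndarray
    inst_kind: np.ndarray
    inst_feeds: np.ndarray
    inst_mrow: np.ndarray
    inst_hrow: np.ndarray
    pool_of_comp: np.ndarray
    ca_tau: float
    ca_gain: float
    ca_kd: float
    gate_rows: list  # (vhalf, k, tau0, tau1, tvh, tk) per gate row


def _pack(circuit: EnsembleCircuit) -> _Packed:
    if circuit.params is None:
        raise ConfigurationError("apply a parameter set before simulating")
    n = len(COMPARTMENTS)
    cm = np.empty(n)
    gl = np.empty(n)
    el = np.empty(n)
    for name, i in _COMP_INDEX.items():
        spec = circuit.compartments[name]
        cm[i] = spec.cm_nF
        gl[i] = spec.g_leak_nS
        el[i] = spec.leak_reversal

    edge_child, edge_parent, edge_w = [], [], []
    for child, parent in PARENT.items():
        edge_child.append(_COMP_INDEX[child])
        edge_parent.append(_COMP_INDEX[parent])
        edge_w.append(circuit.compartments[child].axial_conductance_to_parent)

    # leaves-to-root edge ordering for fill-in-free tree elimination
    children_left = {c: 0 for c in range(n)}
    for p in edge_parent:
        children_left[p] += 1
    order = []
    pending = list(range(len(edge_child)))
    while pending:
        for k in pending:
            if children_left[edge_child[k]] == 0:
                order.append(k)
                pending.remove(k)
                children_left[edge_parent[k]] -= 1
                break
        else:  # pragma: no cover - PARENT is a tree by construction
            raise ConfigurationError("compartment connectivity is not a tree")

    pool_of_comp = np.full(n, -1, dtype=np.int64)
    npool = 0
    for name, i in _COMP_INDEX.items():
        chans = circuit.compartments[name].channel_names
        if any(
            circuit.channels[c].feeds_calcium or circuit.channels[c].calcium_gated
            for c in chans
        ):
            pool_of_comp[i] = npool
            npool += 1

    gate_rows = []

    def _gate_row(vhalf, k, tau0, tau1, tvh, tk):
        key = (vhalf, k, tau0, tau1, tvh, tk)
        for r, existing in enumerate(gate_rows):
            if existing == key:
                return r
        gate_rows.append(key)
        return len(gate_rows) - 1

    inst = {k: [] for k in ("comp", "gbar", "erev", "pexp", "kind", "feeds", "mrow", "hrow")}
    for name, i in _COMP_INDEX.items():
        for cname in circuit.compartments[name].channel_names:
            ch = circuit.channels[cname]
            inst["comp"].append(i)
            inst["gbar"].append(circuit.channel_gbar_nS(name, cname))
            inst["erev"].append(ch.reversal)
            inst["pexp"].append(ch.exponent)
            inst["feeds"].append(1 if ch.feeds_calcium else 0)
            if ch.calcium_gated:
                inst["kind"].append(1)
                inst["mrow"].append(-1)
                inst["hrow"].append(-1)
            else:
                inst["kind"].append(0)
                inst["mrow"].append(
                    _gate_row(ch.m_vhalf, ch.m_k, ch.m_tau0, ch.m_tau1,
                              ch.m_tau_vhalf, ch.m_tau_k)
                )
                inst["hrow"].append(
                    _gate_row(ch.h_vhalf, ch.h_k, ch.h_tau0, ch.h_tau1,
                              ch.h_tau_vhalf, ch.h_tau_k)
                    if ch.has_inactivation
                    else -1
                )

    cal = circuit.config.get("calcium", {})
    return _Packed(
        cm=cm,
        gl=gl,
        el=el,
        edge_child=np.array(edge_child, dtype=np.int64),
        edge_parent=np.array(edge_parent, dtype=np.int64),
        edge_w=np.array(edge_w, dtype=float),
        elim_child=np.array([edge_child[k] for k in order], dtype=np.int64),
        elim_parent=np.array([edge_parent[k] for k in order], dtype=np.int64),
        elim_w=np.array([edge_w[k] for k in order], dtype=float),
        inst_comp=np.array(inst["comp"], dtype=np.int64),
        inst_gbar=np.array(inst["gbar"], dtype=float),
        inst_erev=np.array(inst["erev"], dtype=float),
        inst_pexp=np.array(inst["pexp"], dtype=np.int64),
        inst_kind=np.array(inst["kind"], dtype=np.int64),
        inst_feeds=np.array(inst["feeds"], dtype=np.int64),
        inst_mrow=np.array(inst["mrow"], dtype=np.int64),
        inst_hrow=np.array(inst["hrow"], dtype=np.int64),
        pool_of_comp=pool_of_comp,
        ca_tau=cal.get("tau_s", 0.3),
        ca_gain=cal.get("gain", 0.1),
        ca_kd=cal.get("kd", 0.5),
        gate_rows=gate_rows,
    )


def _gate_tables(gate_rows, dt):
    """Tabulate steady states and per-step decay factors on the V grid."""
    v = _VMIN + _DV * np.arange(_NV)
    nrow = len(gate_rows)
    tab_inf = np.empty((nrow, _NV))
    tab_edt = np.empty((nrow, _NV))
    for r, (vhalf, k, tau0, tau1, tvh, tk) in enumerate(gate_rows):
        tab_inf[r] = _sigmoid(v, vhalf, k)
        tau = _tau_curve(v, tau0, tau1, tvh, tk)
        tab_edt[r] = np.exp(-dt / tau)
    return tab_inf, tab_edt


@njit(cache=True, fastmath=True)
def _run(
    nsteps, dt, theta,
    V, m, h, ca,
    cm, gl, el,
    edge_child, edge_parent, edge_w,
    elim_child, elim_parent, elim_w,
    inst_comp, inst_gbar, inst_erev, inst_pexp, inst_kind, inst_feeds,
    inst_mrow, inst_hrow,
    pool_of_comp, ca_decay, ca_coef, ca_kd,
    tab_inf, tab_edt,
    gsyn, esyn, gsynE, partner, syn_comp,
    rec_every, Vout, Isyn_out,
):
    nn = V.shape[0]
    nc = V.shape[1]
    ninst = inst_comp.shape[0]
    nedge = edge_child.shape[0]
    npool = ca.shape[1]
    nv = tab_inf.shape[1]
    inv_dv = 1.0 / _DV

    wsum = np.zeros(nc)
    for e in range(nedge):
        wsum[edge_child[e]] += edge_w[e]
        wsum[edge_parent[e]] += edge_w[e]

    Vold = np.empty((nn, nc))
    gtot = np.empty(nc)
    bE = np.empty(nc)
    influx = np.empty(npool)
    diag = np.empty(nc)
    b = np.empty(nc)

    # record initial state
    for n in range(nn):
        for c in range(nc):
            Vout[n, c, 0] = V[n, c]
        Isyn_out[n, 0] = gsyn[n, 0] * (esyn - V[n, syn_comp])

    for s in range(nsteps):
        for n in range(nn):
            for c in range(nc):
                Vold[n, c] = V[n, c]
        for n in range(nn):
            for c in range(nc):
                gtot[c] = gl[c]
                bE[c] = gl[c] * el[c]
            for p in range(npool):
                influx[p] = 0.0

            for i in range(ninst):
                c = inst_comp[i]
                v = Vold[n, c]
                if inst_kind[i] == 0:
                    x = (v - _VMIN) * inv_dv
                    if x < 0.0:
                        x = 0.0
                    elif x > nv - 2:
                        x = float(nv - 2)
                    j = int(x)
                    f = x - j
                    r = inst_mrow[i]
                    minf = tab_inf[r, j] + (tab_inf[r, j + 1] - tab_inf[r, j]) * f
                    ed = tab_edt[r, j] + (tab_edt[r, j + 1] - tab_edt[r, j]) * f
                    mm = minf + (m[n, i] - minf) * ed
                    m[n, i] = mm
                    act = mm
                    for _ in range(inst_pexp[i] - 1):
                        act *= mm
                    rh = inst_hrow[i]
                    if rh >= 0:
                        hinf = tab_inf[rh, j] + (tab_inf[rh, j + 1] - tab_inf[rh, j]) * f
                        ehd = tab_edt[rh, j] + (tab_edt[rh, j + 1] - tab_edt[rh, j]) * f
                        hh = hinf + (h[n, i] - hinf) * ehd
                        h[n, i] = hh
                        act *= hh
                else:
                    cc = ca[n, pool_of_comp[c]]
                    act = cc / (cc + ca_kd)
                    m[n, i] = act
                g = inst_gbar[i] * act
                gtot[c] += g
                bE[c] += g * inst_erev[i]
                if inst_feeds[i] == 1:
                    influx[pool_of_comp[c]] += g * (inst_erev[i] - v)

            for p in range(npool):
                cnew = ca[n, p] * ca_decay + ca_coef * influx[p]
                ca[n, p] = cnew if cnew > 0.0 else 0.0

            gs = gsyn[n, s]
            gtot[syn_comp] += gs
            bE[syn_comp] += gs * esyn

            icpl = gsynE * (Vold[partner[n], syn_comp] - Vold[n, syn_comp])

            for c in range(nc):
                diag[c] = cm[c] / dt + theta * (gtot[c] + wsum[c])
                b[c] = (cm[c] / dt - (1.0 - theta) * (gtot[c] + wsum[c])) * Vold[n, c] \
                    + bE[c]
            for e in range(nedge):
                ci = edge_child[e]
                pi = edge_parent[e]
                w = edge_w[e]
                b[ci] += (1.0 - theta) * w * Vold[n, pi]
                b[pi] += (1.0 - theta) * w * Vold[n, ci]
            b[syn_comp] += icpl

            # tree elimination (edges ordered leaves-to-root: zero fill-in)
            for e in range(nedge):
                ci = elim_child[e]
                pi = elim_parent[e]
                tw = theta * elim_w[e]
                diag[pi] -= tw * tw / diag[ci]
                b[pi] += tw * b[ci] / diag[ci]
            V[n, 0] = b[0] / diag[0]
            for e in range(nedge - 1, -1, -1):
                ci = elim_child[e]
                pi = elim_parent[e]
                V[n, ci] = (b[ci] + theta * elim_w[e] * V[n, pi]) / diag[ci]

            for c in range(nc):
                vv = V[n, c]
                if not (-200.0 < vv < 200.0) or vv != vv:
                    return 1, s, n, c

        if (s + 1) % rec_every == 0:
            k = (s + 1) // rec_every
            for n in range(nn):
                for c in range(nc):
                    Vout[n, c, k] = V[n, c]
                Isyn_out[n, k] = gsyn[n, s + 1] * (esyn - V[n, syn_comp])

    return 0, nsteps, -1, -1


@dataclass
class SimulationResult:
    """Recorded traces of one ensemble simulation.

    ``V`` has shape (neuron, compartment, time) in mV on the uniform grid
    ``t``; ``i_syn`` is the total inhibitory synaptic current per neuron in
    nA; ``g_connections`` optionally holds per-connection conductance
    waveforms in nS at the recording rate.
    """

    t: np.ndarray
    V: np.ndarray
    i_syn: np.ndarray
    neurons: tuple
    compartments: tuple
    assignment: dict
    g_connections: dict = None
    #: final gating/calcium state (m, h, ca) — diagnostics only
    final_state: tuple = None

    def _neuron_index(self, side: str, label: str) -> int:
        try:
            return self.neurons.index((side, label))
        except ValueError:
            raise InputError(f"no neuron {side}/{label}") from None

    def voltage(self, side: str, label: str, compartment: str = "soma") -> np.ndarray:
        return self.V[self._neuron_index(side, label), _COMP_INDEX[compartment]]

    def soma_voltage(self, side: str, label: str) -> np.ndarray:
        return self.voltage(side, label, "soma")

    @property
    def fs(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def to_frame(self):
        """Long-format DataFrame (time, side, neuron, compartment, mV)."""
        import pandas as pd

        rows = {}
        for i, (side, label) in enumerate(self.neurons):
            for cname, ci in _COMP_INDEX.items():
                rows[f"{side}.{label}.{cname}"] = self.V[i, ci]
        df = pd.DataFrame(rows)
        df.insert(0, "time_s", self.t)
        return df


def _initial_state(packed: _Packed, v0: float):
    nn = 4
    ninst = packed.inst_comp.shape[0]
    npool = int(packed.pool_of_comp.max()) + 1
    m = np.zeros((nn, ninst))
    h = np.zeros((nn, ninst))
    for i in range(ninst):
        if packed.inst_kind[i] == 0:
            vh, k, *_ = packed.gate_rows[packed.inst_mrow[i]]
            m[:, i] = _sigmoid(v0, vh, k)
            if packed.inst_hrow[i] >= 0:
                vh, k, *_ = packed.gate_rows[packed.inst_hrow[i]]
                h[:, i] = _sigmoid(v0, vh, k)
    ca = np.zeros((nn, max(npool, 1)))
    return m, h, ca


def simulate(
    circuit: EnsembleCircuit,
    pattern,
    duration: float,
    step: float = 1e-4,
    coordination_assignment: dict = None,
    record_every: int = None,
    record_connections: bool = False,
    v_init: float = None,
    theta: float = 0.5,
) -> SimulationResult:
    """Integrate the ensemble driven by played-back premotor spike trains.

    One body side receives the peristaltic pattern and the other the
    synchronous pattern (default: left peristaltic, right synchronous).
    Each neuron receives the four ipsilateral premotor trains of its side's
    coordination, delayed by the per-segment conduction delay and converted
    into depression-scaled conductance waveforms.  Deterministic given
    identical inputs and step.

    Raises :class:`SimulationInstabilityError` if any voltage leaves
    (-200, 200) mV, reporting the time and compartment.
    """
    if coordination_assignment is None:
        coordination_assignment = {"L": "peristaltic", "R": "synchronous"}
    if set(coordination_assignment) != {"L", "R"} or set(
        coordination_assignment.values()
    ) != {"peristaltic", "synchronous"}:
        raise InputError(
            "coordination_assignment must map sides L,R onto the two coordinations"
        )
    if duration <= 0 or step <= 0:
        raise InputError("duration and step must be positive")

    packed = _pack(circuit)
    nsteps = int(round(duration / step))
    if record_every is None:
        record_every = max(1, int(round(5e-4 / step)))
    nrec = nsteps // record_every + 1

    t_grid = np.arange(nsteps + 1) * step
    syn = circuit.synapse
    if circuit.synapse_map is None:
        raise ConfigurationError("circuit has no synapse map")

    gsyn = np.zeros((4, nsteps + 1))
    g_conn = {} if record_connections else None
    for n, (side, label) in enumerate(circuit.neurons):
        coord = coordination_assignment[side]
        for unit in ("HN3", "HN4", "HN6", "HN7"):
            strength_nS = circuit.synapse_map[(unit, label)]
            if strength_nS == 0.0:
                continue
            spikes = pattern.train(unit, coord)
            wave = synaptic_conductance_waveform(
                spikes,
                syn,
                t_grid,
                delay=conduction_delay(unit, label, syn),
                scale=strength_nS / syn.unitary_conductance,
            )
            gsyn[n] += wave
            if record_connections:
                g_conn[(side, label, unit)] = wave[::record_every].copy()

    v0 = v_init if v_init is not None else packed.el[0]
    V = np.full((4, len(COMPARTMENTS)), float(v0))
    m, h, ca = _initial_state(packed, float(v0))

    tab_inf, tab_edt = _gate_tables(packed.gate_rows, step)
    Vout = np.empty((4, len(COMPARTMENTS), nrec))
    Isyn_out = np.empty((4, nrec))
    partner = np.array([2, 3, 0, 1], dtype=np.int64)

    ca_decay = np.exp(-step / packed.ca_tau)
    ca_coef = packed.ca_gain * packed.ca_tau * (1.0 - ca_decay)

    code, s, n, c = _run(
        nsteps, step, theta,
        V, m, h, ca,
        packed.cm, packed.gl, packed.el,
        packed.edge_child, packed.edge_parent, packed.edge_w,
        packed.elim_child, packed.elim_parent, packed.elim_w,
        packed.inst_comp, packed.inst_gbar, packed.inst_erev, packed.inst_pexp,
        packed.inst_kind, packed.inst_feeds, packed.inst_mrow, packed.inst_hrow,
        packed.pool_of_comp, ca_decay, ca_coef, packed.ca_kd,
        tab_inf, tab_edt,
        gsyn, syn.reversal, circuit.g_synE_nS, partner, _SYN_COMP,
        record_every, Vout, Isyn_out,
    )
    if code != 0:
        side, label = circuit.neurons[n]
        raise SimulationInstabilityError(s * step, f"{side}/{label}", COMPARTMENTS[c])

    return SimulationResult(
        t=t_grid[::record_every],
        V=Vout,
        i_syn=Isyn_out * 1e-3,  # pA -> nA
        neurons=tuple(circuit.neurons),
        compartments=COMPARTMENTS,
        assignment=dict(coordination_assignment),
        g_connections=g_conn,
        final_state=(m, h, ca),
    )
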