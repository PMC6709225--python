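"""Construction of the bilateral heart motor neuron ensemble model.

Each heart motor neuron (HE) is a seven-compartment conductance-based model:
a soma, three serially connected primary neurite compartments, a passive
secondary neurite branching from the first primary neurite, a synaptic
compartment hanging off the secondary neurite, and an axon at the end of the
primary neurite chain.  Voltage-gated channels are placed by compartment
class: delayed-rectifier potassium currents K1/K2 in the soma, primary
neurites and axon; the transient KA current in neurites and axon; persistent
sodium P, slow calcium CaS and calcium-dependent potassium KCa in the
neurites; fast sodium Na only in the axon.  The secondary neurite and the
synaptic compartment are passive.

The ensemble circuit contains two bilateral pairs of these neurons, HE(8)
and HE(12) on the left and right sides.  Bilateral partners are electrically
coupled with a conductance g_synE at their synaptic compartments, and each
neuron receives inhibitory synapses from the four ipsilateral premotor
interneurons HN(3,4,6,7).

Maximal conductances are parameterized as percentages of per-compartment
ceiling values, constrained to a 2..100% grid in 2% steps.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, replace

from .errors import ConfigurationError, ValidationError

__all__ = [
    "COMPARTMENTS",
    "PARENT",
    "CHANNELS",
    "CONDUCTANCE_CEILINGS",
    "REFERENCE_PERCENTAGES",
    "PARAMETER_NAMES",
    "G_SYNE_CEILING_NS",
    "CompartmentSpec",
    "ChannelSpec",
    "SynapseSpec",
    "ConductanceParameterSet",
    "EnsembleCircuit",
    "default_config",
    "load_config",
    "save_config",
    "build_ensemble",
    "apply_parameter_set",
    "set_synaptic_strengths",
]

COMPARTMENTS = (
    "soma",
    "primary_neurite_1",
    "primary_neurite_2",
    "primary_neurite_3",
    "axon",
    "secondary_neurite",
    "synaptic",
)

#: Tree connectivity: child -> parent (soma is the root).
PARENT = {
    "primary_neurite_1": "soma",
    "primary_neurite_2": "primary_neurite_1",
    "primary_neurite_3": "primary_neurite_2",
    "axon": "primary_neurite_3",
    "secondary_neurite": "primary_neurite_1",
    "synaptic": "secondary_neurite",
}

CHANNELS = ("Na", "P", "CaS", "K1", "K2", "KA", "KCa")

#: Compartment class used for conductance parameterization.
_COMP_CLASS = {
    "soma": "soma",
    "primary_neurite_1": "neurite",
    "primary_neurite_2": "neurite",
    "primary_neurite_3": "neurite",
    "axon": "axon",
    "secondary_neurite": None,
    "synaptic": None,
}

#: Maximal-conductance ceilings in S/m^2 per (compartment class, channel)
#: parameter.  The delayed-rectifier and A-type ceilings differ between
#: soma, neurites and axon.
CONDUCTANCE_CEILINGS = {
    "soma.K1": 25.0,
    "soma.K2": 25.0,
    "neurite.K1": 375.0,
    "neurite.K2": 375.0,
    "neurite.KA": 50.0,
    "neurite.P": 9.5,
    "neurite.CaS": 0.5,
    "neurite.KCa": 50.0,
    "axon.Na": 3500.0,
    "axon.K1": 500.0,
    "axon.K2": 500.0,
    "axon.KA": 750.0,
}

#: Ceiling of the bilateral electrical coupling, an absolute conductance.
G_SYNE_CEILING_NS = 10.0

#: Conductance parameter names: the 12 (class, channel) pairs plus "synE".
PARAMETER_NAMES = tuple(sorted(CONDUCTANCE_CEILINGS)) + ("synE",)

#: Reference model instance: percentages of ceiling for the selected model.
REFERENCE_PERCENTAGES = {
    "soma.K1": 8,
    "soma.K2": 92,
    "neurite.K1": 56,
    "neurite.K2": 4,
    "neurite.KA": 32,
    "neurite.P": 18,
    "neurite.CaS": 72,
    "neurite.KCa": 4,
    "synE": 22,
    "axon.Na": 76,
    "axon.K1": 4,
    "axon.K2": 96,
    "axon.KA": 80,
}

NEURONS = (("L", "HE8"), ("L", "HE12"), ("R", "HE8"), ("R", "HE12"))
#: Index pairs of bilaterally coupled neurons in NEURONS order.
COUPLING_PAIRS = ((0, 2), (1, 3))


@dataclass(frozen=True)
class CompartmentSpec:
    """Passive properties and channel placement of one compartment."""

    name: str
    area_m2: float
    membrane_capacitance: float  # F/m^2
    leak_conductance: float  # S/m^2
    leak_reversal: float  # mV
    axial_conductance_to_parent: float  # nS; 0 for the root (soma)
    channel_names: tuple

    @property
    def cm_nF(self) -> float:
        return self.membrane_capacitance * self.area_m2 * 1e9

    @property
    def g_leak_nS(self) -> float:
        return self.leak_conductance * self.area_m2 * 1e9


@dataclass(frozen=True)
class ChannelSpec:
    """Hodgkin-Huxley style gating description of one channel type.

    Steady-state curves are sigmoids ``1/(1+exp(-(V-vhalf)/k))`` (``k < 0``
    gives a falling curve for inactivation); voltage-dependent time constants
    are bell-shaped, ``tau0 + 4*tau1*s*(1-s)`` with ``s`` a sigmoid.  KCa is
    gated by the compartmental calcium pool instead of voltage.
    """

    name: str
    reversal: float  # mV
    exponent: int = 1
    m_vhalf: float = 0.0
    m_k: float = 1.0
    m_tau0: float = 1e-3
    m_tau1: float = 0.0
    m_tau_vhalf: float = 0.0
    m_tau_k: float = 1.0
    has_inactivation: bool = False
    h_vhalf: float = 0.0
    h_k: float = -1.0
    h_tau0: float = 1e-3
    h_tau1: float = 0.0
    h_tau_vhalf: float = 0.0
    h_tau_k: float = 1.0
    calcium_gated: bool = False  # KCa: activation = ca/(ca + kd)
    feeds_calcium: bool = False  # CaS: its current charges the calcium pool


@dataclass(frozen=True)
class SynapseSpec:
    """Inhibitory playback synapse with single-factor short-term depression."""

    reversal: float = -62.5  # mV
    rise_tau: float = 0.005  # s
    decay_tau: float = 0.08  # s
    unitary_conductance: float = 25.0  # nS at full weight, before multipliers
    depression_increment: float = 0.1  # per-spike multiplicative decrement
    depression_recovery_tau: float = 0.5  # s
    delay_per_segment: float = 0.020  # s of conduction delay per segment


def _sigmoid_params(d, prefix):
    return {
        f"{prefix}_vhalf": d["vhalf"],
        f"{prefix}_k": d["k"],
        f"{prefix}_tau0": d["tau0"],
        f"{prefix}_tau1": d.get("tau1", 0.0),
        f"{prefix}_tau_vhalf": d.get("tau_vhalf", d["vhalf"]),
        f"{prefix}_tau_k": d.get("tau_k", abs(d["k"])),
    }


def channel_spec_from_config(name: str, d: dict) -> ChannelSpec:
    kw = dict(
        name=name,
        reversal=d["reversal_mV"],
        exponent=d.get("exponent", 1),
        calcium_gated=d.get("calcium_gated", False),
        feeds_calcium=d.get("feeds_calcium", False),
    )
    if "m" in d:
        kw.update(_sigmoid_params(d["m"], "m"))
    if "h" in d:
        kw["has_inactivation"] = True
        kw.update(_sigmoid_params(d["h"], "h"))
    return ChannelSpec(**kw)


# ---------------------------------------------------------------------------
# default configuration (geometry, passive parameters, kinetics)
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """The shipped circuit description: geometry, passive parameters,
    channel placement and default gating kinetics.

    The kinetics are a generic Hodgkin-Huxley parameterization chosen so
    that the reference conductance set produces tonic spiking that is
    sculpted into anti-phase bursts by the inhibitory premotor input.  All
    values are plain data and can be overridden via a JSON config file.
    """
    comp = {
        "soma": dict(area_m2=6.0e-9, axial_nS=0.0,
                     channels=["K1", "K2"]),
        "primary_neurite_1": dict(area_m2=3.0e-9, axial_nS=200.0,
                                  channels=["K1", "K2", "KA", "P", "CaS", "KCa"]),
        "primary_neurite_2": dict(area_m2=3.0e-9, axial_nS=200.0,
                                  channels=["K1", "K2", "KA", "P", "CaS", "KCa"]),
        "primary_neurite_3": dict(area_m2=3.0e-9, axial_nS=200.0,
                                  channels=["K1", "K2", "KA", "P", "CaS", "KCa"]),
        "axon": dict(area_m2=2.0e-9, axial_nS=150.0, channels=["Na", "K1", "K2", "KA"]),
        "secondary_neurite": dict(area_m2=1.5e-9, axial_nS=60.0, channels=[]),
        "synaptic": dict(area_m2=1.0e-9, axial_nS=50.0, channels=[]),
    }
    for d in comp.values():
        d.setdefault("cm_F_per_m2", 0.01)
        d.setdefault("g_leak_S_per_m2", 1.0)
        d.setdefault("e_leak_mV", -60.0)

    channels = {
        # fast sodium: low threshold, rapid inactivation -> axonal spikes
        "Na": {
            "reversal_mV": 45.0, "exponent": 3,
            "m": {"vhalf": -38.0, "k": 3.5, "tau0": 1e-4},
            "h": {"vhalf": -40.0, "k": -4.0, "tau0": 2e-3, "tau1": 6e-3,
                  "tau_vhalf": -40.0, "tau_k": 6.0},
        },
        # persistent sodium: subthreshold depolarizing drive (tonic firing)
        "P": {
            "reversal_mV": 45.0, "exponent": 1,
            "m": {"vhalf": -48.0, "k": 4.5, "tau0": 0.01, "tau1": 0.04,
                  "tau_vhalf": -48.0, "tau_k": 8.0},
        },
        # slow calcium: charges the calcium pool that gates KCa
        "CaS": {
            "reversal_mV": 135.0, "exponent": 2, "feeds_calcium": True,
            "m": {"vhalf": -44.0, "k": 5.0, "tau0": 0.02, "tau1": 0.05,
                  "tau_vhalf": -44.0, "tau_k": 8.0},
        },
        # fast delayed rectifier
        "K1": {
            "reversal_mV": -70.0, "exponent": 2,
            "m": {"vhalf": -18.0, "k": 8.0, "tau0": 0.004, "tau1": 0.006,
                  "tau_vhalf": -18.0, "tau_k": 8.0},
        },
        # slow delayed rectifier: the relaxation variable pacing tonic spikes
        "K2": {
            "reversal_mV": -70.0, "exponent": 2,
            "m": {"vhalf": -33.0, "k": 5.0, "tau0": 0.025},
        },
        # transient A-type: inactivated at rest, transient repolarizing force
        "KA": {
            "reversal_mV": -70.0, "exponent": 2,
            "m": {"vhalf": -36.0, "k": 6.0, "tau0": 0.002},
            "h": {"vhalf": -65.0, "k": -3.5, "tau0": 0.03, "tau1": 0.05,
                  "tau_vhalf": -65.0, "tau_k": 8.0},
        },
        "KCa": {"reversal_mV": -70.0, "calcium_gated": True},
    }

    return {
        "schema_version": 1,
        "compartments": comp,
        "channels": channels,
        "calcium": {"tau_s": 0.3, "gain": 0.1, "kd": 0.5},
        "synapse": {
            "reversal_mV": -62.5,
            "rise_tau_s": 0.005,
            "decay_tau_s": 0.08,
            "unitary_nS": 25.0,
            "depression_increment": 0.1,
            "depression_recovery_tau_s": 0.5,
            "delay_s_per_segment": 0.020,
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = json.load(fh)
    if cfg.get("schema_version") != 1:
        raise ConfigurationError(
            f"unsupported schema_version {cfg.get('schema_version')!r}"
        )
    return cfg


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=1)


# ---------------------------------------------------------------------------
# conductance parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductanceParameterSet:
    """Maximal conductances as percentages of per-compartment-class ceilings.

    Percentages live on the grid {2, 4, ..., 100}.  The absolute maximal
    conductance of a channel is ``percentage * ceiling / 100`` (S/m^2 for
    membrane channels; the electrical coupling synE is a percentage of an
    absolute 10 nS ceiling).
    """

    percentages: dict

    def __post_init__(self):
        for name in PARAMETER_NAMES:
            if name not in self.percentages:
                raise ValidationError(f"missing conductance parameter {name!r}")
        for name, pct in self.percentages.items():
            if name not in PARAMETER_NAMES:
                raise ValidationError(f"unknown conductance parameter {name!r}")
            if not (2 <= pct <= 100) or abs(pct / 2 - round(pct / 2)) > 1e-9:
                raise ValidationError(
                    f"{name}={pct} is off the 2..100% grid in 2% steps"
                )

    @classmethod
    def reference(cls) -> "ConductanceParameterSet":
        return cls(dict(REFERENCE_PERCENTAGES))

    def with_updates(self, **updates) -> "ConductanceParameterSet":
        d = dict(self.percentages)
        d.update(updates)
        return ConductanceParameterSet(d)

    def absolute(self, name: str) -> float:
        """Absolute maximal conductance: S/m^2 for channels, nS for synE."""
        pct = self.percentages[name]
        if name == "synE":
            return pct * G_SYNE_CEILING_NS / 100.0
        return pct * CONDUCTANCE_CEILINGS[name] / 100.0

    @property
    def g_synE_nS(self) -> float:
        return self.absolute("synE")


# ---------------------------------------------------------------------------
# the ensemble circuit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleCircuit:
    """Four bilaterally coupled heart motor neuron models plus their synapse
    map.  All four neurons share one compartment/channel description and one
    conductance parameter set; bilateral partners are coupled at their
    synaptic compartments with g_synE."""

    config: dict
    compartments: dict  # name -> CompartmentSpec
    channels: dict  # name -> ChannelSpec
    synapse: SynapseSpec
    params: ConductanceParameterSet = None
    #: absolute synaptic conductance (nS) per ipsilateral connection
    #: (unit, motor neuron); identical on the two sides
    synapse_map: dict = None
    neurons: tuple = NEURONS
    coupling_pairs: tuple = COUPLING_PAIRS

    @property
    def g_synE_nS(self) -> float:
        if self.params is None:
            raise ConfigurationError("no parameter set applied")
        return self.params.g_synE_nS

    def channel_gbar_nS(self, comp_name: str, chan: str) -> float:
        """Absolute maximal conductance of ``chan`` in ``comp_name`` (nS)."""
        if self.params is None:
            raise ConfigurationError("no parameter set applied")
        cls = _COMP_CLASS[comp_name]
        key = f"{cls}.{chan}"
        if key not in CONDUCTANCE_CEILINGS:
            raise ConfigurationError(f"channel {chan} has no ceiling in {comp_name}")
        g_per_m2 = self.params.absolute(key)
        return g_per_m2 * self.compartments[comp_name].area_m2 * 1e9


def build_ensemble(config: dict = None) -> EnsembleCircuit:
    """Build the four-neuron ensemble circuit from a structured description.

    Validates that all seven compartments and all referenced channels are
    present, that the secondary neurite and synaptic compartments carry no
    voltage-gated channels, and that channel placement has a conductance
    ceiling for every (compartment, channel) pair.
    """
    if config is None:
        config = default_config()
    config = copy.deepcopy(config)

    comp_cfg = config.get("compartments", {})
    missing = [c for c in COMPARTMENTS if c not in comp_cfg]
    if missing:
        raise ConfigurationError(f"missing compartment(s): {missing}")
    unknown = [c for c in comp_cfg if c not in COMPARTMENTS]
    if unknown:
        raise ConfigurationError(f"unknown compartment(s): {unknown}")

    chan_cfg = config.get("channels", {})
    channels = {}
    for name, d in chan_cfg.items():
        if name not in CHANNELS:
            raise ConfigurationError(f"unknown channel label {name!r}")
        channels[name] = channel_spec_from_config(name, d)

    compartments = {}
    for name in COMPARTMENTS:
        d = comp_cfg[name]
        chans = tuple(d.get("channels", ()))
        for ch in chans:
            if ch not in channels:
                raise ConfigurationError(
                    f"compartment {name!r} references unknown channel {ch!r}"
                )
            cls = _COMP_CLASS[name]
            if cls is None:
                raise ConfigurationError(
                    f"compartment {name!r} is passive-only and cannot carry "
                    f"voltage-gated channel {ch!r}"
                )
            if f"{cls}.{ch}" not in CONDUCTANCE_CEILINGS:
                raise ConfigurationError(
                    f"channel {ch!r} has no conductance ceiling in {name!r}"
                )
        compartments[name] = CompartmentSpec(
            name=name,
            area_m2=d["area_m2"],
            membrane_capacitance=d["cm_F_per_m2"],
            leak_conductance=d["g_leak_S_per_m2"],
            leak_reversal=d["e_leak_mV"],
            axial_conductance_to_parent=d["axial_nS"],
            channel_names=chans,
        )

    syn = config.get("synapse", {})
    synapse = SynapseSpec(
        reversal=syn.get("reversal_mV", -62.5),
        rise_tau=syn.get("rise_tau_s", 0.005),
        decay_tau=syn.get("decay_tau_s", 0.08),
        unitary_conductance=syn.get("unitary_nS", 10.0),
        depression_increment=syn.get("depression_increment", 0.1),
        depression_recovery_tau=syn.get("depression_recovery_tau_s", 0.5),
        delay_per_segment=syn.get("delay_s_per_segment", 0.020),
    )

    units = ("HN3", "HN4", "HN6", "HN7")
    targets = ("HE8", "HE12")
    synapse_map = {
        (u, he): synapse.unitary_conductance for he in targets for u in units
    }

    return EnsembleCircuit(
        config=config,
        compartments=compartments,
        channels=channels,
        synapse=synapse,
        synapse_map=synapse_map,
    )


def apply_parameter_set(
    circuit: EnsembleCircuit, params: ConductanceParameterSet
) -> EnsembleCircuit:
    """Return the circuit with a conductance parameter set applied to all
    four neurons identically."""
    if not isinstance(params, ConductanceParameterSet):
        params = ConductanceParameterSet(dict(params))
    return replace(circuit, params=params)


def set_synaptic_strengths(circuit: EnsembleCircuit, profile) -> EnsembleCircuit:
    """Set the absolute synapse conductances from a synaptic profile:
    ``g = unitary_conductance * w * rho * sigma`` per connection."""
    g = circuit.synapse.unitary_conductance
    synapse_map = {
        (u, he): g * profile.strength(u, he) for (u, he) in circuit.synapse_map
    }
    return replace(circuit, synapse_map=synapse_map)
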