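"""Premotor spike-train patterns of the heartbeat interneurons.

The four inhibitory premotor heart interneurons HN(3), HN(4), HN(6) and HN(7)
drive the motor neurons HE(8) and HE(12).  A pattern stores, per interneuron
and per coordination mode (peristaltic / synchronous), the spike times
recorded (or generated) from one body side, together with the common cycle
period.  The bilateral input to the ensemble model is constructed by the
standard mirror convention: at any moment one side of the animal is
peristaltic and the other synchronous, so the model plays one coordination's
trains to one side and the other coordination's trains to the other side;
on disk the contralateral side is written by swapping coordination labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .metrics import circular_mean_phase, segment_bursts, wrap_phase

__all__ = [
    "PREMOTOR_UNITS",
    "MOTOR_NEURONS",
    "COORDINATIONS",
    "SIDES",
    "UNIT_SEGMENT",
    "MOTOR_SEGMENT",
    "PremotorPattern",
    "load_pattern_csv",
    "save_pattern_csv",
]

PREMOTOR_UNITS = ("HN3", "HN4", "HN6", "HN7")
MOTOR_NEURONS = ("HE8", "HE12")
COORDINATIONS = ("peristaltic", "synchronous")
SIDES = ("L", "R")

#: Body segment (ganglion) of each cell; used for conduction delays.
UNIT_SEGMENT = {"HN3": 3, "HN4": 4, "HN6": 6, "HN7": 7}
MOTOR_SEGMENT = {"HE8": 8, "HE12": 12}

_OTHER_COORD = {"peristaltic": "synchronous", "synchronous": "peristaltic"}


@dataclass
class PremotorPattern:
    """Spike trains of the four premotor interneurons for both coordinations.

    ``trains`` maps ``(unit, coordination)`` to a strictly increasing array of
    spike times in seconds.  ``period`` is the burst cycle period, shared by
    both coordinations (patterns with a period change between coordinations
    cannot be mirrored into a bilateral pattern and are not representable).
    """

    trains: dict
    period: float
    pm_delta_phi_spec: dict = field(default_factory=dict)  # requested, if generated

    def __post_init__(self):
        for (unit, coord), t in self.trains.items():
            if unit not in PREMOTOR_UNITS:
                raise InputError(f"unknown premotor unit {unit!r}")
            if coord not in COORDINATIONS:
                raise InputError(f"unknown coordination {coord!r}")
            t = np.asarray(t, dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise InputError(
                    f"spike times of {unit}/{coord} must be strictly increasing"
                )
            self.trains[(unit, coord)] = t
        if not self.period > 0:
            raise InputError("period must be positive")

    def train(self, unit: str, coordination: str) -> np.ndarray:
        try:
            return self.trains[(unit, coordination)]
        except KeyError:
            raise InputError(f"no train for {unit}/{coordination}") from None

    def duration(self) -> float:
        return max((t[-1] for t in self.trains.values() if t.size), default=0.0)

    # -- measured phase structure -------------------------------------------

    def burst_medians(self, unit: str, coordination: str, max_isi: float = None,
                      min_spikes: int = 4) -> np.ndarray:
        if max_isi is None:
            # premotor trains fire at ~10 Hz within bursts and pause for a
            # large fraction of the cycle between them; a fifth of a period
            # separates bursts for any duty cycle below ~0.8
            max_isi = 0.2 * self.period
        return segment_bursts(
            self.train(unit, coordination), max_isi=max_isi, min_spikes=min_spikes
        ).median_times

    def unit_phases(self, coordination: str, reference: str = "HN7") -> dict:
        """Mean burst-median phase of each unit relative to ``reference``."""
        ref = self.burst_medians(reference, coordination)
        if ref.size == 0:
            raise InputError(f"reference unit {reference} has no bursts")
        out = {}
        for unit in PREMOTOR_UNITS:
            med = self.burst_medians(unit, coordination)
            phases = []
            for t in med:
                prev = ref[ref <= t]
                if prev.size:
                    phases.append(((t - prev[-1]) / self.period) % 1.0)
            if not phases:
                raise InputError(f"unit {unit} has no analysable bursts")
            out[unit] = circular_mean_phase(phases)
        return out

    def pm_delta_phi(self, coordination: str) -> float:
        """Measured premotor phase progression: the phase spread of the
        premotor bursts, front-most HN(3) minus rear-most HN(7), wrapped into
        (-0.5, 0.5].  This spread is the quantity that upper-bounds the motor
        phase progression."""
        ph = self.unit_phases(coordination)
        return wrap_phase(ph["HN3"] - ph["HN7"])

    def pm_delta_phi_47(self, coordination: str) -> float:
        """The HN(4)-to-HN(7) phase-difference variant of the progression."""
        ph = self.unit_phases(coordination)
        return wrap_phase(ph["HN4"] - ph["HN7"])


def load_pattern_csv(path, period: float, side: str = "L") -> PremotorPattern:
    """Load a premotor pattern from delimited text.

    The file has columns ``unit,side,coordination,time_s`` with one row per
    spike.  Only rows of the requested ``side`` are used; per the mirror
    convention, requesting the side not present in the file returns the
    recorded side's trains with coordination labels swapped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"unit", "side", "coordination", "time_s"}
    if not required.issubset(df.columns):
        raise InputError(f"pattern file must have columns {sorted(required)}")
    present = set(df["side"].unique())
    if side in present:
        sub = df[df["side"] == side]
        swap = False
    elif len(present) == 1:
        sub = df
        swap = True
    else:
        raise InputError(f"side {side!r} not in file (has {sorted(present)})")
    trains = {}
    for (unit, coord), grp in sub.groupby(["unit", "coordination"]):
        c = _OTHER_COORD[coord] if swap else coord
        trains[(unit, c)] = np.sort(grp["time_s"].to_numpy(dtype=float))
    return PremotorPattern(trains, period)


def save_pattern_csv(pattern: PremotorPattern, path, side: str = "L") -> None:
    """Write a pattern as ``unit,side,coordination,time_s`` rows for one side."""
    rows = []
    for (unit, coord), t in sorted(pattern.trains.items()):
        for ts in t:
            rows.append((unit, side, coord, ts))
    pd.DataFrame(rows, columns=["unit", "side", "coordination", "time_s"]).to_csv(
        path, index=False, float_format="%.17g"
    )
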