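"""Relative synaptic strength profiles and their multipliers.

Synaptic strengths measured by spike-triggered averaging are expressed per
motor neuron in relative terms: the four inputs onto one HE are normalized
by that HE's largest input, so the maximum is 1.  Absolute conductances used
in simulation are recovered through two kinds of multipliers: a global
per-motor-neuron multiplier sigma that scales all of one HE's inputs
together, and individual per-connection multipliers rho that adjust single
strengths around the recorded averages (typically bounded to within one
within-animal SD of the measurement).  The absolute synapse conductance of a
connection is proportional to ``w * rho * sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateProfileError, ValidationError

__all__ = ["CONNECTIONS", "SynapticProfile", "load_profile_csv", "save_profile_csv"]

_UNITS = ("HN3", "HN4", "HN6", "HN7")
_TARGETS = ("HE8", "HE12")

#: The eight ipsilateral premotor connections (unit, motor neuron).
CONNECTIONS = tuple((u, he) for he in _TARGETS for u in _UNITS)


@dataclass(frozen=True)
class SynapticProfile:
    """Relative weights w per connection with SDs and sigma/rho multipliers."""

    w: dict  # (unit, he) -> relative strength, >= 0
    sd: dict = None  # (unit, he) -> within-animal SD on the same scale
    sigma: dict = None  # he -> global multiplier
    rho: dict = None  # (unit, he) -> individual multiplier

    def __post_init__(self):
        if set(self.w) != set(CONNECTIONS):
            raise ValidationError(
                f"profile must define exactly the connections {CONNECTIONS}"
            )
        for k, v in self.w.items():
            if v < 0:
                raise ValidationError(f"w{k} must be >= 0, got {v}")
        object.__setattr__(
            self, "sd", dict(self.sd) if self.sd else {k: 0.0 for k in CONNECTIONS}
        )
        object.__setattr__(
            self,
            "sigma",
            dict(self.sigma) if self.sigma else {he: 1.0 for he in _TARGETS},
        )
        object.__setattr__(
            self, "rho", dict(self.rho) if self.rho else {k: 1.0 for k in CONNECTIONS}
        )

    @classmethod
    def uniform(cls) -> "SynapticProfile":
        """All eight relative weights equal to 1 (unit multipliers)."""
        return cls({k: 1.0 for k in CONNECTIONS})

    @classmethod
    def from_amplitudes(cls, amplitudes: dict, sds: dict = None) -> "SynapticProfile":
        """Normalize absolute per-connection amplitudes so each HE's largest
        input has relative strength 1; SDs are scaled by the same factor."""
        w, sd = {}, {}
        for he in _TARGETS:
            amps = {u: float(amplitudes[(u, he)]) for u in _UNITS}
            peak = max(amps.values())
            if peak <= 0:
                raise DegenerateProfileError(f"all-zero amplitudes for {he}")
            for u in _UNITS:
                w[(u, he)] = amps[u] / peak
                sd[(u, he)] = float(sds[(u, he)]) / peak if sds else 0.0
        return cls(w, sd)

    def strength(self, unit: str, he: str) -> float:
        """Net dimensionless strength multiplier of one connection:
        ``w * rho * sigma``."""
        return self.w[(unit, he)] * self.rho[(unit, he)] * self.sigma[he]

    def with_sigma(self, **sigma) -> "SynapticProfile":
        s = dict(self.sigma)
        s.update(sigma)
        return replace(self, sigma=s)

    def with_rho(self, rho: dict) -> "SynapticProfile":
        r = dict(self.rho)
        r.update(rho)
        return replace(self, rho=r)

    def rho_bounds(self) -> dict:
        """Per-connection bounds for the individual multipliers: the fitted
        strength ``w * rho`` may vary within +-1 SD of the measured average,
        floored at zero, so rho is bounded to [max(0, w-sd)/w, (w+sd)/w]
        (connections with w == 0 are pinned to rho = 1)."""
        out = {}
        for k in CONNECTIONS:
            w, sd = self.w[k], self.sd[k]
            if w <= 0:
                out[k] = (1.0, 1.0)
            else:
                out[k] = (max(0.0, w - sd) / w, (w + sd) / w)
        return out

    def fitted_weights(self) -> dict:
        """The rho-adjusted relative weights ``w * rho`` per connection."""
        return {k: self.w[k] * self.rho[k] for k in CONNECTIONS}


def load_profile_csv(path) -> SynapticProfile:
    """Read a profile from columns ``unit,target,w,sd[,rho]`` (+ optional
    ``sigma_HE8``/``sigma_HE12`` scalar columns repeated on each row)."""
    df = pd.read_csv(path)
    w = {(r.unit, r.target): float(r.w) for r in df.itertuples()}
    sd = {(r.unit, r.target): float(getattr(r, "sd", 0.0)) for r in df.itertuples()}
    rho = None
    if "rho" in df.columns:
        rho = {(r.unit, r.target): float(r.rho) for r in df.itertuples()}
    sigma = None
    if "sigma_HE8" in df.columns:
        sigma = {
            "HE8": float(df["sigma_HE8"].iloc[0]),
            "HE12": float(df["sigma_HE12"].iloc[0]),
        }
    return SynapticProfile(w, sd, sigma, rho)


def save_profile_csv(profile: SynapticProfile, path) -> None:
    rows = []
    for (u, he) in CONNECTIONS:
        rows.append(
            dict(
                unit=u,
                target=he,
                w=profile.w[(u, he)],
                sd=profile.sd[(u, he)],
                rho=profile.rho[(u, he)],
                sigma_HE8=profile.sigma["HE8"],
                sigma_HE12=profile.sigma["HE12"],
            )
        )
    pd.DataFrame(rows).to_csv(path, index=False)
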