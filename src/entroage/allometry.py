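"""Allometric timescale arithmetic for mammalian degradation time.

Mammalian physiology carries two near-universal timescale invariants:

* the lifetime measured in heartbeats, ``T / t_H ~ 1e9`` (humans run 2–3
  times higher);
* the metabolic multiplier ``tau / t_H ~ 30`` linking the heartbeat period
  to the characteristic metabolic reaction time (mouse: t_H = 0.1 s,
  tau = 3 s; elephant: t_H = 2 s, tau = 60 s).

Their quotient ``N = T / tau ~ 3e7`` counts metabolic cycles per lifetime —
the number of fast relaxation events over which slow structural degradation
accumulates, and the scale separation the aging simulator abstracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

__all__ = [
    "TimescaleSet",
    "metabolic_multiplier",
    "lifetime_to_metabolic_ratio",
    "build_timescales",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ParameterError(f"{name} must be strictly positive, got {value}")


def metabolic_multiplier(t_H: float, tau: float) -> float:
    """Ratio tau / t_H of metabolic time to heartbeat period (~30 for
    mammals)."""
    _require_positive(t_H=t_H, tau=tau)
    return tau / t_H


def lifetime_to_metabolic_ratio(beats_per_lifetime: float,
                                multiplier: float) -> float:
    """N = T / tau from the beats-per-lifetime invariant and the metabolic
    multiplier: (T/t_H) / (tau/t_H)."""
    _require_positive(beats_per_lifetime=beats_per_lifetime,
                      multiplier=multiplier)
    return beats_per_lifetime / multiplier


@dataclass(frozen=True)
class TimescaleSet:
    """Consistent set of degradation timescales.

    t_H — heartbeat period [s]; tau — metabolic time [s];
    beats_per_lifetime — T/t_H (dimensionless); multiplier — tau/t_H;
    N — T/tau, metabolic cycles per lifetime; T — lifetime [s].
    """

    t_H: float
    tau: float
    beats_per_lifetime: float
    multiplier: float = field(init=False)
    N: float = field(init=False)
    T: float = field(init=False)

    def __post_init__(self):
        _require_positive(t_H=self.t_H, tau=self.tau,
                          beats_per_lifetime=self.beats_per_lifetime)
        object.__setattr__(self, "multiplier", self.tau / self.t_H)
        object.__setattr__(self, "N", self.beats_per_lifetime / self.multiplier)
        object.__setattr__(self, "T", self.beats_per_lifetime * self.t_H)

    def to_dict(self) -> dict:
        return {
            "t_H_seconds": self.t_H,
            "tau_seconds": self.tau,
            "beats_per_lifetime": self.beats_per_lifetime,
            "multiplier": self.multiplier,
            "N": self.N,
            "T_seconds": self.T,
        }


def build_timescales(t_H: float, tau: float, beats_per_lifetime: float,
                     lifetime_correction: float = 1.0) -> TimescaleSet:
    """Build the full invariant-satisfying timescale set.

    ``lifetime_correction`` scales ``beats_per_lifetime`` for species that
    deviate from the mammalian ~1e9 beats (humans: 2–3); default 1.
    """
    _require_positive(lifetime_correction=lifetime_correction)
    return TimescaleSet(t_H=t_H, tau=tau,
                        beats_per_lifetime=beats_per_lifetime * lifetime_correction)
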