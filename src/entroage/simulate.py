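"""Stochastic compartment simulation of epithelial aging.

The skin surface is divided into identical compartments (40 by default),
each carrying a cell density.  Two processes act on the density field:

* a **fast, chaotic** one — many metabolic acts per unit time, modelled as
  independent multiplicative noise ``value *= 1 + eps``,
  ``eps ~ U(-a, +a)``, which perturbs each compartment while preserving its
  expectation;
* a **slow, systematic** one — age-related thinning, an absolute decrement
  applied every ``slow_every`` fast steps.

Starting from a smooth "young" baseline p(x), the evolving density q(x)
roughens and thins; the Kullback–Leibler divergence D(p||q) tracked along
the run, and its distance |D - 1| from the unit level, are the age
trajectory of the tissue.  In real mammalian tissue the fast and slow
timescales are separated by the invariant N = T/tau ~ 3e7; the simulator
exposes the ratio (``slow_every``) and the per-step rate so that scale
separation can be emulated at desk scale.

A separate generator produces schematic young/old local-entropy-vs-depth
profiles: entropy rises from the basal layer toward the common maximum at
the surface (a dead, peeling cell), with fluctuations that grow with age,
and the old tissue is thinner (L_old < L_young) and everywhere at least as
entropic as the young one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .entropy import deviation_from_unity, kl_divergence
from .errors import ParameterError
from .profiles import DensityProfile, EntropyProfile

__all__ = [
    "AgingSimConfig",
    "SimTrajectory",
    "init_young_profile",
    "metabolic_step",
    "thinning_step",
    "simulate",
    "generate_entropy_schematic",
]


@dataclass
class AgingSimConfig:
    """Run configuration for the compartment aging simulation.

    Defaults: 40 compartments, 500 iterations, relative noise amplitude 0.1,
    absolute thinning 0.002 per slow step, one slow step per fast step, and
    a density floor of 1e-9 — nine decades below the unit baseline, the
    order at which a compartment counts as fully degraded.
    """

    n_compartments: int = 40
    n_iterations: int = 500
    noise_amplitude: float = 0.1
    thinning_rate: float = 0.002
    slow_every: int = 1
    floor: float = 1e-9
    seed: int = 0
    kl_base: float = 10.0
    kl_mode: str = "normalized"
    snapshot_stride: int = 10
    young_shape: str = "constant"      # or "cosine"
    cosine_amplitude: float = 0.05

    def __post_init__(self):
        if self.n_compartments < 1:
            raise ParameterError("n_compartments must be >= 1")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if self.noise_amplitude < 0:
            raise ParameterError("noise_amplitude must be >= 0")
        if self.thinning_rate < 0:
            raise ParameterError("thinning_rate must be >= 0")
        if self.slow_every < 1:
            raise ParameterError("slow_every must be >= 1")
        if not (self.floor > 0):
            raise ParameterError("floor must be > 0")
        if not (self.kl_base > 1):
            raise ParameterError("kl_base must exceed 1")
        if self.kl_mode not in ("normalized", "raw"):
            raise ParameterError("kl_mode must be 'normalized' or 'raw'")
        if self.snapshot_stride < 1:
            raise ParameterError("snapshot_stride must be >= 1")
        if self.young_shape not in ("constant", "cosine"):
            raise ParameterError("young_shape must be 'constant' or 'cosine'")
        if not (0 <= self.cosine_amplitude < 1):
            raise ParameterError("cosine_amplitude must be in [0, 1)")


@dataclass
class SimTrajectory:
    """Recorded output of one simulation run.

    ``snapshots[k]`` is the density profile at ``iterations[k]``;
    ``kl_series[k]`` is D(baseline || snapshot_k) and ``dev_series[k]`` its
    distance |D - 1| from the unit level.  Snapshot 0 is the baseline, so
    ``kl_series[0] == 0`` in normalized mode.
    """

    baseline: DensityProfile
    snapshots: list[DensityProfile]
    iterations: list[int]
    kl_series: np.ndarray
    dev_series: np.ndarray
    seed: int
    config: AgingSimConfig = field(repr=False)

    def __post_init__(self):
        n = len(self.snapshots)
        if not (len(self.iterations) == len(self.kl_series)
                == len(self.dev_series) == n):
            raise ParameterError("trajectory series lengths must match")

    def config_dict(self) -> dict:
        return asdict(self.config)


def init_young_profile(config: AgingSimConfig) -> DensityProfile:
    """Smooth positive baseline density of the young tissue.

    Constant 1.0 by default; the ``cosine`` option superposes a gentle
    half-period modulation of relative amplitude ``cosine_amplitude``.
    """
    n = config.n_compartments
    positions = np.arange(n, dtype=float)
    if config.young_shape == "cosine" and n > 1:
        values = 1.0 + config.cosine_amplitude * np.cos(
            np.pi * positions / (n - 1)
        )
    else:
        values = np.ones(n)
    return DensityProfile(positions=positions, values=values, label="young",
                          floor=config.floor)


def metabolic_step(q: DensityProfile, noise_amplitude: float,
                   rng: np.random.Generator) -> DensityProfile:
    """One fast metabolic step: independent multiplicative noise.

    Each compartment is multiplied by ``1 + eps`` with
    ``eps ~ U(-a, +a)``, then clamped at the floor.  Amplitudes >= 1 are
    rejected (they would admit non-positive factors); the expectation of
    every compartment is unchanged.
    """
    if noise_amplitude < 0:
        raise ParameterError("noise amplitude must be >= 0")
    if noise_amplitude >= 1:
        raise ParameterError(
            f"noise amplitude {noise_amplitude} >= 1 would allow "
            "non-positive density factors"
        )
    if noise_amplitude == 0:
        return q.with_values(q.values.copy())
    factors = 1.0 + rng.uniform(-noise_amplitude, noise_amplitude,
                                size=len(q))
    return q.with_values(np.maximum(q.values * factors, q.floor))


def thinning_step(q: DensityProfile, thinning_rate: float) -> DensityProfile:
    """One slow thinning step: absolute decrement, clamped at the floor."""
    if thinning_rate < 0:
        raise ParameterError("thinning rate must be >= 0")
    return q.with_values(np.maximum(q.values - thinning_rate, q.floor))


def simulate(config: AgingSimConfig) -> SimTrajectory:
    """Run the compartment aging simulation.

    Applies a metabolic step every iteration and a thinning step every
    ``slow_every`` iterations; records a snapshot every ``snapshot_stride``
    iterations (plus iteration 0 and the final one) and computes the KL and
    |D - 1| series against the young baseline.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    baseline = init_young_profile(config)
    q = baseline.with_values(baseline.values.copy())

    snapshots = [baseline.with_values(baseline.values.copy(), label="iter0")]
    iterations = [0]
    for it in range(1, config.n_iterations + 1):
        q = metabolic_step(q, config.noise_amplitude, rng)
        if it % config.slow_every == 0:
            q = thinning_step(q, config.thinning_rate)
        if it % config.snapshot_stride == 0 or it == config.n_iterations:
            if iterations[-1] != it:
                snapshots.append(q.with_values(q.values.copy(),
                                               label=f"iter{it}"))
                iterations.append(it)

    kl = np.array([
        kl_divergence(baseline, snap, base=config.kl_base,
                      mode=config.kl_mode, floor=config.floor)
        for snap in snapshots
    ])
    return SimTrajectory(
        baseline=baseline,
        snapshots=snapshots,
        iterations=iterations,
        kl_series=kl,
        dev_series=deviation_from_unity(kl),
        seed=config.seed,
        config=config,
    )


def generate_entropy_schematic(L_young: float = 1.0, L_old: float = 0.8,
                               base_young: float = 0.1, base_old: float = 0.3,
                               fluct_young: float = 0.01,
                               fluct_old: float = 0.05,
                               seed: int = 0, s_max: float = 1.0,
                               n_nodes: int = 201
                               ) -> tuple[EntropyProfile, EntropyProfile]:
    """Schematic young/old entropy-vs-depth profiles.

    Each profile rises monotonically (in trend) from its basal baseline at
    x = 0 to the common maximum ``s_max`` at its own surface — the entropy
    of a dead, peeling cell — following a quadratic ramp, with additive
    uniform fluctuations of the stated amplitude.  The old tissue is thinner
    (``L_old < L_young``), starts more entropic (``base_old > base_young``),
    fluctuates more (``fluct_old > fluct_young``), and is clipped to lie at
    or above the young profile on their common support.

    Returns ``(young, old)``.
    """
    if not (L_old < L_young):
        raise ParameterError("old tissue must be thinner: L_old < L_young")
    if not (base_old > base_young):
        raise ParameterError("old basal entropy must exceed the young one")
    if not (fluct_old > fluct_young):
        raise ParameterError("old fluctuations must exceed the young ones")
    if fluct_young < 0:
        raise ParameterError("fluctuation amplitudes must be >= 0")
    if not (base_young < s_max and base_old < s_max):
        raise ParameterError("basal entropies must lie below the maximum s_max")
    if n_nodes < 2:
        raise ParameterError("need at least 2 nodes per profile")

    rng = np.random.default_rng(seed)

    def ramp(x, L, base):
        return base + (s_max - base) * (x / L) ** 2

    x_y = np.linspace(0.0, L_young, n_nodes)
    x_o = np.linspace(0.0, L_old, n_nodes)
    S_y = ramp(x_y, L_young, base_young)
    S_o = ramp(x_o, L_old, base_old)
    if fluct_young > 0:
        S_y = S_y + rng.uniform(-fluct_young, fluct_young, size=n_nodes)
    if fluct_old > 0:
        S_o = S_o + rng.uniform(-fluct_old, fluct_old, size=n_nodes)
    # both surfaces end at the dead-cell maximum
    S_y[-1] = s_max
    S_o[-1] = s_max
    # old >= young on the common support [0, L_old]
    S_o = np.maximum(S_o, np.interp(x_o, x_y, S_y))
    young = EntropyProfile(x_nodes=x_y, S=S_y, L=L_young, label="young")
    old = EntropyProfile(x_nodes=x_o, S=S_o, L=L_old, label="old")
    return young, old
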