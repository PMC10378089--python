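"""Matplotlib helpers for the standard figures: entropy-vs-depth schematics,
young/old density profiles, and KL trajectories."""

from __future__ import annotations

from .profiles import DensityProfile, EntropyProfile
from .simulate import SimTrajectory


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_entropy_profiles(young: EntropyProfile, old: EntropyProfile, ax=None):
    """Young (green) and old (blue) local entropy against depth."""
    ax = _axes(ax)
    ax.plot(young.x_nodes, young.S, color="green", label=young.label or "young")
    ax.plot(old.x_nodes, old.S, color="blue", label=old.label or "old")
    ax.set_xlabel("depth x (0 = basal layer)")
    ax.set_ylabel("local entropy S(x)")
    ax.legend()
    return ax


def plot_density_profiles(profiles: list[DensityProfile], ax=None):
    """Surface density relief for one or more snapshots."""
    ax = _axes(ax)
    for prof in profiles:
        ax.plot(prof.positions, prof.values, label=prof.label or None)
    ax.set_xlabel("compartment position")
    ax.set_ylabel("cell density")
    if any(p.label for p in profiles):
        ax.legend()
    return ax


def plot_kl_trajectory(traj: SimTrajectory, ax=None, deviation: bool = True):
    """KL divergence (or |D - 1|) against iteration count."""
    ax = _axes(ax)
    series = traj.dev_series if deviation else traj.kl_series
    ax.plot(traj.iterations, series, marker=".")
    ax.set_xlabel("iteration")
    ax.set_ylabel("|D_KL - 1|" if deviation else "D_KL")
    return ax
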