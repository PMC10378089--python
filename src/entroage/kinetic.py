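"""Discrete-velocity BGK relaxation kinetics and local entropy profiles.

The fast, metabolic timescale of a tissue is modelled by a one-dimensional
stationary kinetic equation of BGK (relaxation) type,

    xi * df/dx = (f_M[f] - f) / tau ,

for a phase-space density f(x, xi) over depth x in [0, L] (x = 0 the basal
layer, x = L the surface) and a velocity-like variable xi.  f_M is the local
Maxwellian sharing f's density, mean velocity and temperature; tau is the
relaxation (metabolic) time.  The same operator with the long degradation
time T in place of tau describes stationary structural turnover, and the
spatially uniform analogue

    df/dt = (f_M - f) / T

is the slow structural relaxation, solved here in closed form.

Entropy enters through the Boltzmann moment S(x) = -int f log f dxi.  The
local equilibrium entropy (that of the matching Maxwellian) bounds the
nonequilibrium entropy from above at every point — a living, driven tissue
sits below its own "line of death".  The depth-integrated difference between
an old and a young entropy profile is the scalar age statistic
``entropy_age_delta``.

All quantities are dimensionless; defaults use 64 spatial nodes on [0, 1]
and 32 Gauss–Legendre velocity nodes on [-8, 8] (even counts keep xi = 0,
where the transport operator degenerates, off the grid).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .errors import (
    ConvergenceError,
    DegenerateStateError,
    DomainError,
    ParameterError,
    ShapeError,
)
from .profiles import EntropyProfile

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseGrid",
    "MacroMoments",
    "KineticState",
    "StructuralState",
    "maxwellian",
    "moments_of",
    "solve_stationary_bgk",
    "stationary_residual",
    "local_entropy_profile",
    "equilibrium_entropy_profile",
    "entropy_age_delta",
    "relax_uniform",
]


@dataclass
class PhaseGrid:
    """Discretization of the (x, xi) phase space.

    x_nodes span [0, L]; xi_nodes are symmetric about 0 with positive
    quadrature weights summing to the velocity-interval length.  xi = 0 is
    excluded (the transport characteristic is degenerate there).
    """

    x_nodes: np.ndarray
    xi_nodes: np.ndarray
    xi_weights: np.ndarray

    def __post_init__(self):
        self.x_nodes = np.asarray(self.x_nodes, dtype=float)
        self.xi_nodes = np.asarray(self.xi_nodes, dtype=float)
        self.xi_weights = np.asarray(self.xi_weights, dtype=float)
        if np.any(np.diff(self.x_nodes) <= 0) or np.any(np.diff(self.xi_nodes) <= 0):
            raise ParameterError("grid nodes must be strictly increasing")
        if self.x_nodes[0] != 0.0:
            raise ParameterError("x grid must start at 0 (basal layer)")
        if len(self.xi_nodes) != len(self.xi_weights):
            raise ShapeError("xi nodes and weights differ in length")
        if np.any(self.xi_weights <= 0):
            raise ParameterError("quadrature weights must be positive")
        if np.any(self.xi_nodes == 0.0):
            raise ParameterError("xi = 0 must not be a grid node")
        # the weights define the integration interval; every node must lie
        # inside it (Gauss nodes never reach the endpoints)
        if self.xi_nodes[-1] > self.xi_max + 1e-9 or \
                self.xi_nodes[0] < -self.xi_max - 1e-9:
            raise ParameterError(
                f"xi nodes exceed the quadrature interval "
                f"[-{self.xi_max}, {self.xi_max}] implied by the weights"
            )

    @property
    def L(self) -> float:
        return float(self.x_nodes[-1])

    @property
    def xi_max(self) -> float:
        """Half-length of the velocity interval; the weights sum to 2*xi_max."""
        return float(self.xi_weights.sum() / 2.0)

    @classmethod
    def regular(cls, nx: int = 64, nxi: int = 32, L: float = 1.0,
                xi_max: float = 8.0) -> "PhaseGrid":
        """Uniform x grid on [0, L] with Gauss–Legendre xi nodes on
        [-xi_max, xi_max].  ``nxi`` must be even so xi = 0 is not a node."""
        if nx < 2 or nxi < 2:
            raise ParameterError("need at least 2 nodes per axis")
        if nxi % 2:
            raise ParameterError("nxi must be even (excludes the xi = 0 node)")
        nodes, weights = np.polynomial.legendre.leggauss(nxi)
        return cls(
            x_nodes=np.linspace(0.0, L, nx),
            xi_nodes=nodes * xi_max,
            xi_weights=weights * xi_max,
        )


@dataclass
class MacroMoments:
    """Hydrodynamic moments per spatial node: density rho > 0, mean velocity
    u, temperature theta > 0.  Scalars describe a single node."""

    rho: np.ndarray | float
    u: np.ndarray | float
    theta: np.ndarray | float

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.rho <= 0):
            raise ParameterError("density rho must be strictly positive")
        if np.any(self.theta <= 0):
            raise ParameterError("temperature theta must be strictly positive")


@dataclass
class KineticState:
    """Phase-space distribution f(x_i, xi_j) with its relaxation time.

    ``values`` has shape (nx, nxi); ``info`` holds solver diagnostics when
    the state came out of :func:`solve_stationary_bgk`.
    """

    grid: PhaseGrid
    values: np.ndarray
    relaxation_time: float
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.grid.x_nodes), len(self.grid.xi_nodes))
        if self.values.shape != expect:
            raise ShapeError(f"values shape {self.values.shape} != grid shape {expect}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("distribution values must be finite")
        if np.any(self.values < 0):
            raise ParameterError("distribution values must be non-negative")
        if not (self.relaxation_time > 0):
            raise ParameterError("relaxation time must be positive")


def maxwellian(m: MacroMoments, grid: PhaseGrid) -> np.ndarray:
    """Equilibrium (Maxwellian) distribution for the given moments.

    f_M(xi) = rho (2 pi theta)^{-1/2} exp(-(xi - u)^2 / (2 theta)).

    Scalar moments give a 1-D array over xi; per-node arrays give the full
    (nx, nxi) field.
    """
    rho, u, theta = m.rho, m.u, m.theta
    xi = grid.xi_nodes
    if rho.ndim == 0:
        arg = -((xi - u) ** 2) / (2.0 * theta)
        return float(rho) / np.sqrt(2.0 * np.pi * theta) * np.exp(arg)
    arg = -((xi[None, :] - u[:, None]) ** 2) / (2.0 * theta[:, None])
    return rho[:, None] / np.sqrt(2.0 * np.pi * theta[:, None]) * np.exp(arg)


def moments_of(f: KineticState) -> MacroMoments:
    """Quadrature moments (rho, u, theta) of a kinetic state, per x node."""
    w = f.grid.xi_weights
    xi = f.grid.xi_nodes
    rho = f.values @ w
    if np.any(rho <= 0):
        node = int(np.argmax(rho <= 0))
        raise DegenerateStateError(
            f"zero quadrature density at x node {node} "
            f"(x = {f.grid.x_nodes[node]:g})",
            node=node,
        )
    u = (f.values @ (w * xi)) / rho
    theta = np.einsum("j,ij->i", w, f.values * (xi[None, :] - u[:, None]) ** 2) / rho
    return MacroMoments(rho=rho, u=u, theta=theta)


def _inflow(m: MacroMoments, grid: PhaseGrid) -> np.ndarray:
    if np.asarray(m.rho).ndim != 0:
        raise ParameterError("boundary moments must be scalars")
    return maxwellian(m, grid)


def solve_stationary_bgk(left_boundary: MacroMoments,
                         right_boundary: MacroMoments,
                         tau: float,
                         grid: PhaseGrid | None = None,
                         tol: float = 1e-8,
                         max_iter: int = 10_000,
                         under_relaxation: float = 0.9) -> KineticState:
    """Solve the stationary BGK equation xi f_x = (f_M[f] - f)/tau.

    Inflow boundary conditions: the left wall (x = 0, basal layer) injects
    its Maxwellian for xi > 0, the right wall (x = L, surface) for xi < 0.
    The discrete problem is solved by implicit upwind sweeps alternated with
    self-consistent moment/Maxwellian updates, under-relaxed, until the
    max-norm change between iterates drops below ``tol``.

    Returns the converged :class:`KineticState`; ``state.info`` carries
    ``iterations``, ``residual`` (final max-norm change) and
    ``residual_history``.

    Raises
    ------
    ConvergenceError
        If ``max_iter`` sweeps do not reach ``tol``; the exception carries
        the residual history.
    """
    if grid is None:
        grid = PhaseGrid.regular()
    if not (tau > 0):
        raise ParameterError("relaxation time tau must be positive")
    if not (tol > 0):
        raise ParameterError("tolerance must be positive")
    if not (0 < under_relaxation <= 1):
        raise ParameterError("under-relaxation factor must be in (0, 1]")

    xi = grid.xi_nodes
    x = grid.x_nodes
    nx, nxi = len(x), len(xi)
    pos = xi > 0
    neg = ~pos
    f_left = _inflow(left_boundary, grid)    # used for xi > 0 at x = 0
    f_right = _inflow(right_boundary, grid)  # used for xi < 0 at x = L
    dx = np.diff(x)

    # initial guess: linear blend of the two wall Maxwellians
    s = (x / grid.L)[:, None]
    f = (1.0 - s) * f_left[None, :] + s * f_right[None, :]
    f[0, pos] = f_left[pos]
    f[-1, neg] = f_right[neg]

    history: list[float] = []
    for iteration in range(1, max_iter + 1):
        fM = maxwellian(moments_of(KineticState(grid, f, tau)), grid)
        f_new = np.empty_like(f)
        # xi > 0: march up from the basal wall
        f_new[0, pos] = f_left[pos]
        for i in range(1, nx):
            c = dx[i - 1] / (xi[pos] * tau)
            f_new[i, pos] = (f_new[i - 1, pos] + c * fM[i, pos]) / (1.0 + c)
        # xi < 0: march down from the surface wall
        f_new[-1, neg] = f_right[neg]
        for i in range(nx - 2, -1, -1):
            c = dx[i] / (-xi[neg] * tau)
            f_new[i, neg] = (f_new[i + 1, neg] + c * fM[i, neg]) / (1.0 + c)

        change = float(np.max(np.abs(f_new - f)))
        history.append(change)
        f = under_relaxation * f_new + (1.0 - under_relaxation) * f
        if change < tol:
            logger.info("stationary BGK converged in %d sweeps (residual %.3e)",
                        iteration, change)
            return KineticState(
                grid, np.maximum(f, 0.0), tau,
                info={"iterations": iteration, "residual": change,
                      "residual_history": history},
            )
    raise ConvergenceError(
        f"stationary BGK solve did not reach tol={tol} in {max_iter} sweeps "
        f"(last residual {history[-1]:.3e})",
        residual_history=history,
    )


def stationary_residual(f: KineticState) -> float:
    """Max-norm residual of the discrete upwind stationary equation.

    Measures how well a state satisfies xi f_x = (f_M - f)/tau with the same
    one-sided differences the solver uses (boundary inflow rows excluded).
    """
    grid, tau = f.grid, f.relaxation_time
    xi, x = grid.xi_nodes, grid.x_nodes
    pos = xi > 0
    neg = ~pos
    fM = maxwellian(moments_of(f), grid)
    rhs = (fM - f.values) / tau
    res = []
    dfdx_up = (f.values[1:, pos] - f.values[:-1, pos]) / np.diff(x)[:, None]
    res.append(xi[pos][None, :] * dfdx_up - rhs[1:, pos])
    dfdx_dn = (f.values[1:, neg] - f.values[:-1, neg]) / np.diff(x)[:, None]
    res.append(xi[neg][None, :] * dfdx_dn - rhs[:-1, neg])
    return float(max(np.max(np.abs(r)) for r in res))


def local_entropy_profile(f: KineticState, label: str = "") -> EntropyProfile:
    """Boltzmann entropy moment S(x) = -sum_j w_j f log f (natural log,
    0 log 0 = 0)."""
    w = f.grid.xi_weights
    S = -(xlogy(f.values, f.values) @ w)
    return EntropyProfile(x_nodes=f.grid.x_nodes, S=S, L=f.grid.L, label=label)


def equilibrium_entropy_profile(f: KineticState, label: str = "") -> EntropyProfile:
    """Entropy of the local Maxwellian sharing each node's (rho, u, theta).

    Bounds :func:`local_entropy_profile` from above at every node, up to
    quadrature tolerance: among distributions with fixed hydrodynamic
    moments the Maxwellian maximizes -int f log f dxi.
    """
    fM = maxwellian(moments_of(f), f.grid)
    eq = KineticState(f.grid, fM, f.relaxation_time)
    return local_entropy_profile(eq, label=label)


def entropy_age_delta(S_old: EntropyProfile, S_young: EntropyProfile,
                      L_old: float | None = None) -> float:
    """Depth-integrated entropy excess of the old profile over the young one,

        Delta_S = int_0^{L_old} (S_old(x) - S_young(x)) dx ,

    the scalar age characteristic of a tissue.  Profiles on different meshes
    are linearly interpolated onto their merged node set restricted to
    [0, L_old]; the integral is the trapezoid rule on that mesh.
    """
    if L_old is None:
        L_old = S_old.L
    if not (L_old > 0):
        raise ParameterError("upper integration limit must be positive")
    for prof, name in ((S_old, "old"), (S_young, "young")):
        if L_old > prof.x_nodes[-1] + 1e-12 or prof.x_nodes[0] > 1e-12:
            raise DomainError(
                f"{name} profile support [{prof.x_nodes[0]:g}, "
                f"{prof.x_nodes[-1]:g}] does not cover [0, {L_old:g}]"
            )
    mesh = np.union1d(S_old.x_nodes, S_young.x_nodes)
    mesh = mesh[(mesh >= 0.0) & (mesh <= L_old)]
    mesh = np.union1d(mesh, [0.0, L_old])
    diff = (np.interp(mesh, S_old.x_nodes, S_old.S)
            - np.interp(mesh, S_young.x_nodes, S_young.S))
    return float(np.trapezoid(diff, mesh))


def relax_uniform(f0: KineticState, T: float,
                  times: Sequence[float]) -> list[KineticState]:
    """Spatially uniform structural relaxation df/dt = (f_M - f)/T.

    The equilibrium target f_M is the Maxwellian with f0's own moments and
    is held fixed (BGK relaxation conserves the hydrodynamic moments, so the
    target never moves), which makes the trajectory exactly

        f(t) = f_M + (f0 - f_M) exp(-t/T) .

    Every returned state is a convex combination of f0 and f_M; moments are
    conserved along the trajectory and entropy is non-decreasing in t
    (H-theorem).
    """
    if not (T > 0):
        raise ParameterError("structural timescale T must be positive")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ParameterError("times must be a non-empty 1-D sequence")
    if np.any(times < 0):
        raise ParameterError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise ParameterError("times must be non-decreasing")
    fM = maxwellian(moments_of(f0), f0.grid)
    out = []
    for t in times:
        if t == 0.0:  # exact initial condition, no round-off through fM
            values = f0.values.copy()
        else:
            values = fM + (f0.values - fM) * math.exp(-t / T)
        out.append(KineticState(f0.grid, np.maximum(values, 0.0), T,
                                info={"time": float(t)}))
    return out


@dataclass
class StructuralState:
    """Structural distribution f_T over (t_T, x_T, e_T) bins with its
    equilibrium counterpart f_MT and degradation timescale T.

    The energy axis e_T is a passive binning coordinate: structural dynamics
    act bin-wise through the same relaxation law as :func:`relax_uniform`.
    """

    values: np.ndarray
    equilibrium: np.ndarray
    timescale: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.equilibrium = np.asarray(self.equilibrium, dtype=float)
        if self.values.shape != self.equilibrium.shape:
            raise ShapeError("f_T and f_MT must share bin shape")
        if np.any(self.values < 0) or np.any(self.equilibrium < 0):
            raise ParameterError("structural densities must be non-negative")
        if not (self.timescale > 0):
            raise ParameterError("timescale T must be positive")

    def relax(self, times: Sequence[float]) -> list[np.ndarray]:
        """Closed-form bin-wise relaxation toward f_MT at rate 1/T."""
        times = np.asarray(times, dtype=float)
        if np.any(times < 0):
            raise ParameterError("times must be non-negative")
        return [
            self.equilibrium + (self.values - self.equilibrium)
            * math.exp(-t / self.timescale)
            for t in times
        ]
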