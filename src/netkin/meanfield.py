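"""Vlasov and monokinetic mean-field solvers.

In the mean-field (large-N) limit with small state increments, the jump
dynamics reduce to a Vlasov-type transport equation in the state variable
whose drift field is

    W(z, z~) = w(x, x~) * ( E_{nu_{z,z~}}[a] + E_{nu_{z~,z}}[b] ),

i.e. the active-role mean increment of z plus the passive-role mean
increment z receives from z~.  Because positions are frozen, the
characteristics move in state space only, which makes a particle method
exact up to time discretisation: each particle keeps its position and mass
and its state follows the mass-weighted pairwise drift.

Monokinetic solutions concentrate all mass at one state V(x, t) per
position; their dynamics close into a nonlocal equation for the field V,
integrated here by the method of lines.

The diffusion (Fokker-Planck) coefficient

    A(z, z~) = 1/2 * w(x, x~) * ( E[a (x) a] + E[b (x) b] )

is assembled from the rule's second moments and exposed for inspection;
the second-order PDE itself is not solved here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._trajectory import Trajectory
from .errors import ParameterError, StabilityError, UnsupportedError
from .interaction_core import InteractionRule
from .spatial_network import Kernel, NodeNetwork, SpatialGrid, evaluate_kernel

__all__ = [
    "VlasovCoefficients",
    "MeanFieldParticles",
    "MonokineticField",
    "vlasov_coefficients",
    "solve_vlasov_particles",
    "solve_monokinetic",
]


@dataclass
class VlasovCoefficients:
    """Drift and diffusion coefficients assembled from an interaction rule.

    ``drift_state(v, v_active)`` is the state part of W: the mean increment
    of a (passive-role) state ``v`` facing a partner state ``v_active``,
    plus its own active-role mean increment; multiplied by the kernel this
    gives the full drift W(z, z~).  ``diffusion_state`` likewise returns
    the state part of A (a symmetric PSD s x s matrix per pair).

    If ``rescaled`` is true both coefficients are divided by the rule's
    small parameter (gamma/(1+gamma), h, ...), matching the mean-field
    convention of measuring time in units of that parameter.
    """

    kernel: Kernel
    rule: InteractionRule
    rescaled: bool = True
    periodic: bool = True

    @property
    def rescale_factor(self) -> float:
        return self.rule.rescale_factor

    @property
    def _scale(self) -> float:
        return 1.0 / self.rule.rescale_factor if self.rescaled else 1.0

    def drift_state(self, v, v_active):
        return self._scale * (
            self.rule.mean_a(v, v_active) + self.rule.mean_b(v_active, v)
        )

    def diffusion_state(self, v, v_active):
        return (
            0.5
            * self._scale
            * (
                self.rule.second_moment_a(v, v_active)
                + self.rule.second_moment_b(v_active, v)
            )
        )

    def W(self, x, v, x_tilde, v_tilde):
        """Full drift W(z, z~) = w(x, x~) * drift_state(v, v~)."""
        w = evaluate_kernel(self.kernel, x, x_tilde, self.periodic)
        return np.asarray(w)[..., None] * self.drift_state(v, v_tilde)

    def A(self, x, v, x_tilde, v_tilde):
        """Full diffusion A(z, z~) = w(x, x~) * diffusion_state(v, v~)."""
        w = evaluate_kernel(self.kernel, x, x_tilde, self.periodic)
        return np.asarray(w)[..., None, None] * self.diffusion_state(v, v_tilde)


def vlasov_coefficients(
    rule: InteractionRule,
    kernel: Kernel,
    rescaled: bool = True,
    periodic: bool = True,
) -> VlasovCoefficients:
    """Assemble Vlasov/Fokker-Planck coefficients from a rule and a kernel."""
    for attr in ("mean_b", "second_moment_b"):
        if getattr(type(rule), attr) is getattr(InteractionRule, attr):
            raise UnsupportedError(
                f"rule {type(rule).__name__} does not expose {attr}; "
                "cannot assemble mean-field coefficients"
            )
    return VlasovCoefficients(
        kernel=kernel, rule=rule, rescaled=rescaled, periodic=periodic
    )


@dataclass
class MeanFieldParticles:
    """Weighted particle representation of the one-agent measure mu.

    Positions are fixed along characteristics; masses sum to one.
    """

    positions: np.ndarray
    states: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if np.any(self.masses < 0):
            raise ParameterError("particle masses must be nonnegative")
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ParameterError("particle masses must sum to one")

    @property
    def n_particles(self) -> int:
        return len(self.positions)


@dataclass
class MonokineticField:
    """Mean-field unknown of a monokinetic solution: one state per position
    plus a stationary density."""

    positions: np.ndarray
    V: np.ndarray
    density: np.ndarray
    quad_weights: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim == 1:
            self.V = self.V[:, None]
        self.density = np.asarray(self.density, dtype=float)
        if self.quad_weights is None:
            self.quad_weights = np.ones(len(self.positions))
        else:
            self.quad_weights = np.asarray(self.quad_weights, dtype=float)

    @classmethod
    def on_grid(cls, grid: SpatialGrid, V, density=None) -> "MonokineticField":
        rho = np.ones(grid.n) if density is None else density
        return cls(grid.points, V, rho, grid.quad_weights)

    @classmethod
    def on_network(cls, network: NodeNetwork, V) -> "MonokineticField":
        return cls(network.positions, V, network.node_density,
                   np.ones(network.n_nodes))


def _renormalize_simplex(states: np.ndarray, cols, tol: float = 1e-12) -> None:
    """Project the given state columns back to unit sum if floating-point
    drift exceeds ``tol``; the drift is analytically tangent to the simplex,
    so this only corrects rounding."""
    block = states[:, cols]
    s = block.sum(axis=1)
    bad = np.abs(s - 1.0) > tol
    if np.any(bad):
        states[np.ix_(bad, np.atleast_1d(cols))] /= s[bad, None]


def _integrate(rhs, y0, t_end, dt, integrator, store_every, postprocess=None):
    """Fixed-step explicit Euler / RK4 method-of-lines driver.

    ``rhs(t, y)`` returns dy/dt; ``postprocess(y)`` mutates y after each
    step (simplex guard).  Returns (times, snapshots) including t=0.
    """
    if dt <= 0 or t_end < 0:
        raise ParameterError("need dt > 0 and t_end >= 0")
    # land exactly on t_end: shrink dt to the nearest integer division
    n_steps = max(int(np.ceil(t_end / dt - 1e-9)), 1) if t_end > 0 else 0
    dt = t_end / n_steps if n_steps else dt
    y = np.array(y0, dtype=float)
    times = [0.0]
    snaps = [y.copy()]
    t = 0.0
    for step in range(1, n_steps + 1):
        if integrator == "euler":
            y = y + dt * rhs(t, y)
        elif integrator == "rk4":
            k1 = rhs(t, y)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2)
            k4 = rhs(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        else:
            raise ParameterError(f"unknown integrator {integrator!r}")
        if not np.all(np.isfinite(y)):
            raise StabilityError(
                f"solution lost finiteness at step {step}; reduce dt"
            )
        if postprocess is not None:
            postprocess(y)
        t = step * dt
        if step % store_every == 0 or step == n_steps:
            times.append(t)
            snaps.append(y.copy())
    return np.asarray(times), np.asarray(snaps)


def solve_vlasov_particles(
    init: MeanFieldParticles,
    coeffs: VlasovCoefficients,
    t_end: float,
    dt: float,
    integrator: str = "rk4",
    simplex_columns=None,
    store_every: int = 1,
) -> Trajectory:
    """Particle (characteristics) solution of the Vlasov equation.

    Each particle's state follows
    dV_p/dt = sum_q m_q w(x_p, x_q) drift_state(V_p, V_q); positions and
    masses never change.  ``simplex_columns`` optionally names state
    columns renormalised to unit sum after each step (rounding guard only).
    """
    x, m = init.positions, init.masses
    wmat = np.asarray(
        evaluate_kernel(coeffs.kernel, x[:, None], x[None, :], coeffs.periodic),
        dtype=float,
    ) * m[None, :]

    def rhs(t, V):
        pairwise = coeffs.drift_state(V[:, None, :], V[None, :, :])
        return np.einsum("pq,pqs->ps", wmat, pairwise)

    post = None
    if simplex_columns is not None:
        cols = np.atleast_1d(simplex_columns)
        post = lambda V: _renormalize_simplex(V, cols)

    times, snaps = _integrate(
        rhs, init.states, t_end, dt, integrator, store_every, post
    )
    return Trajectory(
        times=times,
        states=snaps,
        positions=x,
        masses=m,
        meta={
            "model": "vlasov_particles",
            "integrator": integrator,
            "dt": dt,
            "rescaled": coeffs.rescaled,
        },
    )


def solve_monokinetic(
    fieldV: MonokineticField,
    coeffs: VlasovCoefficients,
    t_end: float,
    dt: float,
    integrator: str = "rk4",
    simplex_columns=None,
    store_every: int = 1,
) -> Trajectory:
    """Method-of-lines solution of the monokinetic field equation

    dV(x_i)/dt = sum_j w(x_i, x_j) qw_j rho_j drift_state(V_i, V_j),

    the closure of the Vlasov dynamics on measures concentrated at one
    state per position.  The density rho is stationary and untouched.
    """
    x = fieldV.positions
    eta = fieldV.quad_weights * fieldV.density
    wmat = np.asarray(
        evaluate_kernel(coeffs.kernel, x[:, None], x[None, :], coeffs.periodic),
        dtype=float,
    ) * eta[None, :]

    def rhs(t, V):
        pairwise = coeffs.drift_state(V[:, None, :], V[None, :, :])
        return np.einsum("iq,iqs->is", wmat, pairwise)

    post = None
    if simplex_columns is not None:
        cols = np.atleast_1d(simplex_columns)
        post = lambda V: _renormalize_simplex(V, cols)

    times, snaps = _integrate(
        rhs, fieldV.V, t_end, dt, integrator, store_every, post
    )
    return Trajectory(
        times=times,
        states=snaps,
        positions=x,
        masses=eta,
        meta={
            "model": "monokinetic",
            "integrator": integrator,
            "dt": dt,
            "rescaled": coeffs.rescaled,
        },
    )
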