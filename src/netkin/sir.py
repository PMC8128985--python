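"""Network-structured SIR epidemic model with nonlocal infection.

Susceptibles do not move; they are infected through the interaction
network at rate int w(x, x~) v(x~) dx~, where v is the infected density,
and infected are removed at a constant rate beta:

    du/dt = - u * int w(x, x~) v(x~) dx~ ,
    dv/dt = + u * int w(x, x~) v(x~) dx~ - beta v ,
    dr/dt = beta v .

Writing alpha(x) = int w(x, x~) dx~ and using the nonlocal Laplacian
L_w, the infection term is alpha u v + u L_w v — a reaction plus a
degenerate nonlocal cross-diffusion that transports only the infection
pressure, never the susceptibles.  The standard nonlocal
reaction-diffusion comparison model instead disperses both populations:

    du/dt = -alpha u v + D1 L_w u ,   dv/dt = alpha u v + D2 L_w v - beta v.

The local (narrow-kernel) limit replaces L_w by a multiple of the
Laplacian and produces a cross-diffusion system that can violate the
monotone decrease of u wherever the infected profile is concave enough
(Lap v < -alpha v); that variant is shipped as a demonstrator of this
ill-behaviour, not as a production solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._trajectory import Trajectory
from .errors import ParameterError, StabilityError
from .interaction_core import InteractionRule, UnaryChannel
from .meanfield import _integrate
from .spatial_network import (
    Kernel,
    KernelMatrix,
    SpatialGrid,
    discretize_kernel,
    nonlocal_laplacian,
)

__all__ = [
    "S",
    "I",
    "R",
    "SIRFields",
    "SIRScenario",
    "SIRRule",
    "sir_rule",
    "solve_sir_network",
    "solve_sir_rd_comparison",
    "solve_sir_local",
    "fig1_scenario",
    "peak_initial_infected",
]

# categorical state codes
S, I, R = 0, 1, 2


@dataclass
class SIRFields:
    """Susceptible / infected / removed densities on a grid, the removal
    rate beta, and the diffusivities of the comparison model."""

    u: np.ndarray
    v: np.ndarray
    r: np.ndarray | None = None
    beta: float = 0.1
    D1: float = 1.0
    D2: float = 1.0

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.r is None:
            self.r = np.zeros_like(self.u)
        else:
            self.r = np.asarray(self.r, dtype=float)
        if np.any(self.u < 0) or np.any(self.v < 0) or np.any(self.r < 0):
            raise ParameterError("initial densities must be nonnegative")
        if self.beta < 0:
            raise ParameterError("removal rate beta must be nonnegative")


class SIRRule(InteractionRule):
    """Agent-level SIR interactions.

    States are categorical codes 0=S, 1=I, 2=R.  The only effective pair
    event is (active infected, passive susceptible) -> passive infected;
    every other ordered pair is a null event.  Removal I -> R at rate beta
    is a unary channel (an explicit extension of the pure pair-interaction
    framework).
    """

    state_space = "categorical"
    state_dim = 1
    rescale_factor = 1.0

    def __init__(self, beta: float):
        if beta < 0:
            raise ParameterError("removal rate beta must be nonnegative")
        self.beta = beta
        self.unary_channels = (
            UnaryChannel(
                name="removal",
                rate=lambda states: beta * (np.asarray(states) == I),
                sample=lambda state, rng: R - I,  # I -> R
            ),
        )

    def sample(self, v_active, v_passive, rng):
        if v_active == I and v_passive == S:
            return 0, I - S
        return 0, 0

    def mean_b(self, v_active, v_passive):
        act = np.asarray(v_active)
        pas = np.asarray(v_passive)
        return ((act == I) & (pas == S)).astype(float) * (I - S)

    def second_moment_b(self, v_active, v_passive):
        # the increment is 0 or 1, so E[b^2] = E[b]
        m = self.mean_b(v_active, v_passive)
        return np.asarray(m, dtype=float)[..., None, None]


def sir_rule(kernel: Kernel, beta: float) -> SIRRule:
    """Agent interaction rule for the SIR model (kernel enters through the
    simulator's pair rates, not the rule itself)."""
    return SIRRule(beta)


def _stack(u, v, r):
    return np.stack([u, v, r], axis=-1)


def _check_nonneg(y, what, tol=-1e-10):
    if y.min() < tol:
        raise StabilityError(
            f"{what} produced negative values ({y.min():.3e}); reduce dt"
        )


def sir_network_rhs(u, v, km: KernelMatrix, beta: float, form: str = "direct"):
    """Infection/removal right-hand side of the network model.

    ``form="direct"`` evaluates u * K[v]; ``form="reaction_diffusion"``
    evaluates the algebraically identical alpha u v + u L_w v.  Both are
    provided so the equivalence of the two formulations can be checked.
    """
    if form == "direct":
        infection = u * km.apply(v)
    elif form == "reaction_diffusion":
        infection = km.row_integral * u * v + u * nonlocal_laplacian(km, v)
    else:
        raise ParameterError(f"unknown form {form!r}")
    return -infection, infection - beta * v, beta * v


def solve_sir_network(
    fields: SIRFields,
    km: KernelMatrix,
    t_end: float,
    dt: float = 0.01,
    scheme: str = "euler",
    form: str = "direct",
    store_every: int = 1,
) -> Trajectory:
    """Explicit time stepping of the network-structured SIR system.

    The default scheme is forward Euler with dt = 0.01 (RK4 optional).
    The pointwise sum u + v + r is conserved exactly by construction of
    the increments; u is nonincreasing at every grid point.
    """
    if fields.u.shape[0] != km.n:
        raise ParameterError("fields do not match the kernel matrix")

    def rhs(t, y):
        u, v, r = y[:, 0], y[:, 1], y[:, 2]
        du, dv, dr = sir_network_rhs(u, v, km, fields.beta, form)
        return _stack(du, dv, dr)

    y0 = _stack(fields.u, fields.v, fields.r)
    times, snaps = _integrate(
        rhs, y0, t_end, dt, scheme, store_every,
        postprocess=lambda y: _check_nonneg(y, "network SIR step"),
    )
    return Trajectory(
        times=times,
        states=snaps,
        positions=km.points,
        masses=km.quad_weights,
        meta={"model": "sir_network", "beta": fields.beta, "dt": dt,
              "scheme": scheme, "form": form},
    )


def solve_sir_rd_comparison(
    fields: SIRFields,
    km: KernelMatrix,
    t_end: float,
    dt: float = 0.01,
    scheme: str = "euler",
    store_every: int = 1,
) -> Trajectory:
    """Standard nonlocal reaction-diffusion SIR comparison model.

    Both u and v disperse (diffusivities D1, D2); for a symmetric kernel
    the nonlocal Laplacian conserves the spatial integral, so total mass
    u + v decays only through removal.
    """
    if fields.u.shape[0] != km.n:
        raise ParameterError("fields do not match the kernel matrix")
    alpha = km.row_integral
    beta, D1, D2 = fields.beta, fields.D1, fields.D2

    def rhs(t, y):
        u, v = y[:, 0], y[:, 1]
        reaction = alpha * u * v
        du = -reaction + D1 * nonlocal_laplacian(km, u)
        dv = reaction + D2 * nonlocal_laplacian(km, v) - beta * v
        return _stack(du, dv, beta * v)

    y0 = _stack(fields.u, fields.v, fields.r)
    times, snaps = _integrate(
        rhs, y0, t_end, dt, scheme, store_every,
        postprocess=lambda y: _check_nonneg(y, "reaction-diffusion SIR step"),
    )
    return Trajectory(
        times=times,
        states=snaps,
        positions=km.points,
        masses=km.quad_weights,
        meta={"model": "sir_rd", "beta": beta, "D1": D1, "D2": D2, "dt": dt,
              "scheme": scheme},
    )


def solve_sir_local(
    fields: SIRFields,
    grid: SpatialGrid,
    t_end: float,
    dt: float = 0.01,
    variant: str = "leading_order",
    alpha: float = 1.0,
    scheme: str = "euler",
    store_every: int = 1,
    blowup_bound: float = 1e6,
) -> Trajectory:
    """Local (narrow-kernel) limits of the network SIR model.

    ``leading_order`` drops the diffusion entirely (classical SIR ODEs at
    every grid point).  ``degenerate`` keeps the cross term u * Lap v; this
    system is not normally elliptic and can make du/dt positive wherever
    Lap v < -alpha v — the trajectory metadata records every grid point
    where that happened.  Short horizons only.
    """
    from .dialect import _periodic_laplacian

    if variant not in ("degenerate", "leading_order"):
        raise ParameterError(f"unknown local variant {variant!r}")
    h = grid.spacing
    beta = fields.beta
    sign_violations = np.zeros(grid.n, dtype=bool)

    def rhs(t, y):
        u, v = y[:, 0], y[:, 1]
        if np.abs(y).max() > blowup_bound:
            raise StabilityError("local SIR solution exceeded the blow-up bound")
        reaction = alpha * u * v
        if variant == "degenerate":
            cross = u * _periodic_laplacian(v, h)
            du = -reaction - cross
            sign_violations[du > 0] = True
            dv = reaction + cross - beta * v
        else:
            du = -reaction
            dv = reaction - beta * v
        return _stack(du, dv, beta * v)

    y0 = _stack(fields.u, fields.v, fields.r)
    times, snaps = _integrate(rhs, y0, t_end, dt, scheme, store_every)
    return Trajectory(
        times=times,
        states=snaps,
        positions=grid.points,
        masses=grid.quad_weights,
        meta={
            "model": f"sir_local_{variant}",
            "beta": beta,
            "alpha": alpha,
            "dt": dt,
            "scheme": scheme,
            "du_sign_violations": sign_violations,
        },
    )


def peak_initial_infected(
    grid: SpatialGrid,
    center: float = 0.5,
    height: float = 0.05,
    width: float = 0.02,
) -> np.ndarray:
    """Narrow Gaussian peak of initially infected at ``center``."""
    return height * np.exp(-((grid.points - center) ** 2) / (2.0 * width**2))


@dataclass(frozen=True)
class SIRScenario:
    """Packaged numerical configuration of the reference epidemic run."""

    n_grid: int = 100
    periodic: bool = True
    kernel_amplitude: float = 0.3
    kernel_cutoff: float = 0.2
    beta: float = 0.1
    dt: float = 0.01
    t_end: float = 5.0
    output_times: tuple = (1.0, 2.0, 3.0, 4.0, 5.0)
    u0_level: float = 1.0
    v0_center: float = 0.5
    v0_height: float = 0.05
    v0_width: float = 0.02
    D1: float = 1.0
    D2: float = 1.0

    def __post_init__(self):
        if min(self.kernel_amplitude, self.kernel_cutoff, self.beta,
               self.dt, self.t_end) <= 0 or self.n_grid <= 0:
            raise ParameterError("scenario parameters must be positive")

    def grid(self) -> SpatialGrid:
        return SpatialGrid.uniform(self.n_grid, periodic=self.periodic)

    def kernel(self) -> Kernel:
        return Kernel.triangular(self.kernel_amplitude, self.kernel_cutoff)

    def kernel_matrix(self) -> KernelMatrix:
        grid = self.grid()
        return discretize_kernel(self.kernel(), grid, density=np.ones(grid.n))

    def fields(self) -> SIRFields:
        grid = self.grid()
        return SIRFields(
            u=np.full(grid.n, self.u0_level),
            v=peak_initial_infected(grid, self.v0_center, self.v0_height,
                                    self.v0_width),
            beta=self.beta,
            D1=self.D1,
            D2=self.D2,
        )

    def run(self, model: str = "network", **kwargs) -> Trajectory:
        km = self.kernel_matrix()
        if model == "network":
            return solve_sir_network(self.fields(), km, self.t_end,
                                     self.dt, **kwargs)
        if model == "rd":
            return solve_sir_rd_comparison(self.fields(), km, self.t_end,
                                           self.dt, **kwargs)
        raise ParameterError(f"unknown scenario model {model!r}")


def fig1_scenario() -> SIRScenario:
    """The reference epidemic configuration: periodic unit interval,
    triangular kernel w(x, y) = 0.3 (0.2 - |x - y|)_+, beta = 0.1, grid
    spacing 0.01, Euler step 0.01, u0 = 1, narrow infected peak at x = 0.5,
    outputs at t = 1..5."""
    return SIRScenario()
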