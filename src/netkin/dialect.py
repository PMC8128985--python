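"""Dialect-evolution model (Burridge-type) in the network-kinetic framework.

Agents carry a memory vector v on the probability simplex
K = {v >= 0, sum v = 1} over M variants of a linguistic feature.  A
speaker (active agent) utters variant i with probability
p_i(v) = v_i^alpha / sum_j v_j^alpha, alpha >= 1 — the conformity bias that
drives phase separation.  The listener (passive agent) blends the heard
variant into its memory with weight gamma/(1+gamma).

Three description levels are provided: the stochastic interaction rule for
the agent simulator, the nonlocal monokinetic field equation

    dV(x)/dt = int w(x, x~) rho(x~) ( p(V(x~)) - V(x) ) dx~,

and the spatially local reaction-diffusion limits obtained for narrow
kernels (sigma = sqrt(C) * eps), including the Allen-Cahn-type
approximations valid when the reaction rate kappa dominates sigma^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._trajectory import Trajectory
from .errors import DomainError, ParameterError, UnsupportedError
from .interaction_core import InteractionRule
from .meanfield import _integrate, _renormalize_simplex
from .spatial_network import KernelMatrix, SpatialGrid

__all__ = [
    "DialectParams",
    "DialectLocalConfig",
    "choice_probabilities",
    "inverse_choice_map",
    "collision_update",
    "pre_collision",
    "DialectRule",
    "dialect_rule",
    "monokinetic_rhs",
    "solve_local_pde",
]


@dataclass(frozen=True)
class DialectParams:
    """M variants, conformity exponent alpha >= 1, memory weight gamma > 0."""

    M: int
    alpha_exp: float = 2.0
    gamma: float = 0.1

    def __post_init__(self):
        if self.M < 2:
            raise ParameterError("need at least two variants")
        if self.alpha_exp < 1:
            raise ParameterError("conformity exponent must satisfy alpha >= 1")
        if self.gamma <= 0:
            raise ParameterError("memory weight gamma must be positive")


def choice_probabilities(v, alpha_exp: float):
    """Conformity-biased choice p_i(v) = v_i^alpha / sum_j v_j^alpha.

    Vectorised over leading axes.  Corners map to themselves (the
    convention 0^alpha = 0 extends p continuously from the interior).
    """
    v = np.asarray(v, dtype=float)
    powed = np.where(v > 0.0, v, 0.0) ** alpha_exp
    norm = powed.sum(axis=-1, keepdims=True)
    if np.any(norm <= 0):
        raise DomainError("choice probabilities undefined for all-zero memory")
    return powed / norm


def inverse_choice_map(P, alpha_exp: float):
    """Inverse of the choice map: v_i = P_i^(1/alpha) / sum_j P_j^(1/alpha)."""
    if alpha_exp == 0:
        raise UnsupportedError("choice map is not invertible at alpha = 0")
    return choice_probabilities(P, 1.0 / alpha_exp)


def collision_update(v, variant_index: int, gamma: float):
    """Listener memory after hearing variant i:
    v' = v/(1+gamma) + gamma/(1+gamma) e_i (a convex combination, so K is
    invariant)."""
    v = np.asarray(v, dtype=float)
    M = v.shape[-1]
    if not 0 <= variant_index < M:
        raise ParameterError(f"variant index {variant_index} out of range")
    e = np.zeros(M)
    e[variant_index] = 1.0
    return v / (1.0 + gamma) + gamma / (1.0 + gamma) * e


def pre_collision(v, variant_index: int, gamma: float):
    """Inverse of :func:`collision_update`: v* = (1+gamma) v - gamma e_i."""
    v = np.asarray(v, dtype=float)
    M = v.shape[-1]
    if not 0 <= variant_index < M:
        raise ParameterError(f"variant index {variant_index} out of range")
    e = np.zeros(M)
    e[variant_index] = 1.0
    return (1.0 + gamma) * v - gamma * e


class DialectRule(InteractionRule):
    """Interaction measure of the dialect model.

    The active agent does not change (a = 0); the passive agent jumps by
    b = gamma/(1+gamma) (e_i - v) where i ~ p(v_active).  The mean passive
    increment is gamma/(1+gamma) (p(v_active) - v_passive); the natural
    mean-field time rescaling is by gamma/(1+gamma).
    """

    state_space = "simplex"

    def __init__(self, params: DialectParams):
        self.params = params
        self.state_dim = params.M
        self.rescale_factor = params.gamma / (1.0 + params.gamma)

    def sample(self, v_active, v_passive, rng):
        p = choice_probabilities(v_active, self.params.alpha_exp)
        i = int(rng.choice(self.params.M, p=p))
        e = np.zeros(self.params.M)
        e[i] = 1.0
        b = self.rescale_factor * (e - np.asarray(v_passive, dtype=float))
        return np.zeros(self.params.M), b

    def mean_b(self, v_active, v_passive):
        p = choice_probabilities(v_active, self.params.alpha_exp)
        return self.rescale_factor * (p - np.asarray(v_passive, dtype=float))

    def second_moment_b(self, v_active, v_passive):
        # sum_i p_i(v_act) * c^2 (e_i - v_pas) (x) (e_i - v_pas)
        p = choice_probabilities(v_active, self.params.alpha_exp)
        v = np.asarray(v_passive, dtype=float)
        M = self.params.M
        d = np.eye(M) - v[..., None, :]  # d[..., i, k] = delta_ik - v_k
        c2 = self.rescale_factor**2
        return c2 * np.einsum("...i,...ik,...il->...kl", p, d, d)


def dialect_rule(params: DialectParams) -> DialectRule:
    """Interaction rule realising the dialect collision dynamics."""
    return DialectRule(params)


def monokinetic_rhs(
    V: np.ndarray,
    km: KernelMatrix,
    params: DialectParams,
    model: str = "network",
) -> np.ndarray:
    """Right-hand side of the nonlocal monokinetic dialect equation.

    ``model="network"`` is the equation derived from the interaction
    dynamics, whose nonlocal diffusion acts on p(V):

        dV/dt = -kappa (V - p(V)) + [ K_rho p(V) - kappa p(V) ],

    with (K_rho f)(x) = int w(x, x~) rho(x~) f(x~) dx~ and
    kappa = K_rho 1.  ``model="standard_rd"`` is the comparison model with
    the linear nonlocal diffusion acting on V itself.

    Both right-hand sides are tangent to the simplex (components sum to
    zero pointwise).  The kernel matrix must carry a density (kappa).
    """
    if km.kappa is None or km.density is None:
        raise ParameterError("kernel matrix needs an attached density (kappa)")
    V = np.asarray(V, dtype=float)
    if V.shape[0] != km.n:
        raise ParameterError("field length does not match kernel matrix")
    kappa = km.kappa[:, None]
    pV = choice_probabilities(V, params.alpha_exp)
    if model == "network":
        return km.apply_density_weighted(pV) - kappa * V
    if model == "standard_rd":
        return -kappa * (V - pV) + km.apply_density_weighted(V) - kappa * V
    raise ParameterError(f"unknown model {model!r}")


@dataclass(frozen=True)
class DialectLocalConfig:
    """Local-limit PDE configuration.

    ``variant``:
      * ``burridge`` — dV/dt = -kappa (V - p(V)) + sigma^2/2 Lap p(V)
        (the local limit of the network monokinetic equation);
      * ``allen_cahn_V`` — diffusion acts on V instead of p(V) (leading
        order when kappa >> sigma^2);
      * ``allen_cahn_P`` — the same dynamics advanced in the probability
        variable P = p(V): dP/dt = -kappa (V(P) - P) + sigma^2/2 Lap P.
    """

    kappa: float | np.ndarray
    sigma: float
    variant: str = "burridge"
    alpha_exp: float = 2.0

    def __post_init__(self):
        if np.any(np.asarray(self.kappa) < 0) or self.sigma < 0:
            raise ParameterError("kappa and sigma must be nonnegative")
        if self.variant not in ("burridge", "allen_cahn_V", "allen_cahn_P"):
            raise ParameterError(f"unknown local variant {self.variant!r}")


def _periodic_laplacian(f: np.ndarray, h: float) -> np.ndarray:
    """Second-order central Laplacian with periodic wrap; f is (n,) or (n, M)."""
    return (np.roll(f, -1, axis=0) - 2.0 * f + np.roll(f, 1, axis=0)) / h**2


def solve_local_pde(
    V0: np.ndarray,
    config: DialectLocalConfig,
    grid: SpatialGrid,
    t_end: float,
    dt: float | None = None,
    integrator: str = "rk4",
    store_every: int = 1,
) -> Trajectory:
    """Method-of-lines integration of the local dialect PDE on a periodic
    grid (rho = 1).  The stored states are always the memory field V; the
    ``allen_cahn_P`` variant is advanced in P and converted back through
    the inverse choice map.

    The default step is dt = 0.2 h^2 / sigma^2; a step beyond the diffusive
    stability limit h^2/sigma^2 triggers a warning.
    """
    if not grid.periodic:
        raise UnsupportedError("local PDE solver requires a periodic grid")
    h = grid.spacing
    sig2 = config.sigma**2
    if dt is None:
        if sig2 == 0:
            raise ParameterError("dt must be given when sigma = 0")
        dt = 0.2 * h**2 / sig2
    if sig2 > 0 and dt > h**2 / sig2:
        warnings.warn(
            f"dt={dt:g} exceeds the diffusive stability scale h^2/sigma^2="
            f"{h ** 2 / sig2:g}",
            stacklevel=2,
        )
    kappa = np.asarray(config.kappa, dtype=float)
    if kappa.ndim == 1:
        kappa = kappa[:, None]
    a = config.alpha_exp

    V0 = np.asarray(V0, dtype=float)
    if config.variant == "burridge":

        def rhs(t, V):
            pV = choice_probabilities(V, a)
            return -kappa * (V - pV) + 0.5 * sig2 * _periodic_laplacian(pV, h)

    elif config.variant == "allen_cahn_V":

        def rhs(t, V):
            pV = choice_probabilities(V, a)
            return -kappa * (V - pV) + 0.5 * sig2 * _periodic_laplacian(V, h)

    else:  # allen_cahn_P, advanced in P

        def rhs(t, P):
            VP = inverse_choice_map(P, a)
            return -kappa * (VP - P) + 0.5 * sig2 * _periodic_laplacian(P, h)

    y0 = choice_probabilities(V0, a) if config.variant == "allen_cahn_P" else V0
    cols = np.arange(V0.shape[-1])
    times, snaps = _integrate(
        rhs, y0, t_end, dt, integrator, store_every,
        postprocess=lambda y: _renormalize_simplex(y, cols),
    )
    if config.variant == "allen_cahn_P":
        snaps = np.asarray([inverse_choice_map(P, a) for P in snaps])
    return Trajectory(
        times=times,
        states=snaps,
        positions=grid.points,
        masses=grid.quad_weights,
        meta={
            "model": f"dialect_local_{config.variant}",
            "dt": dt,
            "integrator": integrator,
            "kappa": config.kappa,
            "sigma": config.sigma,
        },
    )
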