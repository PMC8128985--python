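"""Social-norm construction model (Shaw-type) on a discrete node network.

Each agent holds integer weights omega over M mental representations of an
action and a count I of past interactions.  After rescaling by a large
constant J (v = omega / sum(omega), s = I/J, h = 1/J) the state is a
simplex vector v plus a nonnegative scalar s, and one observed action i
updates

    v' = s/(s+h) v + h/(s+h) e_i,     s' = s + h ,

so early interactions move the weights a lot and later ones barely at all.
The active agent plays the action with the highest weight (ties broken
uniformly).  The monokinetic closure on a network with weights w_kl and
node densities rho_l is the non-autonomous system

    dV_k/dt = sum_l w_kl / (s_k^0 + lambda_k t) ( p(V_l) - V_k ),
    lambda_k = sum_l w_kl rho_l ,

whose 1/t-weakening interaction strength freezes the emerging norms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._trajectory import Trajectory
from .errors import DomainError, ParameterError
from .interaction_core import InteractionRule
from .meanfield import _integrate, _renormalize_simplex
from .dialect import choice_probabilities
from .spatial_network import NodeNetwork

__all__ = [
    "SocialParams",
    "SocialState",
    "rescale_states",
    "action_distribution",
    "social_update",
    "SocialRule",
    "social_rule",
    "interaction_rate_lambda",
    "solve_social_monokinetic",
]

_TIE_DECIMALS = 12  # exact-equality ties after rounding to 12 decimals


@dataclass(frozen=True)
class SocialParams:
    """M representations, rescaling constant J >= 1 (h = 1/J), network, and
    initial interaction-count variables s0 per node."""

    M: int
    J: float
    network: NodeNetwork
    s0: np.ndarray | float = 1.0

    def __post_init__(self):
        if self.M < 2:
            raise ParameterError("need at least two representations")
        if self.J < 1:
            raise ParameterError("rescaling constant J must be >= 1")
        s0 = np.broadcast_to(
            np.asarray(self.s0, dtype=float), (self.network.n_nodes,)
        ).copy()
        if np.any(s0 <= 0):
            raise DomainError("initial interaction counts s0 must be positive")
        object.__setattr__(self, "s0", s0)

    @property
    def h(self) -> float:
        return 1.0 / self.J


@dataclass(frozen=True)
class SocialState:
    """Rescaled agent state: simplex weights v and interaction count s."""

    v: np.ndarray
    s: float

    def as_vector(self) -> np.ndarray:
        return np.concatenate([np.asarray(self.v, dtype=float), [self.s]])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "SocialState":
        vec = np.asarray(vec, dtype=float)
        return cls(v=vec[:-1], s=float(vec[-1]))


def rescale_states(omega, I: float, J: float) -> SocialState:
    """Rescale raw counts: v = omega / sum(omega), s = I / J."""
    omega = np.asarray(omega, dtype=float)
    total = omega.sum()
    if total <= 0:
        raise DomainError("weight vector omega must have positive total")
    return SocialState(v=omega / total, s=I / J)


def action_distribution(v):
    """Uniform distribution over the argmax components of v (played action).

    Ties are detected by exact comparison after rounding to 12 decimals.
    Vectorised over leading axes.
    """
    v = np.asarray(v, dtype=float)
    r = np.round(v, _TIE_DECIMALS)
    top = r.max(axis=-1, keepdims=True)
    mask = (r == top).astype(float)
    return mask / mask.sum(axis=-1, keepdims=True)


def social_update(state: SocialState, action_index: int, h: float) -> SocialState:
    """One observed action i: v' = s/(s+h) v + h/(s+h) e_i, s' = s + h."""
    v = np.asarray(state.v, dtype=float)
    M = v.shape[-1]
    if not 0 <= action_index < M:
        raise ParameterError(f"action index {action_index} out of range")
    e = np.zeros(M)
    e[action_index] = 1.0
    s = state.s
    return SocialState(v=s / (s + h) * v + h / (s + h) * e, s=s + h)


class SocialRule(InteractionRule):
    """Interaction measure of the social-construction model.

    States are stored as (M+1)-vectors [v_1..v_M, s].  The active agent
    plays i ~ action_distribution(v_active) and is unchanged; the passive
    agent receives b = ( h/(s+h) (e_i - v), h ).  The mean-field rescaling
    parameter is h.
    """

    state_space = "simplex_count"

    def __init__(self, params: SocialParams):
        self.params = params
        self.state_dim = params.M + 1
        self.rescale_factor = params.h

    def _split(self, state):
        state = np.asarray(state, dtype=float)
        return state[..., :-1], state[..., -1:]

    def sample(self, v_active, v_passive, rng):
        M, h = self.params.M, self.params.h
        va, _ = self._split(v_active)
        vp, sp = self._split(v_passive)
        p = action_distribution(va)
        i = int(rng.choice(M, p=p))
        e = np.zeros(M)
        e[i] = 1.0
        bv = h / (sp[0] + h) * (e - vp)
        return np.zeros(M + 1), np.concatenate([bv, [h]])

    def mean_b(self, v_active, v_passive):
        h = self.params.h
        va, _ = self._split(v_active)
        vp, sp = self._split(v_passive)
        p = action_distribution(va)
        bv = h / (sp + h) * (p - vp)
        bs = np.full(bv.shape[:-1] + (1,), h)
        return np.concatenate([bv, bs], axis=-1)

    def second_moment_b(self, v_active, v_passive):
        M, h = self.params.M, self.params.h
        va, _ = self._split(v_active)
        vp, sp = self._split(v_passive)
        p = action_distribution(va)
        # atoms b_i = ( h/(s+h) (e_i - v), h ) with probability p_i
        c = h / (sp + h)  # (..., 1)
        d = np.eye(M) - vp[..., None, :]  # (..., i, k)
        bv = c[..., None] * d  # (..., i, k)
        bs = np.broadcast_to(
            h * np.ones(1), bv.shape[:-1]
        )[..., None]  # (..., i, 1)
        atoms = np.concatenate([bv, bs], axis=-1)  # (..., i, M+1)
        return np.einsum("...i,...ik,...il->...kl", p, atoms, atoms)


def social_rule(params: SocialParams) -> SocialRule:
    """Interaction rule realising the social-construction dynamics."""
    return SocialRule(params)


def interaction_rate_lambda(network: NodeNetwork) -> np.ndarray:
    """Per-node mean interaction load lambda_k = sum_l w_kl rho_l."""
    return network.weights @ network.node_density


def solve_social_monokinetic(
    V0: np.ndarray,
    params: SocialParams,
    t_end: float,
    dt: float,
    p_variant: str = "argmax",
    smooth_alpha: float = 20.0,
    integrator: str = "rk4",
    store_every: int = 1,
) -> Trajectory:
    """Integrate the non-autonomous monokinetic norm dynamics per node.

    The interaction count grows deterministically, s_k(t) = s_k^0 +
    lambda_k t, so only the V_k need to be advanced.  ``p_variant`` selects
    the played-action map: the model's discontinuous ``argmax`` (solutions
    may be non-unique at ties; integrated with a fixed small step) or
    ``smooth``, the conformity map v^alpha/sum v^alpha with a large
    exponent as a regularisation.
    """
    net = params.network
    V0 = np.asarray(V0, dtype=float)
    if V0.shape != (net.n_nodes, params.M):
        raise ParameterError("V0 must be (n_nodes, M)")
    lam = interaction_rate_lambda(net)
    s0 = params.s0
    if p_variant == "argmax":
        pmap = action_distribution
    elif p_variant == "smooth":
        pmap = lambda v: choice_probabilities(v, smooth_alpha)
    else:
        raise ParameterError(f"unknown p_variant {p_variant!r}")

    w = net.weights

    def rhs(t, V):
        pV = pmap(V)
        decay = 1.0 / (s0 + lam * t)  # (n,)
        # sum_l w_kl (p(V_l) - V_k) = (w @ pV)_k - rowsum_k V_k
        interaction = w @ pV - w.sum(axis=1)[:, None] * V
        return decay[:, None] * interaction

    cols = np.arange(params.M)
    times, snaps = _integrate(
        rhs, V0, t_end, dt, integrator, store_every,
        postprocess=lambda y: _renormalize_simplex(y, cols),
    )
    return Trajectory(
        times=times,
        states=snaps,
        positions=net.positions,
        masses=net.node_density,
        meta={
            "model": "social_monokinetic",
            "p_variant": p_variant,
            "dt": dt,
            "integrator": integrator,
        },
    )
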