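"""Stochastic N-agent simulator for network-structured binary interactions.

Each of the N agents carries a fixed position x_i (its place in the
interaction network) and a mutable state v_i.  Ordered pairs (i, j) — i
active, j passive — interact at rate w(x_i, x_j)/N; the 1/N mean-field
scaling keeps the total interaction pressure on a single agent of order one
as N grows.  On an interaction, increments (a, b) are drawn from the
interaction rule's measure nu_{z_i, z_j} and applied as v_i += a,
v_j += b.  Unary channels (single-agent transitions at state-dependent
rates, e.g. removal of infected agents) are supported as an explicit
extension of the pure pair-interaction framework.

The simulator is an exact Gillespie (event-driven) realisation of the
underlying jump process: waiting times are exponential with the total event
rate, and the event type is chosen proportionally to its rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, ParameterError, SimulationError
from .spatial_network import Kernel, evaluate_kernel

__all__ = [
    "AgentEnsemble",
    "InteractionRule",
    "UnaryChannel",
    "EventLog",
    "total_pair_rate",
    "simulate_boltzmann",
    "empirical_marginals",
]


@dataclass
class AgentEnsemble:
    """N agents with immutable positions and mutable states.

    ``states`` is ``(N, s)`` float for continuous state spaces (the entries
    of a probability simplex, say) or ``(N,)`` integer for categorical ones.
    Positions are frozen after construction: agents never move, they only
    change state.
    """

    positions: np.ndarray
    states: np.ndarray
    state_space: str = "real"  # real | simplex | categorical | simplex_count

    def __post_init__(self):
        pos = np.array(self.positions, dtype=float)
        pos.setflags(write=False)
        self.positions = pos
        self.states = np.array(self.states)
        if self.states.shape[0] != len(pos):
            raise ParameterError("states and positions must have equal length")

    @property
    def N(self) -> int:
        return len(self.positions)

    def copy(self) -> "AgentEnsemble":
        return AgentEnsemble(self.positions, self.states.copy(), self.state_space)


@dataclass(frozen=True)
class UnaryChannel:
    """Single-agent transition: per-agent rate and sampled state increment."""

    name: str
    rate: Callable[[np.ndarray], np.ndarray]  # states -> (N,) rates
    sample: Callable[[np.ndarray, np.random.Generator], np.ndarray]


class InteractionRule:
    """Contract every interaction model implements.

    The pair-interaction measure nu_{z, z~} of a rule is exposed three ways:
    by sampling (``sample``), through its first moments (``mean_a``,
    ``mean_b``) and through its second moments — the latter two feed the
    Vlasov and Fokker-Planck coefficient assembly.  ``rescale_factor`` is
    the small parameter by which time is rescaled in the mean-field
    (Vlasov) regime.

    Moment methods must broadcast over leading axes of their arguments.
    """

    state_dim: int = 1
    state_space: str = "real"
    rescale_factor: float = 1.0
    unary_channels: Sequence[UnaryChannel] = ()

    # -- sampling ----------------------------------------------------------

    def sample(self, v_active, v_passive, rng: np.random.Generator):
        """Draw one increment pair (a, b) from nu_{z, z~}."""
        raise NotImplementedError

    # -- moments -----------------------------------------------------------

    def mean_a(self, v_active, v_passive):
        """E[a] under nu; a is the active agent's own increment."""
        return np.zeros(np.shape(v_active))

    def mean_b(self, v_active, v_passive):
        """E[b] under nu; b is the passive agent's increment."""
        raise NotImplementedError

    def second_moment_a(self, v_active, v_passive):
        s = self.state_dim
        shape = np.broadcast_shapes(np.shape(v_active)[:-1], np.shape(v_passive)[:-1])
        return np.zeros(shape + (s, s))

    def second_moment_b(self, v_active, v_passive):
        raise NotImplementedError


@dataclass
class EventLog:
    """Record of a simulation run: event times, pairs, applied increments,
    and optional state snapshots."""

    times: np.ndarray
    pairs: np.ndarray  # (n_events, 2): (active, passive); passive=-1 for unary
    increments: list
    n_pair_events: int = 0
    n_unary_events: int = 0
    snapshot_times: np.ndarray | None = None
    snapshots: list = field(default_factory=list)
    snapshot_positions: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ParameterError("event times must be nondecreasing")


def _pair_weight_matrix(ensemble: AgentEnsemble, kernel: Kernel, periodic: bool):
    x = ensemble.positions
    w = evaluate_kernel(kernel, x[:, None], x[None, :], periodic)
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)  # the pair sum runs over i != j
    if not np.all(np.isfinite(w)):
        raise SimulationError("non-finite kernel values among agent pairs")
    return w / ensemble.N


def total_pair_rate(
    ensemble: AgentEnsemble, kernel: Kernel, periodic: bool = True
) -> float:
    """Total interaction rate Lambda = sum_{i != j} w(x_i, x_j) / N."""
    if ensemble.N < 2:
        return 0.0
    return float(_pair_weight_matrix(ensemble, kernel, periodic).sum())


def simulate_boltzmann(
    ensemble: AgentEnsemble,
    rule: InteractionRule,
    kernel: Kernel,
    t_end: float,
    seed: int | np.random.Generator,
    periodic: bool = True,
    snapshot_times: Sequence[float] | None = None,
    snapshot_every_events: int | None = None,
    max_events: int | None = None,
    log_events: bool = False,
) -> tuple[AgentEnsemble, EventLog]:
    """Exact Gillespie simulation of the pair-interaction jump process.

    Returns the final ensemble (positions untouched) and an event log.
    Snapshots can be taken on a time schedule (``snapshot_times``) or every
    k-th event (``snapshot_every_events``); each snapshot stores a copy of
    the states and of the positions, so conservation of the spatial
    marginal can be checked from the log alone.
    """
    if t_end < 0:
        raise ParameterError("t_end must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out = ensemble.copy()
    states = out.states
    N = out.N

    if N >= 2:
        w = _pair_weight_matrix(out, kernel, periodic)
        pair_rate = float(w.sum())
        pair_cum = np.cumsum(w.ravel())
    else:
        pair_rate, pair_cum = 0.0, None

    sched = None
    if snapshot_times is not None:
        sched = np.sort(np.asarray(snapshot_times, dtype=float))
    next_sched = 0

    ev_times: list[float] = []
    ev_pairs: list[tuple[int, int]] = []
    ev_incs: list = []
    snap_t: list[float] = []
    snaps: list[np.ndarray] = []
    snap_pos: list[np.ndarray] = []

    def take_snapshot(t: float):
        snap_t.append(t)
        snaps.append(states.copy())
        snap_pos.append(out.positions.copy())

    if snapshot_every_events is not None:
        take_snapshot(0.0)

    t = 0.0
    n_pair = n_unary = 0
    n_events = 0
    while True:
        if max_events is not None and n_events >= max_events:
            break
        unary_rates = None
        unary_totals = []
        if rule.unary_channels:
            unary_rates = [np.asarray(ch.rate(states), dtype=float)
                           for ch in rule.unary_channels]
            unary_totals = [float(r.sum()) for r in unary_rates]
        total = pair_rate + sum(unary_totals)
        if total <= 0:
            t = t_end
            break
        t_next = t + rng.exponential(1.0 / total)
        # flush scheduled snapshots passed before this event
        if sched is not None:
            while next_sched < len(sched) and sched[next_sched] <= min(t_next, t_end):
                take_snapshot(float(sched[next_sched]))
                next_sched += 1
        if not np.isfinite(t_end) and max_events is None:
            raise ParameterError("infinite t_end requires max_events")
        if t_next > t_end:
            t = t_end
            break
        t = t_next
        u = rng.random() * total
        if u < pair_rate:
            k = int(np.searchsorted(pair_cum, rng.random() * pair_rate))
            k = min(k, N * N - 1)
            i, j = divmod(k, N)
            a, b = rule.sample(states[i], states[j], rng)
            states[i] = states[i] + a
            states[j] = states[j] + b
            n_pair += 1
            if log_events:
                ev_times.append(t)
                ev_pairs.append((i, j))
                ev_incs.append((a, b))
        else:
            u -= pair_rate
            for ch, rates, tot in zip(rule.unary_channels, unary_rates, unary_totals):
                if u < tot:
                    cum = np.cumsum(rates)
                    i = int(np.searchsorted(cum, rng.random() * tot))
                    i = min(i, N - 1)
                    states[i] = states[i] + ch.sample(states[i], rng)
                    n_unary += 1
                    if log_events:
                        ev_times.append(t)
                        ev_pairs.append((i, -1))
                        ev_incs.append((ch.name,))
                    break
                u -= tot
        n_events += 1
        if (
            snapshot_every_events is not None
            and n_events % snapshot_every_events == 0
        ):
            take_snapshot(t)
        # guard floating-point drift off the simplex
        if out.state_space == "simplex":
            ssum = states.sum(axis=1)
            bad = np.abs(ssum - 1.0) > 1e-12
            if np.any(bad):
                states[bad] /= ssum[bad, None]

    if sched is not None:
        while next_sched < len(sched):
            take_snapshot(float(sched[next_sched]))
            next_sched += 1

    log = EventLog(
        times=np.asarray(ev_times),
        pairs=np.asarray(ev_pairs, dtype=int).reshape(-1, 2),
        increments=ev_incs,
        n_pair_events=n_pair,
        n_unary_events=n_unary,
        snapshot_times=np.asarray(snap_t) if snap_t else None,
        snapshots=snaps,
        snapshot_positions=snap_pos,
    )
    return out, log


def empirical_marginals(ensemble: AgentEnsemble, bins):
    """Empirical spatial marginal and per-bin conditional mean state.

    ``bins`` is a bin count or an array of edges covering the domain.
    Returns ``(eta, mean_state, counts)``: ``eta`` sums to one; the mean
    state is NaN where a bin is empty.
    """
    x = ensemble.positions
    if np.isscalar(bins):
        edges = np.linspace(0.0, 1.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(x, bins=edges)
    eta = counts / ensemble.N
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    states = np.asarray(ensemble.states, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    sums = np.zeros((len(edges) - 1, states.shape[1]))
    np.add.at(sums, idx, states)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_state = sums / counts[:, None]
    mean_state[counts == 0] = np.nan
    return eta, mean_state, counts
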