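"""Observables and conservation/concentration diagnostics shared by all
models: quadratic variation of the state distribution, Wasserstein-type
concentration distance to a monokinetic profile, and per-model
conservation reports."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._trajectory import Trajectory
from .errors import ParameterError
from .interaction_core import AgentEnsemble

__all__ = [
    "VarianceReport",
    "Observable",
    "quadratic_variation",
    "concentration_metric",
    "conservation_report",
    "fit_decay_rate",
]


@dataclass
class VarianceReport:
    """Quadratic variation V(t) = sum_x mass |v - Vbar(x, t)|^2 over time,
    with the per-position conditional means and a fitted exponential decay
    rate (least squares on log V where V > 1e-12)."""

    times: np.ndarray
    variation: np.ndarray
    conditional_means: list
    decay_rate: float | None = None
    r_squared: float | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.variation) < -1e-15):
            raise ParameterError("quadratic variation must be nonnegative")


def _group_indices(positions: np.ndarray, binning) -> np.ndarray:
    """Map each sample to a spatial group: unique positions (grid/network
    setups share exact coordinates) or fixed-width bins."""
    if binning == "unique":
        _, idx = np.unique(np.round(positions, 12), return_inverse=True)
        return idx
    edges = (
        np.linspace(0.0, 1.0, int(binning) + 1)
        if np.isscalar(binning)
        else np.asarray(binning, dtype=float)
    )
    return np.clip(np.digitize(positions, edges) - 1, 0, len(edges) - 2)


def _snapshot_variance(positions, states, masses, binning):
    states = np.asarray(states, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    if masses is None:
        masses = np.full(len(positions), 1.0 / len(positions))
    idx = _group_indices(np.asarray(positions, dtype=float), binning)
    n_groups = idx.max() + 1
    msum = np.zeros(n_groups)
    np.add.at(msum, idx, masses)
    vsum = np.zeros((n_groups, states.shape[1]))
    np.add.at(vsum, idx, masses[:, None] * states)
    with np.errstate(invalid="ignore", divide="ignore"):
        vbar = vsum / msum[:, None]
    vbar[msum == 0] = np.nan
    dev = states - vbar[idx]
    total = float(np.sum(masses * np.einsum("ns,ns->n", dev, dev)))
    return total, vbar


def fit_decay_rate(times, values, floor: float = 1e-12):
    """Least-squares exponential decay rate of a positive time series.

    Fits log(values) ~ -rate * t + c on the window where values > floor;
    returns (rate, r_squared) or (None, None) if fewer than two points
    survive."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = values > floor
    if mask.sum() < 2:
        return None, None
    t, y = times[mask], np.log(values[mask])
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return -float(slope), float(r2)


def quadratic_variation(obj, binning="unique", masses=None) -> VarianceReport:
    """Quadratic variation of states about their position-conditional mean.

    ``obj`` may be a :class:`Trajectory` (a full report over time), an
    :class:`AgentEnsemble`, or a tuple ``(positions, states)``; ``binning``
    is ``"unique"`` (group by exact shared positions) or a bin count /
    edge array for scattered positions.
    """
    if isinstance(obj, Trajectory):
        var, means = [], []
        for k in range(obj.n_times):
            tot, vbar = _snapshot_variance(
                obj.positions, obj.states[k], obj.masses, binning
            )
            var.append(tot)
            means.append(vbar)
        rate, r2 = fit_decay_rate(obj.times, np.asarray(var))
        return VarianceReport(
            times=obj.times,
            variation=np.asarray(var),
            conditional_means=means,
            decay_rate=rate,
            r_squared=r2,
        )
    if isinstance(obj, AgentEnsemble):
        positions, states = obj.positions, obj.states
        if masses is None:
            masses = np.full(obj.N, 1.0 / obj.N)
    else:
        positions, states = obj
    tot, vbar = _snapshot_variance(positions, states, masses, binning)
    return VarianceReport(
        times=np.zeros(1), variation=np.asarray([tot]), conditional_means=[vbar]
    )


def concentration_metric(
    positions, states, masses, vbar_at_samples, p: float = 2.0
) -> float:
    """Distance of a per-position state distribution to the concentrated
    (monokinetic) profile vbar.

    When the target measure is concentrated at one state per position, the
    p-Wasserstein distance between the conditional distributions has the
    closed form ( sum mass |v - vbar(x)|^p )^{1/p}; for p = 2 its square
    equals the quadratic variation when vbar is the conditional mean.
    """
    if p < 1:
        raise ParameterError("Wasserstein order p must be >= 1")
    states = np.asarray(states, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    vbar = np.asarray(vbar_at_samples, dtype=float)
    if vbar.ndim == 1:
        vbar = vbar[:, None]
    if masses is None:
        masses = np.full(states.shape[0], 1.0 / states.shape[0])
    dev = np.linalg.norm(states - vbar, axis=-1)
    return float(np.sum(np.asarray(masses) * dev**p) ** (1.0 / p))


_DEFAULT_TOLERANCES = {
    "marginal_drift": 0.0,
    "simplex_residual": 1e-10,
    "mass_residual": 1e-8,
    "monotonicity": 1e-12,
    "negativity": -1e-10,
}


def conservation_report(traj, model_tag: str, tolerances: dict | None = None,
                        event_log=None) -> dict:
    """Conservation and monotonicity summary for a run.

    Tags
    ----
    ``agents`` : max total-variation drift of the empirical spatial
        marginal across snapshots (requires an event log with snapshots,
        or a Trajectory whose states were recorded over time), plus the
        simplex residual when states are simplex-valued.
    ``dialect`` / ``social`` : max pointwise |sum_i V_i - 1|.
    ``sir_network`` / ``sir_rd`` : max pointwise |u+v+r - (u0+v0+r0)|,
        count of u-monotonicity violations, min of u, v, and u+v.

    Every number is reported alongside a pass flag against the configured
    tolerance.
    """
    tol = dict(_DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    report: dict = {"model": model_tag}

    if model_tag == "agents":
        if event_log is None or not event_log.snapshot_positions:
            raise ParameterError("agents report needs an event log with snapshots")
        bins = np.linspace(0.0, 1.0, 21)
        hists = [
            np.histogram(pos, bins=bins)[0] / len(pos)
            for pos in event_log.snapshot_positions
        ]
        drift = max(
            float(np.abs(h - hists[0]).sum()) for h in hists
        ) if hists else 0.0
        report["marginal_drift"] = drift
        report["marginal_drift_pass"] = drift <= tol["marginal_drift"]
        first = event_log.snapshots[0]
        if np.asarray(first).ndim == 2:  # simplex-valued states
            res = max(
                float(np.abs(np.asarray(s).sum(axis=1) - 1.0).max())
                for s in event_log.snapshots
            )
            report["simplex_residual"] = res
            report["simplex_residual_pass"] = res <= tol["simplex_residual"]
        return report

    if not isinstance(traj, Trajectory):
        raise ParameterError("need a Trajectory for field/particle reports")

    if model_tag in ("dialect", "social"):
        res = float(np.abs(traj.states.sum(axis=2) - 1.0).max())
        report["simplex_residual"] = res
        report["simplex_residual_pass"] = res <= tol["simplex_residual"]
        return report

    if model_tag in ("sir_network", "sir_rd"):
        total = traj.states.sum(axis=2)  # (T, n): u+v+r
        res = float(np.abs(total - total[0]).max())
        u = traj.states[:, :, 0]
        v = traj.states[:, :, 1]
        viol = int(np.sum(np.diff(u, axis=0) > tol["monotonicity"]))
        report["mass_residual"] = res
        report["mass_residual_pass"] = res <= tol["mass_residual"]
        report["u_monotonicity_violations"] = viol
        report["u_monotone_pass"] = (viol == 0) if model_tag == "sir_network" else None
        report["min_u"] = float(u.min())
        report["min_v"] = float(v.min())
        report["min_u_plus_v"] = float((u + v).min())
        report["nonnegative_pass"] = min(u.min(), v.min()) >= tol["negativity"]
        return report

    raise ParameterError(f"unknown model tag {model_tag!r}")


@dataclass(frozen=True)
class Observable:
    """Named test function of (x, v), averaged against ensembles, particle
    sets or fields (mass-weighted)."""

    name: str
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def mean(self, positions, states, masses=None) -> float:
        positions = np.asarray(positions, dtype=float)
        vals = np.asarray(self.fn(positions, np.asarray(states)), dtype=float)
        if masses is None:
            masses = np.full(len(positions), 1.0 / len(positions))
        return float(np.sum(np.asarray(masses) * vals))
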