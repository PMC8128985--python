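"""Shared trajectory container for agent, particle and field solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Time series of states attached to fixed positions.

    Attributes
    ----------
    times : (T,) array of output times, nondecreasing.
    states : (T, n, s) array; ``states[k, i]`` is the state of point/agent
        ``i`` at ``times[k]``.  For categorical models ``s == 1`` and the
        entries are integer codes.
    positions : (n,) array of structural (spatial/network) coordinates.
        Positions never change along a trajectory; this is a modelling
        assumption, not a numerical accident.
    masses : (n,) array of point masses (quadrature weight times density for
        fields, particle masses for mean-field particles, ``1/N`` for agents)
        or ``None``.
    meta : free-form run metadata (model tag, parameters, solver options).
    """

    times: np.ndarray
    states: np.ndarray
    positions: np.ndarray
    masses: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.states.ndim == 2:  # scalar state: promote to (T, n, 1)
            self.states = self.states[:, :, None]
        if np.any(np.diff(self.times) < 0):
            raise ValueError("trajectory times must be nondecreasing")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_points(self) -> int:
        return self.states.shape[1]

    @property
    def state_dim(self) -> int:
        return self.states.shape[2]

    def state_at(self, t: float) -> np.ndarray:
        """State snapshot at the stored time closest to ``t``."""
        k = int(np.argmin(np.abs(self.times - t)))
        return self.states[k]
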