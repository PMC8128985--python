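"""Spatial grids, node networks, interaction kernels and nonlocal operators.

Agents live on a structural (spatial or network) variable that never changes
during interactions.  The continuum setting is the periodic unit interval
``[0, 1)``; the discrete setting is a finite weighted graph.  An interaction
kernel ``w(x, y)`` assigns a contact rate to every pair of positions; its
quadrature discretisation yields the matrix operators used by every
mean-field solver, in particular the nonlocal Laplacian

    (L_w phi)(x) = int w(x, y) (phi(y) - phi(x)) dy .
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError, UnsupportedError

__all__ = [
    "SpatialGrid",
    "NodeNetwork",
    "Kernel",
    "KernelMatrix",
    "periodic_distance",
    "evaluate_kernel",
    "discretize_kernel",
    "kernel_matrix_from_network",
    "nonlocal_laplacian",
    "local_limit_sigma",
    "uniform_profile",
    "triangle_profile",
]


def periodic_distance(x, y):
    """Distance on the periodic unit interval: min(|x-y|, 1-|x-y|)."""
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    return np.minimum(d, 1.0 - d)


# --------------------------------------------------------------------------
# grids and networks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialGrid:
    """Node-centred 1-D grid on the half-open unit interval [0, 1).

    ``quad_weights`` are rectangle-rule weights (the grid spacing for a
    uniform grid), so that ``sum(quad_weights * f)`` approximates the
    integral of ``f`` over the domain.
    """

    points: np.ndarray
    spacing: float
    periodic: bool = True
    quad_weights: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or len(pts) == 0:
            raise ParameterError("grid points must be a nonempty 1-D array")
        if np.any(np.diff(pts) <= 0):
            raise ParameterError("grid points must be strictly increasing")
        if self.quad_weights is None:
            object.__setattr__(
                self, "quad_weights", np.full(len(pts), float(self.spacing))
            )
        else:
            qw = np.asarray(self.quad_weights, dtype=float)
            if qw.shape != pts.shape:
                raise ParameterError("quad_weights must match points")
            if np.any(qw <= 0):
                raise ParameterError("quad_weights must be positive")
            object.__setattr__(self, "quad_weights", qw)

    @classmethod
    def uniform(cls, n: int, periodic: bool = True) -> "SpatialGrid":
        """Uniform grid ``x_i = i * h`` with ``h = 1/n`` on [0, 1)."""
        h = 1.0 / n
        return cls(points=np.arange(n) * h, spacing=h, periodic=periodic)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class NodeNetwork:
    """Finite weighted graph of interaction sites.

    ``weights[k, l]`` is the interaction weight from node ``k`` to node
    ``l``; ``node_density[k]`` the (stationary) agent density at node ``k``.
    Whether the diagonal contributes to nonlocal operators is decided when
    building a :class:`KernelMatrix`, not here.
    """

    weights: np.ndarray
    node_density: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ParameterError("weights must be a square matrix")
        if np.any(w < 0):
            raise ParameterError("network weights must be nonnegative")
        self.weights = w
        n = w.shape[0]
        if self.node_density is None:
            self.node_density = np.ones(n)
        else:
            rho = np.asarray(self.node_density, dtype=float)
            if rho.shape != (n,) or np.any(rho < 0):
                raise ParameterError("node_density must be nonnegative, length n")
            self.node_density = rho
        if self.positions is None:
            self.positions = np.arange(n, dtype=float)
        else:
            self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, edge_path, node_path=None) -> None:
        """Write edge list (columns i, j, weight) and optional node table."""
        ii, jj = np.nonzero(self.weights)
        pd.DataFrame(
            {"i": ii, "j": jj, "weight": self.weights[ii, jj]}
        ).to_csv(edge_path, index=False, float_format="%.17g")
        if node_path is not None:
            pd.DataFrame(
                {
                    "i": np.arange(self.n_nodes),
                    "x": self.positions,
                    "rho": self.node_density,
                }
            ).to_csv(node_path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, edge_path, node_path=None, n_nodes=None) -> "NodeNetwork":
        edges = pd.read_csv(edge_path)
        if n_nodes is None:
            n_nodes = int(max(edges["i"].max(), edges["j"].max())) + 1
        w = np.zeros((n_nodes, n_nodes))
        w[edges["i"].to_numpy(int), edges["j"].to_numpy(int)] = edges[
            "weight"
        ].to_numpy(float)
        rho = None
        pos = None
        if node_path is not None:
            nodes = pd.read_csv(node_path).sort_values("i")
            rho = nodes["rho"].to_numpy(float)
            pos = nodes["x"].to_numpy(float)
        return cls(weights=w, node_density=rho, positions=pos)


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------


def uniform_profile() -> tuple[Callable, float]:
    """Even box profile k = 1/2 on [-1, 1]; second moment C = 1/3."""
    return (lambda r: np.where(np.abs(r) <= 1.0, 0.5, 0.0), 1.0 / 3.0)


def triangle_profile() -> tuple[Callable, float]:
    """Even hat profile k(r) = (1 - |r|)_+ ; second moment C = 1/6."""
    return (lambda r: np.maximum(1.0 - np.abs(r), 0.0), 1.0 / 6.0)


_KERNEL_FORMS = ("triangular", "scaled_local", "constant", "matrix")


@dataclass(frozen=True)
class Kernel:
    """Interaction kernel ``w(x, y)`` on the unit interval.

    Forms
    -----
    triangular : ``w = amplitude * (cutoff - d(x, y))_+`` (compact support).
    scaled_local : ``w = eps^{-1} k(d(x, y) / eps)`` with an even,
        nonnegative base profile ``k``; ``second_moment`` is the second
        moment C of ``k``, so the local (eps -> 0) diffusion scale is
        ``sigma = sqrt(C) * eps``.
    constant : ``w = amplitude`` everywhere (all-to-all coupling).
    matrix : discrete node weights; use :func:`kernel_matrix_from_network`.
    """

    form: str
    amplitude: float = 1.0
    cutoff: float = 0.2
    eps: float = 0.1
    base_profile: Callable | None = None
    second_moment: float | None = None
    matrix: np.ndarray | None = None

    def __post_init__(self):
        if self.form not in _KERNEL_FORMS:
            raise ParameterError(f"unknown kernel form {self.form!r}")
        if self.form == "matrix":
            if self.matrix is None:
                raise ParameterError("matrix kernel needs a weight matrix")
            m = np.asarray(self.matrix, dtype=float)
            if np.any(m < 0):
                raise ParameterError("kernel weights must be nonnegative")
            object.__setattr__(self, "matrix", m)
        if self.amplitude < 0:
            raise ParameterError("kernel amplitude must be nonnegative")
        if self.cutoff < 0:
            raise ParameterError("kernel cutoff must be nonnegative")
        if self.form == "scaled_local":
            if self.eps < 0:
                raise ParameterError("kernel scale eps must be nonnegative")
            if self.base_profile is None:
                k, c = uniform_profile()
                object.__setattr__(self, "base_profile", k)
                if self.second_moment is None:
                    object.__setattr__(self, "second_moment", c)

    # convenience constructors ---------------------------------------------

    @classmethod
    def triangular(cls, amplitude: float, cutoff: float) -> "Kernel":
        return cls(form="triangular", amplitude=amplitude, cutoff=cutoff)

    @classmethod
    def constant(cls, amplitude: float = 1.0) -> "Kernel":
        return cls(form="constant", amplitude=amplitude)

    @classmethod
    def scaled_local(cls, eps: float, profile: str | tuple = "uniform") -> "Kernel":
        if isinstance(profile, str):
            k, c = {"uniform": uniform_profile, "triangle": triangle_profile}[
                profile
            ]()
        else:
            k, c = profile
        return cls(form="scaled_local", eps=eps, base_profile=k, second_moment=c)

    @classmethod
    def from_network(cls, network: "NodeNetwork") -> "Kernel":
        """Discrete kernel on a node network; positions are node indices."""
        return cls(form="matrix", matrix=network.weights)


def evaluate_kernel(kernel: Kernel, x, y, periodic: bool = True):
    """Evaluate ``w(x, y)`` (vectorised; broadcasts over x and y).

    Uses the periodic distance min(|x-y|, 1-|x-y|) when ``periodic``;
    otherwise plain |x-y|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kernel.form == "matrix":  # positions are (integer-valued) node ids
        return kernel.matrix[x.astype(int), y.astype(int)]
    if kernel.form == "constant":
        return np.broadcast_arrays(x, y)[0] * 0.0 + kernel.amplitude
    d = periodic_distance(x, y) if periodic else np.abs(x - y)
    if kernel.form == "triangular":
        return kernel.amplitude * np.maximum(kernel.cutoff - d, 0.0)
    # scaled_local
    if kernel.eps == 0:
        raise ParameterError("scaled_local kernel with eps=0 cannot be evaluated")
    return kernel.base_profile(d / kernel.eps) / kernel.eps


def local_limit_sigma(kernel: Kernel) -> float:
    """Diffusion length ``sigma = sqrt(C) * eps`` of a scaled local kernel."""
    if kernel.form != "scaled_local":
        raise UnsupportedError("local limit is defined for scaled_local kernels only")
    if kernel.second_moment is None:
        raise ParameterError("scaled_local kernel needs a second moment")
    return float(np.sqrt(kernel.second_moment) * kernel.eps)


# --------------------------------------------------------------------------
# discretised kernels and nonlocal operators
# --------------------------------------------------------------------------


@dataclass
class KernelMatrix:
    """Quadrature discretisation of a kernel on a grid or node set.

    ``matrix[i, j] = w(x_i, x_j) * quad_weights[j]`` so that
    ``matrix @ f`` approximates ``int w(x_i, y) f(y) dy``.

    ``row_integral[i]`` approximates ``alpha(x_i) = int w(x_i, y) dy`` and
    ``kappa[i] = int w(x_i, y) rho(y) dy`` when a density is attached.
    """

    matrix: np.ndarray
    row_integral: np.ndarray
    points: np.ndarray
    quad_weights: np.ndarray
    density: np.ndarray | None = None
    kappa: np.ndarray | None = None
    include_diagonal: bool = True

    def __post_init__(self):
        if np.any(self.matrix < 0):
            raise ParameterError("kernel matrix entries must be nonnegative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def apply(self, f: np.ndarray) -> np.ndarray:
        """Quadrature of ``int w(x_i, y) f(y) dy`` (f may be (n,) or (n, s))."""
        return self.matrix @ np.asarray(f, dtype=float)

    def apply_density_weighted(self, f: np.ndarray) -> np.ndarray:
        """Quadrature of ``int w(x_i, y) rho(y) f(y) dy``."""
        if self.density is None:
            raise ParameterError("no density attached to this KernelMatrix")
        f = np.asarray(f, dtype=float)
        rho = self.density if f.ndim == 1 else self.density[:, None]
        return self.matrix @ (rho * f)


def discretize_kernel(
    kernel: Kernel,
    grid: SpatialGrid,
    density: np.ndarray | None = None,
    include_diagonal: bool = True,
) -> KernelMatrix:
    """Rectangle-rule discretisation of a kernel on a grid.

    ``include_diagonal`` keeps the self-interaction entry ``w(x_i, x_i)``;
    continuum integrals include it, agent pair sums (which run over i != j)
    do not.
    """
    pts = grid.points
    w = evaluate_kernel(kernel, pts[:, None], pts[None, :], grid.periodic)
    mat = w * grid.quad_weights[None, :]
    if not include_diagonal:
        np.fill_diagonal(mat, 0.0)
    row = mat.sum(axis=1)
    kappa = None
    if density is not None:
        density = np.asarray(density, dtype=float)
        if density.shape != pts.shape:
            raise ParameterError("density must match the grid")
        kappa = mat @ density
    return KernelMatrix(
        matrix=mat,
        row_integral=row,
        points=pts,
        quad_weights=grid.quad_weights,
        density=density,
        kappa=kappa,
        include_diagonal=include_diagonal,
    )


def kernel_matrix_from_network(
    network: NodeNetwork, include_diagonal: bool = True
) -> KernelMatrix:
    """Kernel matrix of a discrete node network (unit quadrature weights)."""
    mat = network.weights.copy()
    if not include_diagonal:
        np.fill_diagonal(mat, 0.0)
    rho = network.node_density
    return KernelMatrix(
        matrix=mat,
        row_integral=mat.sum(axis=1),
        points=network.positions,
        quad_weights=np.ones(network.n_nodes),
        density=rho,
        kappa=mat @ rho,
        include_diagonal=include_diagonal,
    )


def nonlocal_laplacian(km: KernelMatrix, field_values: np.ndarray) -> np.ndarray:
    """Nonlocal Laplacian ``int w(x, y)(f(y) - f(x)) dy`` on the grid.

    Annihilates constants exactly and conserves the quadrature integral of
    ``f`` for symmetric kernels.
    """
    f = np.asarray(field_values, dtype=float)
    if f.shape[0] != km.n:
        raise ParameterError(
            f"field length {f.shape[0]} does not match kernel matrix size {km.n}"
        )
    row = km.row_integral if f.ndim == 1 else km.row_integral[:, None]
    return km.matrix @ f - row * f
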