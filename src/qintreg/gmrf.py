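"""Gaussian Markov random field precision structures and constrained sampling.

The latent effects of the structured additive quantile model are all zero-mean
GMRFs ``x ~ N(0, (kappa * Q)^+)`` with a *structure* matrix ``Q`` that encodes
the smoothness/neighbourhood assumption and a scalar precision hyperparameter
``kappa``:

* ``RW1`` — first-order random walk penalty, ``Q = D1' D1`` (tridiagonal,
  rank n-1, null space = constants);
* ``RW2`` — second-order random walk, ``Q = D2' D2`` (pentadiagonal, rank
  n-2, null space = constants and linear trends);
* ``ICAR`` — intrinsic CAR on a region graph, ``Q = D - A`` (graph Laplacian,
  rank n-1 on a connected graph);
* ``PCAR`` — proper CAR, ``Q = D - rho*A`` with ``|rho| < 1`` (diagonally
  dominant, hence positive definite);
* ``IID`` — exchangeable effects, ``Q = I``.

Intrinsic (rank-deficient) structures are identified via sum-to-zero
constraints; sampling uses conditioning by kriging with a small jitter on the
null space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .graphs import RegionGraph

__all__ = [
    "LatentSpec",
    "PrecisionStructure",
    "build_latent_precision",
    "build_pcar_precision",
    "sample_constrained_gmrf",
    "export_structure",
]

Kind = Literal["RW1", "RW2", "ICAR", "PCAR", "IID"]

#: jitter added along null-space directions when sampling an intrinsic GMRF;
#: the kriging projection removes its influence exactly (see docs/methods.md)
NULL_SPACE_JITTER = 1e-8


@dataclass(frozen=True)
class LatentSpec:
    """Declaration of one latent GMRF term.

    ``dimension`` is required for RW1/RW2/IID; ``graph`` for ICAR/PCAR.
    ``precision_hyperprior`` are the (shape, rate) of the Gamma prior on the
    precision hyperparameter, i.e. a log-gamma prior on the log precision.
    """

    kind: Kind
    dimension: int | None = None
    graph: RegionGraph | None = None
    rho: float | None = None
    precision_hyperprior: tuple[float, float] = (1.0, 5e-5)
    sum_to_zero: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("RW1", "RW2", "ICAR", "PCAR", "IID"):
            raise ValueError(f"unknown latent kind {self.kind!r}")
        if self.kind in ("ICAR", "PCAR"):
            if self.graph is None:
                raise ValueError(f"{self.kind} requires a region graph")
        elif self.dimension is None:
            raise ValueError(f"{self.kind} requires a dimension")
        n = self.size
        if self.kind == "RW2":
            if n < 3:
                raise ValueError("RW2 needs dimension >= 3")
        elif n < 2:
            raise ValueError(f"{self.kind} needs dimension >= 2")
        if self.kind == "PCAR":
            if self.rho is None or not abs(self.rho) < 1:
                raise ValueError("PCAR requires |rho| < 1")
        a, b = self.precision_hyperprior
        if a <= 0 or b <= 0:
            raise ValueError("precision hyperprior shape and rate must be > 0")

    @property
    def size(self) -> int:
        if self.graph is not None:
            return self.graph.n_nodes
        assert self.dimension is not None
        return self.dimension


@dataclass(frozen=True)
class PrecisionStructure:
    """Unscaled symmetric PSD structure matrix with its null space."""

    matrix: sp.csr_matrix = field(repr=False)
    rank_deficiency: int
    null_space: np.ndarray = field(repr=False)  # (n, rank_deficiency)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return self.size - self.rank_deficiency


def _difference_matrix(n: int, order: int) -> sp.csr_matrix:
    d = sp.eye(n, format="csc")
    for _ in range(order):
        m = d.shape[0]
        d = sp.diags([-np.ones(m - 1), np.ones(m - 1)], [0, 1],
                     shape=(m - 1, m)) @ d
    return sp.csr_matrix(d)


def build_latent_precision(spec: LatentSpec) -> PrecisionStructure:
    """Structure matrix for RW1/RW2/ICAR/IID (PCAR via :func:`build_pcar_precision`)."""
    n = spec.size
    if spec.kind == "RW1":
        d = _difference_matrix(n, 1)
        q = (d.T @ d).tocsr()
        null = np.ones((n, 1))
    elif spec.kind == "RW2":
        d = _difference_matrix(n, 2)
        q = (d.T @ d).tocsr()
        null = np.column_stack([np.ones(n), np.arange(1, n + 1, dtype=float)])
    elif spec.kind == "ICAR":
        g = spec.graph
        assert g is not None
        a = g.adjacency()
        q = (sp.diags(g.degrees()) - a).tocsr()
        null = np.ones((n, 1))
    elif spec.kind == "IID":
        q = sp.eye(n, format="csr")
        null = np.empty((n, 0))
    elif spec.kind == "PCAR":
        assert spec.graph is not None and spec.rho is not None
        return build_pcar_precision(spec.graph, spec.rho)
    else:  # pragma: no cover
        raise ValueError(spec.kind)
    # orthonormalise the null basis for later projections
    if null.shape[1]:
        null, _ = np.linalg.qr(null)
    return PrecisionStructure(q, null.shape[1], null)


def build_pcar_precision(graph: RegionGraph, rho: float) -> PrecisionStructure:
    """Proper CAR structure ``D - rho*A``; positive definite for |rho| < 1."""
    if not abs(rho) < 1:
        raise ValueError("PCAR requires |rho| < 1")
    a = graph.adjacency()
    q = (sp.diags(graph.degrees()) - rho * a).tocsr()
    return PrecisionStructure(q, 0, np.empty((graph.n_nodes, 0)))


def sample_constrained_gmrf(
    structure: PrecisionStructure,
    precision: float,
    seed: int | np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw from ``N(0, (precision * Q)^+)`` subject to sum-to-zero.

    Intrinsic structures get a jitter ``NULL_SPACE_JITTER`` along their null
    space to make the precision proper, then the draw is corrected by
    conditioning by kriging onto the sum-to-zero subspace, which removes the
    null-space component (and the jitter's influence) exactly.  Proper
    structures are conditioned on the same constraint.

    Returns an array of shape ``(size, n)`` (squeezed to ``(n,)`` if size=1).
    """
    if precision <= 0:
        raise ValueError("precision must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = structure.size
    q = precision * structure.matrix.toarray()
    if structure.rank_deficiency:
        v = structure.null_space
        q = q + NULL_SPACE_JITTER * (v @ v.T)
    try:
        chol = sla.cholesky(q, lower=False)
    except sla.LinAlgError as exc:
        raise ValueError("structure matrix is not positive semi-definite") from exc
    z = rng.standard_normal((size, n))
    # x' solves U x = z  =>  x ~ N(0, Q^{-1})
    x = sla.solve_triangular(chol, z.T, lower=False).T
    # kriging correction for the constraint  1'x = 0
    a = np.ones(n)
    qinv_a = sla.cho_solve((chol, False), a)
    x = x - np.outer(x @ a / (a @ qinv_a), qinv_a)
    return x[0] if size == 1 else x


def export_structure(structure: PrecisionStructure, path: str | Path) -> Path:
    """Write the structure matrix as ``row col value`` coordinate text."""
    path = Path(path)
    coo = structure.matrix.tocoo()
    lines = [f"{i} {j} {v:.17g}" for i, j, v in zip(coo.row, coo.col, coo.data)]
    path.write_text("\n".join(lines) + "\n")
    return path
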