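"""Finite-difference Laplace solver for the electric potential.

Solves the boundary-value problem

    laplacian(phi) = 0   in the tissue,
    phi = V              on the energized (source) electrode surface,
    phi = 0              on the grounded (sink) electrode surface,
    d(phi)/dn = 0        on every insulated tissue surface,

on the voxel grid of a :class:`~irepulse.geometry.VoxelDomain` with the
standard 7-point stencil.  The homogeneous Neumann condition is imposed by
ghost-cell mirroring, which on the staircase boundary reduces to dropping
the corresponding stencil connection.  The conductivity is uniform, so it
cancels from the equation and enters only the current bookkeeping of
:func:`net_current_balance`.

The discrete system is solved directly (sparse LU) for small grids and by
Jacobi-preconditioned conjugate gradients for large ones; both routes are
deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import EXTERIOR, SINK, SOURCE, TISSUE, VoxelDomain

__all__ = [
    "SolverError",
    "SingularSystemError",
    "PotentialField",
    "solve_potential",
    "net_current_balance",
]

# below this many unknowns a sparse direct factorization is cheaper than CG
_DIRECT_LIMIT = 40_000


class SolverError(RuntimeError):
    """Linear solve failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SingularSystemError(SolverError):
    """The discrete system has no unique solution (floating tissue region)."""


@dataclass(frozen=True)
class PotentialField:
    """Electric potential on the voxel grid.

    ``phi`` holds the potential (V) at every voxel: the solved values on
    tissue, the Dirichlet data on electrodes, NaN on exterior voxels.
    ``residual`` is the final relative residual of the linear solve.
    """

    phi: np.ndarray
    domain: VoxelDomain
    residual: float
    tol: float
    voltage_V: float

    @property
    def tissue_phi(self) -> np.ndarray:
        return self.phi[self.domain.tissue_mask]


def _assemble(domain: VoxelDomain, boundary_values: np.ndarray):
    """Build the 7-point system A x = b over tissue unknowns.

    Row i: sum_nb (phi_i - phi_nb) = 0 over non-exterior neighbors; exterior
    (and out-of-grid) neighbors are Neumann-mirrored, i.e. dropped from both
    the sum and the diagonal.  Dirichlet neighbors move to the RHS.  The
    assembled matrix is symmetric positive definite.
    """
    lab = domain.labels
    tissue = lab == TISSUE
    n = int(tissue.sum())
    idx = -np.ones(lab.shape, dtype=np.int64)
    idx[tissue] = np.arange(n)

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    diag = np.zeros(n)
    for axis in range(3):
        for shift in (1, -1):
            nb_lab = np.zeros(lab.shape, dtype=np.uint8)  # pad: exterior
            nb_idx = -np.ones(lab.shape, dtype=np.int64)
            nb_val = np.zeros(lab.shape)
            dst = [slice(None)] * 3
            src = [slice(None)] * 3
            if shift == 1:
                dst[axis] = slice(0, -1)
                src[axis] = slice(1, None)
            else:
                dst[axis] = slice(1, None)
                src[axis] = slice(0, -1)
            nb_lab[tuple(dst)] = lab[tuple(src)]
            nb_idx[tuple(dst)] = idx[tuple(src)]
            nb_val[tuple(dst)] = boundary_values[tuple(src)]

            diag[idx[tissue]] += (nb_lab[tissue] != EXTERIOR).astype(float)
            m = tissue & (nb_lab == TISSUE)
            rows.append(idx[m])
            cols.append(nb_idx[m])
            vals.append(-np.ones(int(m.sum())))
            md = tissue & ((nb_lab == SOURCE) | (nb_lab == SINK))
            np.add.at(b, idx[md], nb_val[md])

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return A, b, idx, tissue


def _check_connectivity(domain: VoxelDomain) -> None:
    lab = domain.labels
    if not (lab == SOURCE).any() or not (lab == SINK).any():
        raise SolverError("domain must contain non-empty source and sink electrodes")
    structure = ndi.generate_binary_structure(3, 1)  # face connectivity
    comp, ncomp = ndi.label(lab != EXTERIOR, structure=structure)
    src_comps = set(np.unique(comp[lab == SOURCE]))
    snk_comps = set(np.unique(comp[lab == SINK]))
    if not (src_comps & snk_comps):
        raise SingularSystemError("source and sink are not connected through tissue")
    dirichlet_comps = src_comps | snk_comps
    tissue_comps = set(np.unique(comp[lab == TISSUE]))
    if tissue_comps - dirichlet_comps:
        raise SingularSystemError(
            "tissue region with no electrode contact: all-Neumann subproblem is singular"
        )


def solve_potential(
    domain: VoxelDomain,
    tol: float = 1e-8,
    boundary_values: np.ndarray | None = None,
    maxiter: int = 100_000,
) -> PotentialField:
    """Solve the Laplace problem on ``domain``.

    Parameters
    ----------
    domain : VoxelDomain
        Labelled grid with non-empty source and sink.
    tol : float
        Relative residual tolerance of the linear solve.
    boundary_values : ndarray, optional
        Full-grid array of Dirichlet data; values are read at source and sink
        voxels.  Defaults to the domain's applied voltage on the source and 0
        on the sink.  (Non-constant data supports manufactured-solution
        verification.)
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    _check_connectivity(domain)

    lab = domain.labels
    if boundary_values is None:
        boundary_values = np.zeros(lab.shape)
        boundary_values[lab == SOURCE] = domain.voltage_V
    A, b, idx, tissue = _assemble(domain, boundary_values)
    n = A.shape[0]

    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        x = np.zeros(n)
        residual = 0.0
    elif n <= _DIRECT_LIMIT:
        x = spla.spsolve(A.tocsc(), b)
        residual = float(np.linalg.norm(A @ x - b) / bnorm)
    else:
        d = A.diagonal()
        M = spla.LinearOperator((n, n), matvec=lambda v: v / d)
        x, info = spla.cg(A, b, rtol=tol * 1e-2, atol=0.0, maxiter=maxiter, M=M)
        residual = float(np.linalg.norm(A @ x - b) / bnorm)
        if info != 0 or not np.isfinite(residual):
            raise SolverError(
                f"conjugate gradients did not converge (info={info})", residual
            )
    if residual > tol:
        raise SolverError(f"residual {residual:.3e} exceeds tol {tol:.3e}", residual)

    phi = np.full(lab.shape, np.nan)
    phi[tissue] = x
    dir_mask = (lab == SOURCE) | (lab == SINK)
    phi[dir_mask] = boundary_values[dir_mask]
    return PotentialField(
        phi=phi,
        domain=domain,
        residual=residual,
        tol=tol,
        voltage_V=domain.voltage_V,
    )


def net_current_balance(
    field: PotentialField, conductivity_mS_per_mm: float = 1.0
) -> tuple[float, float]:
    """Discrete current leaving the source and entering the sink.

    Sums the face fluxes ``sigma * (phi_electrode - phi_tissue) / h * h**2``
    over every electrode-tissue face.  With conductivity in mS/mm and lengths
    in mm the result is in milliamperes.  For a converged solve the two
    fluxes cancel: ``|source + sink| / |source|`` is of the order of the
    solver residual (contract: < 10 * tol).
    """
    if not np.isfinite(field.residual) or field.residual > field.tol:
        raise SolverError("refusing to integrate flux of a non-converged field")
    lab = field.domain.labels
    h = field.domain.voxel_mm
    phi = field.phi
    out = {}
    for elec_label in (SOURCE, SINK):
        flux = 0.0
        emask = lab == elec_label
        for axis in range(3):
            for shift in (1, -1):
                nb_lab = np.zeros(lab.shape, dtype=np.uint8)
                nb_phi = np.zeros(lab.shape)
                dst = [slice(None)] * 3
                src = [slice(None)] * 3
                if shift == 1:
                    dst[axis] = slice(0, -1)
                    src[axis] = slice(1, None)
                else:
                    dst[axis] = slice(1, None)
                    src[axis] = slice(0, -1)
                nb_lab[tuple(dst)] = lab[tuple(src)]
                nb_phi[tuple(dst)] = phi[tuple(src)]
                m = emask & (nb_lab == TISSUE)
                flux += float(np.sum(phi[m] - nb_phi[m]))
        out[elec_label] = conductivity_mS_per_mm * flux * h  # (dphi/h) * h^2
    return out[SOURCE], out[SINK]
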