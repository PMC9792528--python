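"""Closed-form verification problems for the Laplace solver.

Small analytic boundary-value problems — a plane slab with two Dirichlet
faces and a coaxial (concentric-electrode) annulus — used by the test suite
and the acceptance script to validate the solver against exact solutions.
"""

from __future__ import annotations

import numpy as np

from .geometry import SINK, SOURCE, TISSUE, VoxelDomain

__all__ = ["make_slab_domain", "make_annulus_domain", "coax_exact"]


def make_slab_domain(nx=12, ny=10, nz=21, voxel_mm=1.0) -> VoxelDomain:
    """Tissue box with full Dirichlet faces at z=0 (source) and z=-1 (sink).

    The exact potential is linear in z; the electrode-layer separation is
    ``(nz - 1) * voxel_mm``.
    """
    labels = np.full((nx, ny, nz), TISSUE, dtype=np.uint8)
    labels[:, :, 0] = SOURCE
    labels[:, :, -1] = SINK
    return VoxelDomain(labels=labels, voxel_mm=voxel_mm, origin=(0.0, 0.0, 0.0))


def make_annulus_domain(r_in=2.0, r_out=8.0, h=0.25, nz=3, shell=2):
    """Concentric-electrode (coaxial) staircase domain, invariant along z.

    Source: shell of voxels just inside radius ``r_in``; sink: shell just
    outside ``r_out``; tissue in between; exterior elsewhere.  Returns
    ``(domain, X, Y)`` with the in-plane voxel-center coordinate grids.
    """
    half = r_out + (shell + 1) * h
    n = int(np.ceil(2 * half / h))
    xs = -(n * h) / 2 + h / 2 + h * np.arange(n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    r = np.hypot(X, Y)
    lab2d = np.zeros((n, n), dtype=np.uint8)
    lab2d[(r > r_in) & (r <= r_out)] = TISSUE
    lab2d[(r <= r_in) & (r > r_in - shell * h)] = SOURCE
    lab2d[(r > r_out) & (r <= r_out + shell * h)] = SINK
    labels = np.repeat(lab2d[:, :, None], nz, axis=2)
    dom = VoxelDomain(labels=labels, voxel_mm=h, origin=(xs[0], xs[0], 0.0))
    return dom, X, Y


def coax_exact(r, v, r_in, r_out):
    """Coaxial potential ``V * ln(r_out / r) / ln(r_out / r_in)``."""
    return v * np.log(r_out / np.maximum(r, 1e-12)) / np.log(r_out / r_in)
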