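"""Diffusion gradient tables.

A high-angular-resolution single-shell scheme: unit gradient directions
spread by electrostatic repulsion (antipodally symmetric energy), plus
unweighted b=0 volumes first. Written/read in the FSL bval/bvec dialect.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize


@dataclass
class DiffusionScheme:
    """Per-volume b-values (s/mm^2) and unit direction vectors.

    b=0 volumes carry the zero vector. Invariant: non-b0 directions have
    unit norm to 1e-9.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (self.b_values.size, 3):
            raise ValueError("directions must be (n_volumes, 3)")
        dw = self.b_values > 0
        norms = np.linalg.norm(self.directions[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("weighted directions must be unit vectors")

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b_values == 0))

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(self.b_values > 0))

    def to_fsl(self, prefix) -> None:
        """Write FSL-dialect ``<prefix>.bval`` / ``<prefix>.bvec`` files."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".bval"), self.b_values[None], fmt="%.1f")
        np.savetxt(prefix.with_suffix(".bvec"), self.directions.T, fmt="%.17g")

    @classmethod
    def from_fsl(cls, prefix) -> "DiffusionScheme":
        prefix = Path(prefix)
        bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
        bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(b_values=bvals, directions=bvecs)


def _repulsion_energy(flat, n):
    """Antipodal electrostatic energy and gradient for n points on S^2.

    E = sum_{i<j} 1/|u_i - u_j| + 1/|u_i + u_j|; the self-antipode term is
    constant (distance 2) and excluded. Gradient is projected onto the
    sphere's tangent plane so L-BFGS moves stay near the manifold.
    """
    v = flat.reshape(n, 3)
    u = v / np.linalg.norm(v, axis=1, keepdims=True)
    energy = 0.0
    grad = np.zeros_like(u)
    for sign in (1.0, -1.0):
        diff = u[:, None, :] - sign * u[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        np.fill_diagonal(d2, np.inf)  # drop i == j (pair or self-antipode)
        inv = 1.0 / np.sqrt(d2)
        energy += 0.5 * np.sum(inv)
        grad += np.sum(-diff * (inv**3)[..., None], axis=1)
    grad -= np.sum(grad * u, axis=1, keepdims=True) * u
    return energy, grad.ravel()


def make_scheme(
    n_directions: int = 50,
    b: float = 1250.0,
    n_b0: int = 2,
    seed: int | None = None,
) -> DiffusionScheme:
    """Generate a single-shell scheme with repulsion-spread directions.

    Parameters
    ----------
    n_directions : int
        Number of diffusion-weighted directions (>= 6 for tensor
        identifiability; default 50).
    b : float
        Shell b-value in s/mm^2 (default 1250).
    n_b0 : int
        Unweighted volumes, placed first (default 2).
    seed : int, optional
        Seed for the random initialization of the repulsion optimizer.
    """
    if n_directions < 6:
        raise ValueError("need >= 6 directions to identify a diffusion tensor")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal((n_directions, 3))
    v0 /= np.linalg.norm(v0, axis=1, keepdims=True)
    res = minimize(
        _repulsion_energy,
        v0.ravel(),
        args=(n_directions,),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    u = res.x.reshape(n_directions, 3)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    dirs = np.vstack([np.zeros((n_b0, 3)), u])
    return DiffusionScheme(b_values=bvals, directions=dirs)


def min_pairwise_angle_deg(directions: np.ndarray) -> float:
    """Smallest pairwise angle (degrees, antipodally symmetric) of a set."""
    u = np.asarray(directions, dtype=float)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    dots = np.abs(u @ u.T)
    np.fill_diagonal(dots, 0.0)
    return float(np.degrees(np.arccos(np.clip(dots.max(), -1, 1))))
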