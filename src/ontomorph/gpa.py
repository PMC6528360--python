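"""Generalized Procrustes alignment and thin-plate-spline machinery.

Implements partial Procrustes superimposition (translation, unit
centroid-size scaling, proper rotation), bending-energy-minimizing sliding
of semilandmarks, the 2D thin-plate-spline bending-energy matrix, and
principal/partial warps with a separate uniform (affine) component.

All linear statistics downstream use chord distances in the tangent space
at the consensus, reached by orthogonal projection from the pre-shape
sphere.  The aligned dataset is reported in a canonical orientation
(consensus principal axes, third-moment sign rule) so the output is
invariant under similarity transforms of any input configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkConfiguration, SpecimenMetadata

__all__ = [
    "AlignedDataset",
    "TPSBasis",
    "centroid_size",
    "gpa_align",
    "bending_energy_matrix",
    "slide_semilandmarks",
    "partial_warp_scores",
    "tangent_coordinates",
]


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    dev = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(dev**2)))


@dataclass
class AlignedDataset:
    """GPA-aligned shapes (n, k, 2), their consensus, and specimen metadata.

    Aligned shapes are dimensionless: centred at the origin with unit
    centroid size.  ``centroid_sizes`` keeps the original sizes (length
    units) for allometric models.
    """

    shapes: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    metadata: list[SpecimenMetadata]
    sliders: list[tuple[int, int, int]] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True
    bending_energy_trace: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Shapes as an (n, 2k) matrix, landmark-major (x1, y1, x2, y2, ...)."""
        return self.shapes.reshape(self.n_specimens, -1)

    def tangent(self) -> np.ndarray:
        """Tangent-space coordinates (n, 2k) at the consensus."""
        return tangent_coordinates(self)

    def subset(self, mask) -> "AlignedDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return AlignedDataset(
            shapes=self.shapes[idx],
            consensus=self.consensus,
            centroid_sizes=self.centroid_sizes[idx],
            metadata=[self.metadata[i] for i in idx],
            sliders=self.sliders,
        )


def _center_scale(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(c**2))
    if cs == 0:
        raise ValueError("degenerate configuration with zero centroid size")
    return c / cs


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||shape @ R - target||_F (no reflection)."""
    u, _, vt = np.linalg.svd(shape.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation putting the consensus major principal axis on x.

    The residual two-fold ambiguity (rotation by pi) is resolved by the sign
    of the third moment of x (falling back to y) so the orientation depends
    only on the shape itself, never on input orientation.
    """
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    r = evecs[:, ::-1]  # major axis first
    if np.linalg.det(r) < 0:
        r[:, 1] *= -1.0
    rot = consensus @ r
    m3x = np.sum(rot[:, 0] ** 3)
    m3y = np.sum(rot[:, 1] ** 3)
    m = m3x if abs(m3x) > 1e-12 else m3y
    if m < 0:
        r = r @ np.array([[-1.0, 0.0], [0.0, -1.0]])
    return r


def gpa_align(
    configs: list[LandmarkConfiguration],
    slide: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
    metadata: list[SpecimenMetadata] | None = None,
    slide_iter: int = 5,
) -> AlignedDataset:
    """Generalized Procrustes alignment, optionally with sliding semilandmarks.

    Each configuration is centred, scaled to unit centroid size, and rotated
    (least squares, SVD, determinant +1) to an iteratively updated consensus
    until the consensus root-mean-square change drops below ``tol`` or
    ``max_iter`` is reached.  With ``slide=True`` the first ``slide_iter``
    iterations interleave a bending-energy-minimizing semilandmark sliding
    step (relative to the current consensus) before re-superimposition;
    afterwards plain superimposition runs to convergence, since the
    slide/consensus feedback has a slow drift mode along the curves that
    would otherwise stall convergence without changing the fit.
    """
    if not configs:
        raise ValueError("empty dataset")
    k = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k:
            raise ValueError(
                f"specimen {c.specimen_id!r} has k={c.n_landmarks}, expected {k}"
            )
    sliders = list(configs[0].semilandmark_sliders)
    csizes = np.array([centroid_size(c) for c in configs])
    shapes = np.stack([_center_scale(c.coords) for c in configs])
    n = shapes.shape[0]

    # initial consensus: everything rotated onto the first shape
    ref = shapes[0]
    for i in range(n):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], ref)
    consensus = _center_scale(shapes.mean(axis=0))

    converged = False
    be_trace: list[tuple[float, float]] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if slide and sliders and n_iter <= slide_iter:
            be_mat = bending_energy_matrix(consensus)
            be_before = _total_bending_energy(shapes, consensus, be_mat)
            shapes = slide_semilandmarks(shapes, consensus, sliders, be_matrix=be_mat)
            be_after = _total_bending_energy(shapes, consensus, be_mat)
            be_trace.append((be_before, be_after))
            for i in range(n):
                shapes[i] = _center_scale(shapes[i])
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = _center_scale(shapes.mean(axis=0))
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})",
            stacklevel=2,
        )

    # canonical orientation: invariant to input similarity transforms
    r = _canonical_rotation(consensus)
    consensus = consensus @ r
    shapes = shapes @ r
    for i in range(n):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)

    return AlignedDataset(
        shapes=shapes,
        consensus=consensus,
        centroid_sizes=csizes,
        metadata=list(metadata) if metadata is not None else [],
        sliders=sliders,
        n_iterations=n_iter,
        converged=converged,
        bending_energy_trace=be_trace,
    )


# ---------------------------------------------------------------------------
# Thin-plate spline


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """2D thin-plate-spline bending-energy matrix of a reference shape.

    Kernel U(r) = r^2 ln r (U(0) = 0).  Builds L = [[K, Q], [Q^T, 0]] with
    Q = [1 | x | y] and returns the upper-left k x k block of L^{-1},
    numerically symmetrized.  The matrix is PSD with a 3-dimensional null
    space spanned by the affine functions 1, x, y.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    off = ~np.eye(k, dtype=bool)
    if np.any(d2[off] < 1e-24):
        i, j = np.argwhere((d2 < 1e-24) & off)[0]
        raise np.linalg.LinAlgError(
            f"coincident reference landmarks {int(i)} and {int(j)}: TPS is singular"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        kmat = np.where(d2 > 0, 0.5 * d2 * np.log(np.where(d2 > 0, d2, 1.0)), 0.0)
    q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = kmat
    L[:k, k:] = q
    L[k:, :k] = q.T
    linv = np.linalg.inv(L)
    be = linv[:k, :k]
    return (be + be.T) / 2.0


def _total_bending_energy(shapes: np.ndarray, reference: np.ndarray, be: np.ndarray) -> float:
    dx = shapes[..., 0] - reference[:, 0]
    dy = shapes[..., 1] - reference[:, 1]
    return float(np.einsum("ni,ij,nj->", dx, be, dx) + np.einsum("ni,ij,nj->", dy, be, dy))


def slide_semilandmarks(
    shapes: np.ndarray,
    reference: np.ndarray,
    sliders: list[tuple[int, int, int]],
    be_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Slide semilandmarks along their tangents to minimize bending energy.

    Each semilandmark moves along the unit chord from its ``before`` to its
    ``after`` neighbour (evaluated on the specimen itself); the displacement
    magnitudes solve the exact linear least-squares problem minimizing the
    TPS bending energy of the shape relative to ``reference``, so bending
    energy never increases.

    Accepts a single (k, 2) shape or a stack (n, k, 2); returns the same
    shape slid (a new array).
    """
    single = np.asarray(shapes).ndim == 2
    shp = np.asarray(shapes, dtype=float)[None] if single else np.array(shapes, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if be_matrix is None:
        be_matrix = bending_energy_matrix(ref)
    if not sliders:
        return shp[0] if single else shp
    mids = np.array([s for _, s, _ in sliders])
    befores = np.array([b for b, _, _ in sliders])
    afters = np.array([a for _, _, a in sliders])
    out = shp.copy()
    for i in range(shp.shape[0]):
        x = shp[i]
        tang = x[afters] - x[befores]
        norms = np.linalg.norm(tang, axis=1)
        bad = np.flatnonzero(norms < 1e-12)
        if bad.size:
            b, s, a = sliders[bad[0]]
            raise ValueError(
                f"zero-length tangent for slider ({b}, {s}, {a}): "
                "neighbour landmarks coincide"
            )
        tang = tang / norms[:, None]
        m = len(sliders)
        tx = np.zeros((ref.shape[0], m))
        ty = np.zeros((ref.shape[0], m))
        tx[mids, np.arange(m)] = tang[:, 0]
        ty[mids, np.arange(m)] = tang[:, 1]
        dx = x[:, 0] - ref[:, 0]
        dy = x[:, 1] - ref[:, 1]
        a_mat = tx.T @ be_matrix @ tx + ty.T @ be_matrix @ ty
        rhs = -(tx.T @ be_matrix @ dx + ty.T @ be_matrix @ dy)
        lam = np.linalg.lstsq(a_mat, rhs, rcond=None)[0]
        out[i, mids, 0] += tang[:, 0] * lam
        out[i, mids, 1] += tang[:, 1] * lam
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Tangent space, principal/partial warps


def tangent_coordinates(aligned: AlignedDataset) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space at the
    consensus, returned as (n, 2k) row vectors (landmark-major)."""
    c = _center_scale(aligned.consensus).ravel()
    y = aligned.flat()
    proj = y - np.outer(y @ c, c) + c  # orthogonal projection onto {v: v.c = 1}
    return proj


@dataclass
class TPSBasis:
    """Bending-energy eigenstructure of a consensus and dataset warp scores.

    ``principal_warps`` holds the k-3 nonzero-eigenvalue eigenvectors of the
    bending-energy matrix (columns, ascending eigenvalue).  Partial-warp
    scores are per-axis projections of tangent-space deviations from the
    consensus; the uniform component is the 2D affine complement within the
    tangent space.
    """

    reference: np.ndarray
    bending_energy_eigenvalues: np.ndarray
    principal_warps: np.ndarray  # (k, k-3)
    partial_warp_scores: np.ndarray  # (n, k-3, 2)
    uniform_component: np.ndarray  # (n, 2)
    uniform_basis: np.ndarray  # (2k, 2)

    @property
    def n_warps(self) -> int:
        return self.principal_warps.shape[1]

    def partial_warp_variances(self, ddof: int = 1) -> np.ndarray:
        """Per-warp variance across specimens (x- plus y-score variance)."""
        return self.partial_warp_scores.var(axis=0, ddof=ddof).sum(axis=1)

    def reconstruct(self) -> np.ndarray:
        """Tangent-space shapes rebuilt from warp + uniform scores, (n, k, 2)."""
        k = self.reference.shape[0]
        n = self.partial_warp_scores.shape[0]
        d = np.zeros((n, k, 2))
        for axis in (0, 1):
            d[:, :, axis] = self.partial_warp_scores[:, :, axis] @ self.principal_warps.T
        d = d.reshape(n, 2 * k) + self.uniform_component @ self.uniform_basis.T
        return (self.reference.ravel() + d).reshape(n, k, 2)


def _uniform_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k, 2) of the uniform subspace at the consensus:
    span of affine fields minus translation, rotation, and scale fields."""
    k = consensus.shape[0]
    cx, cy = consensus[:, 0], consensus[:, 1]
    zero = np.zeros(k)

    def fld(xpart, ypart):
        return np.column_stack([xpart, ypart]).ravel()

    affine = np.column_stack([fld(cx, zero), fld(cy, zero), fld(zero, cx), fld(zero, cy)])
    remove = np.column_stack(
        [
            fld(np.ones(k), zero),
            fld(zero, np.ones(k)),
            fld(cx, cy),  # scale
            fld(-cy, cx),  # rotation
        ]
    )
    q_rm, _ = np.linalg.qr(remove)
    resid = affine - q_rm @ (q_rm.T @ affine)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    if rank != 2:
        raise np.linalg.LinAlgError("uniform subspace is degenerate for this consensus")
    return u[:, :2]


def partial_warp_scores(aligned: AlignedDataset) -> TPSBasis:
    """Eigendecompose the consensus bending-energy matrix and project the
    dataset onto principal warps and the uniform component."""
    consensus = _center_scale(aligned.consensus)
    k = consensus.shape[0]
    be = bending_energy_matrix(consensus)
    evals, evecs = np.linalg.eigh(be)
    # 3 null directions (affine) are dropped
    nonzero = evals[3:]
    if np.any(nonzero <= 0):
        raise np.linalg.LinAlgError("bending-energy matrix has fewer than k-3 positive eigenvalues")
    warps = evecs[:, 3:]
    tang = tangent_coordinates(aligned).reshape(-1, k, 2)
    d = tang - consensus
    scores = np.einsum("kj,nka->nja", warps, d)
    ub = _uniform_basis(consensus)
    uniform = d.reshape(d.shape[0], -1) @ ub
    return TPSBasis(
        reference=consensus,
        bending_energy_eigenvalues=nonzero,
        principal_warps=warps,
        partial_warp_scores=scores,
        uniform_component=uniform,
        uniform_basis=ub,
    )
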