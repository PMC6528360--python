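"""Modularity and integration statistics: covariance ratio (CR) and the
global integration (GI) slope.

CR compares squared between-module covariances of landmark coordinates with
squared within-module covariances; values below 1 indicate modularity.  Its
null keeps whole landmarks together (x and y travel as a unit) and randomly
reassigns them to modules of the original sizes; significance is the
proportion of the null at or below the observed CR.

GI regresses the log variance of partial-warp scores on the log bending
energy of the corresponding principal warps.  A slope of -1 marks
self-similarity across spatial scales; slopes below -1 indicate integration
(variation dominated by large-scale deformation), above -1 disintegration
(localized variation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gpa import TPSBasis
from .io import ModulePartition

__all__ = ["CRResult", "GIResult", "covariance_ratio", "global_integration"]


@dataclass
class CRResult:
    cr: float
    null_distribution: np.ndarray
    p: float
    partition: ModulePartition
    n_permutations: int
    seed: int


def _cr_statistic(s: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """CR from a 2k x 2k coordinate covariance, landmark-major ordering.

    Within-module sums exclude diagonals and within-landmark x-y blocks
    (orientation artifacts carrying no anatomical signal).
    """

    def coord_idx(lm_idx: np.ndarray) -> np.ndarray:
        return np.sort(np.concatenate([2 * lm_idx, 2 * lm_idx + 1]))

    ca, cb = coord_idx(idx_a), coord_idx(idx_b)
    between = float(np.sum(s[np.ix_(ca, cb)] ** 2))

    def within(cidx: np.ndarray, lm_idx: np.ndarray) -> float:
        block = s[np.ix_(cidx, cidx)].copy()
        # zero the 2x2 within-landmark blocks (includes the diagonal)
        pos = {lm: 2 * i for i, lm in enumerate(np.sort(lm_idx))}
        for lm in lm_idx:
            j = pos[lm]
            block[j : j + 2, j : j + 2] = 0.0
        return float(np.sum(block**2))

    wa = within(ca, idx_a)
    wb = within(cb, idx_b)
    denom = np.sqrt(wa * wb)
    if denom <= 0:
        return 0.0 if between == 0 else np.inf
    return float(np.sqrt(between / denom))


def covariance_ratio(
    shapes: np.ndarray,
    partition: ModulePartition,
    n_perm: int = 999,
    seed: int = 0,
) -> CRResult:
    """CR modularity test for one group of aligned shapes (n, k, 2).

    p is the proportion of the random-partition null at or below the
    observed CR (small CR = more modular than random landmark sets).
    """
    y = np.asarray(shapes, dtype=float)
    if y.ndim != 3:
        raise ValueError("shapes must be (n, k, 2)")
    n, k, _ = y.shape
    if n < 3:
        raise ValueError("CR needs at least 3 specimens")
    modules = partition.modules
    if len(modules) != 2:
        raise ValueError("CR is defined for a 2-module partition")
    idx_a = partition.indices(modules[0])
    idx_b = partition.indices(modules[1])
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("each module needs at least 3 landmarks")
    if len(idx_a) + len(idx_b) != k:
        raise ValueError("partition does not cover all landmarks")

    flat = y.reshape(n, 2 * k)
    s = np.cov(flat, rowvar=False, ddof=1)
    obs = _cr_statistic(s, idx_a, idx_b)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    all_lm = np.arange(k)
    for b in range(n_perm):
        perm = rng.permutation(all_lm)
        null[b] = _cr_statistic(s, np.sort(perm[: len(idx_a)]), np.sort(perm[len(idx_a) :]))
    p = (1.0 + np.sum(null <= obs + 1e-15)) / (1.0 + n_perm)
    return CRResult(
        cr=float(obs),
        null_distribution=null,
        p=float(p),
        partition=partition,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass
class GIResult:
    slope: float
    intercept: float
    n_warps: int
    classification: str  # integrated | self_similar | disintegrated
    log_be: np.ndarray
    log_var: np.ndarray


def global_integration(
    tps_basis: TPSBasis,
    self_similar_band: float = 0.05,
) -> GIResult:
    """GI slope: OLS of ln(partial-warp variance) on ln(bending energy).

    Per-warp variance sums the x- and y-score variances across specimens.
    Classification compares the slope with -1 using ``self_similar_band``
    as the half-width of the self-similar zone.
    """
    be = np.asarray(tps_basis.bending_energy_eigenvalues, dtype=float)
    v = tps_basis.partial_warp_variances()
    ok = v > 0
    if np.any(~ok):
        warnings.warn(
            f"{int(np.sum(~ok))} partial warps with zero variance dropped from GI",
            stacklevel=2,
        )
    be, v = be[ok], v[ok]
    if be.size < 2:
        raise ValueError("GI needs at least 2 warps with positive score variance")
    x = np.log(be)
    yv = np.log(v)
    slope, intercept = np.polyfit(x, yv, 1)
    if slope < -1.0 - self_similar_band:
        cls = "integrated"
    elif slope > -1.0 + self_similar_band:
        cls = "disintegrated"
    else:
        cls = "self_similar"
    return GIResult(
        slope=float(slope),
        intercept=float(intercept),
        n_warps=int(be.size),
        classification=cls,
        log_be=x,
        log_var=yv,
    )
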