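"""Morphological disparity as Procrustes variance, with permutation tests.

Procrustes variance of a group is the trace of its shape covariance matrix
with divisor n — equivalently the mean squared distance of group members
from the group mean shape.  Pairwise differences are tested by permuting
group-mean-centred residual vectors among groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpa import AlignedDataset
from .models import design_frame

__all__ = ["DisparityResult", "procrustes_variance", "disparity_test"]


def procrustes_variance(shapes: np.ndarray) -> float:
    """Procrustes variance of one group: sum ||y_i - ybar||^2 / n.

    ``shapes`` is (n, k, 2) or (n, 2k); a single specimen gives 0.
    """
    y = np.asarray(shapes, dtype=float)
    y = y.reshape(y.shape[0], -1)
    dev = y - y.mean(axis=0)
    return float(np.sum(dev**2) / y.shape[0])


@dataclass
class DisparityResult:
    """Per-group Procrustes variances and pairwise permutation tests."""

    groups: list[str]
    variances: pd.Series
    differences: pd.DataFrame  # |PV_g - PV_h|
    p: pd.DataFrame
    n_permutations: int
    seed: int


def _group_labels(df: pd.DataFrame, grouping) -> pd.Series:
    """Grouping key: one metadata column or a list of columns (crossed)."""
    if isinstance(grouping, str):
        return df[grouping].astype(str)
    parts = [df[g].astype(str) for g in grouping]
    out = parts[0]
    for p in parts[1:]:
        out = out + ":" + p
    return out


def disparity_test(
    aligned: AlignedDataset,
    grouping="species",
    n_perm: int = 10000,
    seed: int = 0,
) -> DisparityResult:
    """Pairwise Procrustes-variance differences with a permutation null.

    Groups with fewer than 2 specimens are excluded with a warning.  The
    null permutes group-mean-centred residual vectors among specimens while
    keeping group sizes fixed, then recomputes each group's variance.
    """
    df = design_frame(aligned)
    labels = _group_labels(df, grouping)
    y = aligned.flat()
    names = sorted(labels.unique())
    keep = []
    for g in names:
        n_g = int((labels == g).sum())
        if n_g < 2:
            warnings.warn(f"group {g!r} has n={n_g} < 2; excluded from disparity test", stacklevel=2)
        else:
            keep.append(g)
    if len(keep) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    mask = labels.isin(keep).to_numpy()
    y = y[mask]
    labels = labels[mask].reset_index(drop=True)
    codes = labels.map({g: i for i, g in enumerate(keep)}).to_numpy()

    pv = np.array([procrustes_variance(y[codes == i]) for i in range(len(keep))])
    obs = np.abs(pv[:, None] - pv[None, :])

    # group-mean-centred residuals
    resid = y.copy()
    for i in range(len(keep)):
        m = codes == i
        resid[m] -= y[m].mean(axis=0)

    rng = np.random.default_rng(seed)
    count = np.zeros_like(obs)
    for _ in range(n_perm):
        r = resid[rng.permutation(len(resid))]
        pv_b = np.array([procrustes_variance(r[codes == i]) for i in range(len(keep))])
        diff_b = np.abs(pv_b[:, None] - pv_b[None, :])
        count += diff_b >= obs - 1e-15
    p = (1.0 + count) / (1.0 + n_perm)
    np.fill_diagonal(p, 1.0)

    idx = pd.Index(keep)
    return DisparityResult(
        groups=keep,
        variances=pd.Series(pv, index=idx, name="procrustes_variance"),
        differences=pd.DataFrame(obs, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_permutations=n_perm,
        seed=seed,
    )
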