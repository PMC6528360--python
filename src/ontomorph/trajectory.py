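"""Phenotypic trajectory analysis across ontogenetic stages.

A group's trajectory is the ordered sequence of its stage mean shapes.
Three attributes are compared between groups: magnitude (path length in
shape space), direction (angle between principal axes of the stage means),
and trajectory shape (Procrustes distance between the stage-mean point
configurations after translation, unit-size scaling, and orthogonal
rotation computed in the span of the two trajectories).  Nulls come from
RRPP on the residuals of the additive (no group x stage interaction) model;
all three attributes share one permutation stream per seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpa import AlignedDataset
from .models import _perm_summary, design_frame, _hat

__all__ = ["TrajectorySummary", "TrajectoryComparison", "build_trajectories", "compare_trajectories"]


@dataclass
class TrajectorySummary:
    """Ordered stage means of one group with derived attributes."""

    group: str
    stage_labels: list[int]
    stage_means: np.ndarray  # (n_stages, 2k)
    path_length: float
    direction: np.ndarray | None  # unit 2k-vector; None when degenerate
    trajectory_shape: np.ndarray  # centred, unit-size stage-mean configuration

    @property
    def degenerate(self) -> bool:
        return self.direction is None


def _trajectory_attributes(means: np.ndarray):
    """(path_length, direction, shape) of one stage-mean matrix (m, q)."""
    steps = np.diff(means, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    centred = means - means.mean(axis=0)
    size = np.sqrt(np.sum(centred**2))
    if size <= 1e-12 or path <= 1e-12:
        return path, None, centred
    shape = centred / size
    # leading principal axis of the stage means
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    if direction @ (means[-1] - means[0]) < 0:
        direction = -direction
    return path, direction, shape


def build_trajectories(
    aligned: AlignedDataset,
    group: str = "species",
    stage: str = "ontogenetic_stage",
) -> list[TrajectorySummary]:
    """Per-group ontogenetic trajectories from group x stage cell means.

    Stage means are the least-squares means of the full factorial fit,
    which for a model with interaction are the raw cell means.  The
    direction vector is the leading principal axis of a group's stage
    means, oriented from the first toward the last stage.
    """
    df = design_frame(aligned)
    y = aligned.flat()
    groups = sorted(df[group].astype(str).unique())
    stages = sorted(int(s) for s in df[stage].dropna().unique())
    out = []
    for g in groups:
        means = np.empty((len(stages), y.shape[1]))
        for si, st in enumerate(stages):
            m = (df[group].astype(str) == g) & (df[stage] == st)
            if not m.any():
                raise ValueError(f"empty cell: group {g!r} at stage {st}")
            means[si] = y[m.to_numpy()].mean(axis=0)
        path, direction, shape = _trajectory_attributes(means)
        if direction is None:
            warnings.warn(f"group {g!r} has a degenerate (zero-length) trajectory", stacklevel=2)
        out.append(
            TrajectorySummary(
                group=g,
                stage_labels=stages,
                stage_means=means,
                path_length=path,
                direction=direction,
                trajectory_shape=shape,
            )
        )
    return out


def _shape_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Procrustes distance between two centred unit-size trajectory shapes.

    The optimal orthogonal rotation is computed in the joint span of the
    two configurations, which equals the full-space orthogonal Procrustes
    solution (reflections permitted: axis signs in shape space are
    arbitrary).
    """
    q, _ = np.linalg.qr(np.vstack([shape_a, shape_b]).T)
    a = shape_a @ q
    b = shape_b @ q
    s = np.linalg.svd(b.T @ a, compute_uv=False)
    d2 = np.sum(a**2) + np.sum(b**2) - 2.0 * np.sum(s)
    return float(np.sqrt(max(d2, 0.0)))


def _angle_deg(d1: np.ndarray, d2: np.ndarray) -> float:
    """Angle in [0, 90] under the absolute-correlation convention."""
    cos = abs(float(d1 @ d2)) / (np.linalg.norm(d1) * np.linalg.norm(d2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


@dataclass
class TrajectoryComparison:
    """Pairwise trajectory attribute differences with RRPP inference."""

    groups: list[str]
    table: pd.DataFrame  # pair, theta, Z_theta, P_theta, D, Z_D, P_D, dL, Z_L, P_L
    n_permutations: int
    seed: int


def _cell_means(y: np.ndarray, gcodes: np.ndarray, scodes: np.ndarray, ng: int, ns: int):
    means = np.zeros((ng, ns, y.shape[1]))
    counts = np.zeros((ng, ns))
    np.add.at(means, (gcodes, scodes), y)
    np.add.at(counts, (gcodes, scodes), 1.0)
    return means / counts[:, :, None]


def compare_trajectories(
    aligned: AlignedDataset,
    group: str = "species",
    stage: str = "ontogenetic_stage",
    n_perm: int = 10000,
    seed: int = 0,
) -> TrajectoryComparison:
    """Pairwise angle, shape, and magnitude tests between group trajectories.

    Observed attribute differences are compared with nulls built by
    permuting residuals of the additive group + stage model (RRPP), under
    which all groups share one trajectory up to a constant offset.
    """
    df = design_frame(aligned)
    y = aligned.flat()
    glabels = df[group].astype(str)
    names = sorted(glabels.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    stages = sorted(int(s) for s in df[stage].dropna().unique())
    gcodes = glabels.map({g: i for i, g in enumerate(names)}).to_numpy()
    scodes = df[stage].map({s: i for i, s in enumerate(stages)}).to_numpy()
    ng, ns = len(names), len(stages)
    for g in range(ng):
        for s in range(ns):
            if not np.any((gcodes == g) & (scodes == s)):
                raise ValueError(f"empty cell: group {names[g]!r} at stage {stages[s]}")

    def attributes(ymat: np.ndarray):
        means = _cell_means(ymat, gcodes, scodes, ng, ns)
        return [_trajectory_attributes(means[g]) for g in range(ng)]

    obs_attr = attributes(y)

    # reduced (additive) model for RRPP
    gd = pd.get_dummies(glabels, drop_first=True, dtype=float).to_numpy()
    sd = pd.get_dummies(pd.Series(scodes).astype(str), drop_first=True, dtype=float).to_numpy()
    h_red, _ = _hat(np.column_stack([np.ones(len(y)), gd, sd]))
    fitted = h_red @ y
    resid = y - fitted

    pairs = [(i, j) for i in range(ng) for j in range(i + 1, ng)]

    def pair_stats(attr):
        # shapes from _trajectory_attributes are already unit-size unless degenerate
        th = np.full(len(pairs), np.nan)
        dd = np.full(len(pairs), np.nan)
        dl = np.full(len(pairs), np.nan)
        for p_i, (i, j) in enumerate(pairs):
            li, di, si = attr[i]
            lj, dj, sj = attr[j]
            dl[p_i] = abs(li - lj)
            if di is not None and dj is not None:
                th[p_i] = _angle_deg(di, dj)
                dd[p_i] = _shape_distance(si, sj)
        return th, dd, dl

    obs_th, obs_d, obs_l = pair_stats(obs_attr)

    rng = np.random.default_rng(seed)
    null_th = np.empty((n_perm, len(pairs)))
    null_d = np.empty((n_perm, len(pairs)))
    null_l = np.empty((n_perm, len(pairs)))
    for b in range(n_perm):
        y_star = fitted + resid[rng.permutation(len(y))]
        null_th[b], null_d[b], null_l[b] = pair_stats(attributes(y_star))

    rows = []
    for p_i, (i, j) in enumerate(pairs):
        row = {"pair": f"{names[i]} - {names[j]}"}
        for label, obs, null in (
            ("theta", obs_th[p_i], null_th[:, p_i]),
            ("D", obs_d[p_i], null_d[:, p_i]),
            ("dL", obs_l[p_i], null_l[:, p_i]),
        ):
            if np.isnan(obs):
                row[label] = np.nan
                row[f"Z_{label}"] = np.nan
                row[f"P_{label}"] = np.nan
            else:
                res = _perm_summary(obs, null[~np.isnan(null)])
                row[label] = obs
                row[f"Z_{label}"] = res.z
                row[f"P_{label}"] = res.p
        rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["pair", "theta", "Z_theta", "P_theta", "D", "Z_D", "P_D", "dL", "Z_dL", "P_dL"],
    )
    return TrajectoryComparison(groups=names, table=table, n_permutations=n_perm, seed=seed)
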