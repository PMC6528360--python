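"""Shape-space linear models: PCA, Procrustes ANOVA (RRPP), allometry.

The ANOVA machinery fits ordinary least squares to the n x 2k matrix of
aligned shape coordinates and evaluates sequential (type-I) Procrustes sums
of squares.  Null distributions come from a residual randomization
permutation procedure (RRPP): for each term the residuals of the reduced
model (all prior terms) are permuted across specimens, the term SS is
recomputed, and p = (1 + #{null >= observed}) / (1 + n_perm).  Effect sizes
Z are standardized positions of the observed statistic within the null
(log-SS scale by default, which guards against the right skew of SS nulls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpa import AlignedDataset
from .io import metadata_frame

__all__ = [
    "AnovaTable",
    "SlopeComparison",
    "PermutationResult",
    "shape_pca",
    "procrustes_anova",
    "compare_allometric_slopes",
    "design_frame",
]


@dataclass
class PermutationResult:
    """Observed statistic with its permutation null."""

    observed: float
    null: np.ndarray
    z: float
    p: float


def _perm_summary(observed: float, null: np.ndarray, log_scale: bool = False) -> PermutationResult:
    null = np.asarray(null, dtype=float)
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + null.size)
    if log_scale:
        pos = null > 0
        ln_null = np.log(null[pos]) if pos.any() else np.array([0.0])
        ln_obs = np.log(observed) if observed > 0 else -np.inf
        sd = ln_null.std(ddof=1) if ln_null.size > 1 else 0.0
        z = (ln_obs - ln_null.mean()) / sd if sd > 0 else 0.0
    else:
        sd = null.std(ddof=1) if null.size > 1 else 0.0
        z = (observed - null.mean()) / sd if sd > 0 else 0.0
    return PermutationResult(observed=float(observed), null=null, z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# Design matrices


def design_frame(aligned: AlignedDataset) -> pd.DataFrame:
    """Metadata as a model frame with derived size variables."""
    df = metadata_frame(aligned.metadata)
    df["size"] = aligned.centroid_sizes
    df["log_size"] = np.log(aligned.centroid_sizes)
    return df


def _term_columns(df: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one model term (main effect or ':'-interaction)."""
    parts = [p.strip() for p in term.split(":")]
    blocks = []
    for p in parts:
        if p not in df.columns:
            raise ValueError(f"model term {p!r} not found in metadata")
        col = df[p]
        if col.dtype.kind in "OUb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(len(df), -1)
    return out


def _parse_formula(formula: str) -> list[str]:
    terms = [t.strip() for t in formula.replace("~", "").split("+")]
    return [t for t in terms if t]


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())))
    q = q[:, :rank]
    return q @ q.T, rank


# ---------------------------------------------------------------------------
# PCA


def shape_pca(aligned: AlignedDataset):
    """PCA of aligned shape coordinates.

    Returns ``(scores, eigenvalues, percent_variance, loadings)`` where
    eigenvalues are the per-component variances (divisor n-1), percent
    variance sums to 100 over retained (nonzero) components, and loadings
    are unit 2k-vectors (columns).
    """
    y = aligned.flat()
    n = y.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(yc, full_matrices=False)
    evals = s**2 / (n - 1)
    total = evals.sum()
    if total <= 0:
        return (
            np.zeros((n, 0)),
            np.zeros(0),
            np.zeros(0),
            np.zeros((y.shape[1], 0)),
        )
    keep = evals > max(1e-12 * evals[0], 1e-30)
    max_comp = min(n - 1, y.shape[1] - 4)
    idx = np.flatnonzero(keep)[:max_comp]
    scores = (u * s)[:, idx]
    evals = evals[idx]
    percent = 100.0 * evals / evals.sum()
    return scores, evals, percent, vt[idx].T


# ---------------------------------------------------------------------------
# Procrustes ANOVA with RRPP


@dataclass
class AnovaTable:
    """Sequential Procrustes ANOVA table with RRPP inference."""

    terms: list[str]
    df_terms: np.ndarray
    ss: np.ndarray
    ms: np.ndarray
    f: np.ndarray
    z: np.ndarray
    p: np.ndarray
    df_residual: int
    ss_residual: float
    ss_total: float
    n_permutations: int
    seed: int
    log_z: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "df": int(self.df_terms[i]),
                "SS": self.ss[i],
                "MS": self.ms[i],
                "F": self.f[i],
                "Z": self.z[i],
                "p": self.p[i],
            }
            for i, t in enumerate(self.terms)
        ]
        rows.append(
            {
                "term": "residual",
                "df": self.df_residual,
                "SS": self.ss_residual,
                "MS": self.ss_residual / self.df_residual if self.df_residual else np.nan,
                "F": np.nan,
                "Z": np.nan,
                "p": np.nan,
            }
        )
        rows.append(
            {
                "term": "total",
                "df": int(self.df_terms.sum()) + self.df_residual,
                "SS": self.ss_total,
                "MS": np.nan,
                "F": np.nan,
                "Z": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows, columns=["term", "df", "SS", "MS", "F", "Z", "p"])


def procrustes_anova(
    aligned: AlignedDataset,
    formula: str,
    n_perm: int = 10000,
    seed: int = 0,
    log_z: bool = True,
) -> AnovaTable:
    """Sequential (type-I) Procrustes ANOVA of shape on metadata terms.

    ``formula`` is a '+'-separated list of terms over metadata columns
    (``species``, ``life_stage``, ``ontogenetic_stage``, ``size``,
    ``log_size``) with ':' interactions, e.g.
    ``"log_size + species + log_size:species"``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = aligned.flat()
    y = y - y.mean(axis=0)
    n = y.shape[0]
    df = design_frame(aligned)
    terms = _parse_formula(formula)
    if not terms:
        raise ValueError("empty model formula")

    x = np.ones((n, 1))
    hats = []  # hat matrix and rank per nested model, intercept first
    h, rank = _hat(x)
    hats.append((h, rank))
    for t in terms:
        x = np.column_stack([x, _term_columns(df, t)])
        h, new_rank = _hat(x)
        if new_rank == hats[-1][1]:
            raise ValueError(f"rank-deficient design: term {t!r} is aliased with prior terms")
        hats.append((h, new_rank))

    df_terms = np.array([hats[i + 1][1] - hats[i][1] for i in range(len(terms))])
    h_full, rank_full = hats[-1]
    df_res = n - rank_full
    ss_total = float(np.sum((y - hats[0][0] @ y) ** 2))
    ss_res = float(np.sum((y - h_full @ y) ** 2))

    diffs = [hats[i + 1][0] - hats[i][0] for i in range(len(terms))]
    ss = np.array([float(np.sum((d @ y) ** 2)) for d in diffs])
    ms = ss / df_terms
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    f = ms / ms_res if df_res > 0 else np.full(len(terms), np.nan)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    z = np.empty(len(terms))
    p = np.empty(len(terms))
    for i, d in enumerate(diffs):
        h_red = hats[i][0]
        resid = y - h_red @ y
        # nested models: d @ h_red == 0, so permuted SS depends on residuals only
        null = np.array([float(np.sum((d @ resid[pm]) ** 2)) for pm in perms])
        res = _perm_summary(ss[i], null, log_scale=log_z)
        z[i], p[i] = res.z, res.p

    return AnovaTable(
        terms=terms,
        df_terms=df_terms,
        ss=ss,
        ms=ms,
        f=f,
        z=z,
        p=p,
        df_residual=df_res,
        ss_residual=ss_res,
        ss_total=ss_total,
        n_permutations=n_perm,
        seed=seed,
        log_z=log_z,
    )


# ---------------------------------------------------------------------------
# Allometric slope comparison


@dataclass
class SlopeComparison:
    """Pairwise angles (degrees) between per-group allometric vectors with
    RRPP inference under the common-slope null."""

    groups: list[str]
    angles: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.groups):
            for h in self.groups[i + 1 :]:
                rows.append(
                    {
                        "pair": f"{g} - {h}",
                        "angle_deg": self.angles.loc[g, h],
                        "Z": self.z.loc[g, h],
                        "p": self.p.loc[g, h],
                    }
                )
        return pd.DataFrame(rows)


def _group_slopes(y: np.ndarray, x: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-group OLS slope vectors of y (n, q) on centred x; (n_groups, q)."""
    slopes = np.empty((n_groups, y.shape[1]))
    for g in range(n_groups):
        m = codes == g
        xg = x[m] - x[m].mean()
        denom = float(xg @ xg)
        if denom <= 0:
            raise ValueError(f"constant size within group index {g}")
        slopes[g] = (xg @ y[m]) / denom
    return slopes


def _pairwise_angles(slopes: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(slopes, axis=1)
    cos = (slopes @ slopes.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    np.fill_diagonal(ang, 0.0)
    return ang


def compare_allometric_slopes(
    aligned: AlignedDataset,
    group: str = "species",
    size: str = "log_size",
    n_perm: int = 10000,
    seed: int = 0,
) -> SlopeComparison:
    """Pairwise comparison of per-group allometric (shape ~ size) vectors.

    The observed statistic per pair is the angle between group slope
    vectors; its null is built by RRPP under the common-slope model (group
    and size effects but no interaction).
    """
    y = aligned.flat()
    y = y - y.mean(axis=0)
    df = design_frame(aligned)
    labels = df[group].astype(str)
    names = sorted(labels.unique())
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    codes = labels.map({g: i for i, g in enumerate(names)}).to_numpy()
    counts = np.bincount(codes, minlength=len(names))
    if np.any(counts < 3):
        bad = names[int(np.argmin(counts))]
        raise ValueError(f"group {bad!r} has fewer than 3 specimens")
    xsize = df[size].to_numpy(dtype=float)
    for i, g in enumerate(names):
        if np.ptp(xsize[codes == i]) <= 0:
            raise ValueError(f"constant size within group {g!r}")

    obs = _pairwise_angles(_group_slopes(y, xsize, codes, len(names)))

    # common-slope (no interaction) reduced model
    x_red = np.column_stack(
        [np.ones(len(y)), pd.get_dummies(labels, drop_first=True, dtype=float).to_numpy(), xsize]
    )
    h_red, _ = _hat(x_red)
    fitted = h_red @ y
    resid = y - fitted

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(names), len(names)))
    for b in range(n_perm):
        y_star = fitted + resid[rng.permutation(len(y))]
        null[b] = _pairwise_angles(_group_slopes(y_star, xsize, codes, len(names)))

    zmat = np.zeros((len(names), len(names)))
    pmat = np.ones((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = _perm_summary(obs[i, j], null[:, i, j])
            zmat[i, j] = zmat[j, i] = res.z
            pmat[i, j] = pmat[j, i] = res.p
    idx = pd.Index(names)
    return SlopeComparison(
        groups=names,
        angles=pd.DataFrame(obs, index=idx, columns=idx),
        z=pd.DataFrame(zmat, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
        n_permutations=n_perm,
        seed=seed,
    )
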