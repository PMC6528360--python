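"""Landmark and metadata I/O.

Reads and writes 2D landmark configurations in a TPS dialect, specimen
classifier tables (CSV/TSV), semilandmark slider tables and module-partition
tables, and assigns ontogenetic stages from centroid-size percentiles.

TPS dialect
-----------
Each record starts with ``LM=k`` followed by ``k`` whitespace-separated
``x y`` lines (the fixed landmarks digitized on anatomical traits).  An
optional ``CURVES=c`` line introduces ``c`` blocks, each ``POINTS=m``
followed by ``m`` coordinate lines: a digitized curve whose first and last
points are fixed anchors and whose interior points are semilandmarks allowed
to slide along the curve.  Curve points are appended after the fixed
landmarks, in block order.  ``ID=``, ``IMAGE=`` and ``SCALE=`` lines are
recognised; when ``SCALE`` is present all coordinates are multiplied by it.

All user-facing landmark indices (slider tables, partition tables) are
1-indexed; indices are 0-based everywhere inside the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "SpecimenMetadata",
    "ModulePartition",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_classifiers",
    "write_classifiers",
    "read_sliders",
    "write_sliders",
    "read_partition",
    "write_partition",
    "assign_ontogenetic_stage",
    "metadata_frame",
]

LIFE_STAGES = ("juvenile", "adult")


class TPSParseError(ValueError):
    """Raised when a TPS record cannot be parsed."""


@dataclass
class LandmarkConfiguration:
    """One specimen's 2D landmark configuration.

    Parameters
    ----------
    specimen_id : str
        Unique specimen label.
    coords : (k, 2) ndarray
        Landmark coordinates in length units (e.g. mm).
    scale : float, optional
        Units-per-pixel factor already applied to ``coords`` when read from
        a TPS record carrying a ``SCALE=`` line.
    semilandmark_sliders : list of (before, slider, after)
        0-based index triples; the middle landmark slides along the chord
        from ``before`` to ``after`` during superimposition.
    curves : list of list of int
        Index runs of digitized curves (anchors + semilandmarks), kept so
        that TPS round-trips preserve the CURVES/POINTS structure.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    semilandmark_sliders: list[tuple[int, int, int]] = field(default_factory=list)
    curves: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        k = self.coords.shape[0]
        if k < 3:
            raise ValueError(f"configuration needs at least 3 landmarks, got {k}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in specimen {self.specimen_id!r}")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")
        seen_mid: set[int] = set()
        for triple in self.semilandmark_sliders:
            b, s, a = triple
            if len({b, s, a}) != 3:
                raise ValueError(f"slider triple {triple} has repeated indices")
            if not all(0 <= i < k for i in (b, s, a)):
                raise ValueError(f"slider triple {triple} out of range for k={k}")
            if s in seen_mid:
                raise ValueError(f"landmark {s} appears as the sliding point of two triples")
            seen_mid.add(s)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class SpecimenMetadata:
    """Classifier record for one specimen."""

    specimen_id: str
    species: str
    life_stage: str
    ontogenetic_stage: int | None = None
    centroid_size: float | None = None

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(
                f"unknown life_stage {self.life_stage!r} for {self.specimen_id!r}; "
                f"allowed: {', '.join(LIFE_STAGES)}"
            )
        if self.ontogenetic_stage is not None and self.ontogenetic_stage not in (1, 2, 3, 4):
            raise ValueError("ontogenetic_stage must be in {1,2,3,4}")
        if self.centroid_size is not None and not self.centroid_size > 0:
            raise ValueError("centroid_size must be positive")


@dataclass
class ModulePartition:
    """Assignment of every landmark to an anatomical module.

    ``module_labels`` maps 0-based landmark index to a module name
    (canonically ``head`` and ``trunk_tail``, but any >=2 labels work).
    Each module must contain at least 3 landmarks.
    """

    module_labels: dict[int, str]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for lab in self.module_labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        if len(counts) < 2:
            raise ValueError("a partition needs at least 2 modules")
        small = [m for m, c in counts.items() if c < 3]
        if small:
            raise ValueError(f"modules with fewer than 3 landmarks: {', '.join(small)}")
        idx = sorted(self.module_labels)
        if idx != list(range(len(idx))):
            raise ValueError("every landmark index 0..k-1 must be assigned exactly once")

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.module_labels.values()))

    def indices(self, module: str) -> np.ndarray:
        return np.array(sorted(i for i, m in self.module_labels.items() if m == module))


# ---------------------------------------------------------------------------
# TPS reading / writing


def _slider_triples_for_curve(indices: list[int]) -> list[tuple[int, int, int]]:
    # interior points slide between their immediate neighbours on the curve
    return [
        (indices[j - 1], indices[j], indices[j + 1]) for j in range(1, len(indices) - 1)
    ]


def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS file; one :class:`LandmarkConfiguration` per record.

    Curve points are appended after the fixed landmarks; interior curve
    points are registered as semilandmarks with neighbour-derived slider
    triples (curve endpoints are fixed anchors).  ``SCALE`` is applied to
    the coordinates when present.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]

    configs: list[LandmarkConfiguration] = []
    pos = 0
    record_index = 0
    while pos < len(lines):
        if not lines[pos].upper().startswith("LM="):
            raise TPSParseError(
                f"record {record_index}: expected 'LM=' header, got {lines[pos]!r}"
            )
        try:
            k_fixed = int(lines[pos].split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"record {record_index}: bad LM count") from exc
        pos += 1

        def read_points(n: int, what: str) -> np.ndarray:
            nonlocal pos
            pts = []
            for _ in range(n):
                if pos >= len(lines):
                    raise TPSParseError(
                        f"record {record_index}: file ends inside {what} block"
                    )
                parts = lines[pos].split()
                if len(parts) != 2:
                    raise TPSParseError(
                        f"record {record_index}: expected 'x y' in {what} block, "
                        f"got {lines[pos]!r}"
                    )
                try:
                    pts.append([float(parts[0]), float(parts[1])])
                except ValueError as exc:
                    raise TPSParseError(
                        f"record {record_index}: non-numeric coordinate {lines[pos]!r}"
                    ) from exc
                pos += 1
            return np.array(pts, dtype=float).reshape(n, 2)

        fixed = read_points(k_fixed, "LM")

        curves_pts: list[np.ndarray] = []
        specimen_id: str | None = None
        scale: float | None = None
        while pos < len(lines) and not lines[pos].upper().startswith("LM="):
            ln = lines[pos]
            key = ln.split("=", 1)[0].upper()
            if key == "CURVES":
                n_curves = int(ln.split("=", 1)[1])
                pos += 1
                for _ in range(n_curves):
                    if pos >= len(lines) or not lines[pos].upper().startswith("POINTS="):
                        raise TPSParseError(
                            f"record {record_index}: expected POINTS= inside CURVES block"
                        )
                    m = int(lines[pos].split("=", 1)[1])
                    if m < 3:
                        raise TPSParseError(
                            f"record {record_index}: a curve needs >=3 points, got {m}"
                        )
                    pos += 1
                    curves_pts.append(read_points(m, "POINTS"))
            elif key == "ID":
                specimen_id = ln.split("=", 1)[1].strip()
                pos += 1
            elif key == "IMAGE":
                pos += 1
            elif key == "SCALE":
                scale = float(ln.split("=", 1)[1])
                pos += 1
            elif key == "POINTS":
                raise TPSParseError(
                    f"record {record_index}: POINTS= outside a CURVES block"
                )
            else:
                parts = ln.split()
                if len(parts) == 2:
                    raise TPSParseError(
                        f"record {record_index}: more coordinate lines than the LM "
                        f"count announces"
                    )
                pos += 1  # unknown key=value line: ignored

        coords_blocks = [fixed] + curves_pts
        coords = np.vstack(coords_blocks) if coords_blocks else fixed
        sliders: list[tuple[int, int, int]] = []
        curve_indices: list[list[int]] = []
        offset = k_fixed
        for pts in curves_pts:
            idx = list(range(offset, offset + len(pts)))
            curve_indices.append(idx)
            sliders.extend(_slider_triples_for_curve(idx))
            offset += len(pts)
        if scale is not None:
            coords = coords * scale
        if specimen_id is None:
            specimen_id = f"record_{record_index}"
        if coords.shape[0] < 3:
            raise TPSParseError(
                f"record {record_index}: k={coords.shape[0]} < 3 landmarks"
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                coords=coords,
                scale=scale,
                semilandmark_sliders=sliders,
                curves=curve_indices,
            )
        )
        record_index += 1
    return configs


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations in the TPS dialect read by :func:`read_tps`.

    Coordinates are written already scaled (no ``SCALE`` line is emitted),
    so write -> read -> write is byte-stable.
    """
    if not configs:
        raise ValueError("empty dataset: nothing to write")
    out_lines: list[str] = []
    for cfg in configs:
        curve_idx = set(i for c in cfg.curves for i in c)
        fixed_idx = [i for i in range(cfg.n_landmarks) if i not in curve_idx]
        # the dialect appends curve points after fixed landmarks
        if fixed_idx and fixed_idx != list(range(len(fixed_idx))):
            raise ValueError(
                f"specimen {cfg.specimen_id!r}: curve points must follow all fixed landmarks"
            )
        out_lines.append(f"LM={len(fixed_idx)}")
        for i in fixed_idx:
            out_lines.append(f"{_fmt(cfg.coords[i, 0])} {_fmt(cfg.coords[i, 1])}")
        if cfg.curves:
            out_lines.append(f"CURVES={len(cfg.curves)}")
            for idx in cfg.curves:
                out_lines.append(f"POINTS={len(idx)}")
                for i in idx:
                    out_lines.append(f"{_fmt(cfg.coords[i, 0])} {_fmt(cfg.coords[i, 1])}")
        out_lines.append(f"ID={cfg.specimen_id}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# Classifier tables


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_classifiers(path) -> list[SpecimenMetadata]:
    """Read a specimen classifier table (CSV or TSV).

    Required columns: ``specimen_id``, ``species``, ``life_stage``;
    optional: ``ontogenetic_stage``, ``centroid_size``.
    """
    df = pd.read_csv(path, sep=_detect_sep(path))
    required = {"specimen_id", "species", "life_stage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"classifier table missing columns: {sorted(missing)}")
    ids = df["specimen_id"].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate specimen_id values: {dup}")
    records = []
    for _, row in df.iterrows():
        stage = row.get("ontogenetic_stage")
        stage = None if stage is None or pd.isna(stage) else int(stage)
        cs = row.get("centroid_size")
        cs = None if cs is None or pd.isna(cs) else float(cs)
        records.append(
            SpecimenMetadata(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                life_stage=str(row["life_stage"]),
                ontogenetic_stage=stage,
                centroid_size=cs,
            )
        )
    return records


def write_classifiers(metadata: list[SpecimenMetadata], path) -> None:
    metadata_frame(metadata).to_csv(path, index=False)


def metadata_frame(metadata: list[SpecimenMetadata]) -> pd.DataFrame:
    """Tabular view of metadata records (one row per specimen)."""
    return pd.DataFrame(
        {
            "specimen_id": [m.specimen_id for m in metadata],
            "species": [m.species for m in metadata],
            "life_stage": [m.life_stage for m in metadata],
            "ontogenetic_stage": [m.ontogenetic_stage for m in metadata],
            "centroid_size": [m.centroid_size for m in metadata],
        }
    )


# ---------------------------------------------------------------------------
# Slider and partition tables (1-indexed on disk)


def read_sliders(path) -> list[tuple[int, int, int]]:
    df = pd.read_csv(path, sep=_detect_sep(path))
    cols = list(df.columns[:3])
    return [tuple(int(v) - 1 for v in row) for row in df[cols].to_numpy()]


def write_sliders(sliders: list[tuple[int, int, int]], path) -> None:
    pd.DataFrame(
        [(b + 1, s + 1, a + 1) for b, s, a in sliders],
        columns=["before", "slider", "after"],
    ).to_csv(path, index=False)


def read_partition(path) -> ModulePartition:
    df = pd.read_csv(path, sep=_detect_sep(path))
    labels = {int(r["landmark"]) - 1: str(r["module"]) for _, r in df.iterrows()}
    return ModulePartition(labels)


def write_partition(partition: ModulePartition, path) -> None:
    rows = sorted((i + 1, m) for i, m in partition.module_labels.items())
    pd.DataFrame(rows, columns=["landmark", "module"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ontogenetic staging


def assign_ontogenetic_stage(metadata: list[SpecimenMetadata]) -> list[SpecimenMetadata]:
    """Assign ontogenetic stages 1-4 from centroid-size percentiles.

    Adults are stage 4.  Within each species, juveniles are split into
    thirds of the centroid-size distribution: stage 1 up to the 33rd
    percentile (first tertile), stage 2 up to the 66th (second tertile),
    stage 3 above.  Percentiles use average ranks, so ties share a stage,
    and the rule is invariant under any monotone rescaling of CS.
    """
    out = [replace(m) for m in metadata]
    by_species: dict[str, list[int]] = {}
    for i, m in enumerate(out):
        if m.life_stage == "adult":
            m.ontogenetic_stage = 4
        else:
            if m.centroid_size is None:
                raise ValueError(
                    f"juvenile {m.specimen_id!r} has no centroid_size; staging needs CS"
                )
            by_species.setdefault(m.species, []).append(i)
    from scipy.stats import rankdata

    eps = 1e-9
    for species, idx in by_species.items():
        if len(idx) < 3:
            warnings.warn(
                f"species {species!r} has only {len(idx)} juveniles; "
                "tertile staging is degenerate but applied as defined",
                stacklevel=2,
            )
        cs = np.array([out[i].centroid_size for i in idx])
        pct = 100.0 * rankdata(cs, method="average") / len(idx)
        for i, p in zip(idx, pct):
            if p <= 100.0 / 3.0 + eps:
                out[i].ontogenetic_stage = 1
            elif p <= 200.0 / 3.0 + eps:
                out[i].ontogenetic_stage = 2
            else:
                out[i].ontogenetic_stage = 3
    return out
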