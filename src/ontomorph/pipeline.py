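"""End-to-end analysis pipeline with deterministic per-step seeding.

Runs GPA (with sliding semilandmarks) then PCA, Procrustes ANOVA,
allometric-slope comparison, phenotypic trajectory analysis, disparity, and
per-cell CR/GI, writing one CSV per step plus a run manifest.  One global
seed fans out into independent per-step generator streams (step name hashed
into the stream id), so toggling one step never perturbs another's
permutations.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .disparity import disparity_test, procrustes_variance
from .gpa import AlignedDataset, gpa_align, partial_warp_scores
from .integration import covariance_ratio, global_integration
from .io import (
    LandmarkConfiguration,
    metadata_frame,
    read_classifiers,
    read_partition,
    read_sliders,
    read_tps,
    write_classifiers,
    write_partition,
    write_sliders,
    write_tps,
)
from .models import compare_allometric_slopes, procrustes_anova, shape_pca
from .simulate import OntogenySimConfig, generate_dataset
from .trajectory import compare_trajectories

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "step_seed"]

ALL_STEPS = ("gpa", "pca", "anova", "allometry", "trajectory", "disparity", "integration")


def step_seed(seed: int, step: str) -> int:
    """Derive an independent, stable sub-seed for one pipeline step."""
    digest = hashlib.sha256(f"{seed}:{step}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run.

    Exactly one of (``tps_path`` + ``classifier_path``) or ``simulate``
    must be provided.
    """

    tps_path: str | None = None
    classifier_path: str | None = None
    slider_path: str | None = None
    partition_path: str | None = None
    simulate: OntogenySimConfig | None = None
    n_permutations: int = 10000
    seed: int = 0
    out_dir: str = "ontomorph_out"
    steps: tuple = ALL_STEPS
    slide: bool = True

    def __post_init__(self) -> None:
        has_files = self.tps_path is not None and self.classifier_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError("provide exactly one of input paths or a simulate block")


@dataclass
class PipelineResult:
    aligned: AlignedDataset
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured analysis graph and write its report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    partition = None
    if config.simulate is not None:
        lm_configs, metadata, _truth = generate_dataset(config.simulate)
        partition = config.simulate.module_partition
        write_tps(lm_configs, out / "simulated.tps")
        write_classifiers(metadata, out / "simulated_classifiers.csv")
        write_sliders(config.simulate.sliders, out / "simulated_sliders.csv")
        write_partition(partition, out / "simulated_partition.csv")
    else:
        lm_configs = read_tps(config.tps_path)
        metadata = read_classifiers(config.classifier_path)
        by_id = {m.specimen_id: m for m in metadata}
        missing = [c.specimen_id for c in lm_configs if c.specimen_id not in by_id]
        if missing:
            raise ValueError(f"specimens without classifier rows: {missing[:5]}")
        metadata = [by_id[c.specimen_id] for c in lm_configs]
        if config.slider_path:
            sliders = read_sliders(config.slider_path)
            lm_configs = [
                LandmarkConfiguration(
                    specimen_id=c.specimen_id,
                    coords=c.coords,
                    scale=c.scale,
                    semilandmark_sliders=sliders,
                    curves=c.curves,
                )
                for c in lm_configs
            ]
        if config.partition_path:
            partition = read_partition(config.partition_path)

    steps = tuple(config.steps)
    tables: dict[str, pd.DataFrame] = {}

    aligned = gpa_align(lm_configs, slide=config.slide, metadata=metadata)
    flat = aligned.flat()
    coord_cols = [f"{ax}{i + 1}" for i in range(aligned.n_landmarks) for ax in ("x", "y")]
    aligned_df = pd.concat(
        [
            pd.Series([m.specimen_id for m in metadata], name="specimen_id"),
            pd.DataFrame(flat, columns=coord_cols),
        ],
        axis=1,
    )
    tables["aligned"] = aligned_df
    _csv(aligned_df, out / "aligned_coordinates.csv")

    n_perm = config.n_permutations

    if "pca" in steps:
        scores, evals, percent, _ = shape_pca(aligned)
        pca_df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
        pca_df.insert(0, "specimen_id", [m.specimen_id for m in metadata])
        tables["pca_scores"] = pca_df
        tables["pca_variance"] = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(evals))],
                "eigenvalue": evals,
                "percent_variance": percent,
            }
        )
        _csv(pca_df, out / "pca_scores.csv")
        _csv(tables["pca_variance"], out / "pca_variance.csv")

    if "anova" in steps:
        tab = procrustes_anova(
            aligned,
            "species + life_stage + species:life_stage",
            n_perm=n_perm,
            seed=step_seed(config.seed, "anova"),
        )
        tables["anova"] = tab.to_frame()
        _csv(tables["anova"], out / "procrustes_anova.csv")

    if "allometry" in steps:
        allo_seed = step_seed(config.seed, "allometry")
        tab = procrustes_anova(
            aligned, "log_size + species + log_size:species", n_perm=n_perm, seed=allo_seed
        )
        tables["allometry_anova"] = tab.to_frame()
        _csv(tables["allometry_anova"], out / "allometry_anova.csv")
        cmp_ = compare_allometric_slopes(aligned, n_perm=n_perm, seed=allo_seed)
        tables["slope_comparison"] = cmp_.to_frame()
        _csv(tables["slope_comparison"], out / "slope_comparison.csv")

    if "trajectory" in steps:
        cmp_ = compare_trajectories(
            aligned, n_perm=n_perm, seed=step_seed(config.seed, "trajectory")
        )
        tables["trajectory"] = cmp_.table
        _csv(cmp_.table, out / "trajectory_comparison.csv")

    if "disparity" in steps:
        disp_seed = step_seed(config.seed, "disparity")
        df_meta = metadata_frame(metadata)
        rows = []
        for sp in sorted(df_meta["species"].unique()):
            for st in sorted(df_meta["ontogenetic_stage"].dropna().unique()):
                m = ((df_meta["species"] == sp) & (df_meta["ontogenetic_stage"] == st)).to_numpy()
                if m.any():
                    rows.append(
                        {
                            "group": "species_stage",
                            "species": sp,
                            "stage": int(st),
                            "n": int(m.sum()),
                            "procrustes_variance": procrustes_variance(flat[m]),
                        }
                    )
        for st in sorted(df_meta["ontogenetic_stage"].dropna().unique()):
            m = (df_meta["ontogenetic_stage"] == st).to_numpy()
            rows.append(
                {
                    "group": "stage_pooled",
                    "species": "all",
                    "stage": int(st),
                    "n": int(m.sum()),
                    "procrustes_variance": procrustes_variance(flat[m]),
                }
            )
            # among-species-mean disparity at this stage
            means = np.stack(
                [
                    flat[m & (df_meta["species"] == sp).to_numpy()].mean(axis=0)
                    for sp in sorted(df_meta["species"].unique())
                    if (m & (df_meta["species"] == sp).to_numpy()).any()
                ]
            )
            rows.append(
                {
                    "group": "stage_species_means",
                    "species": "all",
                    "stage": int(st),
                    "n": means.shape[0],
                    "procrustes_variance": procrustes_variance(means),
                }
            )
        tables["disparity"] = pd.DataFrame(rows)
        _csv(tables["disparity"], out / "disparity.csv")
        test = disparity_test(aligned, grouping="ontogenetic_stage", n_perm=n_perm, seed=disp_seed)
        pmat = test.p.reset_index(names="stage")
        tables["disparity_test"] = pmat
        _csv(pmat, out / "disparity_stage_pvalues.csv")

    if "integration" in steps and partition is not None:
        int_seed = step_seed(config.seed, "integration")
        df_meta = metadata_frame(metadata)
        rows = []
        for sp in sorted(df_meta["species"].unique()):
            for st in sorted(df_meta["ontogenetic_stage"].dropna().unique()):
                m = ((df_meta["species"] == sp) & (df_meta["ontogenetic_stage"] == st)).to_numpy()
                if m.sum() < 4:
                    continue
                cell = aligned.subset(m)
                cr = covariance_ratio(
                    cell.shapes, partition, n_perm=min(n_perm, 999), seed=int_seed
                )
                try:
                    gi = global_integration(partial_warp_scores(cell))
                    gi_slope, gi_cls = gi.slope, gi.classification
                except (ValueError, np.linalg.LinAlgError) as exc:
                    warnings.warn(f"GI failed for {sp} stage {st}: {exc}", stacklevel=2)
                    gi_slope, gi_cls = np.nan, "undefined"
                rows.append(
                    {
                        "species": sp,
                        "stage": int(st),
                        "n": int(m.sum()),
                        "CR": cr.cr,
                        "CR_p": cr.p,
                        "GI_slope": gi_slope,
                        "GI_class": gi_cls,
                    }
                )
        tables["integration"] = pd.DataFrame(rows)
        _csv(tables["integration"], out / "integration_modularity.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_permutations": n_perm,
        "steps": list(steps),
        "n_specimens": aligned.n_specimens,
        "n_landmarks": aligned.n_landmarks,
        "slide": config.slide,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "seed": config.seed,
                    "n_permutations": n_perm,
                    "steps": list(steps),
                    "slide": config.slide,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(aligned=aligned, tables=tables, manifest=manifest)
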