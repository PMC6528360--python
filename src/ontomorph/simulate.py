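"""Synthetic ontogenetic landmark datasets with known generating truth.

Emulates a cross-sectional ontogenetic study design: several species
sampled at several centroid-size-defined stages, with species-specific mean
shapes, piecewise-linear ontogenetic trajectories through shape space,
species-specific allometric vectors, stagewise convergence of species
offsets (developmental canalization) followed by divergence, and
block-structured (module-wise) landmark covariance.

All shape arithmetic happens in the tangent space at the template; the
nuisance similarity transform (random rotation, translation, and scaling to
the target centroid size) is applied last, so Procrustes alignment must
remove exactly what was added.  Every generating parameter is returned in a
truth record for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LandmarkConfiguration, ModulePartition, SpecimenMetadata

__all__ = [
    "OntogenySimConfig",
    "make_template",
    "make_config",
    "four_species_scenario",
    "generate_dataset",
]


def make_template(n_fixed: int = 7, n_curves: int = 4, pts_per_curve: int = 7):
    """Fish-like template: fixed landmarks plus curves on an elliptical body.

    Returns ``(coords, curves, sliders)`` where each curve contributes its
    own anchor endpoints (fixed) and ``pts_per_curve - 2`` interior
    semilandmarks equally spaced along the arc.  Defaults give 35 landmarks
    of which 20 slide, on 4 curves.
    """
    a, b = 1.0, 0.45
    fixed = np.array(
        [
            [1.08, 0.0],  # snout tip
            [0.80, -0.16],  # mouth corner
            [0.62, 0.15],  # eye
            [0.34, 0.02],  # opercular edge
            [-0.85, 0.13],  # dorsal caudal peduncle
            [-0.85, -0.13],  # ventral caudal peduncle
            [-1.12, 0.0],  # tail tip
        ]
    )[:n_fixed]
    arcs = [(12.0, 72.0), (95.0, 163.0), (197.0, 265.0), (288.0, 348.0)][:n_curves]
    coords = [fixed]
    curves: list[list[int]] = []
    sliders: list[tuple[int, int, int]] = []
    offset = len(fixed)
    for th0, th1 in arcs:
        theta = np.radians(np.linspace(th0, th1, pts_per_curve))
        pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        idx = list(range(offset, offset + pts_per_curve))
        coords.append(pts)
        curves.append(idx)
        sliders.extend((idx[j - 1], idx[j], idx[j + 1]) for j in range(1, pts_per_curve - 1))
        offset += pts_per_curve
    template = np.vstack(coords)
    template -= template.mean(axis=0)
    template /= np.sqrt(np.sum(template**2))
    return template, curves, sliders


def _similarity_fields(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k, 4) of translation/rotation/scale fields."""
    k = template.shape[0]
    tx, ty = template[:, 0], template[:, 1]
    zero = np.zeros(k)

    def fld(xp, yp):
        return np.column_stack([xp, yp]).ravel()

    fields = np.column_stack(
        [fld(np.ones(k), zero), fld(zero, np.ones(k)), fld(tx, ty), fld(-ty, tx)]
    )
    q, _ = np.linalg.qr(fields)
    return q


def _project_tangent(v: np.ndarray, sim_basis: np.ndarray) -> np.ndarray:
    return v - sim_basis @ (sim_basis.T @ v)


@dataclass
class OntogenySimConfig:
    """Full parameterization of the synthetic ontogenetic design.

    Displacement vectors (offsets, trajectory paths, allometric vectors)
    live in the tangent space at the unit-size template (dimensionless
    shape units); centroid sizes are in length units (mm).  ``convergence``
    holds one shrink factor per stage in [0, 1]: the species offsets are
    multiplied by (1 - convergence[stage]).
    """

    n_species: int = 4
    stages: int = 4
    n_per_cell: int = 25
    cell_sizes: np.ndarray | None = None  # (n_species, stages) overrides n_per_cell
    k_landmarks: int = 35
    n_semilandmarks: int = 20
    template: np.ndarray = None
    curves: list[list[int]] = field(default_factory=list)
    sliders: list[tuple[int, int, int]] = field(default_factory=list)
    species_names: list[str] = field(default_factory=list)
    species_offsets: np.ndarray = None  # (n_species, 2k)
    trajectory_paths: np.ndarray = None  # (n_species, stages, 2k)
    convergence: np.ndarray = None  # (stages,)
    allometric_vectors: np.ndarray = None  # (n_species, 2k)
    cs_ranges: np.ndarray = None  # (stages, 2) in mm
    cs_ref: float = 50.0
    module_partition: ModulePartition = None
    within_module_corr: float = 0.45
    between_module_corr: float = 0.10
    noise_sd: np.ndarray = None  # (stages,) per-coordinate sd
    seed: int = 0
    apply_nuisance: bool = True  # False: emit tangent-frame shapes (unit size, no rotation)

    def n_cell(self, s: int, t: int) -> int:
        if self.cell_sizes is not None:
            return int(self.cell_sizes[s, t])
        return self.n_per_cell

    def noise_correlation(self) -> np.ndarray:
        """Landmark-level (k x k) noise correlation implied by the partition."""
        k = self.k_landmarks
        labels = np.array([self.module_partition.module_labels[i] for i in range(k)])
        same = labels[:, None] == labels[None, :]
        c = np.where(same, self.within_module_corr, self.between_module_corr)
        np.fill_diagonal(c, 1.0)
        return c

    def implied_covariance(self, stage: int) -> np.ndarray:
        """Per-specimen 2k x 2k noise covariance at one stage (x, y independent)."""
        c = self.noise_correlation()
        k = self.k_landmarks
        cov = np.zeros((2 * k, 2 * k))
        cov[0::2, 0::2] = c
        cov[1::2, 1::2] = c
        return self.noise_sd[stage] ** 2 * cov

    def validate(self) -> None:
        if self.between_module_corr > self.within_module_corr:
            raise ValueError("between_module_corr must not exceed within_module_corr")
        if not (0 <= self.between_module_corr < 1 and 0 <= self.within_module_corr < 1):
            raise ValueError("correlations must lie in [0, 1)")
        evals = np.linalg.eigvalsh(self.noise_correlation())
        if evals.min() < -1e-10:
            raise ValueError(
                f"implied noise covariance is not PSD (min eigenvalue {evals.min():.3e})"
            )
        if np.any(np.asarray(self.convergence) < 0) or np.any(np.asarray(self.convergence) > 1):
            raise ValueError("convergence factors must lie in [0, 1]")
        if np.any(self.cs_ranges[:, 0] <= 0) or np.any(self.cs_ranges[:, 1] < self.cs_ranges[:, 0]):
            raise ValueError("cs_ranges must be positive (min, max) pairs")


def make_config(
    n_species: int = 4,
    stages: int = 4,
    n_per_cell: int = 25,
    cell_sizes=None,
    seed: int = 0,
    species_names: list[str] | None = None,
    offset_norm: float = 0.025,
    step_schedule: tuple = (0.0, 0.04, 0.08, 0.20),
    divergence_norm: float = 0.12,
    allometry_norm: float = 0.05,
    convergence: tuple = (0.0, 0.3, 0.7, 0.0),
    noise_sd: tuple = (0.006, 0.0045, 0.003, 0.009),
    within_module_corr: float = 0.45,
    between_module_corr: float = 0.10,
) -> OntogenySimConfig:
    """Build a fully-specified config around the fish template.

    Structure vectors (species offsets, a shared ontogeny axis with
    species-specific adult divergence, allometric vectors) are drawn once
    from ``seed`` and projected into the tangent space at the template.
    Defaults encode the study regime the generator is meant to emulate:
    convergence of species means peaking at the late-juvenile stage,
    divergence and a noise release at the adult stage, and a mildly modular
    (head vs trunk+tail) noise covariance.
    """
    template, curves, sliders = make_template()
    k = template.shape[0]
    sim_basis = _similarity_fields(template)
    rng = np.random.default_rng(seed)

    def tangent_unit(v):
        v = _project_tangent(v, sim_basis)
        return v / np.linalg.norm(v)

    def centred_directions(raw: np.ndarray, norm: float) -> np.ndarray:
        centred = raw - raw.mean(axis=0)
        mean_len = np.mean(np.linalg.norm(centred, axis=1))
        if norm == 0.0 or mean_len < 1e-12:
            return np.zeros_like(raw)
        return centred * (norm / mean_len)

    # species mean-shape offsets, centred so they sum to zero
    offsets = centred_directions(
        np.stack([tangent_unit(rng.standard_normal(2 * k)) for _ in range(n_species)]),
        offset_norm,
    )

    # shared ontogeny axis plus species-specific adult divergence
    u = tangent_unit(rng.standard_normal(2 * k))
    w = np.stack([tangent_unit(rng.standard_normal(2 * k)) for _ in range(n_species)])
    w = w - np.outer(w @ u, u)  # divergence orthogonal to the shared axis
    w = centred_directions(w, divergence_norm)
    steps = np.asarray(step_schedule[:stages], dtype=float)
    paths = np.zeros((n_species, stages, 2 * k))
    for s in range(n_species):
        for t in range(stages):
            paths[s, t] = steps[t] * u
        paths[s, stages - 1] += w[s]

    allo = np.stack([tangent_unit(u + 0.4 * rng.standard_normal(2 * k)) for _ in range(n_species)])
    allo *= allometry_norm

    if species_names is None:
        species_names = [f"sp{i + 1}" for i in range(n_species)]

    # anterior landmarks form the head module
    head = template[:, 0] > 0.3 * template[:, 0].max()
    if head.sum() < 3 or (~head).sum() < 3:
        raise ValueError("template does not split into valid head/trunk_tail modules")
    partition = ModulePartition(
        {i: ("head" if head[i] else "trunk_tail") for i in range(k)}
    )

    cs_ranges = np.array([[20.0, 35.0], [35.0, 50.0], [50.0, 65.0], [90.0, 140.0]])[:stages]

    cfg = OntogenySimConfig(
        n_species=n_species,
        stages=stages,
        n_per_cell=n_per_cell,
        cell_sizes=None if cell_sizes is None else np.asarray(cell_sizes, dtype=int),
        k_landmarks=k,
        n_semilandmarks=sum(len(c) - 2 for c in curves),
        template=template,
        curves=curves,
        sliders=sliders,
        species_names=list(species_names),
        species_offsets=offsets,
        trajectory_paths=paths,
        convergence=np.asarray(convergence[:stages], dtype=float),
        allometric_vectors=allo,
        cs_ranges=cs_ranges,
        cs_ref=float(np.exp(np.mean(np.log(cs_ranges.mean(axis=1))))),
        module_partition=partition,
        within_module_corr=within_module_corr,
        between_module_corr=between_module_corr,
        noise_sd=np.asarray(noise_sd[:stages], dtype=float),
        seed=seed,
    )
    cfg.validate()
    return cfg


def four_species_scenario(seed: int = 1905) -> OntogenySimConfig:
    """Frozen four-species, four-stage design with the study's cell sizes.

    390 specimens total: 291 juveniles across three settlement stages and
    99 adults, in species cells 34/35/37/21, 16/15/17/18, 26/27/29/38 and
    18/18/19/22.  Convergence peaks at the late-juvenile stage, adults
    diverge, and adult within-cell noise exceeds the juvenile levels, so
    inter-specific disparity is minimal at stage 3 and maximal at stage 4.
    """
    cell_sizes = np.array(
        [
            [34, 35, 37, 21],
            [16, 15, 17, 18],
            [26, 27, 29, 38],
            [18, 18, 19, 22],
        ]
    )
    return make_config(
        cell_sizes=cell_sizes,
        seed=seed,
        species_names=["D_annularis", "D_puntazzo", "D_sargus", "D_vulgaris"],
    )


def generate_dataset(config: OntogenySimConfig):
    """Sample a landmark dataset from the configured generative model.

    Returns ``(configs, metadata, truth)``: TPS-ready landmark
    configurations with nuisance rotation/translation/scale applied,
    specimen metadata (species, life stage, true stage, centroid size), and
    a truth record with every generating parameter plus the per-specimen
    tangent-space noise draws and cell mean vectors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.k_landmarks
    template = config.template
    chol = np.linalg.cholesky(
        config.noise_correlation() + 1e-12 * np.eye(k)
    )

    configs: list[LandmarkConfiguration] = []
    metadata: list[SpecimenMetadata] = []
    noise_draws = []
    cell_means = np.zeros((config.n_species, config.stages, 2 * k))
    counter = 0
    for s in range(config.n_species):
        for t in range(config.stages):
            mean_t = (
                template.ravel()
                + (1.0 - config.convergence[t]) * config.species_offsets[s]
                + config.trajectory_paths[s, t]
            )
            cell_means[s, t] = mean_t
            n_cell = config.n_cell(s, t)
            lo, hi = config.cs_ranges[t]
            cs = rng.uniform(lo, hi, size=n_cell)
            zx = rng.standard_normal((n_cell, k)) @ chol.T
            zy = rng.standard_normal((n_cell, k)) @ chol.T
            noise = np.empty((n_cell, 2 * k))
            noise[:, 0::2] = zx * config.noise_sd[t]
            noise[:, 1::2] = zy * config.noise_sd[t]
            for i in range(n_cell):
                shape = (
                    mean_t
                    + config.allometric_vectors[s] * np.log(cs[i] / config.cs_ref)
                    + noise[i]
                ).reshape(k, 2)
                if config.apply_nuisance:
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    rot = np.array(
                        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                    )
                    dev = shape - shape.mean(axis=0)
                    size_now = np.sqrt(np.sum(dev**2))
                    coords = (dev / size_now * cs[i]) @ rot.T + rng.uniform(-100, 100, size=2)
                else:
                    coords = shape
                counter += 1
                sid = f"{config.species_names[s]}_st{t + 1}_{counter:04d}"
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=sid,
                        coords=coords,
                        semilandmark_sliders=list(config.sliders),
                        curves=[list(c) for c in config.curves],
                    )
                )
                metadata.append(
                    SpecimenMetadata(
                        specimen_id=sid,
                        species=config.species_names[s],
                        life_stage="adult" if t == config.stages - 1 else "juvenile",
                        ontogenetic_stage=t + 1,
                        centroid_size=float(cs[i]),
                    )
                )
            noise_draws.append(noise)

    truth = {
        "config": config,
        "cell_means": cell_means,
        "noise": np.vstack(noise_draws),
        "implied_covariance": [config.implied_covariance(t) for t in range(config.stages)],
    }
    return configs, metadata, truth
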