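import numpy as np
import pytest

from ontomorph import AlignedDataset, SpecimenMetadata, generate_dataset, make_config


def make_aligned(shapes, species, stages, csizes=None):
    """Build an AlignedDataset directly from shape-space arrays.

    Used by tests that exercise the statistical layer on exactly known
    coordinates, bypassing superimposition.
    """
    shapes = np.asarray(shapes, dtype=float)
    n = shapes.shape[0]
    if shapes.ndim == 2:  # (n, 2k) -> (n, k, 2)
        shapes = shapes.reshape(n, -1, 2)
    if csizes is None:
        csizes = np.ones(n)
    metadata = [
        SpecimenMetadata(
            specimen_id=f"s{i}",
            species=str(species[i]),
            life_stage="adult" if int(stages[i]) == 4 else "juvenile",
            ontogenetic_stage=int(stages[i]),
            centroid_size=float(csizes[i]),
        )
        for i in range(n)
    ]
    return AlignedDataset(
        shapes=shapes,
        consensus=shapes.mean(axis=0),
        centroid_sizes=np.asarray(csizes, dtype=float),
        metadata=metadata,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Small 4-species x 4-stage simulated dataset (raw configurations)."""
    cfg = make_config(n_per_cell=6, seed=11)
    configs, metadata, truth = generate_dataset(cfg)
    return cfg, configs, metadata, truth


@pytest.fixture(scope="session")
def small_aligned(small_dataset):
    from ontomorph import gpa_align

    cfg, configs, metadata, _ = small_dataset
    return cfg, gpa_align(configs, slide=True, metadata=metadata)
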