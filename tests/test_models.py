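"""Shape PCA, Procrustes ANOVA with RRPP, allometric slope comparison."""

import numpy as np
import pytest

from ontomorph import compare_allometric_slopes, procrustes_anova, shape_pca

from conftest import make_aligned


def gaussian_aligned(rng, n, q=16, species=None, stages=None, csizes=None, mean=None):
    y = rng.normal(size=(n, q)) * 0.01
    if mean is not None:
        y = y + mean
    species = species if species is not None else ["sp1"] * n
    stages = stages if stages is not None else [1] * n
    return make_aligned(y, species, stages, csizes)


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_shapes_no_components():
    al = make_aligned(np.ones((5, 16)), ["a"] * 5, [1] * 5)
    scores, evals, percent, _ = shape_pca(al)
    assert scores.shape[1] == 0 and evals.size == 0


def test_pca_percent_sums_to_100():
    rng = np.random.default_rng(0)
    al = gaussian_aligned(rng, 30)
    _, _, percent, _ = shape_pca(al)
    assert percent.sum() == pytest.approx(100.0, abs=1e-6)


def test_pca_matches_svd_oracle_up_to_sign():
    rng = np.random.default_rng(1)
    y = rng.normal(size=(5, 8))
    al = make_aligned(y, ["a"] * 5, [1] * 5)
    scores, evals, _, loadings = shape_pca(al)
    yc = y - y.mean(axis=0)
    oracle_evals, oracle_vecs = np.linalg.eigh(yc.T @ yc / 4)
    order = np.argsort(oracle_evals)[::-1]
    oracle_evals = oracle_evals[order][: evals.size]
    np.testing.assert_allclose(evals, oracle_evals, atol=1e-10)
    for j in range(evals.size):
        v = oracle_vecs[:, order[j]]
        assert min(
            np.abs(loadings[:, j] - v).max(), np.abs(loadings[:, j] + v).max()
        ) <= 1e-8


def test_pca_single_specimen_rejected():
    al = make_aligned(np.ones((1, 8)), ["a"], [1])
    with pytest.raises(ValueError):
        shape_pca(al)


# ---------------------------------------------------------------------------
# Procrustes ANOVA


def test_two_group_toy_matches_projection_oracle():
    """Balanced 2-group toy data: SS and F against closed-form projections."""
    rng = np.random.default_rng(2)
    y = rng.normal(size=(6, 4))
    groups = ["a", "a", "a", "b", "b", "b"]
    al = make_aligned(y, groups, [1] * 6)
    tab = procrustes_anova(al, "species", n_perm=9, seed=0)

    yc = y - y.mean(axis=0)
    ma = yc[:3].mean(axis=0)
    mb = yc[3:].mean(axis=0)
    ss_between = 3 * 3 / 6 * np.sum((ma - mb) ** 2)
    ss_within = np.sum((yc[:3] - ma) ** 2) + np.sum((yc[3:] - mb) ** 2)
    assert tab.ss[0] == pytest.approx(ss_between, abs=1e-10)
    assert tab.ss_residual == pytest.approx(ss_within, abs=1e-10)
    assert tab.f[0] == pytest.approx((ss_between / 1) / (ss_within / 4), abs=1e-10)
    assert tab.ss_total == pytest.approx(tab.ss.sum() + tab.ss_residual, abs=1e-8)


def test_huge_separation_gives_minimal_p():
    rng = np.random.default_rng(3)
    mean = np.zeros((40, 8))
    mean[20:, 0] = 50.0  # 50 sigma apart at unit noise
    y = rng.normal(size=(40, 8)) + mean
    al = make_aligned(y, ["a"] * 20 + ["b"] * 20, [1] * 40)
    tab = procrustes_anova(al, "species", n_perm=199, seed=4)
    assert tab.p[0] == pytest.approx(1.0 / 200.0)
    assert tab.z[0] > 2


def test_permutations_reproducible_and_order_invariant():
    rng = np.random.default_rng(5)
    y = rng.normal(size=(24, 10))
    species = (["a"] * 8 + ["b"] * 8 + ["c"] * 8)
    stages = [1, 2] * 12
    al = make_aligned(y, species, stages)
    t1 = procrustes_anova(al, "species + ontogenetic_stage", n_perm=99, seed=7)
    t2 = procrustes_anova(al, "species + ontogenetic_stage", n_perm=99, seed=7)
    np.testing.assert_array_equal(t1.p, t2.p)
    np.testing.assert_array_equal(t1.z, t2.z)

    # permuting specimen order leaves every SS unchanged
    perm = np.random.default_rng(8).permutation(24)
    al_p = make_aligned(y[perm], [species[i] for i in perm], [stages[i] for i in perm])
    t3 = procrustes_anova(al_p, "species + ontogenetic_stage", n_perm=9, seed=7)
    np.testing.assert_allclose(t1.ss, t3.ss, atol=1e-10)


def test_aliased_term_rejected():
    rng = np.random.default_rng(6)
    y = rng.normal(size=(10, 4))
    al = make_aligned(y, ["a"] * 5 + ["b"] * 5, [1] * 10)
    with pytest.raises(ValueError, match="aliased"):
        procrustes_anova(al, "species + species", n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# allometric slopes


def _allometric_dataset(rng, slopes, n_per_group=20, noise=0.01):
    n_groups = len(slopes)
    ys, species, css = [], [], []
    for g, b in enumerate(slopes):
        logcs = rng.uniform(1.0, 3.0, size=n_per_group)
        y = np.outer(logcs, b) + rng.normal(size=(n_per_group, len(b))) * noise
        ys.append(y)
        species += [f"g{g}"] * n_per_group
        css.append(np.exp(logcs))
    return make_aligned(np.vstack(ys), species, [1] * n_per_group * n_groups, np.concatenate(css))


def test_orthogonal_slopes_recovered():
    rng = np.random.default_rng(7)
    b1 = np.zeros(12)
    b1[0] = 0.2
    b2 = np.zeros(12)
    b2[1] = 0.2
    al = _allometric_dataset(rng, [b1, b2])
    cmp_ = compare_allometric_slopes(al, n_perm=99, seed=1)
    assert cmp_.angles.loc["g0", "g1"] == pytest.approx(90.0, abs=2.0)


def test_identical_slopes_not_significant():
    rng = np.random.default_rng(8)
    b = np.zeros(12)
    b[0] = 0.2
    rejections = 0
    for rep in range(10):
        al = _allometric_dataset(np.random.default_rng(100 + rep), [b, b], noise=0.02)
        cmp_ = compare_allometric_slopes(al, n_perm=99, seed=rep)
        rejections += cmp_.p.loc["g0", "g1"] <= 0.05
    assert rejections <= 2  # near-nominal false positive rate under the null


def test_angle_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(9)
    b1, b2, b3 = np.eye(3, 12) * 0.3
    al = _allometric_dataset(rng, [b1, b2, b3], n_per_group=10)
    cmp_ = compare_allometric_slopes(al, n_perm=19, seed=0)
    a = cmp_.angles.to_numpy()
    np.testing.assert_allclose(a, a.T, atol=1e-10)
    assert np.abs(np.diag(a)).max() == 0.0


def test_constant_size_rejected():
    al = make_aligned(np.random.default_rng(0).normal(size=(8, 6)),
                      ["a"] * 4 + ["b"] * 4, [1] * 8, np.ones(8))
    with pytest.raises(ValueError, match="constant size"):
        compare_allometric_slopes(al, n_perm=9, seed=0)
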