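"""GPA, thin-plate-spline bending energy, sliding, partial warps.

Independent small-instance oracles: a brute-force alternating-optimization
GPA (closed-form 2D rotation angles), a linear-solve assembly of the TPS
system, scalar numeric minimization for sliding, and explicit projection
loops for partial-warp scores.
"""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ontomorph import (
    LandmarkConfiguration,
    bending_energy_matrix,
    centroid_size,
    generate_dataset,
    gpa_align,
    make_config,
    partial_warp_scores,
    slide_semilandmarks,
    tangent_coordinates,
)
from ontomorph.gpa import _center_scale, _total_bending_energy


def lc(coords, specimen_id="s", sliders=()):
    return LandmarkConfiguration(
        specimen_id=specimen_id, coords=np.asarray(coords, float),
        semilandmark_sliders=list(sliders),
    )


# ---------------------------------------------------------------------------
# centroid size


def test_centroid_size_unit_square():
    assert centroid_size(lc([(0, 0), (1, 0), (1, 1), (0, 1)])) == pytest.approx(np.sqrt(2))


def test_centroid_size_homogeneity():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(35, 2))
    assert centroid_size(lc(coords * 3.7)) == pytest.approx(3.7 * centroid_size(lc(coords)))


def test_centroid_size_brute_force():
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(35, 2))
    expected = np.sqrt(
        sum((x - coords[:, 0].mean()) ** 2 for x in coords[:, 0])
        + sum((y - coords[:, 1].mean()) ** 2 for y in coords[:, 1])
    )
    assert centroid_size(lc(coords)) == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# GPA


def brute_force_gpa(shapes, n_iter=2000):
    """Alternating optimization with closed-form 2D rotation angles."""
    shapes = [s - s.mean(axis=0) for s in shapes]
    shapes = [s / np.sqrt(np.sum(s**2)) for s in shapes]
    consensus = shapes[0].copy()
    for _ in range(n_iter):
        rotated = []
        for s in shapes:
            num = np.sum(s[:, 0] * consensus[:, 1] - s[:, 1] * consensus[:, 0])
            den = np.sum(s * consensus)
            theta = np.arctan2(num, den)
            r = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            rotated.append(s @ r.T)
        shapes = rotated
        c = np.mean(shapes, axis=0)
        c -= c.mean(axis=0)
        consensus = c / np.sqrt(np.sum(c**2))
    return consensus, np.stack(shapes)


def _align_frames(a, b):
    """Optimal rotation of stacked shapes a onto b (removes the arbitrary
    global orientation before comparing two GPA solutions)."""
    u, _, vt = np.linalg.svd(a.reshape(-1, 2).T @ b.reshape(-1, 2))
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return a @ r


def test_single_configuration_aligns_to_itself():
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(10, 2)) * 5 + 3
    al = gpa_align([lc(coords)])
    expected = _center_scale(coords)
    np.testing.assert_allclose(
        _align_frames(al.shapes[0], expected), expected, atol=1e-10
    )


def test_exact_superimposition_of_rotated_copy():
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(12, 2))
    rot90 = coords @ np.array([[0.0, -1.0], [1.0, 0.0]]).T + np.array([4.0, -2.0])
    al = gpa_align([lc(coords, "a"), lc(rot90, "b")])
    assert np.linalg.norm(al.shapes[0] - al.shapes[1]) <= 1e-10


def test_matches_brute_force_oracle_on_triangles():
    rng = np.random.default_rng(4)
    shapes = rng.normal(size=(10, 3, 2))
    al = gpa_align([lc(s, f"t{i}") for i, s in enumerate(shapes)], tol=1e-12)
    oracle_c, oracle_s = brute_force_gpa(list(shapes))
    np.testing.assert_allclose(
        _align_frames(oracle_c, al.consensus), al.consensus, atol=1e-8
    )
    np.testing.assert_allclose(
        _align_frames(oracle_s, al.shapes), al.shapes, atol=1e-8
    )


def test_unit_size_and_zero_centroid(small_aligned):
    _, al = small_aligned
    cs = np.sqrt((al.shapes**2).sum(axis=(1, 2)))
    assert np.abs(cs - 1).max() <= 1e-8
    assert np.abs(al.shapes.mean(axis=1)).max() <= 1e-8
    # consensus is the (unit-scaled) arithmetic mean of the aligned shapes
    np.testing.assert_allclose(al.consensus, _center_scale(al.shapes.mean(axis=0)), atol=1e-6)


def test_invariance_under_similarity_transforms(small_dataset):
    import copy

    _, configs, metadata, _ = small_dataset
    al = gpa_align(configs, slide=True, metadata=metadata)
    moved = copy.deepcopy(configs)
    th = 0.83
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    moved[0].coords = moved[0].coords @ r.T * 2.5 + np.array([-7.0, 11.0])
    moved[5].coords = moved[5].coords * 0.2 + np.array([100.0, 0.0])
    al2 = gpa_align(moved, slide=True, metadata=metadata)
    assert np.abs(al.shapes - al2.shapes).max() <= 1e-8
    assert np.abs(al.consensus - al2.consensus).max() <= 1e-8


def test_mismatched_landmark_count_rejected():
    a = lc(np.zeros((4, 2)) + np.eye(4, 2), "a")
    rng = np.random.default_rng(0)
    b = lc(rng.normal(size=(5, 2)), "b")
    with pytest.raises(ValueError, match="k="):
        gpa_align([a, b])


# ---------------------------------------------------------------------------
# bending energy


def oracle_bending_energy(ref):
    """Assemble L and extract the k x k block via column-wise linear solves."""
    k = len(ref)
    kmat = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            r2 = np.sum((ref[i] - ref[j]) ** 2)
            kmat[i, j] = 0.0 if r2 == 0 else r2 * np.log(np.sqrt(r2))
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = kmat
    L[:k, k] = 1.0
    L[k, :k] = 1.0
    L[:k, k + 1 : k + 3] = ref
    L[k + 1 : k + 3, :k] = ref.T
    cols = [np.linalg.solve(L, e) for e in np.eye(k + 3)[:k]]
    return np.column_stack(cols)[:k, :]


def test_square_matches_hand_assembled_solve():
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    be = bending_energy_matrix(square)
    oracle = oracle_bending_energy(square)
    np.testing.assert_allclose(be, (oracle + oracle.T) / 2, atol=1e-10)


def test_affine_vectors_annihilated():
    rng = np.random.default_rng(5)
    ref = rng.normal(size=(12, 2))
    be = bending_energy_matrix(ref)
    for v in (np.ones(12), ref[:, 0], ref[:, 1]):
        assert np.linalg.norm(be @ v) <= 1e-8 * max(1, np.linalg.norm(v))


def test_psd_with_three_nulls():
    rng = np.random.default_rng(6)
    ref = rng.normal(size=(15, 2))
    evals = np.linalg.eigvalsh(bending_energy_matrix(ref))
    assert evals.min() >= -1e-10
    assert np.sum(np.abs(evals) < 1e-9 * max(1.0, evals.max())) == 3


def test_coincident_landmarks_rejected():
    ref = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
    with pytest.raises(np.linalg.LinAlgError, match="0 and 1"):
        bending_energy_matrix(ref)


# ---------------------------------------------------------------------------
# sliding


@pytest.fixture(scope="module")
def slide_setup():
    from ontomorph import make_template

    template, _, sliders = make_template()
    return template, sliders


def test_no_displacement_at_reference(slide_setup):
    template, sliders = slide_setup
    slid = slide_semilandmarks(template.copy(), template, sliders)
    np.testing.assert_allclose(slid, template, atol=1e-10)


def test_single_perturbation_recovered(slide_setup):
    template, sliders = slide_setup
    be = bending_energy_matrix(template)
    b, s, a = sliders[3]
    tangent = template[a] - template[b]
    tangent /= np.linalg.norm(tangent)
    shape = template.copy()
    shape[s] += 0.02 * tangent
    e_before = _total_bending_energy(shape[None], template, be)

    slid = slide_semilandmarks(shape, template, sliders, be_matrix=be)
    e_after = _total_bending_energy(slid[None], template, be)
    assert e_after < e_before
    # moves back toward the reference position
    assert np.linalg.norm(slid[s] - template[s]) < np.linalg.norm(shape[s] - template[s])


def test_matches_scalar_minimization_oracle(slide_setup):
    """One slider free: compare with numeric 1D minimization of the energy."""
    template, sliders = slide_setup
    be = bending_energy_matrix(template)
    b, s, a = sliders[7]
    tangent = template[a] - template[b]
    tangent /= np.linalg.norm(tangent)
    shape = template.copy()
    shape[s] += 0.015 * tangent

    one = [sliders[7]]
    slid = slide_semilandmarks(shape, template, one, be_matrix=be)

    def energy(lam):
        trial = shape.copy()
        trial[s] = shape[s] + lam * tangent
        return _total_bending_energy(trial[None], template, be)

    lam_star = minimize_scalar(energy, bounds=(-0.1, 0.1), method="bounded").x
    expected = shape[s] + lam_star * tangent
    np.testing.assert_allclose(slid[s], expected, atol=1e-6)


def test_bending_energy_monotone_within_iterations(small_aligned):
    _, al = small_aligned
    assert al.bending_energy_trace, "sliding GPA records the energy trace"
    for before, after in al.bending_energy_trace:
        assert after <= before + 1e-9


def test_zero_length_tangent_rejected(slide_setup):
    template, sliders = slide_setup
    b, s, a = sliders[0]
    shape = template.copy()
    shape[a] = shape[b]
    with pytest.raises(ValueError, match="zero-length tangent"):
        slide_semilandmarks(shape, template, [sliders[0]])


# ---------------------------------------------------------------------------
# partial warps


def test_consensus_projects_to_zero(small_aligned):
    _, al = small_aligned
    basis = partial_warp_scores(al)
    d = basis.reference.ravel() - _center_scale(al.consensus).ravel()
    assert np.abs(d).max() <= 1e-12
    scores = np.einsum("kj,ka->ja", basis.principal_warps, _center_scale(al.consensus) - basis.reference)
    assert np.abs(scores).max() <= 1e-12


def test_reconstruction_closes(small_aligned):
    _, al = small_aligned
    basis = partial_warp_scores(al)
    tang = tangent_coordinates(al).reshape(al.n_specimens, -1, 2)
    assert np.abs(basis.reconstruct() - tang).max() <= 1e-8


def test_uniform_component_has_zero_bending(small_aligned):
    _, al = small_aligned
    basis = partial_warp_scores(al)
    be = bending_energy_matrix(basis.reference)
    for col in basis.uniform_basis.T:
        field = col.reshape(-1, 2)
        e = field[:, 0] @ be @ field[:, 0] + field[:, 1] @ be @ field[:, 1]
        assert abs(e) <= 1e-10


def test_warp_variances_match_projection_loop():
    """6-landmark toy set: per-warp variance vs an explicit projection loop."""
    rng = np.random.default_rng(9)
    base = np.array([[0, 0], [2, 0], [2, 1], [1, 1.6], [0, 1], [-0.5, 0.4]], float)
    configs = [
        LandmarkConfiguration(f"s{i}", base + rng.normal(scale=0.03, size=base.shape))
        for i in range(8)
    ]
    al = gpa_align(configs)
    basis = partial_warp_scores(al)
    tang = tangent_coordinates(al).reshape(8, 6, 2)
    d = tang - basis.reference
    for j in range(basis.n_warps):
        for axis in range(2):
            proj = np.array([basis.principal_warps[:, j] @ d[i, :, axis] for i in range(8)])
            expected = proj.var(ddof=1)
            got = basis.partial_warp_scores[:, j, axis].var(ddof=1)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-18)
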