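import numpy as np
import pytest

from bandseg import (
    PhantomSpec,
    ValidationError,
    fit_point_distribution_model,
    generate_shape_family,
    procrustes_align,
    project_shape,
    reconstruct_shape,
)
from bandseg.shape_model import ShapeModel


def _blob(rng, n=30):
    t = 2 * np.pi * np.arange(n) / n
    r = 10 + 2 * np.cos(2 * t + rng.uniform(0, 2 * np.pi))
    return np.column_stack([r * np.sin(t), r * np.cos(t)])


def _similarity(p, scale, angle, shift):
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return scale * (p @ rot) + np.asarray(shift)


def test_procrustes_aligns_similarity_copies(rng):
    base = _blob(rng)
    shapes = [
        _similarity(base, s, a, t)
        for s, a, t in [(1.0, 0.0, (0, 0)), (2.5, 0.7, (30, -12)), (0.4, -1.2, (5, 99))]
    ]
    res = procrustes_align(shapes)
    # pose differences are pure similarity -> perfect alignment
    for a in res.aligned[1:]:
        assert np.allclose(a, res.aligned[0], atol=1e-8)
    assert res.residuals[-1] < 1e-12
    # mean convention: zero centroid, unit centroid size
    assert np.allclose(res.mean.mean(axis=0), 0.0, atol=1e-12)
    assert np.linalg.norm(res.mean) == pytest.approx(1.0)
    # stored transforms map inputs onto their aligned versions
    for s, tr, a in zip(shapes, res.transforms, res.aligned):
        assert np.allclose(tr.apply(s), a, atol=1e-8)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)


def test_procrustes_residuals_non_increasing(rng):
    shapes = [_blob(rng) + rng.normal(scale=0.3, size=(30, 2)) for _ in range(8)]
    res = procrustes_align(shapes)
    assert np.all(np.diff(res.residuals) <= 1e-12)


def test_pdm_eigenvalues_against_known_covariance():
    # two planted orthogonal directions with variances 9 and 1 (biased 1/n);
    # coefficients chosen with exact sample variance
    n_pts = 10
    base = np.zeros((n_pts, 2))
    base[:, 0] = np.arange(n_pts)  # non-degenerate contour
    e1 = np.zeros(2 * n_pts)
    e1[0] = 1.0
    e2 = np.zeros(2 * n_pts)
    e2[3] = 1.0
    coeff = np.array([-1.0, 1.0])  # mean 0, biased variance 1
    shapes = [
        (base.ravel() + 3.0 * c1 * e1 + 1.0 * c2 * e2).reshape(n_pts, 2)
        for c1 in coeff
        for c2 in coeff
    ]
    model = fit_point_distribution_model(shapes, mu=0.89)
    # cumulative fractions: 9/10 = 0.9 > 0.89 -> a single retained mode
    assert model.n_modes == 1
    assert model.eigenvalues[0] == pytest.approx(9.0)
    assert model.total_variance == pytest.approx(10.0)
    # with a higher target both modes are needed
    model2 = fit_point_distribution_model(shapes, mu=0.95)
    assert model2.n_modes == 2
    assert np.allclose(model2.eigenvalues, [9.0, 1.0])


def test_pdm_zero_variance_keeps_no_modes():
    square = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
    model = fit_point_distribution_model([square, square.copy()], mu=0.95)
    assert model.n_modes == 0
    assert model.total_variance == 0.0


def test_planted_mode_count_recovered():
    # well-separated variances keep the 2-mode cumulative fraction far below
    # the 0.95 cut, so the count is stable under sampling fluctuation
    fam = generate_shape_family(50, PhantomSpec(seed=5), mode_sds=(8.0, 6.0, 5.0), seed=5)
    model = fit_point_distribution_model(fam, mu=0.95)
    assert model.n_modes == 3


def test_all_zero_mode_sds_gives_identical_contours():
    fam = generate_shape_family(
        6, PhantomSpec(seed=3), mode_sds=(0.0, 0.0), seed=3, noise_sd=0.0
    )
    for f in fam[1:]:
        assert np.allclose(f, fam[0])


def test_eigenvalue_ratios_match_planted_sds():
    fam = generate_shape_family(
        200, PhantomSpec(seed=11), mode_sds=(8.0, 4.0, 2.0), seed=11, noise_sd=0.0
    )
    model = fit_point_distribution_model(fam, mu=0.999)
    ratios = model.eigenvalues[:3] / model.eigenvalues[0]
    planted = np.array([1.0, (4 / 8) ** 2, (2 / 8) ** 2])
    assert np.allclose(ratios, planted, rtol=0.25)  # sampling error at n = 200


def test_project_reconstruct_roundtrip(rng):
    fam = generate_shape_family(30, PhantomSpec(seed=7), mode_sds=(6.0, 3.0), seed=7)
    model = fit_point_distribution_model(fam, mu=1 - 1e-9)
    x = fam[4]
    back = reconstruct_shape(model, project_shape(model, x))
    assert np.allclose(back, x, atol=1e-8)


def test_model_json_roundtrip(tmp_path, rng):
    fam = generate_shape_family(20, PhantomSpec(seed=9), mode_sds=(5.0, 2.0), seed=9)
    model = fit_point_distribution_model(fam)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = ShapeModel.from_json(path)
    assert back.n_points == model.n_points
    assert np.allclose(back.mean_shape, model.mean_shape)
    assert np.allclose(back.eigenvectors, model.eigenvectors)
    assert np.allclose(back.eigenvalues, model.eigenvalues)


def test_validation_errors():
    with pytest.raises(ValidationError):
        procrustes_align([])
    sq = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
    tri = sq[:3]
    with pytest.raises(ValidationError):
        procrustes_align([sq, tri])  # point-count mismatch
    with pytest.raises(ValidationError):
        fit_point_distribution_model([sq], mu=0.95)  # one shape
    with pytest.raises(ValidationError):
        fit_point_distribution_model([sq, sq], mu=1.5)  # bad mu
    model = fit_point_distribution_model(
        generate_shape_family(10, PhantomSpec(seed=1), mode_sds=(4.0,), seed=1)
    )
    with pytest.raises(ValidationError):
        reconstruct_shape(model, np.zeros(model.n_modes + 1))
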