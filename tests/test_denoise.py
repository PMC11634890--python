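import numpy as np
import pytest

from bandseg import (
    EtsdParams,
    ValidationError,
    bidirectional_denoise,
    build_narrowband,
    curvature,
    detect_outliers,
    etsd_backward,
    etsd_forward,
    fuse,
    lambda_schedule,
    nnvo,
)

from ._oracles import fixed_lambda_weights


def test_lambda_schedule_values():
    # min(lambda0, (1+k)/(10+k)): ramps up, capped at lambda0
    assert lambda_schedule(0.9, 1) == pytest.approx(2 / 11)
    assert lambda_schedule(0.9, 10) == pytest.approx(11 / 20)
    assert lambda_schedule(0.9, 1000) == pytest.approx(0.9)
    assert lambda_schedule(0.3, 10) == pytest.approx(0.3)
    with pytest.raises(ValidationError):
        lambda_schedule(0.9, 0)
    with pytest.raises(ValidationError):
        lambda_schedule(1.5, 3)


def test_fixed_lambda_matches_closed_form_small_case():
    # two-sample hand computation at λ = 0.5:
    #   m1 = 0.5*0 + 0.5*4 = 2, normalizer 1 - 0.5 = 0.5 -> 4
    #   m2 = 0.5*2 + 0.5*8 = 5, normalizer 1 - 0.25 = 0.75 -> 20/3
    out = etsd_forward([4.0, 8.0], EtsdParams(lambda0=0.5), dynamic=False)
    assert np.allclose(out, [4.0, 20.0 / 3.0], atol=1e-12)


def test_first_output_equals_first_input(rng):
    x = rng.normal(size=30)
    for dynamic in (False, True):
        out = etsd_forward(x, EtsdParams(lambda0=0.8), dynamic=dynamic)
        assert out[0] == pytest.approx(x[0], abs=1e-12)


def test_constant_sequence_is_preserved_exactly(rng):
    x = np.full(50, -3.25)
    for dynamic in (False, True):
        assert np.allclose(
            etsd_forward(x, EtsdParams(), dynamic=dynamic), x, atol=1e-12
        )


def test_outputs_are_convex_combinations_of_prefix(rng):
    for _ in range(20):
        x = rng.normal(scale=rng.uniform(0.5, 20), size=int(rng.integers(1, 60)))
        p = EtsdParams(lambda0=float(rng.uniform(0.05, 0.95)))
        for dynamic in (False, True):
            out = etsd_forward(x, p, dynamic=dynamic)
            for k in range(x.size):
                lo, hi = x[: k + 1].min(), x[: k + 1].max()
                assert lo - 1e-9 <= out[k] <= hi + 1e-9


def test_backward_is_reversed_forward(rng):
    x = rng.normal(size=40)
    p = EtsdParams()
    assert np.allclose(etsd_backward(x, p), etsd_forward(x[::-1], p)[::-1])


def test_fixed_lambda_matches_normalized_exponential_weights(rng):
    for lam in (0.3, 0.5, 0.9):
        x = rng.normal(scale=5.0, size=25)
        out = etsd_forward(x, EtsdParams(lambda0=lam), dynamic=False)
        for k in range(x.size):
            w = fixed_lambda_weights(lam, k)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert out[k] == pytest.approx(float(w @ x[: k + 1]), abs=1e-10)


def test_square_turning_angle_is_right_angle():
    square = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
    theta = curvature(square)
    assert np.allclose(np.abs(theta), np.pi / 2, atol=1e-12)


def test_curvature_rejects_coincident_triple():
    with pytest.raises(ValidationError):
        curvature(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 0.0]]))


def test_detect_outliers_flags_a_spike():
    t = 2 * np.pi * np.arange(60) / 60
    pts = np.column_stack([50 + 20 * np.sin(t), 50 + 20 * np.cos(t)])
    smooth_mask = detect_outliers(pts, EtsdParams())
    assert not smooth_mask.any()  # a fine polygon turns well below pi/4 per step
    spiked = pts.copy()
    spiked[30] += 12.0 * (spiked[30] - [50, 50]) / np.linalg.norm(spiked[30] - [50, 50])
    mask = detect_outliers(spiked, EtsdParams())
    assert mask[30]


def test_fuse_formulas_exact():
    raw = np.array([0.0, 10.0])
    smooth = np.array([10.0, 0.0])
    out = fuse(raw, smooth, np.array([False, True]), alpha=0.9)
    # normal: 0.9*raw + 0.1*smooth; anomalous: 0.1*raw + 0.9*smooth
    assert np.allclose(out, [1.0, 1.0])
    with pytest.raises(ValidationError):
        fuse(raw, smooth, np.array([True]), alpha=0.9)


def test_bidirectional_denoise_repairs_single_spike():
    # dark disk; run the full band machinery with one corrupted estimate
    rr, cc = np.mgrid[0:200, 0:200]
    img = np.where(np.hypot(rr - 100.0, cc - 100.0) <= 60.0, 20.0, 200.0)
    t = 2 * np.pi * np.arange(80) / 80
    prior = np.column_stack([100 + 58 * np.sin(t), 100 + 58 * np.cos(t)])
    nb = build_narrowband(img, prior, L=12)
    est = nnvo(nb, m_left=0, m_right=0)
    spiked = est.offsets.astype(float)
    true_val = spiked[40]
    spiked[40] = 12.0  # push one boundary point to the outer band edge
    from bandseg.operators import BoundaryEstimate

    den = bidirectional_denoise(BoundaryEstimate(offsets=spiked), nb, EtsdParams())
    # the spike is pulled most of the way back toward its true position
    assert abs(den.offsets[40] - true_val) < abs(spiked[40] - true_val) / 2
    # all outputs stay inside the band
    assert np.all(np.abs(den.offsets) <= nb.L)


def test_denoise_validation():
    from bandseg.operators import BoundaryEstimate

    with pytest.raises(ValidationError):
        etsd_forward([], EtsdParams())
    with pytest.raises(ValidationError):
        EtsdParams(lambda0=1.0)
    with pytest.raises(ValidationError):
        EtsdParams(alpha=0.0)
    with pytest.raises(ValidationError):
        EtsdParams(k_step=0)
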