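import numpy as np
import pytest

from bandseg import ValidationError, base_operator, cumulative_gray_difference, nnvo
from bandseg.narrowband import NarrowBand, build_narrowband

from ._oracles import base_operator_brute, make_random_band, nnvo_brute, score_brute


def test_base_operator_matches_bruteforce_on_random_bands(rng):
    for _ in range(25):
        nb = make_random_band(rng)
        got = base_operator(nb).offsets
        assert np.array_equal(got, base_operator_brute(nb, nb.L))


def test_nnvo_matches_bruteforce_on_random_bands(rng):
    for _ in range(25):
        nb = make_random_band(rng)
        m_left = int(rng.integers(0, min(4, nb.n_profiles - 1)))
        m_right = int(rng.integers(0, min(3, nb.n_profiles - m_left)))
        got = nnvo(nb, m_left=m_left, m_right=m_right).offsets
        assert np.array_equal(got, nnvo_brute(nb, nb.L, m_left, m_right))


def test_nnvo_with_zero_neighbours_equals_base(rng):
    for _ in range(5):
        nb = make_random_band(rng)
        assert np.array_equal(
            nnvo(nb, m_left=0, m_right=0).offsets, base_operator(nb).offsets
        )


def test_strict_cumulative_difference_hand_computed():
    # one relevant profile, L = 3, known samples
    pts = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])
    nb = NarrowBand(
        points=pts,
        normals=np.tile([0.0, 1.0], (4, 1)),
        IM=np.zeros((4, 6, 2)),
        GM=np.zeros((4, 6)),
        L=3,
    )
    nb.GM[0] = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
    # offset +1 -> column 3; w = 2: outer = cols 4,5 = 11+12, inner = cols 1,2 = 2+3
    assert cumulative_gray_difference(nb, 0, 1, 2) == pytest.approx(18.0)
    # offset -1 -> column 2; w = 2: outer = cols 3,4 = 10+11, inner = cols 0,1 = 1+2
    assert cumulative_gray_difference(nb, 0, -1, 2) == pytest.approx(18.0)
    # offset +2 -> column 4; w = 1: outer = col 5 = 12, inner = col 3 = 10
    assert cumulative_gray_difference(nb, 0, 2, 1) == pytest.approx(2.0)
    # strict form: window exceeding the band is an error, not a clipped value
    with pytest.raises(ValidationError):
        cumulative_gray_difference(nb, 0, 2, 2)
    with pytest.raises(ValidationError):
        cumulative_gray_difference(nb, 0, 1, 0)


def test_step_edge_located_exactly():
    # dark inside / bright outside with the step at the true boundary
    rr, cc = np.mgrid[0:200, 0:200]
    img = np.where(np.hypot(rr - 100.0, cc - 100.0) <= 60.0, 20.0, 200.0)
    t = 2 * np.pi * np.arange(50) / 50
    prior = np.column_stack([100 + 55 * np.sin(t), 100 + 55 * np.cos(t)])
    nb = build_narrowband(img, prior, L=10)
    offs = base_operator(nb).offsets
    # boundary is 5 px outside the prior everywhere
    assert np.all(np.abs(offs - 5) <= 1)


def test_constant_profile_scores_zero_and_prefers_innermost():
    pts = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [10.0, 0.0]])
    nb = NarrowBand(
        points=pts,
        normals=np.tile([0.0, 1.0], (4, 1)),
        IM=np.zeros((4, 8, 2)),
        GM=np.full((4, 8), 42.0),
        L=4,
    )
    est = base_operator(nb)
    # mean-normalized clipped windows score exactly zero on a constant profile
    assert np.allclose(est.scores, 0.0)
    # all-tie: break toward smallest |offset|, inside before outside
    assert np.array_equal(est.offsets, [-1, -1, -1, -1])


def test_scores_are_achieved_maxima(rng):
    nb = make_random_band(rng)
    est = base_operator(nb)
    for k in range(nb.n_profiles):
        best = max(
            score_brute(nb.GM[k], j, nb.L) for j in range(1, 2 * nb.L - 1)
        )
        assert est.scores[k] == pytest.approx(best)


def test_nnvo_validation(rng):
    nb = make_random_band(rng, n_max=5, l_max=3)
    with pytest.raises(ValidationError):
        nnvo(nb, m_left=-1)
    with pytest.raises(ValidationError):
        nnvo(nb, m_left=nb.n_profiles, m_right=0)
    with pytest.raises(ValidationError):
        base_operator(nb, half_window=0)
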