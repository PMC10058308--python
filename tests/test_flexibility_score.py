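"""Flexibility score Q: spatial terms, topology term, classes and Vg."""

import numpy as np
import pytest

from rpflex.flexibility_score import (
    classify_flexibility,
    flexibility_Q,
    overlapping_volume,
    score_group,
    spatial_terms,
    topology_term,
)
from rpflex.pocket_detect import PocketMetrics


def _metrics(V, A, psi=None):
    psi_val = (np.pi ** (1 / 3) * (6 * V) ** (2 / 3) / A
               if psi is None else psi)
    return PocketMetrics(Vp=V, Ap=A, psi=psi_val, reff=3 * V / A,
                         centroid=(0, 0, 0))


def test_spatial_terms_identical_pockets():
    sigma, S, Pbar = spatial_terms(np.ones((4, 4)))
    assert np.allclose(sigma, 0) and S == 0 and Pbar == 1


def test_spatial_terms_worked_example():
    """3×3 matrix with off-diagonal 0.5: each row is {1, 0.5, 0.5}."""
    sub = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1.0]])
    sigma, S, Pbar = spatial_terms(sub)
    expected_row_sd = np.std([1, 0.5, 0.5])  # population, ÷m
    assert sigma == pytest.approx([expected_row_sd] * 3)
    assert S == pytest.approx(0.23570226)
    assert Pbar == pytest.approx(2 / 3)


def test_spatial_terms_relabel_invariant():
    rng = np.random.default_rng(0)
    sub = rng.uniform(0.1, 1.0, size=(5, 5))
    np.fill_diagonal(sub, 1.0)
    perm = rng.permutation(5)
    _, S0, P0 = spatial_terms(sub)
    _, S1, P1 = spatial_terms(sub[np.ix_(perm, perm)])
    assert S1 == pytest.approx(S0) and P1 == pytest.approx(P0)


def test_spatial_terms_rejects_small_groups():
    with pytest.raises(ValueError, match="m = 2"):
        spatial_terms(np.ones((2, 2)))


def test_topology_term_identical_pockets():
    """All V_i = V̄ and A_i = Ā: Γ degenerates to the mean sphericity."""
    mets = [_metrics(1000.0, 600.0)] * 3
    assert topology_term(mets) == pytest.approx(mets[0].psi)


def test_topology_term_scalar_oracle():
    """Term-by-term evaluation with plain scalar arithmetic."""
    V = [1000.0, 1100.0, 900.0]
    A = [600.0, 650.0, 550.0]
    psis = [0.8, 0.8, 0.8]
    mets = [_metrics(v, a, psi=p) for v, a, p in zip(V, A, psis)]
    vbar, abar = sum(V) / 3, sum(A) / 3
    terms = []
    for v, a, p in zip(V, A, psis):
        if abs(a - abar) < 1e-9:  # degenerate area difference: |Ψ_i| alone
            terms.append(abs(p))
        else:
            terms.append(abs(
                p - np.pi ** (1 / 3) * (6 * abs(v - vbar)) ** (2 / 3)
                / (a - abar)))
    assert topology_term(mets) == pytest.approx(np.mean(terms))


def test_topology_term_dimensional_homogeneity():
    """Scaling V by 8 and A by 4 leaves every inner quotient unchanged."""
    V = [1000.0, 1150.0, 870.0]
    A = [600.0, 655.0, 540.0]
    psi = [0.75, 0.8, 0.7]
    m1 = [_metrics(v, a, p) for v, a, p in zip(V, A, psi)]
    m2 = [_metrics(8 * v, 4 * a, p) for v, a, p in zip(V, A, psi)]
    assert topology_term(m1) == pytest.approx(topology_term(m2))


def test_topology_term_literal_form():
    V = [1000.0, 1100.0, 900.0]
    A = [600.0, 650.0, 550.0]
    mets = [_metrics(v, a, psi=0.8) for v, a in zip(V, A)]
    vbar, abar = sum(V) / 3, sum(A) / 3
    terms = []
    for v, a in zip(V, A):
        if abs(a - abar) < 1e-9:
            terms.append(0.8)
        else:
            terms.append(abs(0.8 - abs(v - vbar) ** (2 / 3)
                             / (6 * (a - abar))))
    assert topology_term(mets, gamma_form="literal") == pytest.approx(
        np.mean(terms))


def test_flexibility_Q_forms():
    assert flexibility_Q(0.0, 0.5, 1.3) == 0.0  # identical pockets are rigid
    assert flexibility_Q(0.2, 0.5, 2.0) == pytest.approx(0.2)
    assert flexibility_Q(0.2, 0.5, 2.0, form="product") == pytest.approx(0.8)
    with pytest.raises(ValueError, match="Gamma"):
        flexibility_Q(0.2, 0.5, 0.0)
    with pytest.raises(ValueError, match="Pbar"):
        flexibility_Q(0.2, 0.0, 1.0)


@pytest.mark.parametrize(
    "Q,expected",
    [(0.0, "rigidity"), (0.09, "rigidity"), (0.299, "rigidity"),
     (0.30, "intermediate"), (0.59, "intermediate"),
     (0.60, "flexibility"), (0.84, "flexibility")],
)
def test_classify_flexibility(Q, expected):
    assert classify_flexibility(Q) == expected


def test_overlapping_volume_bins():
    assert overlapping_volume(1000, 0.8) == (800.0, "medium")
    assert overlapping_volume(400, 1.0) == (400.0, "small")
    assert overlapping_volume(500, 1.0)[1] == "small"  # boundary inclusive
    assert overlapping_volume(1500, 1.0)[1] == "medium"
    with pytest.warns(UserWarning, match="7200"):
        _, size = overlapping_volume(8000, 1.0)
    assert size == "large"


def test_score_group_zero_iff_identical():
    mets = [_metrics(500.0, 400.0)] * 3
    res = score_group(np.ones((3, 3)), mets)
    assert res.S == 0 and res.Q == 0 and res.flex_class == "rigidity"
    assert res.Vg == pytest.approx(res.Vbar * res.Pbar)

    sub = np.array([[1, 0.6, 0.7], [0.5, 1, 0.6], [0.7, 0.5, 1.0]])
    res2 = score_group(sub, [_metrics(500.0, 400.0),
                             _metrics(600.0, 440.0),
                             _metrics(450.0, 380.0)])
    assert res2.S > 0 and res2.Q > 0
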