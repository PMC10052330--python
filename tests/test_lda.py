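"""Scatter matrices, the generalized eigenproblem, and projection."""

import numpy as np
import pytest

from asvrf import fit_lda, project, scatter_matrices
from conftest import make_dataset


def _two_class(rng, n=500, dim=5, shift=None, cov=None):
    if shift is None:
        shift = np.zeros(dim)
    if cov is None:
        cov = np.eye(dim)
    a = rng.multivariate_normal(np.zeros(dim), cov, size=n // 2)
    b = rng.multivariate_normal(shift, cov, size=n - n // 2)
    x = np.vstack([a, b])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return make_dataset(x, y)


def test_scatter_hand_computed():
    """S_C and S_V match an explicit double loop over samples."""
    x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [4.0, 4.0], [5.0, 4.0], [4.0, 5.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    ds = make_dataset(x, y)
    s_c, s_v = scatter_matrices(ds)
    mu = x.mean(axis=0)
    sc_ref = np.zeros((2, 2))
    sv_ref = np.zeros((2, 2))
    for c in (0, 1):
        xk = x[y == c]
        mk = xk.mean(axis=0)
        sc_ref += len(xk) * np.outer(mk - mu, mk - mu)
        for row in xk:
            sv_ref += np.outer(row - mk, row - mk)
    np.testing.assert_allclose(s_c, sc_ref, atol=1e-12)
    np.testing.assert_allclose(s_v, sv_ref, atol=1e-12)
    # symmetric PSD
    for m in (s_c, s_v):
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(m) > -1e-9)


def test_scatter_degenerate_cases():
    # equal class means -> zero between-class scatter
    x = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    ds = make_dataset(x, [0, 0, 1, 1])
    s_c, _ = scatter_matrices(ds)
    np.testing.assert_allclose(s_c, 0, atol=1e-12)
    # one point per class -> zero within-class scatter
    ds2 = make_dataset([[1.0, 2.0], [3.0, 4.0]], [0, 1])
    _, s_v = scatter_matrices(ds2)
    np.testing.assert_allclose(s_v, 0, atol=1e-12)


def test_total_scatter_identity(rng):
    """S_C + S_V equals the total scatter matrix (algebraic identity)."""
    x = rng.standard_normal((60, 4))
    y = rng.integers(0, 3, 60)
    ds = make_dataset(x, y)
    s_c, s_v = scatter_matrices(ds)
    centered = x - x.mean(axis=0)
    np.testing.assert_allclose(s_c + s_v, centered.T @ centered, atol=1e-9)


def test_fisher_direction_recovery(rng):
    """Leading basis vector aligns with the closed form Sigma^-1 (mu1 - mu0)."""
    dim = 5
    cov = 0.5 * np.eye(dim) + 0.3
    shift = np.array([1.0, 0.5, -0.5, 0.25, 0.0])
    ds = _two_class(rng, n=500, dim=dim, shift=shift, cov=cov)
    model = fit_lda(ds, L=1)
    fisher = np.linalg.solve(cov, shift)
    fisher /= np.linalg.norm(fisher)
    cosine = abs(model.W[:, 0] @ fisher)
    assert cosine >= 0.99
    assert model.eigenvalues[0] > 0


def test_positive_eigenvalue_count_bounded(rng):
    """At most a-1 strictly positive discriminant eigenvalues."""
    x = rng.standard_normal((90, 6))
    y = rng.integers(0, 3, 90)
    model = fit_lda(make_dataset(x, y), L=2)
    # ask for the full spectrum via scatter matrices directly
    import scipy.linalg

    from asvrf.lda import scatter_matrices as sm
    s_c, s_v = sm(make_dataset(x, y))
    vals = scipy.linalg.eigh(s_c, s_v + 1e-9 * np.eye(6), eigvals_only=True)
    assert np.sum(vals > 1e-6) <= 2


def test_basis_columns_unit_and_sign_fixed(rng):
    ds = _two_class(rng, n=200, dim=4, shift=np.array([2.0, 0, 0, 0]))
    model = fit_lda(ds)
    norms = np.linalg.norm(model.W, axis=0)
    np.testing.assert_allclose(norms, 1.0, atol=1e-12)
    for k in range(model.L):
        lead = np.argmax(np.abs(model.W[:, k]))
        assert model.W[lead, k] > 0


def test_l_out_of_range(rng):
    ds = _two_class(rng, n=40, dim=3, shift=np.array([1.0, 0, 0]))
    with pytest.raises(ValueError, match="L must lie"):
        fit_lda(ds, L=2)  # a=2 caps L at 1


def test_project_identity_and_hand_product(rng):
    ds = _two_class(rng, n=20, dim=2, shift=np.array([3.0, 0.0]))
    model = fit_lda(ds, L=1)
    # hand multiply three rows
    z = project(model, ds)
    np.testing.assert_allclose(z.features[:3, 0], ds.features[:3] @ model.W[:, 0], atol=1e-12)
    np.testing.assert_array_equal(z.labels, ds.labels)
    assert z.n_features == 1


def test_project_linearity_of_reflection(rng):
    ds = _two_class(rng, n=30, dim=3, shift=np.array([2.0, 0, 0]))
    model = fit_lda(ds)
    x = ds.features[0]
    mu = np.zeros(3)
    refl = 2 * mu - x
    assert np.allclose(model.W.T @ refl, -(model.W.T @ x))


def test_project_dimension_mismatch(rng):
    ds = _two_class(rng, n=20, dim=3, shift=np.array([1.0, 0, 0]))
    model = fit_lda(ds)
    with pytest.raises(ValueError, match="mismatch"):
        project(model, make_dataset(np.ones((2, 5)), [0, 1]))


def test_missing_values_rejected(rng):
    x = rng.standard_normal((10, 2))
    miss = np.zeros_like(x, dtype=bool)
    miss[0, 0] = True
    ds = make_dataset(x, [0, 1] * 5, missing=miss)
    with pytest.raises(ValueError, match="missing"):
        scatter_matrices(ds)
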