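from fractions import Fraction

import numpy as np
import pytest

import germeval as ge
from germeval.errors import DegenerateDataError, ValidationError
from germeval.pca_fmf import PcaModel

from _oracle import composite_oracle
from conftest import make_table


def _model(eigenvalues):
    lam = np.asarray(eigenvalues, float)
    p = lam.size
    return PcaModel(
        trait_means=np.zeros(p), trait_sds=np.ones(p),
        eigenvalues=lam, loadings=np.eye(p), scores=np.zeros((3, p)),
        contribution_rates=lam / p, retained_mask=lam > 1.0,
    )


# -- standardize --------------------------------------------------------


def test_standardize_simple_column():
    z, means, sds = ge.standardize(np.array([[1.0], [2.0], [3.0]]))
    assert np.allclose(z[:, 0], [-1.0, 0.0, 1.0])
    assert means[0] == 2.0 and sds[0] == 1.0


def test_standardize_contract_and_idempotence():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 50, size=(40, 6))
    z, _, _ = ge.standardize(X)
    assert np.abs(z.mean(axis=0)).max() < 1e-12
    assert np.abs(z.std(axis=0, ddof=1) - 1.0).max() < 1e-12
    z2, _, _ = ge.standardize(z)
    assert np.allclose(z, z2, atol=1e-12)


def test_standardize_constant_column_named():
    X = np.ones((10, 2))
    X[:, 0] = np.arange(10.0)
    with pytest.raises(DegenerateDataError, match="oil"):
        ge.standardize(X, ["protein", "oil"])


# -- fit_pca ------------------------------------------------------------


def test_uncorrelated_pair_gives_unit_eigenvalues():
    # exactly orthogonal columns after standardization
    x = np.array([-1.0, 0.0, 1.0])
    y = np.array([1.0, -2.0, 1.0])
    z, _, _ = ge.standardize(np.column_stack([x, y]))
    model = ge.fit_pca(z)
    assert np.allclose(model.eigenvalues, [1.0, 1.0], atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_two_trait_eigenvalues_closed_form(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(30, 2))
    z, _, _ = ge.standardize(X)
    r = float(np.corrcoef(X, rowvar=False)[0, 1])
    model = ge.fit_pca(z)
    assert model.eigenvalues == pytest.approx([1 + abs(r), 1 - abs(r)], abs=1e-12)


def test_trace_and_orthonormality(panel259):
    table, _ = panel259
    z, _, _ = ge.standardize(table.values)
    model = ge.fit_pca(z)
    assert model.eigenvalues.sum() == pytest.approx(34.0, abs=1e-8)
    assert np.allclose(model.loadings.T @ model.loadings, np.eye(34), atol=1e-8)
    assert np.abs(model.scores.mean(axis=0)).max() < 1e-10
    assert model.contribution_rates.sum() == pytest.approx(1.0, abs=1e-12)


def test_fit_pca_matches_oracle_small():
    rng = np.random.default_rng(11)
    X = rng.uniform(0, 10, size=(50, 10))
    z, _, _ = ge.standardize(X)
    model = ge.fit_pca(z)
    F_oracle, lam_oracle, *_ = composite_oracle(X, threshold=0.0)
    assert np.allclose(model.eigenvalues, lam_oracle, atol=1e-8)


def test_handles_more_traits_than_accessions():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(5, 12))  # p > n
    z, _, _ = ge.standardize(X)
    model = ge.fit_pca(z)
    assert model.eigenvalues.shape == (12,)
    assert model.eigenvalues.min() >= -1e-12
    assert model.eigenvalues.sum() == pytest.approx(12.0, abs=1e-8)


# -- component selection / weights -------------------------------------


def test_kaiser_selection():
    assert ge.select_components(_model([2.5, 1.2, 0.9, 0.4])) == [0, 1]
    # exactly 1.0 is excluded: strict inequality
    assert ge.select_components(_model([2.5, 1.0, 0.4])) == [0]


def test_kaiser_no_component_errors():
    with pytest.raises(DegenerateDataError, match="threshold"):
        ge.select_components(_model([1.0]))


def test_weights_examples():
    assert np.allclose(ge.compute_weights(_model([3.0, 1.0]), [0, 1]), [0.75, 0.25])
    assert np.allclose(ge.compute_weights(_model([5.0]), [0]), [1.0])
    W = ge.compute_weights(_model([2.2, 1.6, 1.1]), [0, 1, 2])
    expected = [Fraction(22, 49), Fraction(16, 49), Fraction(11, 49)]
    assert np.allclose(W, [float(f) for f in expected], atol=1e-12)
    assert W.sum() == pytest.approx(1.0, abs=1e-12)


# -- membership / composite --------------------------------------------


def test_membership_examples():
    U = ge.membership_normalize(np.array([1.0, 3.0, 5.0]))
    assert np.allclose(U[:, 0], [0.0, 0.5, 1.0])
    U = ge.membership_normalize(np.array([-2.0, 0.0, 2.0]))
    assert np.allclose(U[:, 0], [0.0, 0.5, 1.0])


def test_membership_exact_endpoints():
    rng = np.random.default_rng(3)
    U = ge.membership_normalize(rng.normal(size=(100, 4)))
    assert np.array_equal(U.min(axis=0), np.zeros(4))
    assert np.array_equal(U.max(axis=0), np.ones(4))
    assert U.min() >= 0.0 and U.max() <= 1.0


def test_membership_degenerate_column():
    scores = np.column_stack([np.arange(4.0), np.full(4, 2.0)])
    with pytest.raises(DegenerateDataError):
        ge.membership_normalize(scores)
    U = ge.membership_normalize(scores, degenerate_value=0.5)
    assert np.all(U[:, 1] == 0.5)


def test_composite_examples():
    W = np.array([0.6, 0.4])
    assert ge.composite_score(np.array([[1.0, 1.0]]), W)[0] == 1.0
    assert ge.composite_score(np.array([[0.0, 0.0]]), W)[0] == 0.0
    F = ge.composite_score(np.array([[0.5, 0.25]]), np.array([0.75, 0.25]))
    assert F[0] == pytest.approx(0.4375, abs=1e-15)  # 0.375 + 0.0625
    with pytest.raises(ValidationError):
        ge.composite_score(np.array([[0.5, 0.25]]), np.array([1.0]))


# -- ranking ------------------------------------------------------------


def test_elite_counts():
    ids259 = [f"A{i:04d}" for i in range(259)]
    F = np.linspace(0, 1, 259)
    _, elite = ge.rank_and_select(F, ids259, proportion=0.05)
    assert elite.sum() == 13
    _, elite = ge.rank_and_select(F[:100], ids259[:100], proportion=0.05)
    assert elite.sum() == 5
    _, elite = ge.rank_and_select(F[:10], ids259[:10], proportion=0.05)
    assert elite.sum() == 1  # ceil(0.5)


def test_rank_ties_break_by_id():
    F = np.array([0.5, 0.9, 0.5])
    ranks, elite = ge.rank_and_select(F, ["b", "c", "a"], proportion=0.4)
    assert list(ranks) == [3, 1, 2]  # tie between 'a' and 'b' -> 'a' first
    assert list(elite) == [False, True, True]
    assert sorted(ranks) == [1, 2, 3]


def test_rank_validates_proportion():
    with pytest.raises(ValidationError):
        ge.rank_and_select(np.array([0.1]), ["a"], proportion=0.0)
    with pytest.raises(ValidationError):
        ge.rank_and_select(np.array([]), [], proportion=0.05)


# -- full evaluation ----------------------------------------------------


def test_evaluate_invariants_and_determinism(panel259):
    table, _ = panel259
    model, fmf = ge.evaluate(table)
    assert fmf.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert fmf.memberships.min() >= 0.0 and fmf.memberships.max() <= 1.0
    assert fmf.f_values.min() >= 0.0 and fmf.f_values.max() <= 1.0
    assert sorted(fmf.ranks) == list(range(1, 260))
    assert fmf.elite.sum() == 13
    _, fmf2 = ge.evaluate(table)
    assert np.array_equal(fmf.f_values, fmf2.f_values)


def test_evaluate_affine_invariance(panel259):
    table, _ = panel259
    _, fmf = ge.evaluate(table)
    rng = np.random.default_rng(4)
    scale = rng.uniform(0.3, 0.9, size=34)
    shift = rng.uniform(0.0, 3.0, size=34)
    rescaled = make_table(n=table.n_accessions, values=table.values * scale + shift)
    rescaled.origin[:] = table.origin
    rescaled.period[:] = table.period
    _, fmf2 = ge.evaluate(rescaled)
    assert np.allclose(fmf.f_values, fmf2.f_values, atol=1e-10)


def test_sign_convention_orients_pc1_with_protein(panel259):
    """The first component of the reference panel points toward high
    protein / amino acids and away from oil."""
    table, _ = panel259
    model, _ = ge.evaluate(table)
    reg = table.registry
    assert model.loadings[reg.index("protein"), 0] > 0
    for code in reg.family_codes("amino_acid"):
        assert model.loadings[reg.index(code), 0] > 0
    assert model.loadings[reg.index("oil"), 0] < 0


def test_sign_flip_reflects_membership():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=(30, 2))
    U = ge.membership_normalize(scores)
    U_flipped = ge.membership_normalize(-scores)
    assert np.allclose(U_flipped, 1.0 - U, atol=1e-12)


def test_dominant_accession_ranks_first():
    """With a single positive factor driving all traits, the accession
    that dominates every trait attains the maximum composite score."""
    rng = np.random.default_rng(6)
    n, p = 40, 34
    factor = rng.normal(size=n)
    values = 50.0 + 8.0 * factor[:, None] + rng.normal(0, 1.2, size=(n, p))
    best = np.argmax(values.sum(axis=1))
    values[best] = values.max(axis=0) + 1.0
    table = make_table(n=n, values=np.clip(values, 0, 100))
    _, fmf = ge.evaluate(table)
    assert fmf.ranks[best] == 1
    assert fmf.f_values[best] == fmf.f_values.max()
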