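"""Potts inference by pseudolikelihood, statistical energies, contact scores."""

import numpy as np
import pytest
from scipy.optimize import check_grad

from dcscan import (
    PottsModel,
    coupling_scores,
    dca_mutant_cycles,
    encode,
    fit_plm,
    make_planted_potts,
    pair_coupling_tensor,
    sample_potts_msa,
    scramble_noncontact,
    single_mutant_energies,
    statistical_energy,
    zero_sum_gauge,
)
from dcscan.dca import _plm_objective


def random_model(L=5, q=4, seed=0, scale=0.7):
    rng = np.random.default_rng(seed)
    h = rng.normal(0, scale, (L, q))
    A = rng.normal(0, scale, (L, L, q, q))
    J = 0.5 * (A + A.transpose(1, 0, 3, 2))
    J[np.arange(L), np.arange(L)] = 0.0
    return PottsModel(h, J, alphabet="ACDE"[:q])


def test_energy_zero_model():
    m = PottsModel.zeros(6, 21)
    assert statistical_energy(m, np.zeros(6, dtype=int)) == 0.0


def test_energy_fields_only_additive():
    rng = np.random.default_rng(1)
    h = rng.normal(0, 1, (5, 21))
    m = PottsModel(h, np.zeros((5, 5, 21, 21)))
    seq = rng.integers(0, 21, 5)
    assert np.isclose(statistical_energy(m, seq), h[np.arange(5), seq].sum())


def test_energy_single_coupling_term():
    m = PottsModel.zeros(4, 21)
    m.J[1, 3, 2, 5] = 0.9
    m.J[3, 1, 5, 2] = 0.9
    seq = np.array([0, 2, 0, 5])
    seq_off = np.array([0, 4, 0, 5])  # mutate a away at position 1
    assert np.isclose(
        statistical_energy(m, seq) - statistical_energy(m, seq_off), 0.9
    )


def test_zero_sum_gauge_preserves_energy_differences():
    m = random_model(seed=2)
    z = zero_sum_gauge(m)
    rng = np.random.default_rng(3)
    for _ in range(20):
        s1 = rng.integers(0, m.n_states, m.n_positions)
        s2 = rng.integers(0, m.n_states, m.n_positions)
        d_before = statistical_energy(m, s1) - statistical_energy(m, s2)
        d_after = statistical_energy(z, s1) - statistical_energy(z, s2)
        assert abs(d_before - d_after) < 1e-10
    # zero-sum property
    assert np.allclose(z.J.sum(axis=2), 0.0, atol=1e-12)
    assert np.allclose(z.J.sum(axis=3), 0.0, atol=1e-12)


def test_plm_objective_gradient_is_exact():
    rng = np.random.default_rng(4)
    L, q, n = 3, 3, 20
    msa = rng.integers(0, q, (n, L))
    Xoh = np.zeros((n, L * q))
    Xoh[np.repeat(np.arange(n), L), (msa + np.arange(L)[None, :] * q).ravel()] = 1.0
    diag_mask = np.kron(1.0 - np.eye(L), np.ones((q, q)))
    w = np.ones(n)
    args = (Xoh, w, L, q, 0.01, 0.02, diag_mask)
    theta0 = rng.normal(0, 0.1, L * q + (L * q) ** 2)
    err = check_grad(
        lambda t: _plm_objective(t, *args)[0],
        lambda t: _plm_objective(t, *args)[1],
        theta0,
    )
    assert err < 1e-5


def test_plm_reaches_small_gradient_on_small_instance():
    model, _ = make_planted_potts(n_positions=5, n_edges=2, n_states=6, seed=5)
    msa = sample_potts_msa(model, 300, seed=5, burn_in=200, thin=3)
    _, info = fit_plm(msa, n_states=6, maxiter=2000, tol=1e-7)
    assert info["grad_norm"] < 1e-4


def test_large_regularization_shrinks_couplings():
    model, _ = make_planted_potts(n_positions=6, n_edges=3, n_states=6, seed=6)
    msa = sample_potts_msa(model, 300, seed=6, burn_in=200, thin=3)
    fit, _ = fit_plm(msa, n_states=6, lam_j=1e5, maxiter=500)
    assert np.abs(fit.J).max() < 1e-3


def test_independent_sites_infer_weak_couplings():
    """Paired simulation: APC coupling scores inferred from an independent-site
    alignment are below 10% of the planted-edge scores from a coupled one."""
    q = 6
    rng = np.random.default_rng(7)
    h = rng.normal(0, 0.5, (8, q))
    indep = PottsModel(h, np.zeros((8, 8, q, q)), alphabet="ACDEFG")
    msa0 = sample_potts_msa(indep, 2000, seed=7, burn_in=200, thin=3)
    fit0, _ = fit_plm(msa0, n_states=q, maxiter=600)

    coupled, edges = make_planted_potts(n_positions=8, n_edges=3, n_states=q, coupling=2.0, seed=7)
    msa1 = sample_potts_msa(coupled, 2000, seed=8, burn_in=200, thin=3)
    fit1, _ = fit_plm(msa1, n_states=q, maxiter=600)

    s0, _ = coupling_scores(fit0, min_separation=1, residues_only=False)
    s1, _ = coupling_scores(fit1, min_separation=1, residues_only=False)
    iu, ju = np.triu_indices(8, 1)
    noise = np.abs(s0[iu, ju]).mean()
    signal = np.mean([s1[i - 1, j - 1] for i, j in edges])
    assert noise < 0.1 * signal


def test_two_site_interactions_exact_as_lambda_vanishes():
    """For L = 2 with population-weighted data, the fitted model's pairwise
    interaction (double-centred log joint) matches the empirical one up to a
    regularization bias that shrinks as lambda -> 0.  (The joint itself is
    recovered only up to per-site factors: the field/coupling split of a
    symmetrized pseudolikelihood fit is gauge-dependent.)"""
    rng = np.random.default_rng(8)
    q = 3
    probs = rng.dirichlet(np.ones(q * q))
    msa = np.array([[a, b] for a in range(q) for b in range(q)])
    w = probs * 1000.0
    emp = probs.reshape(q, q)

    def interaction(logp):
        return logp - logp.mean(0, keepdims=True) - logp.mean(1, keepdims=True) + logp.mean()

    errs = []
    for lam in (0.1, 0.001):
        fit, _ = fit_plm(msa, weights=w, n_states=q, lam_h=lam, lam_j=lam,
                         maxiter=20000, tol=1e-12)
        e = np.array(
            [
                [statistical_energy(fit, np.array([a, b])) for b in range(q)]
                for a in range(q)
            ]
        )
        p = np.exp(-e)
        p /= p.sum()
        errs.append(np.abs(interaction(np.log(p)) - interaction(np.log(emp))).max())
    assert errs[1] < 0.05 * errs[0]
    assert errs[1] < 1e-3


def test_planted_edges_top_ranked_single_seed():
    model, edges = make_planted_potts(seed=0)
    msa = sample_potts_msa(model, 2000, seed=0)
    fit, _ = fit_plm(msa, maxiter=150)
    _, ranked = coupling_scores(fit)
    assert set(ranked[:10]) == {tuple(e) for e in edges}


def test_pair_coupling_tensor_matches_energy_differences():
    m = random_model(L=5, q=6, seed=9)
    wt = np.array([0, 1, 2, 3, 4])
    dde = pair_coupling_tensor(m, wt)
    de = single_mutant_energies(m, wt)
    e_wt = statistical_energy(m, wt)
    rng = np.random.default_rng(10)
    for _ in range(40):
        i, j = sorted(rng.choice(5, 2, replace=False))
        x, y = rng.integers(0, 6, 2)
        dbl = wt.copy()
        dbl[i], dbl[j] = x, y
        de_ij = statistical_energy(m, dbl) - e_wt
        expected = (de[i, x] + de[j, y]) - de_ij
        assert np.isclose(dde[i, j, x, y], expected, atol=1e-10)


def test_fields_only_model_has_zero_couplings():
    rng = np.random.default_rng(11)
    m = PottsModel(rng.normal(0, 1, (6, 21)), np.zeros((6, 6, 21, 21)))
    dde = dca_mutant_cycles(m, {"H1": np.zeros(6, dtype=int)})
    assert np.allclose(dde["ddg"], 0.0)


def test_single_j_block_couples_only_its_pair():
    m = PottsModel.zeros(6, 21)
    rng = np.random.default_rng(12)
    blk = rng.normal(0, 1, (21, 21))
    m.J[1, 4] = blk
    m.J[4, 1] = blk.T
    dde = dca_mutant_cycles(m, {"H1": np.zeros(6, dtype=int)})
    by_pair = dde.groupby(["pos_i", "pos_j"])["ddg"].apply(lambda v: np.abs(v).max())
    for (i, j), v in by_pair.items():
        if (i, j) == (2, 5):
            assert v > 0.1
        else:
            assert v < 1e-12


def test_dde_symmetric_in_mutation_order():
    m = random_model(L=4, q=5, seed=13)
    wt = np.array([0, 1, 2, 3])
    dde = pair_coupling_tensor(m, wt)
    # ddE[i,j,x,y] must equal ddE[j,i,y,x]
    assert np.allclose(dde, dde.transpose(1, 0, 3, 2), atol=1e-12)


def test_apc_of_rank_one_scores_is_zero():
    from dcscan.dca import apc_correct

    rng = np.random.default_rng(14)
    v = rng.random(8) + 0.5
    corrected = apc_correct(np.outer(v, v))
    assert np.abs(corrected).max() < 1e-12


def test_scramble_preserves_retained_and_block_multiset():
    model, edges = make_planted_potts(seed=1)
    msa = sample_potts_msa(model, 800, seed=1)
    fit, _ = fit_plm(msa, maxiter=80)
    edited, retained = scramble_noncontact(fit, edges, seed=3)
    assert retained  # some top pairs are contacts
    for i, j in retained:
        assert np.array_equal(edited.J[i - 1, j - 1], fit.J[i - 1, j - 1])
    iu, ju = np.triu_indices(fit.n_positions, 1)
    def block_norms(m):
        return sorted(
            round(float(np.sqrt((m.J[i, j] ** 2).sum())), 10)
            for i, j in zip(iu, ju) if (i + 1, j + 1) not in set(retained)
        )
    assert block_norms(fit) == block_norms(edited)
    # symmetry maintained
    assert np.allclose(edited.J, edited.J.transpose(1, 0, 3, 2))


def test_scramble_with_everything_retained_is_identity():
    m = random_model(L=4, q=4, seed=15)
    z = zero_sum_gauge(m)
    all_pairs = [(i, j) for i in range(1, 5) for j in range(i + 1, 5)]
    edited, retained = scramble_noncontact(z, all_pairs, n_top=6, min_separation=1, seed=0)
    assert len(retained) == 6
    assert np.allclose(edited.J, z.J)
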