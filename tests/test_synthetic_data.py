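"""Generators: combinatorics, truth landscapes, read counts, Potts sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcscan import (
    EquilibriumParams,
    LandscapeConfig,
    LibraryDesign,
    enumerate_library,
    make_planted_potts,
    make_standards,
    make_truth_landscape,
    mutant_cycle_couplings,
    sample_potts_msa,
    simulate_selection_counts,
)
from dcscan.synthetic_data import expected_selection_frequencies
from conftest import energies_from_truth


def brute_force_counts(design):
    """Oracle: enumerate every variant explicitly."""
    p, s, h = design.n_positions, design.n_substitutions, design.n_homologs
    singles = [(i, a) for i in range(p) for a in range(s)]
    doubles = [
        ((i, a), (j, b))
        for i, j in itertools.combinations(range(p), 2)
        for a in range(s)
        for b in range(s)
    ]
    return len(singles), len(doubles), h * (len(singles) + len(doubles) + 1)


@pytest.mark.parametrize(
    "design, singles, doubles, cycles, total",
    [
        (LibraryDesign(9, 19, 5), 171, 12996, 361, 65840),
        (LibraryDesign(1, 19, 1), 19, 0, 361, 20),
        (LibraryDesign(3, 2, 2), 6, 12, 4, 38),
    ],
)
def test_enumerate_library_examples(design, singles, doubles, cycles, total):
    counts = enumerate_library(design)
    assert counts.singles_per_homolog == singles
    assert counts.doubles_per_homolog == doubles
    assert counts.total_variants == total
    if doubles:
        assert counts.cycles_per_pair == cycles


@given(
    p=st.integers(1, 5), s=st.integers(1, 4), h=st.integers(1, 3)
)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_enumerate_matches_brute_force(p, s, h):
    design = LibraryDesign(p, s, h)
    counts = enumerate_library(design)
    singles, doubles, total = brute_force_counts(design)
    assert counts.singles_per_homolog == singles
    assert counts.doubles_per_homolog == doubles
    assert counts.total_variants == total
    assert counts.possible_cycles == h * doubles


def test_enumerate_rejects_invalid_design():
    with pytest.raises(ValueError):
        LibraryDesign(0, 19, 5)
    with pytest.raises(ValueError):
        LibraryDesign(9, -1, 5)


# ---------------------------------------------------------------------------
# truth landscape


def test_zero_perturbation_scales_give_flat_landscape(small_design):
    cfg = LandscapeConfig(
        sd_ln_kx=0.0, sd_ln_alpha=0.0, sd_ln_kc_small=0.0,
        sd_ln_kc_large=0.0, kc_large_mean=0.0, homolog_kc_jitter=0.0,
    )
    land = make_truth_landscape(small_design, kc_sensitive_positions=(1,), config=cfg, seed=0)
    assert np.allclose(land.table["dg_true"], 0.0)


def test_no_kc_sensitivity_means_no_mean_coupling():
    """With K_c untouched, log-perturbations are additive: couplings ~ 0."""
    land = make_truth_landscape(
        LibraryDesign(6, 10, 2), kc_sensitive_positions=(), seed=3
    )
    cp = mutant_cycle_couplings(energies_from_truth(land.table))
    for (_, _), grp in cp.groupby(["pos_i", "pos_j"]):
        v = grp["ddg"].to_numpy()
        sem = v.std() / np.sqrt(len(v))
        assert abs(v.mean()) < 3 * max(sem, 1e-12)


def test_only_kc_sensitive_pairs_couple(paper_landscape):
    cp = mutant_cycle_couplings(energies_from_truth(paper_landscape.table))
    sens = set(paper_landscape.kc_sensitive_positions)
    means = cp.groupby(["pos_i", "pos_j"])["ddg"].mean()
    for (i, j), m in means.items():
        if i in sens and j in sens:
            assert abs(m) > 0.2, f"sensitive pair {(i, j)} should couple"
        else:
            assert abs(m) < 0.1, f"pair {(i, j)} should not couple"


def test_landscape_deterministic(small_design):
    a = make_truth_landscape(small_design, kc_sensitive_positions=(1, 4), seed=5)
    b = make_truth_landscape(small_design, kc_sensitive_positions=(1, 4), seed=5)
    pd.testing.assert_frame_equal(a.table, b.table)


# ---------------------------------------------------------------------------
# selection counts


def test_selection_a_zero_no_enrichment(small_landscape):
    p_u, p_s = expected_selection_frequencies(small_landscape.table, a=0.0, c=-1.0, l_free=1e-6)
    assert np.allclose(p_u, p_s)


def test_selection_single_variant_gets_all_reads(small_landscape):
    one = small_landscape.table.iloc[[0]]
    cnt = simulate_selection_counts(one, a=2.0, c=-5.0, l_free=1e-6,
                                    depth_unselected=1000, depth_selected=2000, seed=0)
    assert cnt["count_unselected"].iloc[0] == 1000
    assert cnt["count_selected"].iloc[0] == 2000


def test_selection_counts_match_analytic_frequencies():
    """At high depth the count vector converges on the analytic frequencies."""
    rng = np.random.default_rng(0)
    truth = pd.DataFrame(
        {
            "homolog": "H1",
            "pos1": np.arange(1, 101), "aa1": "A", "pos2": 0, "aa2": "",
            "kd_true": np.exp(rng.uniform(np.log(1e-8), np.log(1e-4), 100)),
        }
    )
    depth = 100_000_000
    cnt = simulate_selection_counts(truth, a=2.0, c=-5.0, l_free=1e-6,
                                    depth_unselected=depth, depth_selected=depth, seed=1)
    _, p_s = expected_selection_frequencies(truth, a=2.0, c=-5.0, l_free=1e-6)
    obs = cnt["count_selected"].to_numpy() / depth
    # abundant variants: within 1% relative error; rare ones: within 4 binomial SE
    common = p_s >= 1e-3
    assert np.all(np.abs(obs[common] - p_s[common]) / p_s[common] < 0.01)
    se = np.sqrt(p_s * (1 - p_s) / depth)
    assert np.all(np.abs(obs - p_s) < 4 * se + 1e-12)


def test_selection_roundtrip_enrichment_within_binomial_error():
    """Measured dE agrees with the analytic dE to within counting noise."""
    from dcscan.calibration import relative_enrichment

    rng = np.random.default_rng(4)
    kd = np.exp(rng.uniform(np.log(1e-8), np.log(1e-4), 100))
    truth = pd.DataFrame(
        {"homolog": "H1", "pos1": np.arange(1, 101), "aa1": "A", "pos2": 0,
         "aa2": "", "kd_true": kd}
    )
    depth = 10_000_000
    cnt = simulate_selection_counts(truth, a=2.0, c=-5.0, l_free=1e-6,
                                    depth_unselected=depth, depth_selected=depth, seed=5)
    enr = relative_enrichment(cnt)
    p_u, p_s = expected_selection_frequencies(truth, a=2.0, c=-5.0, l_free=1e-6)
    de_true = np.log((p_s / p_u) / (p_s / p_u).sum())
    # dE error dominated by selected-count Poisson noise (plus the unselected)
    se = np.sqrt(1.0 / np.maximum(cnt["count_selected"], 1)
                 + 1.0 / np.maximum(cnt["count_unselected"], 1))
    frac_ok = np.mean(np.abs(enr["delta_e"] - de_true) < 3 * se)
    assert frac_ok >= 0.99


def test_counts_deterministic(small_landscape):
    kw = dict(a=2.0, c=-5.0, l_free=1e-6, depth_unselected=10000, depth_selected=10000, seed=9)
    a = simulate_selection_counts(small_landscape.table, **kw)
    b = simulate_selection_counts(small_landscape.table, **kw)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# standards


def test_standards_noiseless_lie_on_curve():
    std = make_standards(20, noise_sd=0.0, seed=0, a=1.7, c=-4.0, l_free=1e-6)
    expected = 1.7 * np.log(1e-6 / (1e-6 + std["kd_molar"])) - 4.0
    assert np.allclose(std["delta_e"], expected)


def test_standards_degenerate_range_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        make_standards(10, kd_range=(1e-3, 1e-2), l_free=1e-6)
    with pytest.raises(ValueError):
        make_standards(3)


# ---------------------------------------------------------------------------
# Potts sampling


def test_potts_fields_only_matches_softmax():
    """With J = 0, column frequencies follow the single-site Boltzmann law."""
    rng = np.random.default_rng(0)
    L, q, n = 6, 21, 4000
    h = rng.normal(0, 1.0, (L, q))
    from dcscan import PottsModel

    model = PottsModel(h, np.zeros((L, L, q, q)))
    msa = sample_potts_msa(model, n, seed=1, burn_in=200, thin=2)
    expected = np.exp(-h) / np.exp(-h).sum(axis=1, keepdims=True)
    for i in range(L):
        obs = np.bincount(msa[:, i], minlength=q) / n
        se = np.sqrt(expected[i] * (1 - expected[i]) / n)
        # thinning leaves no dependence for independent sites; allow 4 SE slack
        assert np.all(np.abs(obs - expected[i]) < 4 * np.maximum(se, 1e-3))


def test_potts_strong_field_fixes_column():
    from dcscan import PottsModel

    L, q = 4, 21
    h = np.zeros((L, q))
    h[2, :] = 10.0
    h[2, 7] = -10.0
    model = PottsModel(h, np.zeros((L, L, q, q)))
    msa = sample_potts_msa(model, 200, seed=2, burn_in=100, thin=2)
    assert np.all(msa[:, 2] == 7)


def test_potts_planted_pair_has_top_mutual_information():
    model, edges = make_planted_potts(n_positions=8, n_edges=1, coupling=2.0, seed=3)
    msa = sample_potts_msa(model, 2000, seed=3)
    (pi, pj) = edges[0]

    def mi(x, y):
        joint = np.histogram2d(x, y, bins=(21, 21), range=((0, 21), (0, 21)))[0] / len(x)
        px, py = joint.sum(1), joint.sum(0)
        nz = joint > 0
        return (joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])).sum()

    planted_mi = mi(msa[:, pi - 1], msa[:, pj - 1])
    null = [
        mi(msa[:, i], msa[:, j])
        for i in range(8) for j in range(i + 1, 8)
        if (i + 1, j + 1) != (pi, pj)
    ]
    assert planted_mi > max(null)


def test_potts_sampler_deterministic():
    model, _ = make_planted_potts(n_positions=6, n_edges=2, seed=0)
    a = sample_potts_msa(model, 50, seed=4, burn_in=50, thin=2)
    b = sample_potts_msa(model, 50, seed=4, burn_in=50, thin=2)
    assert np.array_equal(a, b)


def test_potts_rejects_nonfinite():
    from dcscan import PottsModel

    with pytest.raises(ValueError):
        PottsModel(np.full((3, 21), np.nan), np.zeros((3, 3, 21, 21)))
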