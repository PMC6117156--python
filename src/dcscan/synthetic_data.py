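"""Generators for every input of the deep-coupling-scan pipeline.

The study design this module emulates: a short mutated segment (default nine
positions, the PDZ alpha2-helix frame) scanned with all 19 substitutions at
each position, singly and in all pairwise combinations, across several
homologs.  Ground-truth binding free energies come from the coupled
conformational-equilibrium model (:mod:`dcscan.equilibrium_model`): every
mutation perturbs K_x and alpha log-normally, and mutations at a designated
set of "K_c-sensitive" positions additionally perturb the internal equilibrium
K_c strongly.  Selection-sequencing read counts, calibration standards, and
Potts-sampled alignments complete the set of inputs, so the entire analysis is
testable end to end with known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .equilibrium_model import RT, EquilibriumParams, apparent_kd
from .dca import AA20, ALPHABET, GAP, PottsModel

#: marker used in variant tables for "no mutation at this slot"
NO_POS = 0
NO_AA = ""


@dataclass(frozen=True)
class LibraryDesign:
    """Combinatorial design of the mutant library."""

    n_positions: int = 9
    n_substitutions: int = 19
    n_homologs: int = 5

    def __post_init__(self) -> None:
        if min(self.n_positions, self.n_substitutions, self.n_homologs) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.n_substitutions > 19:
            raise ValueError("at most 19 non-wildtype residues per site")


@dataclass(frozen=True)
class LibraryCounts:
    singles_per_homolog: int
    doubles_per_homolog: int
    cycles_per_pair: int
    position_pairs: int
    singles_total: int
    doubles_total: int
    possible_cycles: int
    total_variants: int


def enumerate_library(design: LibraryDesign) -> LibraryCounts:
    """Exact combinatorics of the single/double mutant library.

    Per homolog: P*S singles, C(P,2)*S^2 doubles, plus wild type; every
    position pair supports S^2 mutant cycles per homolog.
    """
    p, s, h = design.n_positions, design.n_substitutions, design.n_homologs
    pairs = math.comb(p, 2)
    singles = p * s
    doubles = pairs * s * s
    return LibraryCounts(
        singles_per_homolog=singles,
        doubles_per_homolog=doubles,
        cycles_per_pair=s * s,
        position_pairs=pairs,
        singles_total=h * singles,
        doubles_total=h * doubles,
        possible_cycles=h * pairs * s * s,
        total_variants=h * (singles + doubles + 1),
    )


# ---------------------------------------------------------------------------
# ground-truth energy landscape


@dataclass(frozen=True)
class LandscapeConfig:
    """Mutational perturbation scales for the truth landscape (log space).

    Mutations at K_c-sensitive positions draw the strong, directional K_c
    perturbation (log-mean ``kc_large_mean``) with probability
    ``kc_large_fraction``; all other K_c effects are small and zero-centred.
    """

    sd_ln_kx: float = 1.5
    sd_ln_alpha: float = 0.5
    sd_ln_kc_small: float = 0.05
    sd_ln_kc_large: float = 1.0
    kc_large_mean: float = 6.0
    kc_large_fraction: float = 0.5
    homolog_kc_jitter: float = 0.3


class TruthLandscape:
    """Ground-truth energies for every library variant, plus the generator state.

    ``table`` is the full truth table (one row per variant, including a
    wild-type row per homolog with dg_true = 0).  The per-mutation perturbation
    triples are retained so that free energies of arbitrary multi-mutants can
    be computed (perturbations compose multiplicatively, i.e. additively in
    log space, with no intrinsic coupling in any microscopic constant).
    """

    def __init__(
        self,
        design: LibraryDesign,
        wt_params: EquilibriumParams,
        kc_sensitive_positions: tuple[int, ...],
        config: LandscapeConfig,
        seed: int,
    ):
        self.design = design
        self.config = config
        self.kc_sensitive_positions = tuple(sorted(kc_sensitive_positions))
        bad = [p for p in self.kc_sensitive_positions if not 1 <= p <= design.n_positions]
        if bad:
            raise ValueError(f"kc-sensitive positions outside segment: {bad}")
        rng = np.random.default_rng(seed)
        P = design.n_positions
        self.homologs = [f"H{k + 1}" for k in range(design.n_homologs)]
        # homolog wild types: random segment sequences, slight K_c variation
        self.wt_seq = {h: rng.integers(0, 20, P) for h in self.homologs}
        self.wt_params = {
            h: EquilibriumParams(
                wt_params.k_x,
                wt_params.k_c * float(np.exp(rng.normal(0.0, config.homolog_kc_jitter))),
                wt_params.alpha,
            )
            for h in self.homologs
        }
        # per-(homolog, position, residue) perturbation triples; wt residue = 0
        sensitive = np.zeros(P, dtype=bool)
        sensitive[[p - 1 for p in self.kc_sensitive_positions]] = True
        self.effects = {}
        for h in self.homologs:
            eff = np.zeros((P, 20, 3))  # (dln_kx, dln_kc, dln_alpha)
            eff[:, :, 0] = rng.normal(0.0, config.sd_ln_kx, (P, 20))
            eff[:, :, 2] = rng.normal(0.0, config.sd_ln_alpha, (P, 20))
            large = sensitive[:, None] & (rng.random((P, 20)) < config.kc_large_fraction)
            eff[:, :, 1] = np.where(
                large,
                rng.normal(config.kc_large_mean, config.sd_ln_kc_large, (P, 20)),
                rng.normal(0.0, config.sd_ln_kc_small, (P, 20)),
            )
            eff[np.arange(P), self.wt_seq[h], :] = 0.0
            self.effects[h] = eff
        self.table = self._build_table()

    def _variant_kd(self, hom: str, dlogs: np.ndarray) -> np.ndarray:
        wt = self.wt_params[hom]
        return apparent_kd(
            wt.k_x * np.exp(dlogs[..., 0]),
            wt.k_c * np.exp(dlogs[..., 1]),
            wt.alpha * np.exp(dlogs[..., 2]),
        )

    def dg_of_codes(self, hom: str, codes: np.ndarray, rt: float = RT) -> np.ndarray:
        """Binding free energy (kcal/mol, vs wild type) of arbitrary sequences."""
        codes = np.atleast_2d(codes)
        eff = self.effects[hom]
        dlogs = eff[np.arange(codes.shape[1])[None, :], codes, :].sum(axis=1)
        kd = self._variant_kd(hom, dlogs)
        return rt * np.log(kd / apparent_kd(self.wt_params[hom]))

    def _build_table(self) -> pd.DataFrame:
        P, S = self.design.n_positions, self.design.n_substitutions
        aa = np.array(list(AA20))
        rows = []
        for h in self.homologs:
            wt = self.wt_seq[h]
            eff = self.effects[h]
            kd_wt = apparent_kd(self.wt_params[h])
            subs = [np.array([a for a in range(20) if a != wt[p]][:S]) for p in range(P)]
            rows.append(
                pd.DataFrame(
                    {"homolog": h, "pos1": NO_POS, "aa1": NO_AA, "pos2": NO_POS,
                     "aa2": NO_AA, "kd_true": kd_wt, "dg_true": 0.0}, index=[0]
                )
            )
            # singles
            p_idx = np.repeat(np.arange(P), S)
            a_idx = np.concatenate(subs)
            kd = self._variant_kd(h, eff[p_idx, a_idx])
            rows.append(
                pd.DataFrame(
                    {
                        "homolog": h, "pos1": p_idx + 1, "aa1": aa[a_idx],
                        "pos2": NO_POS, "aa2": NO_AA,
                        "kd_true": kd, "dg_true": RT * np.log(kd / kd_wt),
                    }
                )
            )
            # doubles
            for i in range(P):
                for j in range(i + 1, P):
                    xi, yj = np.meshgrid(subs[i], subs[j], indexing="ij")
                    dl = eff[i, xi.ravel()] + eff[j, yj.ravel()]
                    kd = self._variant_kd(h, dl)
                    rows.append(
                        pd.DataFrame(
                            {
                                "homolog": h,
                                "pos1": i + 1, "aa1": aa[xi.ravel()],
                                "pos2": j + 1, "aa2": aa[yj.ravel()],
                                "kd_true": kd, "dg_true": RT * np.log(kd / kd_wt),
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def make_truth_landscape(
    design: LibraryDesign = LibraryDesign(),
    wt_params: EquilibriumParams = EquilibriumParams(),
    kc_sensitive_positions: tuple[int, ...] = (1, 4, 5, 8),
    config: LandscapeConfig = LandscapeConfig(),
    seed: int = 0,
) -> TruthLandscape:
    """Ground-truth landscape from the coupled-equilibrium model (seeded)."""
    return TruthLandscape(design, wt_params, kc_sensitive_positions, config, seed)


# ---------------------------------------------------------------------------
# selection read counts and calibration standards


def simulate_selection_counts(
    truth: pd.DataFrame,
    a: float,
    c: float,
    l_free: float,
    depth_unselected: int = 10_000_000,
    depth_selected: int = 10_000_000,
    seed: int = 0,
    bias_concentration: float | None = None,
) -> pd.DataFrame:
    """Multinomial read counts before/after selection for a truth table.

    Unselected frequencies are uniform (or Dirichlet with the given
    concentration, modelling unequal library representation).  Selection
    multiplies each variant's frequency by exp(a*ln f_b + c) with
    f_b = L/(L + K_d), the growth-selection model of the two-hybrid assay,
    before renormalization and multinomial resampling at the selected depth.
    """
    if l_free <= 0:
        raise ValueError("free ligand concentration must be positive")
    if depth_unselected < 0 or depth_selected < 0:
        raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(truth)
    if bias_concentration is None:
        p_u = np.full(n, 1.0 / n)
    else:
        p_u = rng.dirichlet(np.full(n, bias_concentration))
    fb = l_free / (l_free + truth["kd_true"].to_numpy())
    w = p_u * np.exp(a * np.log(fb) + c)
    p_s = w / w.sum()
    out = truth[["homolog", "pos1", "aa1", "pos2", "aa2"]].copy()
    out["count_unselected"] = rng.multinomial(depth_unselected, p_u)
    out["count_selected"] = rng.multinomial(depth_selected, p_s)
    return out


def expected_selection_frequencies(truth: pd.DataFrame, a: float, c: float, l_free: float):
    """Analytic (infinite-depth) unselected and selected frequency vectors."""
    n = len(truth)
    p_u = np.full(n, 1.0 / n)
    fb = l_free / (l_free + truth["kd_true"].to_numpy())
    w = p_u * np.exp(a * np.log(fb) + c)
    return p_u, w / w.sum()


def make_standards(
    n: int = 45,
    kd_range: tuple[float, float] = (1e-8, 1e-4),
    a: float = 1.0,
    c: float = -5.0,
    l_free: float = 1e-6,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration standards: variants of known K_d with 'measured' enrichment.

    K_d values are log-uniform over ``kd_range`` (which should straddle the
    free ligand concentration); the observed enrichment is the standard curve
    a*ln(L/(L+K_d)) + c plus Gaussian noise.  A range on one side of L gives
    no occupancy contrast and is rejected.
    """
    if n < 4:
        raise ValueError("need at least 4 standards (3 free parameters)")
    lo, hi = kd_range
    if not 0 < lo < hi:
        raise ValueError("invalid kd_range")
    if hi <= l_free or lo >= l_free:
        raise ValueError("degenerate standards: kd_range must span both sides of L")
    rng = np.random.default_rng(seed)
    kd = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    de = a * np.log(l_free / (l_free + kd)) + c + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"id": [f"std{k}" for k in range(n)], "kd_molar": kd, "delta_e": de})


# ---------------------------------------------------------------------------
# Potts-model alignments


@njit(cache=True)
def _gibbs_chain(h, J, n_seqs, burn_in, thin, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    L, q = h.shape
    seq = np.empty(L, np.int64)
    for i in range(L):
        seq[i] = np.random.randint(0, q)
    out = np.empty((n_seqs, L), np.int64)
    e = np.empty(q)
    total = burn_in + n_seqs * thin
    for s in range(total):
        for i in range(L):
            for a in range(q):
                v = h[i, a]
                for j in range(L):
                    if j != i:
                        v += J[i, j, a, seq[j]]
                e[a] = -v
            m = e[0]
            for a in range(1, q):
                if e[a] > m:
                    m = e[a]
            tot = 0.0
            for a in range(q):
                e[a] = np.exp(e[a] - m)
                tot += e[a]
            r = np.random.random() * tot
            acc = 0.0
            k = q - 1
            for a in range(q):
                acc += e[a]
                if r < acc:
                    k = a
                    break
            seq[i] = k
        if s >= burn_in and (s - burn_in) % thin == thin - 1:
            out[(s - burn_in) // thin] = seq
    return out


def sample_potts_msa(
    model: PottsModel,
    n_seqs: int,
    seed: int = 0,
    burn_in: int = 1000,
    thin: int = 10,
) -> np.ndarray:
    """Gibbs-sample sequences from P(sigma) ~ exp(-E(sigma)).

    One long chain with burn-in and thinning (not one chain per sequence);
    returns an (n_seqs, L) array of integer codes.  Bit-reproducible given
    (model, seed).
    """
    if not (np.isfinite(model.h).all() and np.isfinite(model.J).all()):
        raise ValueError("non-finite Potts parameters")
    if burn_in < 0 or thin < 1:
        raise ValueError("burn_in must be >= 0 and thin >= 1")
    return _gibbs_chain(model.h, model.J, int(n_seqs), int(burn_in), int(thin), int(seed) % 2**31)


def make_planted_potts(
    n_positions: int = 20,
    n_edges: int = 10,
    coupling: float = 2.0,
    field_sd: float = 0.5,
    n_states: int = 21,
    gap_penalty: float = 4.0,
    min_separation: int = 3,
    background_sd: float = 0.0,
    edges: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> tuple[PottsModel, list[tuple[int, int]]]:
    """Potts model with random fields and a set of planted coupled edges.

    Each planted edge favours a random residue bijection: J_ij(a, perm(a)) =
    -coupling for the 20 residues.  Edges are drawn among pairs at sequence
    separation >= ``min_separation``, matching the contact-scoring convention.
    With ``background_sd`` > 0, every position pair additionally carries weak
    dense Gaussian couplings — the distributed functional signal that contact-
    focused editing destroys.  The gap state carries a large positive field so
    sampled alignments are essentially gapless.  Returns the model and the
    planted edge list (1-based, i < j).
    """
    rng = np.random.default_rng(seed)
    L, q = n_positions, n_states
    h = rng.normal(0.0, field_sd, (L, q))
    if q > 20:
        h[:, 20:] += gap_penalty
    if edges is not None:
        edges = [(min(i, j) - 1, max(i, j) - 1) for i, j in edges]
    else:
        all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L) if j - i >= min_separation]
        sel = rng.choice(len(all_pairs), size=n_edges, replace=False)
        edges = [all_pairs[k] for k in sel]
    n_res = min(20, q)
    J = np.zeros((L, L, q, q))
    if background_sd > 0:
        for i in range(L):
            for j in range(i + 1, L):
                block = np.zeros((q, q))
                block[:n_res, :n_res] = rng.normal(0.0, background_sd, (n_res, n_res))
                J[i, j] = block
                J[j, i] = block.T
    for i, j in edges:
        perm = rng.permutation(n_res)
        block = np.zeros((q, q))
        block[np.arange(n_res), perm] = -coupling
        J[i, j] += block
        J[j, i] += block.T
    model = PottsModel(h, J, alphabet=ALPHABET[:q])
    return model, [(i + 1, j + 1) for i, j in edges]


def make_sector_potts(
    n_positions: int = 20,
    sector_positions: tuple[int, ...] = (3, 8, 13, 18),
    coupling: float = 1.0,
    sector_field: float = 1.0,
    gap_penalty: float = 4.0,
    seed: int = 0,
) -> tuple[PottsModel, dict]:
    """Potts model with a planted coevolving (sector-like) position group.

    Background positions carry a single favoured residue of varying
    conservation.  Sector positions are two-state: a primary and a secondary
    residue are both viable, and pairwise couplings reward concordant choices
    (primary with primary, secondary with secondary) across every sector pair
    — conserved positions with correlated deviations, the signature that
    conservation-weighted covariance analysis detects.  Returns the model and
    a dict with the primary/secondary residue assignments.
    """
    rng = np.random.default_rng(seed)
    L, q = n_positions, 21
    sector0 = [p - 1 for p in sector_positions]
    if any(not 0 <= p < L for p in sector0):
        raise ValueError("sector positions outside the alignment")
    h = np.zeros((L, q))
    h[:, 20] = gap_penalty
    primary = rng.integers(0, 20, L)
    secondary = (primary + rng.integers(1, 20, L)) % 20
    for i in range(L):
        h[i, primary[i]] = -rng.uniform(0.5, 2.5)
    for i in sector0:
        h[i, primary[i]] = -sector_field
        h[i, secondary[i]] = -0.6 * sector_field
    J = np.zeros((L, L, q, q))
    for i, j in ((a, b) for k, a in enumerate(sector0) for b in sector0[k + 1:]):
        blk = np.zeros((q, q))
        blk[primary[i], primary[j]] = -coupling
        blk[secondary[i], secondary[j]] = -coupling
        blk[primary[i], secondary[j]] = coupling
        blk[secondary[i], primary[j]] = coupling
        J[i, j] = blk
        J[j, i] = blk.T
    model = PottsModel(h, J, alphabet=ALPHABET)
    return model, {"primary": primary, "secondary": secondary}


def sample_fitness_msa(
    landscape: TruthLandscape,
    homolog: str,
    n_seqs: int,
    beta: float = 2.0,
    seed: int = 0,
    burn_in: int = 200,
    thin: int = 5,
) -> np.ndarray:
    """Gibbs-sample segment sequences under fitness ~ exp(-beta * dG_bind).

    Unlike the Potts sampler, the energy here is the *nonlinear* truth
    landscape (log-perturbations summed over all mutated positions, passed
    through the apparent-K_d curve), so the sampled alignment carries the
    distributed, sector-like covariation that a pairwise model can only
    approximate.  Returns (n_seqs, L) residue codes (0..19).
    """
    rng = np.random.default_rng(seed)
    P = landscape.design.n_positions
    eff = landscape.effects[homolog]  # (P, 20, 3)
    wt = landscape.wt_params[homolog]
    kd_wt = apparent_kd(wt)
    seq = landscape.wt_seq[homolog].copy()
    dlog = eff[np.arange(P), seq].sum(axis=0)  # (3,)
    out = np.empty((n_seqs, P), dtype=np.int64)
    n_kept = 0
    for sweep in range(burn_in + n_seqs * thin):
        for i in range(P):
            base = dlog - eff[i, seq[i]]
            cand = base[None, :] + eff[i]  # (20, 3)
            kd = apparent_kd(
                wt.k_x * np.exp(cand[:, 0]),
                wt.k_c * np.exp(cand[:, 1]),
                wt.alpha * np.exp(cand[:, 2]),
            )
            dg = RT * np.log(kd / kd_wt)
            logp = -beta * dg
            logp -= logp.max()
            p = np.exp(logp)
            p /= p.sum()
            new = rng.choice(20, p=p)
            seq[i] = new
            dlog = base + eff[i, new]
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            out[n_kept] = seq
            n_kept += 1
    return out
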