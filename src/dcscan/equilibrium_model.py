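"""Coupled two-state conformational equilibrium model of ligand binding.

A protein exchanges between two conformations, 0 and 1, and either can bind
ligand, giving four states: 0F, 1F (free) and 0B, 1B (bound).  Conformation 1
binds with dissociation constant ``K_x`` and conformation 0 with ``alpha *
K_x``; the internal equilibrium of the free protein is ``K_c = [0F]/[1F]``.
Because binding and the conformational change are thermodynamically coupled,
the observed (apparent) dissociation constant ``K_x_app`` interpolates between
``K_x`` (K_c -> 0) and ``alpha * K_x`` (K_c -> inf), linearly in K_x,
saturating in alpha, and sigmoidally in log K_c.

Mutations are modelled as log-normal perturbations of (K_x, K_c, alpha).
Double mutants compose perturbations multiplicatively, i.e. with no intrinsic
coupling in any microscopic constant; all thermodynamic coupling between
mutations then arises from the nonlinearity of K_x_app in K_c.  Depending on
whether mutations perturb K_c weakly, strongly, or as a mixture, the resulting
mutant-cycle coupling distributions are unimodal at zero, unimodal away from
zero, or bimodal with one mode at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: thermal energy at 25 degC, kcal/mol
RT = 0.592


@dataclass(frozen=True)
class EquilibriumParams:
    """Microscopic constants of the four-state binding scheme.

    k_x : dissociation constant of the binding-competent conformation (M)
    k_c : conformational equilibrium of the free protein, [0F]/[1F]
    alpha : coupling factor; conformation 0 binds with dissociation alpha*k_x
    """

    k_x: float = 1e-6
    k_c: float = 1.0
    alpha: float = 100.0

    def __post_init__(self) -> None:
        if not (self.k_x > 0 and self.k_c > 0 and self.alpha > 0):
            raise ValueError("all equilibrium parameters must be positive")

    def perturbed(self, dln_kx: float, dln_kc: float, dln_alpha: float) -> "EquilibriumParams":
        """Apply multiplicative (log-additive) perturbations."""
        return EquilibriumParams(
            k_x=self.k_x * float(np.exp(dln_kx)),
            k_c=self.k_c * float(np.exp(dln_kc)),
            alpha=self.alpha * float(np.exp(dln_alpha)),
        )


def apparent_kd(k_x, k_c=None, alpha=None):
    """Closed-form apparent dissociation constant of the four-state scheme.

    ``K_x_app = K_x (1 + K_c) / (1 + K_c / alpha)``.

    Accepts either an :class:`EquilibriumParams` or array-like (k_x, k_c,
    alpha).  Validated against :func:`apparent_kd_numeric`, which solves the
    mass-action system directly.
    """
    if isinstance(k_x, EquilibriumParams):
        p = k_x
        k_x, k_c, alpha = p.k_x, p.k_c, p.alpha
    k_x = np.asarray(k_x, dtype=float)
    k_c = np.asarray(k_c, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(k_x <= 0) or np.any(k_c <= 0) or np.any(alpha <= 0):
        raise ValueError("all equilibrium parameters must be positive")
    out = k_x * (1.0 + k_c) / (1.0 + k_c / alpha)
    return float(out) if out.ndim == 0 else out


def fraction_bound_numeric(params: EquilibriumParams, l_free: float) -> float:
    """Fraction of protein bound at fixed free-ligand concentration.

    Built from the state populations of the reaction scheme only (no apparent
    constant): relative to 1F = 1, 0F = K_c, 1B = L/K_x, and 0B follows from
    conformation 0 binding with dissociation constant alpha*K_x.
    """
    pop_1f = 1.0
    pop_0f = params.k_c
    pop_1b = l_free / params.k_x
    pop_0b = params.k_c * l_free / (params.alpha * params.k_x)
    bound = pop_1b + pop_0b
    return bound / (bound + pop_1f + pop_0f)


def apparent_kd_numeric(params: EquilibriumParams) -> float:
    """Brute-force apparent K_d: free-ligand concentration at half occupancy.

    Independent oracle for :func:`apparent_kd`; root-finds fraction bound = 1/2
    on the mass-action populations.
    """
    lo = params.k_x * min(1.0, params.alpha) * 1e-6
    hi = params.k_x * max(1.0, params.alpha) * 1e6
    return brentq(
        lambda l: fraction_bound_numeric(params, l) - 0.5,
        lo, hi, xtol=1e-300, rtol=8.9e-16,
    )


def binding_dg(params: EquilibriumParams, wt: EquilibriumParams, rt: float = RT) -> float:
    """Binding free energy of a variant relative to wild type (kcal/mol)."""
    return rt * float(np.log(apparent_kd(params) / apparent_kd(wt)))


@dataclass(frozen=True)
class PerturbationSpec:
    """Mutational perturbation model in log-parameter space.

    Single mutations draw independent normal deviates on ln K_x, ln alpha and
    ln K_c.  A fraction ``kc_large_fraction`` of mutations perturb K_c
    strongly and directionally (log-mean ``kc_large_mean``: mutations at
    equilibrium-setting positions consistently push the poised K_c ~ 1
    equilibrium toward the weak-binding conformation), the rest draw from the
    small, zero-centred SD.  ``noise_sd`` is the Gaussian measurement error
    added to every simulated free-energy determination (kcal/mol), emulating
    replicate error of the selection assay.  The three canonical regimes:

    - ``kc_large_fraction = 0``: couplings unimodal, centred at zero
    - ``kc_large_fraction = 1``: couplings unimodal, centred away from zero
    - intermediate: bimodal with one mode at zero
    """

    sd_ln_kx: float = 1.5
    sd_ln_alpha: float = 0.5
    sd_ln_kc_small: float = 0.05
    sd_ln_kc_large: float = 1.0
    kc_large_mean: float = 6.0
    kc_large_fraction: float = 0.0
    n_mutations: int = 30
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if min(self.sd_ln_kx, self.sd_ln_alpha, self.sd_ln_kc_small,
               self.sd_ln_kc_large, self.noise_sd) < 0:
            raise ValueError("perturbation and noise SDs must be non-negative")
        if not 0.0 <= self.kc_large_fraction <= 1.0:
            raise ValueError("kc_large_fraction must lie in [0, 1]")
        if self.n_mutations < 2:
            raise ValueError("need at least two mutations to form a cycle")


#: presets reproducing the three regime demonstrations (unimodal-zero,
#: bimodal with one mode at zero, unimodal-nonzero)
REGIME_PRESETS = {
    "E": PerturbationSpec(kc_large_fraction=0.0),
    "F": PerturbationSpec(kc_large_fraction=0.35),
    "G": PerturbationSpec(kc_large_fraction=1.0),
}


def draw_perturbations(spec: PerturbationSpec, rng: np.random.Generator):
    """Draw (dln_kx, dln_kc, dln_alpha) for n single mutations."""
    n = spec.n_mutations
    dln_kx = rng.normal(0.0, spec.sd_ln_kx, n)
    dln_alpha = rng.normal(0.0, spec.sd_ln_alpha, n)
    is_large = rng.random(n) < spec.kc_large_fraction
    dln_kc = np.where(
        is_large,
        rng.normal(spec.kc_large_mean, spec.sd_ln_kc_large, n),
        rng.normal(0.0, spec.sd_ln_kc_small, n),
    )
    return dln_kx, dln_kc, dln_alpha


def simulate_mutation_couplings(
    wt: EquilibriumParams,
    spec: PerturbationSpec,
    seed: int | np.random.Generator = 0,
    rt: float = RT,
    return_pairs: bool = False,
):
    """Mutant-cycle coupling distribution under the equilibrium model.

    Draws ``spec.n_mutations`` single-mutant perturbations, composes all
    pairwise doubles multiplicatively, converts each variant's apparent K_d to
    a binding free energy relative to wild type (plus measurement noise), and
    returns the coupling dG_i + dG_j - dG_ij for every pair (kcal/mol).  With
    ``return_pairs`` also returns the (i, j) index arrays mapping couplings to
    the underlying single mutations (needed for dependence-aware SEMs).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dkx, dkc, da = draw_perturbations(spec, rng)
    n = spec.n_mutations

    kd_wt = apparent_kd(wt)
    kd_single = apparent_kd(wt.k_x * np.exp(dkx), wt.k_c * np.exp(dkc), wt.alpha * np.exp(da))
    dg_single = rt * np.log(kd_single / kd_wt) + rng.normal(0.0, spec.noise_sd, n)

    iu, ju = np.triu_indices(n, k=1)
    kd_double = apparent_kd(
        wt.k_x * np.exp(dkx[iu] + dkx[ju]),
        wt.k_c * np.exp(dkc[iu] + dkc[ju]),
        wt.alpha * np.exp(da[iu] + da[ju]),
    )
    dg_double = rt * np.log(kd_double / kd_wt) + rng.normal(0.0, spec.noise_sd, len(iu))
    ddg = (dg_single[iu] + dg_single[ju]) - dg_double
    if return_pairs:
        return ddg, iu, ju
    return ddg


def coupling_mean_sem_jackknife(ddg: np.ndarray, iu: np.ndarray, ju: np.ndarray, n_mutations: int) -> float:
    """Delete-one-mutation jackknife SEM of the mean coupling.

    All-pairs cycles share single mutants, so the naive sd/sqrt(n_cycles)
    badly understates the variability of the mean; jackknifing over the
    underlying mutations accounts for the dependence.
    """
    means = np.array(
        [ddg[(iu != k) & (ju != k)].mean() for k in range(n_mutations)]
    )
    return float(np.sqrt((n_mutations - 1) / n_mutations * ((means - means.mean()) ** 2).sum()))
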