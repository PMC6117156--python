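# Methods

`dcscan` implements a complete, simulation-backed version of a deep coupling
scan: a selection experiment measuring the binding effect of every single and
double mutation in a short protein segment, converted to thermodynamic
double-mutant-cycle couplings, summarized per position pair by Gaussian
mixtures, explained mechanistically by a coupled conformational equilibrium,
and compared against couplings predicted from sequence coevolution (SCA and
pseudolikelihood DCA). This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic data do and do not
emulate.

## Study design

The default library design mirrors a nine-position helical segment scanned
with all 19 substitutions per site in five homologous domains: per homolog,
171 singles, C(9,2) x 19^2 = 12,996 doubles, and the wild type — 65,840
variants in total, supporting 361 mutant cycles per position pair per homolog
(64,980 overall). `enumerate_library` reproduces these counts exactly for any
design.

## Ground-truth energy landscape

Binding free energies come from a four-state model: a protein exchanges
between conformations 0 and 1 (equilibrium K_c = [0F]/[1F] for the free
protein); conformation 1 binds ligand with dissociation constant K_x,
conformation 0 with alpha*K_x. The apparent dissociation constant is

    K_x_app = K_x (1 + K_c) / (1 + K_c / alpha),

which runs from K_x (K_c -> 0) to alpha*K_x (K_c -> infinity), is linear in
K_x, saturating in alpha, and sigmoidal in log K_c. The closed form is
derived, not assumed: `apparent_kd_numeric` solves the mass-action populations
directly and the test suite requires agreement to 1e-10 in relative error on a
1,000-point log-grid. Convention note: we define alpha so that conformation 0
binds with dissociation constant alpha*K_x (hence the bound-state ratio
0B/1B = K_c/alpha); with alpha > 1, state 1 is the binding-competent
conformation.

Mutations perturb (K_x, K_c, alpha) log-normally — log-space keeps the
constants positive, and "effect sizes" of mutations on equilibrium constants
are naturally multiplicative. Double mutants add log-perturbations with no
intrinsic coupling in any microscopic constant, so every thermodynamic
coupling in the landscape arises from the nonlinearity of K_x_app in K_c.
Defaults (wild type K_x = 1 uM, K_c = 1, alpha = 100; perturbation SDs
sd_ln_kx = 1.5, sd_ln_alpha = 0.5, sd_ln_kc_small = 0.05):

- K_c sits at the steep point of its sigmoid, the poised regime where
  couplings are possible at all.
- "Large" K_c effects are strong and directional: ln K_c shifts by N(6, 1).
  Directionality matters: zero-centred large perturbations scatter variants
  onto both plateaus and produce multimodal coupling distributions, whereas
  the observed all-mutations-coupled regime is unimodal at a nonzero value —
  which requires mutations at equilibrium-setting positions to push the poised
  equilibrium consistently toward the weak-binding conformation (the
  biophysically expected direction for mutations that destroy a marginally
  stable native bias).
- A 0.25 kcal/mol Gaussian measurement error is added to each simulated
  free-energy determination in the regime simulations, emulating the replicate
  error of a selection assay. Without it, the pure curvature couplings form
  product-normal spikes (sharply peaked, heavy-tailed) that a BIC comparison
  rightly refuses to model as a single Gaussian.

With these defaults the three perturbation presets reproduce the three
canonical coupling-distribution shapes: only-K_x/alpha perturbations give a
unimodal distribution at zero; all-large K_c effects give a unimodal
distribution away from zero; a 35% large fraction gives a bimodal distribution
with one mode at zero.

In the full landscape, mutations at the designated K_c-sensitive positions
(default {1, 4, 5, 8}) draw the large K_c effect with probability 0.5; all
other mutations perturb K_c negligibly. The resulting truth table shows
nonzero mean couplings at exactly the pairs between sensitive positions,
per-pair bimodal distributions, and homolog averaging that preserves these
conserved couplings while shrinking homolog-specific ones by 1/n_homologs.

### Statistical caution: cycles share mutations

All-pairs mutant cycles built from n single mutants are strongly dependent
(each single enters n-1 cycles). The naive SEM, sd/sqrt(n_cycles),
understates the sampling variability of the mean coupling by a factor of
roughly 0.8*sqrt(n); tests of "mean consistent with zero" therefore use a
delete-one-mutation jackknife SEM (`coupling_mean_sem_jackknife`).

## Selection and calibration

Selection is modelled as growth proportional to occupancy: a variant's
selected frequency is its unselected frequency times exp(a ln f_b + C) with
f_b = L/(L + K_d), and reads are multinomial at the stated depths (default
1e7, uniform initial library; a Dirichlet option models representation bias).
The canonical study runs one sequencing experiment per homolog (13,168
variants each at depth 1e7, i.e. ~760 reads per variant), which is also why
wild-type anchoring exists: it reconciles batch offsets between experiments.
The assay slope defaults to a = 1. This choice sets a real tradeoff: free-
energy precision scales with a (the enrichment signal per unit dG), but the
dynamic range compresses as a grows and weak binders drop below the read
thresholds — at a = 2 and this depth, roughly half the cycles (exactly the
strongly coupled, weak-binding variants) are censored, while a = 1 keeps
~90-95% of cycles at a median |dG error| near 0.06 kcal/mol.
Enrichment is z = f_s/f_u, dE = ln(z / sum z); zero unselected counts are
flagged and excluded from the normalizing sum, zero selected counts yield
z = 0 and are flagged non-invertible rather than pseudocounted.

The standard curve dE = a ln(L/(L+K_d)) + C is fitted to 45 standards of
known K_d (log-uniform over 0.01L–100L by default; the identity and range of
real standards are not public, so this is a documented choice). Given L the
model is linear in (a, C), so the fit scans L on a log grid (1e-9–1e-3 M),
solves (a, C) in closed form, and polishes the best point by
Levenberg–Marquardt on (a, C, ln L). A fit is flagged unidentifiable when the
fitted occupancies barely vary (log f_b spread below 0.1) or the slope is
within 3 SE of zero — in either case a and C are confounded. Wild-type
anchoring applies the additive dE shift (per homolog) that puts the known
wild-type K_d on the curve, making independently sequenced batches
comparable; it is idempotent. Inversion f_b = exp((dE - C)/a) must land in
(0, 1); anything else is flagged out-of-range, never returned as a number.
RT = 0.592 kcal/mol (25 degC) throughout.

At the canonical study scale (five per-homolog experiments at depth 1e7,
standards noise SD 0.1) the full pipeline recovers variant free energies with
a median absolute error near 0.06 kcal/mol, and the homolog-averaged coupling
matrix puts the six pairs among the planted equilibrium-setting positions an
order of magnitude above every other pair.

## Couplings, filtering, mixtures

A cycle's coupling is ddG = (dG_i^x + dG_j^y) - dG_ij^xy, all relative to the
homolog's wild type. QC thresholds (default: >= 10 unselected, >= 5 selected
reads) propagate through the cycle dependency — a cycle survives only if the
double, both singles, and wild type pass. Homolog averaging defaults to the
strict intersection (a mutation pair must be measured in every homolog) to
avoid composition bias between position pairs; `min_homologs` relaxes this.

Per-pair distributions are fit with 1- and 2-component Gaussian mixtures
(scikit-learn EM; 5 k-means-initialized restarts, tol 1e-6, max 200
iterations — more restarts or tighter tolerances never changed a selection in
calibration runs and cost ~5x the time) and the minimum-BIC model is chosen,
with two tie-breaks: a 2-component fit whose smaller weight is below 0.02 is
discarded as a degenerate spike, and a BIC advantage smaller than 2 goes to
the single Gaussian (parsimony). The population-weighted mean sum_k w_k mu_k
is the native-coupling estimate; over pairs it fills the symmetric coupling
matrix (NaN where unfit).

## SCA

From scratch: sequence weights 1/(number of neighbours at >= 80% identity);
frequencies pseudocounted with lambda = 0.03 toward uniform; gaps treated as
missing data by default (frequencies renormalized over the 20 residues; a
gap-as-state mode exists). For gapless alignments the marginalization
identity sum_b f_ij^ab = f_i^a holds exactly after pseudocounting; with gaps
it is approximate (per-pair normalization). The background q defaults to a
uniform 0.05 per residue. The conservation weight is
phi = ln[f(1-q)/(q(1-f))], the gradient of the binary KL conservation D.
The coupling tensor phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b) is reduced to a
positional matrix by the Frobenius norm, eigendecomposed, and cleaned to the
rank-one top mode lambda_1 v1 v1^T; v1's sign is fixed by its largest entry,
and the sector is the set of positions above the 90th percentile of |v1|
(the full top mode is also returned). Ablations: dropping phi leaves the
Frobenius norm of the raw correlations; dropping correlations leaves the
conservation outer product D_i D_j, where D_i = sum_a f ln(f/q) — the paper
trail for the correlation-free measure is incomplete, so this construction is
our documented interpretation.

## DCA

Pseudolikelihood maximization of a 21-state Potts model (gap as a state):
the objective is the weighted sum over sites of the conditional
log-likelihood, L2-penalized (lambda_h = 0.01, lambda_J = 0.01*(L-1),
plmDCA-style scaling), optimized jointly by L-BFGS over the fields and an
asymmetric coupling matrix, then symmetrized and expressed in the zero-sum
gauge (which preserves all energy differences; verified to 1e-10).
Convention: P(sigma) ~ exp(-E(sigma)) with
E = sum h_i(sigma_i) + sum_{i<j} J_ij(sigma_i, sigma_j).
One caveat established during development: a symmetrized pseudolikelihood fit
recovers a two-site joint distribution only up to per-site factors (the
field/coupling split is gauge-dependent), so exactness tests target the
gauge-invariant interaction part of the log-joint, which converges linearly
as lambda -> 0.

Contact scores are Frobenius norms of the residue-only (gap excluded) J
blocks after gauge fixing, APC-corrected (F_ij - F_i. F_.j / F_.., which
annihilates exactly rank-one score matrices); pairs closer than 3 in sequence
are excluded from the ranking and the top L/2 are reported. Mutational
couplings ddE use the same cycle formula as the experiment, computed for all
residue pairs from each homolog's wild-type sequence, averaged across
homologs, and summarized by the same mixture machinery — so DCA predictions
and experimental couplings are processed identically. The edited-model
experiment retains the top-L/2 pairs that are contacts and permutes all other
J blocks wholesale between the remaining position pairs (preserving the block
multiset and within-block structure), seeded.

## Comparison statistics

Predictions vs experiment use OLS over the upper-triangle position pairs
(pairwise-complete), r2 = 1 - SS_res/SS_tot, and the F-test
F = r2(n-2)/(1-r2) ~ F(1, n-2) under the no-correlation null. Contact
prediction is precision@k against a contact-map pair list.

## Synthetic data: what passing tests show, and what they do not

The generators emulate multinomial sequencing noise, selection proportional
to occupancy, calibration-standard noise, homolog-to-homolog variation of
K_c and of wild-type sequences, Potts-distributed alignments (one long Gibbs
chain, default 1,000 burn-in sweeps and thinning 10 — per-sequence chains
would be needlessly slow), and fitness-constrained alignments sampled from
the nonlinear truth landscape. They do not model PCR bias, sequencing error,
stop codons or codon-level degeneracy, protein-stability effects on
selection, phylogenetic correlation between sequences, or alignment/curation
error — so passing tests demonstrate correctness and statistical calibration
of the pipeline under idealized sampling, not robustness to those real-data
artifacts. The headline real-data correlation values of coevolution-based
prediction are not reproducible without the original measured energy tables
and curated alignments and are deliberately out of scope.

The SCA-versus-DCA contrast (conservation-weighted coevolution predicting
couplings better than Potts mutational couplings) is reproduced as a property
test on a landscape where the distributed conformational constraint dominates
(background sd_ln_kx reduced to 0.5, selection beta = 1.5, 800 sequences per
homolog): when background single-site constraints rival the sector
constraint, the top eigenmode mixes and the contrast is not reliable at this
alignment size. That sensitivity is itself informative: the contrast is a
statement about constraint hierarchy, not a universal ranking of methods.

## Problem sizes used in tests and the acceptance script

Library checks run at full scale (65,840 variants, depth 1e7). Regime rates
use 50 seeds x 30 mutations (435 cycles each); BIC rates use 200 seeds at
n = 315, matching the mean cycles per pair-homolog; SCA recovery uses 50
seeds x 1,000 sequences x 20 positions; DCA recovery uses L = 20, q = 21,
n = 2,000 with 10 planted edges (L-BFGS capped at 150 iterations, which
ranking accuracy does not benefit beyond), 20 seeds in the test suite and 8
in the acceptance script. The F-test oracle uses 10^4 permutations at
n in {10, 36, 100}.
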