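# dcscan

Analysis pipeline for a **deep coupling scan**: a selection experiment that
measures the binding effect of *every* single and double mutation in a short
protein segment (here, a nine-position helix scanned in five homologous
PDZ-like domains), turns read counts into calibrated binding free energies,
assembles thermodynamic double-mutant cycles, and asks whether the resulting
couplings can be predicted from sequence coevolution.

It is written for protein scientists who want a tested, reusable version of
this kind of analysis with simulation-backed ground truth: every stage can be
exercised against synthetic data whose true energies are known.

## What it computes

**Couplings from selection data.** For mutations x, y at positions i, j, the
thermodynamic double-mutant-cycle coupling is

    ddG_ij^xy = (dG_i^x + dG_j^y) - dG_ij^xy ,

the deviation of the double mutant from additivity. Free energies come from
sequencing counts via the relative enrichment dE_x = ln(z_x / Σ_i z_i) with
z_x = f_s^x / f_u^x, the standard curve dE = a·ln(L/(L+K_d)) + C fitted to
calibration standards, wild-type anchoring, and dG = RT·ln(K_d/K_d^wt).
Per-pair coupling distributions (per homolog or homolog-averaged) are
summarized by 1- or 2-component Gaussian mixtures selected by BIC; the
population-weighted mean is the estimate of the native coupling.

**A mechanistic model.** A four-state coupled equilibrium — conformations 0/1
with internal equilibrium K_c, binding with K_x (state 1) or αK_x (state 0) —
gives K_x^app = K_x(1+K_c)/(1+K_c/α). With K_c poised near 1, log-normal
mutational perturbations of (K_x, K_c, α) that compose additively (no
intrinsic coupling) reproduce all three observed coupling-distribution
shapes: unimodal at zero, bimodal with one zero mode, unimodal away from
zero.

**Coevolution-based prediction.** SCA (conservation-weighted correlation
tensor φφ(f_ij − f_i f_j), Frobenius reduction, top-eigenmode cleaning
Ĉ = λ₁v₁v₁ᵀ) and pseudolikelihood DCA (21-state Potts model, zero-sum gauge,
APC-corrected Frobenius contact scores, in-silico mutant cycles ddE) are
implemented from scratch, along with the comparison statistics (OLS r²,
F-test on F = r²(n−2)/(1−r²), precision@L/2 against a contact map) and the
edited-model experiment in which all non-contact couplings are scrambled.

**Synthetic data.** `dcscan.synthetic_data` generates everything the pipeline
consumes: library enumerations, ground-truth landscapes from the equilibrium
model, multinomial selection read counts, calibration standards, and
alignments Gibbs-sampled from Potts models (planted contacts, planted
sectors) or from fitness-constrained landscape sampling.

## Worked example

Simulate a complete study (one sequencing experiment per homolog, as in the
assay the package models), calibrate, and estimate couplings:

```python
import numpy as np, pandas as pd, dcscan as d

# ground truth: 9 positions x 19 substitutions x 5 homologs, with positions
# {1,4,5,8} controlling the conformational equilibrium
land = d.make_truth_landscape(seed=7)
wt = land.table[(land.table.pos1 == 0) & (land.table.pos2 == 0)]
wt_kd = dict(zip(wt.homolog, wt.kd_true))

# calibration on 45 standards of known affinity
std = d.make_standards(45, noise_sd=0.1, seed=9)
params, report = d.fit_standard_curve(std)
print(f"a={params.a:.3f} L={params.l:.2e} identifiable={report['identifiable']}")

# one depth-1e7 sequencing experiment per homolog; QC-filter, calibrate,
# anchor each on its wild type
frames = []
for k, hom in enumerate(land.homologs):
    counts = d.simulate_selection_counts(
        land.table[land.table.homolog == hom], a=1.0, c=-5.0, l_free=1e-6,
        depth_unselected=10_000_000, depth_selected=10_000_000, seed=100 + k)
    filtered, qc = d.filter_counts(counts, min_unselected=10, min_selected=5)
    print(f"{hom}: cycle retention {100 * qc['cycle_retention']:.1f}%")
    frames.append(d.counts_to_energies(filtered, params, {hom: wt_kd[hom]}))
energies = pd.concat(frames, ignore_index=True)

ok = energies[energies.flag == "ok"].merge(
    land.table, on=["homolog", "pos1", "aa1", "pos2", "aa2"])
print(f"median |dG error|: "
      f"{np.median(np.abs(ok.dg_kcal_mol - ok.dg_true)):.3f} kcal/mol")

cycles = d.mutant_cycle_couplings(energies)
avg = d.homolog_average(cycles)
matrix = d.coupling_matrix(d.fit_pair_mixtures(avg, seed=0), 9)
print(f"collected {len(cycles)} cycles; strongest averaged couplings:")
iu, ju = np.triu_indices(9, 1)
for k in np.argsort(-np.abs(matrix[iu, ju]))[:7]:
    print(f"  pair {iu[k]+1}-{ju[k]+1}: {matrix[iu[k], ju[k]]:+.2f} kcal/mol")
```

Output:

```
a=0.985 L=9.22e-07 identifiable=True
H1: cycle retention 94.4%
H2: cycle retention 94.9%
H3: cycle retention 92.2%
H4: cycle retention 94.3%
H5: cycle retention 90.1%
median |dG error|: 0.059 kcal/mol
collected 60310 cycles; strongest averaged couplings:
  pair 4-5: +0.63 kcal/mol
  pair 5-8: +0.60 kcal/mol
  pair 1-5: +0.53 kcal/mol
  pair 4-8: +0.50 kcal/mol
  pair 1-4: +0.50 kcal/mol
  pair 1-8: +0.44 kcal/mol
  pair 1-3: +0.05 kcal/mol
```

Free energies are recovered to ~0.06 kcal/mol (median) with ~90-95% of the
64,980 possible mutant cycles surviving QC, and the six strongest
homolog-averaged couplings are exactly the six pairs among the planted
equilibrium-controlling positions {1, 4, 5, 8} — couplings are sparse,
confined to the positions that set the conformational equilibrium, conserved
across homologs, and an order of magnitude above the next pair.

The same analyses are available as a CLI (`dcscan simulate-selection`,
`calibrate`, `energies`, `couplings`, `average`, `mixtures`, `matrix`,
`simulate-regimes`, `sca`, `dca fit|energy|cycles|contacts|scramble`,
`compare`), each writing TSV/JSON/YAML plus a provenance sidecar.

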