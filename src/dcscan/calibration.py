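"""From read counts to calibrated binding free energies.

The selection assay enriches variants in proportion to their ligand occupancy.
For each variant x we form z_x = f_s/f_u (selected over unselected frequency)
and the relative enrichment dE_x = ln(z_x / sum_i z_i).  On the standard curve

    dE = a * ln(f_b) + C,      f_b = L / (L + K_d)

(a, C and the in-vivo free ligand concentration L are fitted to standards of
known K_d), enrichment inverts to a dissociation constant, and anchoring on
the known wild-type affinity removes the batch-specific offset, yielding
binding free energies dG = RT ln(K_d / K_d^wt) in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .equilibrium_model import RT

FLAG_OK = "ok"
FLAG_NO_UNSELECTED = "no_unselected"
FLAG_ZERO_SELECTED = "zero_selected"
FLAG_OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class CalibrationParams:
    """Standard-curve parameters: slope a, offset c, free ligand l (M)."""

    a: float
    c: float
    l: float
    rt: float = RT

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("slope a must be nonzero")
        if self.l <= 0:
            raise ValueError("free ligand concentration must be positive")

    def delta_e(self, kd) -> np.ndarray:
        """Standard curve: expected enrichment for given K_d."""
        kd = np.asarray(kd, dtype=float)
        return self.a * np.log(self.l / (self.l + kd)) + self.c


def relative_enrichment(counts: pd.DataFrame) -> pd.DataFrame:
    """Compute z = f_s/f_u and dE = ln(z / sum z) per variant.

    Variants with zero unselected counts are flagged and excluded from the
    normalizing sum; variants with zero selected counts get z = 0 (dE = -inf)
    and are flagged non-invertible.  Over unflagged + zero-selected variants,
    sum(exp(dE)) == 1.
    """
    cu = counts["count_unselected"].to_numpy(dtype=float)
    cs = counts["count_selected"].to_numpy(dtype=float)
    if cu.sum() == 0 or cs.sum() == 0:
        raise ValueError("all-zero count table")
    fu = cu / cu.sum()
    fs = cs / cs.sum()
    out = counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(cu > 0, fs / np.where(cu > 0, fu, 1.0), np.nan)
    zsum = np.nansum(z)
    with np.errstate(divide="ignore"):
        de = np.log(z / zsum)
    flag = np.full(len(counts), FLAG_OK, dtype=object)
    flag[cu == 0] = FLAG_NO_UNSELECTED
    flag[(cu > 0) & (cs == 0)] = FLAG_ZERO_SELECTED
    out["z"] = z
    out["delta_e"] = de
    out["flag"] = flag
    return out


def fit_standard_curve(
    standards: pd.DataFrame,
    l_grid: np.ndarray | None = None,
    min_fb_spread: float = 0.1,
) -> tuple[CalibrationParams, dict]:
    """Fit dE = a ln(L/(L+K_d)) + C to standards by least squares.

    For each candidate L on a log grid, (a, C) solve in closed form (the model
    is linear given L); the best grid point seeds a joint refinement over
    (a, C, ln L).  Returns the parameters and a report with residual SD and an
    identifiability flag (False when fitted occupancies barely vary or the
    slope is indistinguishable from zero, in which case a and C are
    confounded).
    """
    kd = standards["kd_molar"].to_numpy(dtype=float)
    de = standards["delta_e"].to_numpy(dtype=float)
    if len(kd) < 4:
        raise ValueError("need at least 4 standards")
    if l_grid is None:
        l_grid = np.logspace(-9, -3, 25)

    def lin_fit(l):
        x = np.log(l / (l + kd))
        X = np.column_stack([x, np.ones_like(x)])
        coef, res, *_ = np.linalg.lstsq(X, de, rcond=None)
        rss = float(((de - X @ coef) ** 2).sum())
        return coef, rss

    best = min(((lin_fit(l), l) for l in l_grid), key=lambda t: t[0][1])
    (a0, c0), _ = best[0]
    l0 = best[1]

    def resid(theta):
        a, c, lnl = theta
        l = np.exp(lnl)
        return a * np.log(l / (l + kd)) + c - de

    sol = least_squares(resid, [a0 if a0 != 0 else 1e-6, c0, np.log(l0)], method="lm")
    a, c, l = sol.x[0], sol.x[1], float(np.exp(sol.x[2]))
    n = len(kd)
    dof = max(n - 3, 1)
    residual_sd = float(np.sqrt((sol.fun**2).sum() / dof))
    fb = l / (l + kd)
    spread = float(np.log(fb).max() - np.log(fb).min())
    se_a = _slope_se(np.log(fb), residual_sd)
    identifiable = bool(spread > min_fb_spread and abs(a) > 3 * se_a)
    report = {
        "residual_sd": residual_sd,
        "identifiable": identifiable,
        "log_fb_spread": spread,
        "n": n,
    }
    if a == 0:
        a = 1e-12  # keep params constructible; flagged unidentifiable
        report["identifiable"] = False
    return CalibrationParams(a=float(a), c=float(c), l=l), report


def _slope_se(x: np.ndarray, residual_sd: float) -> float:
    sxx = float(((x - x.mean()) ** 2).sum())
    return residual_sd / np.sqrt(sxx) if sxx > 0 else np.inf


def anchor_to_wildtype(
    enrich: pd.DataFrame,
    wt_kd: dict | float,
    params: CalibrationParams,
) -> pd.DataFrame:
    """Shift dE so each homolog's wild type sits on the standard curve.

    ``wt_kd`` maps homolog name to the known wild-type dissociation constant
    (a scalar applies one global shift).  Idempotent: anchoring an anchored
    table is a no-op.
    """
    out = enrich.copy()
    is_wt = (out["pos1"] == 0) & (out["pos2"] == 0)
    if isinstance(wt_kd, dict):
        missing = set(out["homolog"].unique()) - set(wt_kd)
        if missing:
            raise ValueError(f"no wild-type K_d for homologs: {sorted(missing)}")
        groups = out.groupby("homolog").groups
        for hom, idx in groups.items():
            wt_rows = out.loc[idx][is_wt.loc[idx]]
            if wt_rows.empty or not np.isfinite(wt_rows["delta_e"]).any():
                raise ValueError(f"wild-type variant missing or unusable for {hom}")
            target = float(params.delta_e(wt_kd[hom]))
            shift = target - float(wt_rows["delta_e"].iloc[0])
            out.loc[idx, "delta_e"] = out.loc[idx, "delta_e"] + shift
    else:
        wt_rows = out[is_wt]
        if wt_rows.empty:
            raise ValueError("wild-type variant missing")
        target = float(params.delta_e(wt_kd))
        out["delta_e"] = out["delta_e"] + (target - float(wt_rows["delta_e"].iloc[0]))
    return out


def enrichment_to_energy(
    enrich: pd.DataFrame,
    params: CalibrationParams,
    wt_kd: dict | float,
) -> pd.DataFrame:
    """Invert anchored enrichments to K_d and dG_bind (kcal/mol vs wild type).

    f_b = exp((dE - C)/a) must fall in (0, 1) to invert; variants outside the
    validated occupancy range are flagged rather than assigned a number.
    """
    out = enrich.copy()
    de = out["delta_e"].to_numpy(dtype=float)
    with np.errstate(over="ignore"):
        fb = np.exp((de - params.c) / params.a)
    ok = np.isfinite(fb) & (fb > 0) & (fb < 1)
    kd = np.where(ok, params.l * (1.0 - fb) / np.where(ok, fb, 1.0), np.nan)
    if isinstance(wt_kd, dict):
        kd_wt = out["homolog"].map(wt_kd).to_numpy(dtype=float)
    else:
        kd_wt = float(wt_kd)
    with np.errstate(invalid="ignore", divide="ignore"):
        dg = params.rt * np.log(kd / kd_wt)
    flag = out["flag"].to_numpy(dtype=object).copy() if "flag" in out else np.full(len(out), FLAG_OK, dtype=object)
    flag[(flag == FLAG_OK) & ~ok] = FLAG_OUT_OF_RANGE
    out["fraction_bound"] = fb
    out["kd_molar"] = kd
    out["dg_kcal_mol"] = dg
    out["flag"] = flag
    return out


def counts_to_energies(
    counts: pd.DataFrame,
    params: CalibrationParams,
    wt_kd: dict | float,
) -> pd.DataFrame:
    """Convenience pipeline: enrichment -> anchoring -> energies."""
    enrich = relative_enrichment(counts)
    anchored = anchor_to_wildtype(enrich, wt_kd, params)
    return enrichment_to_energy(anchored, params, wt_kd)
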