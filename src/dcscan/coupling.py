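"""Thermodynamic double-mutant cycles and their homolog-averaged distributions.

For mutations x at position i and y at position j, the coupling free energy is

    ddG_ij^xy = (dG_i^x + dG_j^y) - dG_ij^xy

— the deviation of the double mutant from additivity of its constituent
singles.  A cycle requires four measurements (wild type, both singles, the
double), so quality filtering is propagated through that dependency: a cycle
survives only if all four variants pass the read-count thresholds.  Averaging
each mutation pair's coupling across homologs suppresses idiosyncratic
(homolog-specific) couplings while preserving conserved ones.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .calibration import FLAG_OK


def _is_wt(df: pd.DataFrame) -> pd.Series:
    return (df["pos1"] == 0) & (df["pos2"] == 0)


def _is_single(df: pd.DataFrame) -> pd.Series:
    return (df["pos1"] > 0) & (df["pos2"] == 0)


def _is_double(df: pd.DataFrame) -> pd.Series:
    return (df["pos1"] > 0) & (df["pos2"] > 0)


def filter_counts(
    counts: pd.DataFrame,
    min_unselected: int = 10,
    min_selected: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Drop variants below read-count thresholds; report retained cycles.

    A variant passes if count_unselected >= min_unselected and count_selected
    >= min_selected.  The retention report counts the double-mutant cycles
    whose double, both singles, and wild type all pass, as a fraction of all
    doubles present in the table.
    """
    if min_unselected < 0 or min_selected < 0:
        raise ValueError("thresholds must be non-negative")
    passes = (counts["count_unselected"] >= min_unselected) & (
        counts["count_selected"] >= min_selected
    )
    filtered = counts[passes].reset_index(drop=True)

    singles = counts[_is_single(counts) & passes]
    single_pass = set(zip(singles["homolog"], singles["pos1"], singles["aa1"]))
    wt_pass = set(counts.loc[_is_wt(counts) & passes, "homolog"])
    doubles = counts[_is_double(counts)]
    dbl_pass = passes[doubles.index].to_numpy()
    ok_first = [
        (h, p, a) in single_pass
        for h, p, a in zip(doubles["homolog"], doubles["pos1"], doubles["aa1"])
    ]
    ok_second = [
        (h, p, a) in single_pass
        for h, p, a in zip(doubles["homolog"], doubles["pos2"], doubles["aa2"])
    ]
    ok_wt = doubles["homolog"].isin(wt_pass).to_numpy()
    retained = dbl_pass & np.array(ok_first) & np.array(ok_second) & ok_wt
    n_possible = len(doubles)
    report = {
        "min_unselected": min_unselected,
        "min_selected": min_selected,
        "variants_retained": int(passes.sum()),
        "variants_total": int(len(counts)),
        "cycles_retained": int(retained.sum()),
        "cycles_possible": n_possible,
        "cycle_retention": float(retained.sum() / n_possible) if n_possible else float("nan"),
    }
    return filtered, report


def retention_summary(collected_cycles: int, possible_cycles: int, n_pair_homologs: int) -> dict:
    """Summary arithmetic for a cycle-collection campaign.

    E.g. 56,694 collected of 64,980 possible over 36 pairs x 5 homologs gives
    a mean of ~315 cycles per pair-homolog and ~87% retention.
    """
    return {
        "collected_cycles": collected_cycles,
        "possible_cycles": possible_cycles,
        "mean_cycles_per_pair_homolog": collected_cycles / n_pair_homologs,
        "retention_percent": 100.0 * collected_cycles / possible_cycles,
    }


def mutant_cycle_couplings(energies: pd.DataFrame, require_ok: bool = True) -> pd.DataFrame:
    """All double-mutant-cycle couplings from a variant energy table.

    Emits one row per cycle: homolog, pos_i < pos_j, mutations aa_x, aa_y and
    ddg = (dG_i^x + dG_j^y) - dG_ij^xy (kcal/mol).  Cycles are emitted only
    when the double and both singles are present (and unflagged when
    ``require_ok``).
    """
    df = energies
    if not _is_wt(df).any():
        raise ValueError("energy table has no wild-type rows")
    if require_ok and "flag" in df:
        df = df[df["flag"] == FLAG_OK]
    singles = df[_is_single(df)][["homolog", "pos1", "aa1", "dg_kcal_mol"]]
    doubles = df[_is_double(df)][["homolog", "pos1", "aa1", "pos2", "aa2", "dg_kcal_mol"]]
    merged = doubles.rename(columns={"dg_kcal_mol": "dg_double"}).merge(
        singles.rename(columns={"dg_kcal_mol": "dg_x"}), on=["homolog", "pos1", "aa1"]
    )
    merged = merged.merge(
        singles.rename(columns={"pos1": "pos2", "aa1": "aa2", "dg_kcal_mol": "dg_y"}),
        on=["homolog", "pos2", "aa2"],
    )
    out = pd.DataFrame(
        {
            "homolog": merged["homolog"],
            "pos_i": merged["pos1"],
            "pos_j": merged["pos2"],
            "aa_x": merged["aa1"],
            "aa_y": merged["aa2"],
            "ddg": (merged["dg_x"] + merged["dg_y"]) - merged["dg_double"],
        }
    )
    return out[np.isfinite(out["ddg"])].reset_index(drop=True)


def homolog_average(couplings: pd.DataFrame, min_homologs: int | None = None) -> pd.DataFrame:
    """Average each (pos_i, pos_j, aa_x, aa_y) coupling across homologs.

    Mutation pairs present in fewer than ``min_homologs`` homologs are dropped
    (default: must be present in every homolog in the table — the strict
    intersection, which avoids composition bias between position pairs).
    """
    n_hom = couplings["homolog"].nunique()
    if min_homologs is None:
        min_homologs = n_hom
    g = couplings.groupby(["pos_i", "pos_j", "aa_x", "aa_y"])["ddg"].agg(["mean", "count"])
    g = g[g["count"] >= min_homologs].reset_index()
    if g.empty:
        raise ValueError("no mutation pairs shared by enough homologs")
    g.insert(0, "homolog", "averaged")
    g = g.rename(columns={"mean": "ddg", "count": "n_homologs"})
    return g


def couplings_by_pair(couplings: pd.DataFrame):
    """Iterate (pos_i, pos_j) -> ddg value arrays, homologs pooled."""
    for (i, j), grp in couplings.groupby(["pos_i", "pos_j"]):
        yield (int(i), int(j)), grp["ddg"].to_numpy()
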