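import warnings

import numpy as np
import pandas as pd
import pytest

from dcscan import (
    EquilibriumParams,
    LandscapeConfig,
    LibraryDesign,
    make_truth_landscape,
)

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_design():
    return LibraryDesign(n_positions=4, n_substitutions=3, n_homologs=2)


@pytest.fixture(scope="session")
def small_landscape(small_design):
    """Small truth landscape with one Kc-sensitive pair, reused across tests."""
    return make_truth_landscape(
        design=small_design,
        wt_params=EquilibriumParams(),
        kc_sensitive_positions=(1, 4),
        config=LandscapeConfig(),
        seed=11,
    )


@pytest.fixture(scope="session")
def paper_landscape():
    """Full-scale landscape (9 positions, 19 subs, 5 homologs)."""
    return make_truth_landscape(seed=7)


def energies_from_truth(table: pd.DataFrame) -> pd.DataFrame:
    """Treat true free energies as a measured energy table (no noise)."""
    out = table.rename(columns={"dg_true": "dg_kcal_mol"}).copy()
    out["flag"] = "ok"
    return out
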