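import numpy as np
import pandas as pd
import pytest

from irquant import panel
from irquant.synthetic import generate_nmr_cohort


@pytest.fixture(scope="session")
def assignments():
    return panel.default_assignments()


@pytest.fixture(scope="session")
def folds_24h():
    return panel.planted_fold_table("24h")


@pytest.fixture(scope="session")
def nmr_cohort(assignments, folds_24h):
    """One seeded 4x8 cohort shared by the NMR tests (read-only)."""
    return generate_nmr_cohort(8, assignments, folds_24h, seed=42)


@pytest.fixture()
def unit_folds(assignments):
    """All-ones fold table over the default panel."""
    mets = [a.name for a in assignments]
    return pd.DataFrame(
        1.0,
        index=mets,
        columns=["veh_sham_vs_veh_IR", "SCN_sham_vs_SCN_IR", "veh_IR_vs_SCN_IR"],
    )


@pytest.fixture(scope="session")
def echo_effects():
    rows = []
    for g in ("vehicle/sham", "vehicle/IR", "SCN/sham", "SCN/IR"):
        for site in ("base", "mid", "apex"):
            for tp in ("pre", "48h", "1w", "2w", "4w"):
                rows.append(dict(group=g, site=site, timepoint=tp, lvd_mm=8.0, lvs_mm=4.5))
    return pd.DataFrame(rows)
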