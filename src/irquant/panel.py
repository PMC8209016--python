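"""Default serum metabolite panel for 1H-NMR quantification.

24 endogenous serum metabolites with their assigned chemical shifts, plus
example between-group effect sizes (fold changes for the three standard
comparisons) at the two study timepoints.  The effect columns are used by the
synthetic cohort generator as default planted truths for parameter-recovery
testing; the shift column drives fixed-window quantification.

Comparison naming: ``fold_change = mean(second arm) / mean(first arm)``, i.e.
``veh_sham_vs_veh_IR`` is the vehicle-IR mean relative to the vehicle-sham
mean.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import MetaboliteAssignment

COMPARISONS = (
    "veh_sham_vs_veh_IR",
    "SCN_sham_vs_SCN_IR",
    "veh_IR_vs_SCN_IR",
)

# name, shift (ppm), 24 h folds (3 comparisons), 4 w folds (3 comparisons)
_PANEL = [
    ("Formate", 8.52, 0.95, 1.41, 1.02, 0.76, 1.00, 0.84),
    ("Cytidine", 7.80, 0.93, 0.97, 0.96, 0.85, 0.93, 0.91),
    ("Methylhistidine", 7.74, 0.88, 1.08, 0.95, 0.94, 0.86, 1.02),
    ("Histidine", 7.71, 0.98, 1.07, 1.08, 0.84, 0.82, 0.97),
    ("Phenylalanine", 7.40, 0.82, 1.09, 0.94, 0.99, 0.96, 1.02),
    ("Tyrosine", 7.17, 0.89, 1.05, 0.96, 0.82, 0.92, 0.90),
    ("Lactate", 4.11, 1.01, 1.01, 1.11, 1.05, 1.05, 1.07),
    ("Isoleucine", 3.65, 0.95, 0.99, 0.99, 0.96, 0.92, 1.08),
    ("Creatinine/creatine phosphate", 3.03, 0.94, 1.13, 0.95, 0.85, 0.90, 0.90),
    ("Creatine", 3.00, 0.95, 1.08, 0.95, 0.82, 0.88, 0.91),
    ("Trimethylamine", 2.91, 1.02, 1.06, 1.00, 0.88, 0.98, 0.92),
    ("Methylguanidine", 2.81, 1.08, 1.07, 0.97, 1.01, 0.96, 1.05),
    ("Methionine", 2.64, 0.95, 1.07, 0.98, 0.95, 0.97, 0.97),
    ("Glutamine", 2.46, 0.98, 1.15, 1.00, 0.91, 0.95, 0.94),
    ("Acetoacetate", 2.22, 1.18, 0.84, 1.05, 1.08, 1.16, 0.96),
    ("Acetyl groups (1)", 2.13, 0.96, 1.07, 0.98, 0.92, 0.95, 0.93),
    ("Acetyl groups (2)", 2.06, 1.01, 1.02, 1.03, 0.95, 0.98, 0.95),
    ("Acetate", 1.91, 0.83, 0.89, 0.95, 1.26, 0.96, 1.09),
    ("Leucine", 1.72, 0.95, 1.09, 0.97, 0.89, 0.90, 0.95),
    ("Lipids (VLDL)", 1.57, 1.23, 0.82, 1.04, 1.08, 1.17, 0.96),
    ("Alanine", 1.47, 0.98, 1.08, 1.04, 0.94, 0.92, 0.95),
    ("Hydroxyisobutyrate", 1.08, 1.02, 1.03, 0.99, 1.00, 0.93, 1.02),
    ("Valine", 1.03, 0.90, 1.02, 0.99, 0.99, 0.98, 1.00),
    ("Lipids (LDL)", 0.87, 1.04, 0.96, 1.00, 1.02, 1.05, 0.97),
]


def panel_table() -> pd.DataFrame:
    """Full panel as a DataFrame (one row per metabolite, shift order)."""
    return pd.DataFrame(
        _PANEL,
        columns=["metabolite", "shift_ppm"]
        + [f"{c}_24h" for c in COMPARISONS]
        + [f"{c}_4w" for c in COMPARISONS],
    )


def default_assignments(window_halfwidth_ppm: float = 0.02) -> list[MetaboliteAssignment]:
    """Panel as :class:`MetaboliteAssignment` objects, descending shift order."""
    return [
        MetaboliteAssignment(row[0], row[1], window_halfwidth_ppm) for row in _PANEL
    ]


def planted_fold_table(timepoint: str = "24h") -> pd.DataFrame:
    """Per-metabolite fold-change table for one timepoint.

    Returns a DataFrame indexed by metabolite name with the three comparison
    columns of :data:`COMPARISONS`.
    """
    if timepoint not in ("24h", "4w"):
        raise ValueError("timepoint must be '24h' or '4w'")
    tab = panel_table().set_index("metabolite")
    cols = {f"{c}_{timepoint}": c for c in COMPARISONS}
    return tab[list(cols)].rename(columns=cols)
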