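"""Reporter-assay arithmetic: luciferase fold activation and beta-gal Units.

Luciferase: within each independent experiment the triplicate readings of a
construct are averaged and divided by that experiment's empty-vector control
mean (control = 1.0); per-construct folds are then averaged over experiments
and reported with SE = s / sqrt(n_experiments), s the sample (n-1) standard
deviation of the per-experiment folds.

beta-galactosidase:  Units = 1000 * OD415 / (V * t * OD595)
with V the volume of cells used (ml) and t the reaction time (min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

LUCIFERASE_COLUMNS = ["construct", "experiment", "replicate", "reading", "is_control"]
BETAGAL_COLUMNS = ["construct", "od415", "od595", "v_ml", "t_min"]


@dataclass
class FoldActivation:
    construct: str
    fold: float
    se: float
    n_experiments: int


def fold_activation(assays: pd.DataFrame) -> pd.DataFrame:
    """Per-construct fold over the empty-vector control, with SE.

    ``assays`` is a long table with columns (construct, experiment,
    replicate, reading, is_control); each experiment must contain control
    readings with a positive mean.
    """
    missing = set(LUCIFERASE_COLUMNS) - set(assays.columns)
    if missing:
        raise ValueError(f"luciferase table missing columns: {sorted(missing)}")
    if (assays["reading"] < 0).any():
        raise ValueError("luminescence readings must be non-negative")
    controls = assays[assays["is_control"].astype(bool)]
    control_means = controls.groupby("experiment")["reading"].mean()
    experiments = assays["experiment"].unique()
    absent = set(experiments) - set(control_means.index)
    if absent:
        raise ValueError(f"experiments without a control: {sorted(absent)}")
    if (control_means <= 0).any():
        raise ValueError("control mean must be positive in every experiment")

    means = assays.groupby(["construct", "experiment"])["reading"].mean()
    folds = means / control_means.reindex(means.index.get_level_values("experiment")).values
    rows = []
    for construct, per_exp in folds.groupby("construct"):
        vals = per_exp.to_numpy(dtype=float)
        n = len(vals)
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(FoldActivation(construct, float(vals.mean()), se, n))
    return pd.DataFrame([vars(r) for r in rows]).sort_values("construct").reset_index(drop=True)


def beta_gal_units(od415, od595, v_ml, t_min):
    """Units = 1000 * OD415 / (V * t * OD595); accepts scalars or arrays."""
    od415 = np.asarray(od415, dtype=float)
    od595 = np.asarray(od595, dtype=float)
    v_ml = np.asarray(v_ml, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    if np.any(od415 < 0):
        raise ValueError("OD415 must be non-negative")
    if np.any(od595 <= 0) or np.any(v_ml <= 0) or np.any(t_min <= 0):
        raise ValueError("OD595, V and t must be positive")
    units = 1000.0 * od415 / (v_ml * t_min * od595)
    return float(units) if units.ndim == 0 else units


def beta_gal_table(assays: pd.DataFrame) -> pd.DataFrame:
    """Units per row of a (construct, od415, od595, v_ml, t_min) table."""
    missing = set(BETAGAL_COLUMNS) - set(assays.columns)
    if missing:
        raise ValueError(f"beta-gal table missing columns: {sorted(missing)}")
    out = assays.copy()
    out["units"] = beta_gal_units(assays["od415"], assays["od595"],
                                  assays["v_ml"], assays["t_min"])
    return out


def summarize_units(units_table: pd.DataFrame) -> pd.DataFrame:
    """Average Units per construct with SE over samples."""
    rows = []
    for construct, grp in units_table.groupby("construct"):
        vals = grp["units"].to_numpy(dtype=float)
        n = len(vals)
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append({"construct": construct, "units": float(vals.mean()),
                     "se": se, "n": n})
    return pd.DataFrame(rows)
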