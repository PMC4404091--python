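"""Cohort demographics from the study metadata sheet.

The packaged ``table1.csv`` transcribes the study's subject sheet: per
aneurysm an age, sex, location, caliper size "height x width" in mm, rupture
status, follow-up interval in months and cohort label.  The clinically
measured sac size is the larger caliper.  The analysis unit is the aneurysm;
rows sharing age, sex and follow-up interval are treated as one patient for
per-patient follow-up means.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .metrics import clinical_size
from .stats import mann_whitney_one_tailed, roc

REQUIRED_COLUMNS = (
    "subject", "age", "sex", "location", "size_mm", "ruptured",
    "followup_months", "cohort",
)


def load_table1() -> pd.DataFrame:
    """The packaged study demographics sheet."""
    with resources.files("coilwatch.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def parse_size(size: str) -> float:
    """'26x17' -> clinical size 26.0 (mm, largest caliper)."""
    try:
        h, w = (float(part) for part in str(size).lower().split("x"))
    except ValueError as err:
        raise ValueError(f"malformed size field {size!r}; expected 'HxW'") from err
    return clinical_size(h, w)


def validate_cohort_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata sheet is missing columns: {missing}")
    bad = []
    for _, row in table.iterrows():
        try:
            parse_size(row["size_mm"])
        except ValueError:
            bad.append(str(row["subject"]))
        if not row["followup_months"] > 0:
            bad.append(str(row["subject"]))
    if bad:
        raise ValueError(f"malformed rows for subjects: {sorted(set(bad))}")


def demographics_summary(table: pd.DataFrame) -> dict:
    """Per-cohort counts, clinical sizes and follow-up intervals.

    Returns a dict with one entry per cohort (n aneurysms, n patients,
    median/min/max clinical size, count of aneurysms >= 10 mm, mean follow-up
    per aneurysm and per patient) plus the two-sided Mann-Whitney p for the
    between-cohort size difference and the ROC AUC of clinical size as a
    recurrence predictor.
    """
    validate_cohort_table(table)
    table = table.copy()
    table["clinical_size_mm"] = table["size_mm"].map(parse_size)

    out: dict = {}
    for cohort, grp in table.groupby("cohort"):
        patients = grp.drop_duplicates(subset=["age", "sex", "followup_months"])
        sizes = grp["clinical_size_mm"].to_numpy()
        out[cohort] = {
            "n_aneurysms": int(len(grp)),
            "n_patients": int(len(patients)),
            "median_size_mm": float(np.median(sizes)),
            "min_size_mm": float(sizes.min()),
            "max_size_mm": float(sizes.max()),
            "n_size_ge_10mm": int((sizes >= 10).sum()),
            "mean_followup_months_per_aneurysm": float(grp["followup_months"].mean()),
            "mean_followup_months_per_patient": float(patients["followup_months"].mean()),
        }

    cohorts = set(table["cohort"])
    if {"recurrence", "control"} <= cohorts:
        rec = table.loc[table["cohort"] == "recurrence", "clinical_size_mm"]
        ctl = table.loc[table["cohort"] == "control", "clinical_size_mm"]
        _, p = mann_whitney_one_tailed(rec, ctl, alternative="two-sided")
        out["size_mannwhitney_two_sided_p"] = float(p)
        size_roc = roc(
            table["clinical_size_mm"].to_numpy(),
            (table["cohort"] == "recurrence").to_numpy(),
        )
        out["size_roc_auc"] = size_roc.auc
        out["size_roc_optimal_threshold_mm"] = size_roc.optimal_threshold
    return out
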