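"""Quadrat-based skin morphometry summaries.

Hair-follicle phenotypes are quantified on stained skin sections by
counting hairs, measuring pilary-canal diameters and the total area
covered by pilary canals within 1-mm^2 quadrats, for an affected animal
and a control.  This module computes per-group means at the precision
the measurements are reported with (one decimal for counts and
diameters, whole square micrometres for areas) and case/control fold
changes.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from ._util import round_half_up

__all__ = ["load_quadrats", "group_summary", "fold_changes"]

REQUIRED = ["group", "quadrat_id", "hair_count", "mean_diameter_um",
            "total_area_um2"]
GROUPS = ("control", "affected")


def load_quadrats(path) -> pd.DataFrame:
    """Read a quadrat measurement table from delimited text."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return validate_quadrats(df)


def validate_quadrats(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"quadrat table missing columns {missing}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}")
    if (df["hair_count"] < 0).any():
        raise ValueError("negative hair counts")
    if (df["mean_diameter_um"] <= 0).any() or (df["total_area_um2"] <= 0).any():
        raise ValueError("diameters and areas must be positive")
    return df


def group_summary(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Per-group means at the printed precision.

    Returns, for each group present, ``mean_hair_count`` and
    ``mean_diameter_um`` rounded half-up to one decimal and
    ``mean_total_area_um2`` rounded half-up to an integer, plus the
    unrounded means under ``raw_*`` keys.
    """
    df = validate_quadrats(table)
    out: dict[str, dict[str, float]] = {}
    for group, sub in df.groupby("group"):
        if sub.empty:
            raise ValueError(f"empty group {group!r}")
        hair = float(sub["hair_count"].mean())
        diam = float(sub["mean_diameter_um"].mean())
        area = float(sub["total_area_um2"].mean())
        out[group] = {
            "mean_hair_count": round_half_up(hair, 1),
            "mean_diameter_um": round_half_up(diam, 1),
            "mean_total_area_um2": round_half_up(area, 0),
            "raw_mean_hair_count": hair,
            "raw_mean_diameter_um": diam,
            "raw_mean_total_area_um2": area,
            "n_quadrats": int(len(sub)),
        }
    return out


def fold_changes(summary: Mapping[str, Mapping[str, float]]) -> dict:
    """Affected/control fold changes from a :func:`group_summary` result.

    Hair count increases in the affected animal, so its fold is
    affected/control; pilary-canal diameter decreases, so that fold is
    reported as control/affected ("n times smaller").  Folds are computed
    from the printed-precision means and reported both to one decimal
    and as nearest-integer folds.
    """
    for g in GROUPS:
        if g not in summary:
            raise ValueError(f"missing group {g!r} in summary")
    aff, ctl = summary["affected"], summary["control"]
    if ctl["mean_hair_count"] == 0 or aff["mean_diameter_um"] == 0:
        raise ValueError("zero denominator in fold change")
    hair_fold = aff["mean_hair_count"] / ctl["mean_hair_count"]
    diam_fold = ctl["mean_diameter_um"] / aff["mean_diameter_um"]
    return {
        "hair_count_fold": round_half_up(hair_fold, 1),
        "diameter_fold": round_half_up(diam_fold, 1),
        "hair_count_fold_int": int(round_half_up(hair_fold, 0)),
        "diameter_fold_int": int(round_half_up(diam_fold, 0)),
    }
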