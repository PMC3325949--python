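"""Measurement conventions and derived retinal-layer features.

The manually segmented layers (RGC+IPL, INL, OPL) are measured at the
nasal and temporal thickest points of the macula and summarized as their
arithmetic mean; the outer nuclear layer has a single central thickest
point (or, rarely, nasal and temporal maxima, in which case the higher
value is used).  From these, two dimensionless ratios are derived:
ONL/OPL and INL/OPL, both against the mean OPL.  The ONL/OPL ratio is
the basis of the PSP screening rule.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import Cohort, subject_eye_means
from .params_table import PANEL_FIELDS

#: Derived columns added on top of the per-eye panel aggregates.
DERIVED_FEATURES = ("mean_rgc_ipl", "mean_inl", "mean_opl", "onl",
                    "ratio_onl_opl", "ratio_inl_opl")

FEATURE_COLUMNS = ("subject_id", "group") + DERIVED_FEATURES + PANEL_FIELDS


def layer_mean_nasal_temporal(nasal: float, temporal: float) -> float:
    """Mean of the nasal and temporal thickest-point measurements (µm).

    If either side is missing the result is missing (NaN): a one-sided
    measurement is not a valid layer summary under this convention.
    """
    if math.isnan(nasal) or math.isnan(temporal):
        return math.nan
    return (nasal + temporal) / 2.0


def onl_value(central: float = math.nan, nasal_max: float = math.nan,
              temporal_max: float = math.nan) -> float:
    """ONL thickness under the central-maximum convention (µm).

    Most subjects show a single central thickest point, whose value is
    used directly.  For the few with distinct nasal and temporal maxima,
    the higher of the two is used.
    """
    if not math.isnan(central):
        return central
    vals = [v for v in (nasal_max, temporal_max) if not math.isnan(v)]
    return max(vals) if vals else math.nan


def ratio(numerator: float, denominator: float) -> float:
    """Thickness ratio; missing (never infinite) if denominator ≤ 0 or NaN."""
    if math.isnan(numerator) or math.isnan(denominator) or denominator <= 0:
        return math.nan
    return numerator / denominator


def build_feature_table(cohort: Cohort,
                        eye_handling: str = "subject_means",
                        opl_for_ratio: str = "mean") -> pd.DataFrame:
    """Per-subject (or per-eye) feature table for a QC-passed cohort.

    Parameters
    ----------
    cohort : Cohort
        Cohort after :func:`~parkoct.cohort.qc_filter`.
    eye_handling : {"subject_means", "duplicates"}
        ``subject_means`` (default) averages the two eyes before deriving
        features — one row per subject, the convention used for
        classification and figures.  ``duplicates`` keeps both eyes as
        statistically dependent rows, the convention of the study's group
        statistics; rows then carry an extra ``side`` column.
    opl_for_ratio : {"mean", "nasal"}
        Denominator of the ONL/OPL and INL/OPL ratios.  ``mean`` (the
        nasal/temporal mean) is the default convention; ``nasal`` is the
        alternative of interest because the nasal OPL is the component
        thickened in PSP.

    Missingness propagates only into dependent fields: a subject missing
    both OPL measurements has missing ratios but intact layer means.
    """
    if eye_handling == "subject_means":
        base = subject_eye_means(cohort)
    elif eye_handling == "duplicates":
        base = cohort.eyes.merge(
            cohort.subjects.loc[:, ["subject_id", "group"]],
            on="subject_id", how="left")
        cols = ["subject_id", "group", "side"] + list(PANEL_FIELDS)
        base = base.loc[:, cols]
    else:
        raise ValueError(f"unknown eye_handling={eye_handling!r}")

    if opl_for_ratio not in ("mean", "nasal"):
        raise ValueError(f"unknown opl_for_ratio={opl_for_ratio!r}")

    out = base.copy()
    out["mean_rgc_ipl"] = _pairmean(base, "rgc_ipl_nasal", "rgc_ipl_temporal")
    out["mean_inl"] = _pairmean(base, "inl_nasal", "inl_temporal")
    out["mean_opl"] = _pairmean(base, "opl_nasal", "opl_temporal")
    out["onl"] = base["onl_central"]
    denom = out["mean_opl"] if opl_for_ratio == "mean" else base["opl_nasal"]
    out["ratio_onl_opl"] = _vratio(out["onl"], denom)
    out["ratio_inl_opl"] = _vratio(out["mean_inl"], denom)

    lead = ["subject_id", "group"] + (
        ["side"] if eye_handling == "duplicates" else [])
    cols = lead + list(DERIVED_FEATURES) + list(PANEL_FIELDS)
    return out.loc[:, cols]


def percent_reduction(reference: float, value: float) -> float:
    """Percentage reduction of ``value`` relative to ``reference``.

    E.g. a group mean thickness against the control mean; positive when
    the group is thinner than the reference.
    """
    if reference <= 0:
        return math.nan
    return 100.0 * (reference - value) / reference


def _pairmean(df: pd.DataFrame, a: str, b: str) -> pd.Series:
    va, vb = df[a], df[b]
    out = (va + vb) / 2.0
    return out.where(va.notna() & vb.notna(), np.nan)


def _vratio(num: pd.Series, den: pd.Series) -> pd.Series:
    ok = num.notna() & den.notna() & (den > 0)
    return (num / den).where(ok, np.nan)
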