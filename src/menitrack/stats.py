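"""Zonal summaries and one-way ANOVA across regions."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .parcellation import Parcellation

_METRICS = ("fa", "md", "ad", "rd")


def zonal_summary(maps, parcellation: Parcellation) -> pd.DataFrame:
    """Per-region volume fraction and mean ± sd of each scalar map.

    Volume fraction is the label's voxel share of the whole mask, percent;
    fractions over one parcellation sum to 100.  The sd is the sample
    (n−1) standard deviation.  Empty labels yield NaN rows with a warning.
    """
    labels = parcellation.labels
    total = int(np.count_nonzero(labels > 0))
    rows = []
    for code in parcellation.codes:
        sel = labels == code
        n = int(np.count_nonzero(sel))
        entry = parcellation.table[code]
        row = {
            "label": code,
            "zone": entry.get("zone"),
            "part": entry.get("part"),
            "n_voxels": n,
            "volume_pct": 100.0 * n / total if total else np.nan,
        }
        if n == 0:
            warnings.warn(f"label {code} is empty; summary row is NaN")
        for metric in _METRICS:
            vals = np.asarray(getattr(maps, metric))[sel]
            vals = vals[np.isfinite(vals)]
            row[f"{metric}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{metric}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def one_way_anova(groups) -> tuple:
    """One-way fixed-effects ANOVA: (F statistic, p value).

    F = (SSB/dfB)/(SSW/dfW), dfB = k−1, dfW = N−k; p from the upper tail
    of the F distribution.  All-constant data (zero between and within
    variance) yields F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def voxelwise_zone_anova(maps, parcellation: Parcellation, metric: str = "fa") -> tuple:
    """Pooled voxelwise ANOVA of one metric across region labels.

    Anti-conservative: voxels within a region are not independent; prefer
    per-specimen means (``one_way_anova`` over specimen-level summaries)
    when several specimens are available.
    """
    vol = np.asarray(getattr(maps, metric))
    groups = []
    for code in parcellation.codes:
        vals = vol[parcellation.labels == code]
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            groups.append(vals)
    return one_way_anova(groups)


def percent_change(reference: float, value: float) -> float:
    """Relative change from reference to value, percent of |reference|."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return (value - reference) / abs(reference) * 100.0
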