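"""Community-weighted ecological indicator values.

A plot's weighted indicator value is Σ(r_ij·x_i)/Σr_ij over the species
present in the plot, where r_ij is the ordinal cover score (abundance
scale 1–5) and x_i the species' indicator value.  Species with a missing
indicator value are dropped pairwise per indicator; the Phosphorus
indicator is read but excluded from default reports (it is strongly
collinear with Nitrogen in the source indicator system).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from floodmeadow.community import CoverMatrix
from floodmeadow.io import INDICATOR_NAMES, GroupAssignment, ValidationError


def weighted_indicator(cover_row: pd.Series, indicator: pd.Series) -> float:
    """Abundance-weighted mean indicator value for one plot.

    Returns NaN when no present species carries a known indicator value.
    """
    r = cover_row.astype(float)
    x = indicator.reindex(r.index)
    usable = (r > 0) & x.notna()
    if not usable.any():
        return float("nan")
    rw = r[usable]
    return float((rw * x[usable]).sum() / rw.sum())


def weighted_indicator_table(
    cover: CoverMatrix,
    indicator_table: pd.DataFrame,
    indicators: tuple[str, ...] = INDICATOR_NAMES,
) -> pd.DataFrame:
    """Long table of weighted indicator values for every plot × indicator."""
    rows = []
    for name in indicators:
        if name not in indicator_table.columns:
            raise ValidationError(f"indicator {name!r} missing from table")
        col = indicator_table[name]
        for plot_id, cover_row in cover.scores.iterrows():
            usable = int(((cover_row > 0) & col.reindex(cover_row.index).notna()).sum())
            rows.append(
                {
                    "plot_id": plot_id,
                    "survey_year": cover.survey_year,
                    "indicator": name,
                    "value": weighted_indicator(cover_row, col),
                    "n_species_used": usable,
                }
            )
    return pd.DataFrame(rows)


def indicator_trajectories(
    weighted: pd.DataFrame, grouping: GroupAssignment
) -> pd.DataFrame:
    """Group means ± standard errors per (group, survey, indicator).

    s.e. = sample s.d./√n; a group of size 1 yields NaN s.e. (flagged via
    the n column).
    """
    df = weighted.copy()
    missing = [p for p in df["plot_id"].unique() if p not in grouping.labels]
    if missing:
        raise ValidationError(f"ungrouped plots: {missing[:5]}")
    df["group"] = [grouping.labels[p] for p in df["plot_id"]]
    df = df.dropna(subset=["value"])
    out = (
        df.groupby(["group", "survey_year", "indicator"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def indicator_correlation_screen(
    indicator_table: pd.DataFrame, pair: tuple[str, str]
) -> float:
    """Pearson correlation of two indicators over species carrying both.

    Returns NaN when either indicator is constant over the shared species.
    """
    a, b = pair
    sub = indicator_table[[a, b]].dropna()
    if len(sub) < 3:
        raise ValidationError(f"fewer than 3 species share {a!r} and {b!r}")
    x = sub[a].to_numpy(dtype=float)
    y = sub[b].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
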