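"""Climate and habitat predictors from tabular per-site records.

Covers the ecological side of the analysis: iterative pruning of
inter-correlated bioclim variables, NDVI monthly maximum-value
composites with quality-flag filtering, species summer-NDVI means,
mid-range dichotomization into high/low greenness classes, and
majority-vote classification of the predominant calling substrate
(arboreal vs shrubby).  Raster extraction is out of scope: all
operations consume per-site value tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "prune_correlated_variables", "monthly_max_composite",
    "species_summer_ndvi", "dichotomize_midrange", "classify_calling_site",
]

SUMMER_MONTHS = (6, 7, 8)


def prune_correlated_variables(table: pd.DataFrame, threshold: float = 0.75
                               ) -> list[str]:
    """Iteratively drop the variable with the most |Pearson r| > threshold
    partners until no pair exceeds the threshold.

    Tie-break: among equally connected variables, drop the one with the
    larger mean |r| to the others; remaining ties fall back to input
    order.  Constant variables (undefined correlation) are removed
    first with a warning.  Survivors are returned in input order.
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 rows")
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant variable(s) removed: {constant}")
    active = [c for c in cols if c not in constant]
    while True:
        R = table[active].corr(method="pearson").abs().to_numpy()
        np.fill_diagonal(R, 0.0)
        counts = (R > threshold).sum(axis=1)
        if counts.max() == 0:
            break
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) > 1:
            mean_r = R[tied].mean(axis=1)
            tied = tied[mean_r == mean_r.max()]
        drop_idx = int(tied[0])  # input order fallback
        active.pop(drop_idx)
        if len(active) < 2:
            break
    return [c for c in cols if c in active]


def monthly_max_composite(series: pd.DataFrame) -> pd.DataFrame:
    """Monthly maximum-value composite of half-monthly NDVI records.

    ``series`` columns: site_id, year, month, halfmonth, ndvi, flag
    (0 good, 1 spline-interpolated, 2 snow/cloud).  Per (site, year,
    month), the maximum over quality-passing (flag 0) values; months
    where every half-month fails QC are missing (NaN propagates, it is
    never zero-filled).  Idempotent on already-monthly data.
    """
    required = {"site_id", "year", "month", "ndvi", "flag"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"NDVI series missing columns: {sorted(missing)}")
    bad = ~series["flag"].isin([0, 1, 2])
    if bad.any():
        raise ValueError("flag values must be in {0, 1, 2}")
    good = series[series["flag"] == 0]
    keys = ["site_id", "year", "month"]
    out = (good.groupby(keys)["ndvi"].max()
               .reindex(pd.MultiIndex.from_frame(
                   series[keys].drop_duplicates()), fill_value=np.nan)
               .rename("ndvi").reset_index())
    return out


def species_summer_ndvi(monthly: pd.DataFrame, membership: dict[str, str],
                        months: tuple[int, ...] = SUMMER_MONTHS,
                        years: tuple[int, int] | None = None) -> pd.Series:
    """Species mean NDVI over summer (site, year, month) values.

    ``membership`` maps site_id -> species.  Missing monthly values are
    skipped.  A species whose sites contribute no summer data raises.
    """
    df = monthly.copy()
    df = df[df["month"].isin(months)]
    if years is not None:
        df = df[(df["year"] >= years[0]) & (df["year"] <= years[1])]
    df = df.dropna(subset=["ndvi"])
    df["species"] = df["site_id"].map(membership)
    df = df.dropna(subset=["species"])
    out = df.groupby("species")["ndvi"].mean()
    empty = sorted(set(membership.values()) - set(out.index))
    if empty:
        raise ValueError(f"species with no summer NDVI data: {empty}")
    return out


def dichotomize_midrange(values: dict[str, float] | pd.Series
                         ) -> tuple[dict[str, str], float]:
    """Classify values as high/low at the mid-range cutoff (max+min)/2.

    A value exactly at the cutoff is classified high.  The
    classification is invariant to affine rescaling of all values.
    """
    s = pd.Series(values, dtype=float)
    if s.nunique() < 2:
        raise ValueError("all values identical: mid-range cutoff is degenerate")
    cutoff = float((s.max() + s.min()) / 2.0)
    classes = {k: ("high" if v >= cutoff else "low") for k, v in s.items()}
    return classes, cutoff


def classify_calling_site(observations: pd.DataFrame
                          ) -> pd.DataFrame:
    """Majority-vote calling-site class per species.

    ``observations`` columns: species, substrate in {arboreal,
    shrubby} (per-individual records; shrub/herbaceous observations are
    coded shrubby).  Returns a species-indexed frame with the class and
    the percentage of individuals on each substrate.  An exact 50/50
    split raises and must be resolved manually.
    """
    required = {"species", "substrate"}
    if not required <= set(observations.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    allowed = {"arboreal", "shrubby"}
    bad = set(observations["substrate"]) - allowed
    if bad:
        raise ValueError(f"unknown substrate values: {sorted(bad)}")
    rows = []
    for sp, sub in observations.groupby("species"):
        n = len(sub)
        n_arb = int((sub["substrate"] == "arboreal").sum())
        pct_arb = 100.0 * n_arb / n
        if n_arb * 2 == n:
            raise ValueError(
                f"exact 50/50 substrate split for {sp!r}: manual override needed")
        rows.append({"species": sp,
                     "calling_site": "arboreal" if n_arb * 2 > n else "shrubby",
                     "pct_arboreal": pct_arb,
                     "pct_shrubby": 100.0 - pct_arb,
                     "n_observations": n})
    return pd.DataFrame(rows).set_index("species")
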