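"""Indirect standardization: statewide rates, expected counts and SIRs.

Under the equal-risk assumption each area is given the pooled statewide
incidence rate of its own group, so the expected count for a cell is
``e = n * r_k`` and the standardized incidence ratio is ``SIR = y / e``.
An SIR of 1 means average risk; group-specific rates remove the purely
compositional part of any disparity before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ArealPanel


class StandardizationError(ValueError):
    pass


@dataclass
class ExpectedCounts:
    """Per-cell expected counts ``e = n * r_k`` plus the rates used."""

    values: pd.Series  # aligned to panel.data rows
    rates: pd.DataFrame  # columns cancer, group, rate

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SirTable:
    """Observed SIRs per cell; ``defined`` is False where e = 0."""

    data: pd.DataFrame  # panel columns + expected, sir, defined


def statewide_rates(panel: ArealPanel) -> pd.DataFrame:
    """Pooled rate r_k per (cancer, group): total cases / total person-years.

    All years are pooled, matching the statewide-average construction of
    the expected counts.
    """
    g = panel.data.groupby(["cancer", "group"], as_index=False).agg(
        cases=("count", "sum"), person_years=("population", "sum")
    )
    if (g["person_years"] == 0).any():
        bad = g[g["person_years"] == 0]
        raise StandardizationError(
            f"zero total person-years for strata:\n{bad[['cancer', 'group']]}"
        )
    g["rate"] = g["cases"] / g["person_years"]
    return g[["cancer", "group", "rate"]]


def expected_counts(panel: ArealPanel, rates: pd.DataFrame) -> ExpectedCounts:
    """Cell-wise e = n * r_k using the supplied (cancer, group) rates."""
    need = panel.data[["cancer", "group"]].drop_duplicates()
    have = rates[["cancer", "group"]].drop_duplicates()
    missing = need.merge(have, how="left", indicator=True)
    missing = missing[missing["_merge"] == "left_only"]
    if len(missing):
        raise StandardizationError(
            f"no rate for strata:\n{missing[['cancer', 'group']]}"
        )
    merged = panel.data.merge(rates, on=["cancer", "group"], how="left")
    values = pd.Series(
        merged["population"].to_numpy() * merged["rate"].to_numpy(),
        index=panel.data.index,
        name="expected",
    )
    return ExpectedCounts(values=values, rates=rates)


def sir(panel: ArealPanel, expected: ExpectedCounts) -> SirTable:
    """Observed SIR = y / e per cell; cells with e = 0 are flagged undefined."""
    if len(expected) != len(panel.data):
        raise StandardizationError("expected counts not aligned to panel")
    df = panel.data.copy()
    e = expected.values.to_numpy(dtype=float)
    df["expected"] = e
    defined = e > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(defined, df["count"].to_numpy() / np.where(defined, e, 1.0), np.nan)
    df["sir"] = s
    df["defined"] = defined
    return SirTable(df)


def sir_ratio_by_year(
    sir_table: SirTable, method: str = "ratio-of-means"
) -> pd.DataFrame:
    """Per-year disparity in observed SIRs: focal (group 1) vs reference (0).

    ``ratio-of-means`` (default) divides the group-wise means of the defined
    county SIRs; it is robust to individual zero-expected cells.
    ``mean-of-ratios`` averages per-county SIR ratios instead (counties where
    the reference SIR is 0 or undefined drop out).
    """
    if method not in ("ratio-of-means", "mean-of-ratios"):
        raise StandardizationError(f"unknown method {method!r}")
    df = sir_table.data[sir_table.data["defined"]]
    if set(df["group"].unique()) != {0, 1}:
        raise StandardizationError("both groups are required for a ratio")
    rows = []
    for (cancer, year), sub in df.groupby(["cancer", "year"]):
        foc = sub[sub["group"] == 1]
        ref = sub[sub["group"] == 0]
        mean_f = foc["sir"].mean() if len(foc) else np.nan
        mean_r = ref["sir"].mean() if len(ref) else np.nan
        if method == "ratio-of-means":
            ratio = mean_f / mean_r if (mean_r is not np.nan and mean_r != 0) else np.nan
        else:
            merged = foc.merge(ref, on="area_id", suffixes=("_f", "_r"))
            merged = merged[merged["sir_r"] > 0]
            ratio = (merged["sir_f"] / merged["sir_r"]).mean() if len(merged) else np.nan
        rows.append(
            {
                "cancer": cancer,
                "year": year,
                "mean_sir_focal": mean_f,
                "mean_sir_reference": mean_r,
                "sir_ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def site_distribution(counts: pd.DataFrame | dict) -> pd.DataFrame:
    """Tabulate site-specific case counts into shares of their system total.

    ``counts`` is either a mapping ``{site: count}`` or a frame with columns
    ``site, count`` (optionally ``system`` for a grouped tabulation).
    Returns one row per site with ``count``, ``percent`` (share of the
    system total) and a ``__total__`` row per system.
    """
    if isinstance(counts, dict):
        df = pd.DataFrame({"site": list(counts), "count": list(counts.values())})
    else:
        df = counts.copy()
    if "system" not in df.columns:
        df["system"] = "all"
    out = []
    for system, sub in df.groupby("system", sort=False):
        total = sub["count"].sum()
        sub = sub.copy()
        sub["percent"] = 100.0 * sub["count"] / total if total else np.nan
        out.append(sub)
        out.append(
            pd.DataFrame(
                [{"site": "__total__", "count": total, "system": system, "percent": 100.0}]
            )
        )
    return pd.concat(out, ignore_index=True)[["system", "site", "count", "percent"]]
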