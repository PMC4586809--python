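"""Stratified areal incidence panels.

The central data container is :class:`ArealPanel`: one record per
(area, year, group, cancer type) holding a case count and a population at
risk, together with a small table of per-area covariates.  The panel is the
input to indirect standardization and to the hierarchical disparity models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["cancer", "area_id", "year", "group", "count", "population"]
COVARIATE_COLUMNS = ["poverty", "hospitals_per10k", "construction", "metro"]


class PanelValidationError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass
class ArealPanel:
    """A complete (area x year x group) incidence grid per cancer type.

    Parameters
    ----------
    data:
        Tidy frame with columns ``cancer, area_id, year, group, count,
        population``.  ``group`` is binary: 1 for the focal group (Hispanic
        in the motivating Texas analysis), 0 for the reference group.
    covariates:
        Optional per-area frame indexed by ``area_id`` with columns
        ``poverty, hospitals_per10k, construction, metro``.  Covariates are
        constant over years within an area.
    """

    data: pd.DataFrame
    covariates: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = _validate_panel_frame(self.data)
        if self.covariates is not None:
            self.covariates = _validate_covariates(self.covariates, self.areas())

    # -- accessors ---------------------------------------------------------
    def areas(self) -> list:
        return sorted(self.data["area_id"].unique().tolist())

    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    def cancers(self) -> list[str]:
        return sorted(self.data["cancer"].unique().tolist())

    def subset(self, cancer: str) -> "ArealPanel":
        """Return the single-cancer stratum as a new panel."""
        sub = self.data[self.data["cancer"] == cancer]
        if sub.empty:
            raise KeyError(f"no such cancer stratum: {cancer!r}")
        return ArealPanel(sub.reset_index(drop=True), self.covariates)

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "ArealPanel") -> bool:
        """Exact equality of the count grid; covariates to numeric tolerance.

        Covariates pass through text round-trips, so they are compared with
        a 1e-12 relative tolerance rather than bitwise.
        """
        same = self.data.reset_index(drop=True).equals(other.data.reset_index(drop=True))
        if self.covariates is None or other.covariates is None:
            return same and (self.covariates is None) == (other.covariates is None)
        a = self.covariates.sort_index()
        b = other.covariates.sort_index()
        return (
            same
            and a.shape == b.shape
            and a.index.equals(b.index)
            and bool(np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-12, atol=1e-15))
        )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def covariates_to_csv(self, path) -> None:
        if self.covariates is None:
            raise PanelValidationError("panel has no covariates attached")
        self.covariates.reset_index().rename(columns={"index": "area_id"}).to_csv(
            path, index=False
        )


def _validate_panel_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"panel is missing columns: {missing}")
    df = df[PANEL_COLUMNS].copy()

    for col in ("count", "population"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise PanelValidationError(f"non-numeric values in {col!r}")
        if (vals < 0).any():
            raise PanelValidationError(f"negative values in {col!r}")
        df[col] = vals.astype(np.int64)
    if not set(df["group"].unique()) <= {0, 1}:
        raise PanelValidationError("group must be binary (1 = focal, 0 = reference)")
    df["group"] = df["group"].astype(np.int64)
    df["year"] = df["year"].astype(np.int64)

    key = ["cancer", "area_id", "year", "group"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].head(4)
        raise PanelValidationError(f"duplicate panel cells, e.g.\n{dup}")

    # grid completeness per cancer stratum
    for cancer, sub in df.groupby("cancer"):
        n_areas = sub["area_id"].nunique()
        n_years = sub["year"].nunique()
        n_groups = sub["group"].nunique()
        if len(sub) != n_areas * n_years * n_groups:
            raise PanelValidationError(
                f"incomplete (area x year x group) grid for cancer {cancer!r}: "
                f"{len(sub)} cells, expected {n_areas * n_years * n_groups}; "
                "use complete=True in read_panel to fill explicit zeros"
            )
    return df.sort_values(key).reset_index(drop=True)


def _validate_covariates(cov: pd.DataFrame, areas: list) -> pd.DataFrame:
    cov = cov.copy()
    if "area_id" in cov.columns:
        cov = cov.set_index("area_id")
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise PanelValidationError(f"covariate table missing columns: {missing}")
    absent = set(areas) - set(cov.index)
    if absent:
        raise PanelValidationError(f"covariates missing for areas: {sorted(absent)[:5]}")
    return cov.loc[areas, COVARIATE_COLUMNS].astype(float)


def read_panel(
    source,
    covariates=None,
    complete: bool = False,
) -> ArealPanel:
    """Read a panel CSV (``area_id,year,group,cancer,count,population``).

    With ``complete=True``, missing (area, year, group) cells within a cancer
    stratum are filled with an explicit zero count.  The population for a
    filled cell is taken from the same (area, group) pair in other years
    (its median), or zero if the pair is never observed; the count of filled
    cells is recorded in ``panel.warnings``.
    """
    df = pd.read_csv(source)
    warnings: list[str] = []
    if complete:
        df, n_filled = _complete_grid(df)
        if n_filled:
            warnings.append(f"filled {n_filled} missing cells with zero counts")
    cov = None
    if covariates is not None:
        cov = covariates if isinstance(covariates, pd.DataFrame) else pd.read_csv(covariates)
    panel = ArealPanel(df, cov)
    panel.warnings.extend(warnings)
    return panel


def _complete_grid(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"panel is missing columns: {missing}")
    out = []
    n_filled = 0
    for cancer, sub in df.groupby("cancer"):
        areas = sub["area_id"].unique()
        years = sub["year"].unique()
        groups = sub["group"].unique()
        full = pd.MultiIndex.from_product(
            [areas, years, groups], names=["area_id", "year", "group"]
        ).to_frame(index=False)
        merged = full.merge(sub, on=["area_id", "year", "group"], how="left")
        merged["cancer"] = cancer
        hole = merged["count"].isna()
        n_filled += int(hole.sum())
        merged.loc[hole, "count"] = 0
        # population policy: median of the same (area, group) across years
        pop_ref = (
            sub.groupby(["area_id", "group"])["population"].median().rename("pop_ref")
        )
        merged = merged.merge(pop_ref, on=["area_id", "group"], how="left")
        merged["population"] = merged["population"].fillna(merged["pop_ref"]).fillna(0)
        out.append(merged[PANEL_COLUMNS])
    return pd.concat(out, ignore_index=True), n_filled
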