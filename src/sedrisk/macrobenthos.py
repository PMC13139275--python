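"""Macrobenthos biomass estimation and its association with contamination.

Organisms from each 1 m^2 plot are dried at 60 C and weighed daily until
the mass stops changing (drying to constant mass); the stabilised mass is
the plot's dry biomass.  Site-season biomass is the mean over plots of the
summed per-taxon plot masses, in g dry mass per m^2.  Association with
metal concentrations and composite contamination indices is plain Pearson
correlation over pooled site-season observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import correlation_matrix

__all__ = [
    "BIOMASS_UNIT",
    "BiomassRecord",
    "constant_mass",
    "site_biomass",
    "biomass_association",
    "read_biomass",
    "write_biomass",
]

BIOMASS_UNIT = "g dry mass / m^2"

#: Relative change between consecutive weighings below which the mass
#: counts as constant ("no change between days").
DEFAULT_REL_TOL = 0.005


def constant_mass(series: Sequence[float], rel_tol: float = DEFAULT_REL_TOL) -> tuple[float, bool]:
    """Apply the drying-to-constant-mass stopping rule to a weighing series.

    Returns ``(final_mass, stabilised)``: the first mass whose relative
    change from the previous weighing is within ``rel_tol``.  A series that
    never stabilises (including a single weighing) returns its last mass
    flagged ``stabilised=False``.
    """
    masses = [float(m) for m in series]
    if not masses:
        raise ValueError("empty weighing series")
    if any(m <= 0 for m in masses):
        raise ValueError("weighing series must be strictly positive")
    for prev, cur in zip(masses, masses[1:]):
        if abs(cur - prev) / prev <= rel_tol:
            return cur, True
    return masses[-1], False


@dataclass
class BiomassRecord:
    """Dry-mass weighing series for one (site, season, plot, taxon)."""

    site: str
    season: str
    plot: int
    taxon: str
    weighing_series: list[float]
    tolerant: bool | None = None
    rel_tol: float = DEFAULT_REL_TOL
    final_biomass: float = field(init=False)
    stabilised: bool = field(init=False)

    def __post_init__(self) -> None:
        self.final_biomass, self.stabilised = constant_mass(self.weighing_series, self.rel_tol)


def site_biomass(records: Iterable[BiomassRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate records to site-season biomass (g dry mass / m^2).

    Returns ``(totals, by_taxon)``: ``totals`` has one row per site-season
    with the mean-over-plots of summed final masses and the plot count;
    ``by_taxon`` keeps the per-taxon breakdown (mean over plots as well).
    Additive over disjoint taxon sets by construction.
    """
    rows = [
        dict(site=r.site, season=r.season, plot=r.plot, taxon=r.taxon, mass=r.final_biomass)
        for r in records
    ]
    if not rows:
        raise ValueError("no biomass records")
    df = pd.DataFrame(rows)
    n_plots = df.groupby(["site", "season"])["plot"].nunique().rename("n_plots")
    plot_totals = df.groupby(["site", "season", "plot"])["mass"].sum()
    totals = (
        plot_totals.groupby(["site", "season"]).mean().rename("biomass").reset_index()
    )
    totals = totals.merge(n_plots.reset_index(), on=["site", "season"])
    totals["unit"] = BIOMASS_UNIT
    by_taxon = (
        df.groupby(["site", "season", "taxon"])["mass"].sum().reset_index(name="total_mass")
    )
    by_taxon = by_taxon.merge(n_plots.reset_index(), on=["site", "season"])
    by_taxon["biomass"] = by_taxon["total_mass"] / by_taxon["n_plots"]
    by_taxon["unit"] = BIOMASS_UNIT
    return totals, by_taxon[["site", "season", "taxon", "biomass", "n_plots", "unit"]]


def biomass_association(
    biomass: pd.DataFrame, predictors: pd.DataFrame, bh_correct: bool = False
) -> pd.DataFrame:
    """Correlate site-season biomass with concentrations and composite indices.

    ``biomass``: site, season, biomass.  ``predictors``: site, season plus
    one column per predictor (metal means, CD, PLI, RI, ...).  Observations
    are pooled across all sites and seasons.  Returns the biomass rows of
    the Pearson correlation table: predictor, r, p, n.
    """
    merged = biomass[["site", "season", "biomass"]].merge(
        predictors, on=["site", "season"], how="inner"
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 aligned site-season observations")
    value_cols = ["biomass"] + [
        c for c in predictors.columns if c not in ("site", "season")
    ]
    corr = correlation_matrix(merged[value_cols], bh_correct=bh_correct)
    mask = (corr["var_a"] == "biomass") & (corr["var_b"] != "biomass")
    out = corr[mask].rename(columns={"var_b": "predictor"})
    return out.drop(columns=["var_a"]).reset_index(drop=True)


def write_biomass(records: Iterable[BiomassRecord], path) -> None:
    """Long weighing-table CSV: site,season,plot,taxon,day,mass."""
    rows = []
    for r in records:
        for day, mass in enumerate(r.weighing_series, start=1):
            rows.append(dict(site=r.site, season=r.season, plot=r.plot,
                             taxon=r.taxon, day=day, mass=mass))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_biomass(path, rel_tol: float = DEFAULT_REL_TOL) -> list[BiomassRecord]:
    df = pd.read_csv(path, dtype={"site": str, "season": str, "taxon": str})
    required = {"site", "season", "plot", "taxon", "day", "mass"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    records = []
    for (site, season, plot, taxon), grp in df.groupby(
        ["site", "season", "plot", "taxon"], sort=False
    ):
        series = grp.sort_values("day")["mass"].tolist()
        records.append(BiomassRecord(site, season, int(plot), taxon, series, rel_tol=rel_tol))
    return records
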