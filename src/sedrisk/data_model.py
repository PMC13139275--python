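"""Long-format sediment survey data model.

A survey is a collection of replicate metal concentrations (mg/kg dry
weight) indexed by (site, season, metal, replicate).  Sites are ordered
upstream to downstream; the ordering is explicit metadata, never inferred
from labels.  Concentrations below the instrument detection limit are
*censored*: they are stored with the detection limit as the bound and are
never substituted by a surrogate value unless a censoring policy says so.

The on-disk dialect is a plain UTF-8 CSV with columns
``site,season,metal,replicate,concentration`` where the concentration
column admits ``<LOD`` tokens (e.g. ``<0.001``) for censored entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "KNOWN_METALS",
    "CensorPolicy",
    "ParseError",
    "ConfigurationError",
    "DomainError",
    "MetalMeasurement",
    "SurveyTable",
    "parse_concentration",
    "format_concentration",
    "summarize",
    "read_survey",
    "write_survey",
]

SEASONS = ("wet", "dry")

#: Element codes accepted by default; extensible via the ``metals`` argument
#: of :func:`read_survey` and :meth:`SurveyTable.validate`.
KNOWN_METALS = ("As", "Cr", "Cu", "Fe", "Zn", "Sb", "Al", "Pb", "Cd", "Ni", "Mn", "Hg")


class ParseError(ValueError):
    """A malformed token or table cell."""


class ConfigurationError(ValueError):
    """Missing or inconsistent reference data (backgrounds, toxicity, guidelines)."""


class DomainError(ValueError):
    """An argument outside the mathematical domain of an index."""


class CensorPolicy(str, Enum):
    """How censored (below detection limit) replicates enter summaries.

    ``OMIT`` (default) drops censored replicates; a group whose replicates
    are all censored yields a below-LOD summary with no usable mean, which
    downstream index computation leaves blank.  ``HALF_LOD`` and
    ``FULL_LOD`` substitute LOD/2 or the LOD itself, the two conventional
    single-value imputations.
    """

    OMIT = "omit"
    HALF_LOD = "half_lod"
    FULL_LOD = "full_lod"


@dataclass(frozen=True)
class MetalMeasurement:
    """One replicate concentration for a (site, season, metal)."""

    site: str
    season: str
    metal: str
    replicate: int
    value: float
    censored: bool = False
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ParseError(f"unknown season {self.season!r}; expected one of {SEASONS}")
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")
        if self.value < 0:
            raise ValueError(f"negative concentration {self.value} for {self.site}/{self.metal}")
        if self.censored and (self.lod is None or self.lod <= 0):
            raise ValueError("censored measurement requires a positive detection limit")


_SURVEY_COLUMNS = ["site", "season", "metal", "replicate", "value", "censored", "lod"]


@dataclass
class SurveyTable:
    """Replicate-level survey with an explicit upstream-to-downstream site order.

    ``data`` columns: site, season, metal, replicate, value, censored, lod.
    """

    data: pd.DataFrame
    site_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.site_order:
            self.site_order = list(pd.unique(self.data["site"]))
        self.validate()

    @classmethod
    def from_measurements(
        cls, measurements: Iterable[MetalMeasurement], site_order: Sequence[str] | None = None
    ) -> "SurveyTable":
        rows = [
            (m.site, m.season, m.metal, m.replicate, m.value, m.censored, m.lod)
            for m in measurements
        ]
        df = pd.DataFrame(rows, columns=_SURVEY_COLUMNS)
        return cls(df, list(site_order) if site_order else [])

    def validate(self, metals: Sequence[str] | None = None) -> None:
        df = self.data
        missing = [c for c in _SURVEY_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"survey table missing columns: {missing}")
        if len(df) == 0:
            raise ParseError("survey table is empty")
        unknown_sites = set(df["site"]) - set(self.site_order)
        if unknown_sites:
            raise ParseError(f"sites not in declared site order: {sorted(unknown_sites)}")
        bad_season = set(df["season"]) - set(SEASONS)
        if bad_season:
            raise ParseError(f"unknown season codes: {sorted(bad_season)}")
        allowed = set(metals if metals is not None else KNOWN_METALS)
        bad_metal = set(df["metal"]) - allowed
        if bad_metal:
            raise ParseError(f"unknown metal codes: {sorted(bad_metal)}")
        dup = df.duplicated(subset=["site", "season", "metal", "replicate"])
        if dup.any():
            keys = df.loc[dup, ["site", "season", "metal", "replicate"]].to_records(index=False)
            raise ParseError(f"duplicate replicate keys: {list(keys)[:5]}")
        if (df["value"] < 0).any():
            raise ParseError("negative concentrations present")
        cens = df["censored"].astype(bool)
        if cens.any() and df.loc[cens, "lod"].isna().any():
            raise ParseError("censored rows must carry a detection limit")

    @property
    def sites(self) -> list[str]:
        return list(self.site_order)

    def metals(self) -> list[str]:
        return sorted(self.data["metal"].unique())

    def __len__(self) -> int:
        return len(self.data)


def parse_concentration(token: str) -> tuple[float, bool, float | None]:
    """Parse a concentration cell in the ``<LOD`` dialect.

    ``"45.46"`` -> ``(45.46, False, None)``;
    ``"<0.001"`` -> ``(0.001, True, 0.001)``.
    """
    text = str(token).strip()
    if not text:
        raise ParseError("empty concentration token")
    censored = text.startswith("<")
    body = text[1:].strip() if censored else text
    try:
        value = float(body)
    except ValueError as exc:
        raise ParseError(f"malformed concentration token {token!r}") from exc
    if not math.isfinite(value) or value < 0:
        raise ParseError(f"concentration token {token!r} out of range")
    if censored:
        if value <= 0:
            raise ParseError(f"censored token {token!r} requires a positive detection limit")
        return value, True, value
    return value, False, None


def format_concentration(value: float, censored: bool, lod: float | None) -> str:
    # repr() is the shortest decimal that round-trips the float exactly,
    # keeping write -> read the identity on valid tables
    if censored:
        return f"<{float(lod)!r}"
    return repr(float(value))


def summarize(table: SurveyTable, policy: CensorPolicy = CensorPolicy.OMIT) -> pd.DataFrame:
    """Site-season-metal summary: mean, standard error, replicate bookkeeping.

    Returns a DataFrame with columns ``site, season, metal, mean, se, n,
    n_censored, below_lod``.  Under the default ``omit`` policy the mean and
    SE are computed over uncensored replicates only and ``n`` counts them; a
    group whose replicates are all censored is flagged ``below_lod`` with
    ``mean``/``se`` left missing (its detection limit is the only bound we
    have).  Under the substitution policies every replicate contributes,
    censored ones at LOD/2 or LOD.
    """
    policy = CensorPolicy(policy)
    rows = []
    for (site, season, metal), grp in table.data.groupby(
        ["site", "season", "metal"], sort=False
    ):
        cens = grp["censored"].astype(bool)
        n_cens = int(cens.sum())
        all_cens = n_cens == len(grp)
        if policy is CensorPolicy.OMIT:
            vals = grp.loc[~cens, "value"].to_numpy(dtype=float)
        else:
            factor = 0.5 if policy is CensorPolicy.HALF_LOD else 1.0
            vals = np.where(cens, grp["lod"].to_numpy(dtype=float) * factor,
                            grp["value"].to_numpy(dtype=float))
        if len(vals) == 0:
            mean = se = float("nan")
            n = 0
        else:
            mean = float(np.mean(vals))
            n = len(vals)
            se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "site": site,
                "season": season,
                "metal": metal,
                "mean": mean,
                "se": se,
                "n": n,
                "n_censored": n_cens,
                "below_lod": bool(all_cens),
            }
        )
    out = pd.DataFrame(rows)
    out["site"] = pd.Categorical(out["site"], categories=table.site_order, ordered=True)
    return out.sort_values(["site", "season", "metal"], ignore_index=True).astype({"site": str})


def read_survey(
    path, site_order: Sequence[str] | None = None, metals: Sequence[str] | None = None
) -> SurveyTable:
    """Read the long-format survey CSV.

    Without an explicit ``site_order`` the order of first appearance in the
    file is used (the writer emits sites in declared order, so a round trip
    preserves it).
    """
    raw = pd.read_csv(path, dtype={"site": str, "season": str, "metal": str})
    required = ["site", "season", "metal", "replicate", "concentration"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    values, censored, lods = [], [], []
    for i, token in enumerate(raw["concentration"]):
        try:
            v, c, lod = parse_concentration(token)
        except ParseError as exc:
            raise ParseError(f"{path}: row {i + 2}, column 'concentration': {exc}") from exc
        values.append(v)
        censored.append(c)
        lods.append(lod)
    df = pd.DataFrame(
        {
            "site": raw["site"],
            "season": raw["season"],
            "metal": raw["metal"],
            "replicate": raw["replicate"].astype(int),
            "value": values,
            "censored": censored,
            "lod": [float("nan") if x is None else x for x in lods],
        }
    )
    table = SurveyTable(df, list(site_order) if site_order else [])
    table.validate(metals=metals)
    return table


def write_survey(table: SurveyTable, path) -> None:
    """Write the survey to the long-format CSV dialect (round-trips with read)."""
    df = table.data.copy()
    df["site"] = pd.Categorical(df["site"], categories=table.site_order, ordered=True)
    df = df.sort_values(["site", "season", "metal", "replicate"], kind="stable")
    out = pd.DataFrame(
        {
            "site": df["site"].astype(str),
            "season": df["season"],
            "metal": df["metal"],
            "replicate": df["replicate"],
            "concentration": [
                format_concentration(v, c, lod)
                for v, c, lod in zip(df["value"], df["censored"], df["lod"])
            ],
        }
    )
    out.to_csv(path, index=False)
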