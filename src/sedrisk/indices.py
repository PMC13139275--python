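"""Sediment contamination and ecological risk indices.

Per-metal indices relative to a geochemical background B_n:

* contamination factor       CF   = C_n / B_n
* enrichment factor          EF   = (C_n / C_ref)_sample / (B_n / B_ref)_background
* geoaccumulation index      Igeo = log2( C_n / (1.5 B_n) )

Composite (per site-season) indices over the n metals assessed there:

* pollution load index       PLI = (CF_1 x ... x CF_n)^(1/n)   (geometric mean)
* contamination degree       CD  = sum CF_i
* ecological risk factor     Er  = T_r x CF          (T_r: toxicity coefficient)
* potential ecological risk  RI  = sum Er_i          (Hakanson)

All functions accept scalars or numpy arrays.  Every index value is mapped
onto an ordered category label by a :class:`ClassificationScheme`; the
bundled schemes follow the conventional literature class boundaries and are
plain data, overridable from configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CensorPolicy, ConfigurationError, DomainError, SurveyTable, summarize
from .references import BackgroundSet, ToxicityTable

__all__ = [
    "contamination_factor",
    "enrichment_factor",
    "geoaccumulation_index",
    "pollution_load_index",
    "contamination_degree",
    "ecological_risk_factor",
    "risk_index",
    "ClassificationScheme",
    "classify",
    "DEFAULT_SCHEMES",
    "cd_scheme",
    "assess_survey",
]


def contamination_factor(c_n, b_n):
    """CF = C_n / B_n."""
    c_n = np.asarray(c_n, dtype=float)
    b_n = np.asarray(b_n, dtype=float)
    if np.any(b_n <= 0):
        raise DomainError("background concentration must be positive")
    if np.any(c_n < 0):
        raise DomainError("sample concentration must be non-negative")
    out = c_n / b_n
    return float(out) if out.ndim == 0 else out


def enrichment_factor(c_n, c_ref_sample, b_n, b_ref):
    """EF = (C_n/C_ref)_sample / (B_n/B_ref)_background.

    Algebraically EF = CF_n / CF_ref: normalising to a conservative
    reference element (Fe here) separates anthropogenic enrichment from
    lithological dilution.  The reference metal against itself gives
    exactly 1.
    """
    c_n = np.asarray(c_n, dtype=float)
    c_ref_sample = np.asarray(c_ref_sample, dtype=float)
    if np.any(c_ref_sample <= 0):
        raise DomainError("reference-metal sample concentration must be positive")
    if np.any(np.asarray(b_n, float) <= 0) or np.any(np.asarray(b_ref, float) <= 0):
        raise DomainError("background concentrations must be positive")
    if np.any(c_n < 0):
        raise DomainError("sample concentration must be non-negative")
    out = (c_n / c_ref_sample) / (np.asarray(b_n, float) / np.asarray(b_ref, float))
    return float(out) if out.ndim == 0 else out


def geoaccumulation_index(c_n, b_n):
    """Igeo = log2(C_n / (1.5 B_n)); the 1.5 buffers lithological variation.

    Identically log2(CF) - log2(1.5).  Undefined at zero concentration —
    callers report such cells as not computable rather than -inf.
    """
    c_n = np.asarray(c_n, dtype=float)
    b_n = np.asarray(b_n, dtype=float)
    if np.any(b_n <= 0):
        raise DomainError("background concentration must be positive")
    if np.any(c_n <= 0):
        raise DomainError("geoaccumulation index undefined at zero concentration")
    out = np.log2(c_n / (1.5 * b_n))
    return float(out) if out.ndim == 0 else out


def pollution_load_index(cfs) -> float:
    """PLI: geometric mean of contamination factors, computed in log space."""
    cfs = np.asarray(cfs, dtype=float)
    if cfs.size == 0:
        raise DomainError("PLI requires at least one contamination factor")
    if np.any(cfs <= 0):
        raise DomainError("PLI requires strictly positive contamination factors")
    return float(np.exp(np.mean(np.log(cfs))))


def contamination_degree(cfs) -> float:
    """CD: arithmetic sum of contamination factors."""
    cfs = np.asarray(cfs, dtype=float)
    if cfs.size == 0:
        raise DomainError("CD requires at least one contamination factor")
    return float(np.sum(cfs))


def ecological_risk_factor(t_r, cf):
    """Er = T_r x CF."""
    t_r = np.asarray(t_r, dtype=float)
    if np.any(t_r <= 0):
        raise DomainError("toxicity coefficient must be positive")
    out = t_r * np.asarray(cf, dtype=float)
    return float(out) if out.ndim == 0 else out


def risk_index(ers) -> float:
    """RI: sum of per-metal ecological risk factors for one site-season."""
    ers = np.asarray(ers, dtype=float)
    if ers.size == 0:
        raise DomainError("RI requires at least one ecological risk factor")
    return float(np.sum(ers))


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered interval classification for one index.

    ``bounds`` are strictly increasing cut points; intervals are
    left-closed/right-open, so value v gets ``labels[i]`` where i counts the
    bounds not exceeding v.  ``labels`` has exactly ``len(bounds) + 1``
    entries, the last one open-ended.
    """

    index_name: str
    bounds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bounds) + 1:
            raise ConfigurationError(
                f"{self.index_name}: need {len(self.bounds) + 1} labels, got {len(self.labels)}"
            )
        if any(b2 <= b1 for b1, b2 in zip(self.bounds, self.bounds[1:])):
            raise ConfigurationError(f"{self.index_name}: bounds must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError(f"{self.index_name}: labels must be unique")

    def classify(self, value: float) -> str:
        if not math.isfinite(value):
            raise DomainError(f"cannot classify non-finite {self.index_name} value {value}")
        i = int(np.searchsorted(self.bounds, value, side="right"))
        return self.labels[i]

    def rank(self, label: str) -> int:
        return self.labels.index(label)


def classify(value: float, scheme: ClassificationScheme) -> str:
    """Label one index value under a scheme."""
    return scheme.classify(value)


DEFAULT_SCHEMES: dict[str, ClassificationScheme] = {
    "CF": ClassificationScheme(
        "CF", (1.0, 3.0, 6.0),
        ("low contamination", "moderate contamination",
         "considerable contamination", "very high contamination"),
    ),
    "EF": ClassificationScheme(
        "EF", (2.0, 5.0, 20.0, 40.0),
        ("minimal enrichment", "moderate enrichment", "significant enrichment",
         "very high enrichment", "extremely high enrichment"),
    ),
    "Igeo": ClassificationScheme(
        "Igeo", (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        ("unpolluted", "unpolluted to moderately polluted", "moderately polluted",
         "moderately to strongly polluted", "strongly polluted",
         "strongly to extremely polluted", "extremely polluted"),
    ),
    "PLI": ClassificationScheme("PLI", (1.0,), ("unpolluted", "polluted")),
    "Er": ClassificationScheme(
        "Er", (40.0, 80.0, 160.0, 320.0),
        ("low risk", "moderate risk", "considerable risk", "high risk", "very high risk"),
    ),
    "RI": ClassificationScheme(
        "RI", (150.0, 300.0, 600.0),
        ("low risk", "moderate risk", "considerable risk", "very high risk"),
    ),
}


def cd_scheme(n_metals: int) -> ClassificationScheme:
    """Contamination-degree scheme scaled to the number of metals assessed.

    Hakanson's original CD classes assume eight metals; scaling the cut
    points by n generalises them to any metal count: < n low, [n, 2n)
    moderate, [2n, 4n) considerable, >= 4n very high.
    """
    if n_metals < 1:
        raise DomainError("CD scheme requires at least one metal")
    n = float(n_metals)
    return ClassificationScheme(
        "CD", (n, 2 * n, 4 * n),
        ("low degree of contamination", "moderate degree of contamination",
         "considerable degree of contamination", "very high degree of contamination"),
    )


def _per_metal_rows(site, season, metal, cf, ef, igeo, er, schemes):
    er_scheme = schemes.get("Er", DEFAULT_SCHEMES["Er"])
    rows = [
        dict(site=site, season=season, metal=metal, index="CF", value=cf,
             label=schemes["CF"].classify(cf), n_metals_used=np.nan),
        dict(site=site, season=season, metal=metal, index="EF", value=ef,
             label=schemes["EF"].classify(ef), n_metals_used=np.nan),
        dict(site=site, season=season, metal=metal, index="Er", value=er,
             label=er_scheme.classify(er), n_metals_used=np.nan),
    ]
    if igeo is not None:
        rows.insert(2, dict(site=site, season=season, metal=metal, index="Igeo", value=igeo,
                            label=schemes["Igeo"].classify(igeo), n_metals_used=np.nan))
    else:
        rows.insert(2, dict(site=site, season=season, metal=metal, index="Igeo",
                            value=np.nan, label=None, n_metals_used=np.nan))
    return rows


def assess_survey(
    summaries: pd.DataFrame,
    background: BackgroundSet,
    toxicity: ToxicityTable,
    schemes: Mapping[str, ClassificationScheme] | None = None,
) -> pd.DataFrame:
    """Compute and classify every index for every site-season of a summary table.

    ``summaries`` is the output of :func:`sedrisk.data_model.summarize` (or
    any frame with site/season/metal/mean/below_lod columns).  Per-metal
    CF/EF/Igeo/Er are computed from the site-season mean concentration;
    below-detection metals yield blank rows (missing value, no label) and
    are excluded from the composites PLI, CD and RI, whose ``n_metals_used``
    records how many metals actually entered them.

    The reference metal (for EF) must be quantified at every site-season;
    a metal lacking a background or toxicity coefficient is a configuration
    error naming the metal.
    """
    schemes = dict(DEFAULT_SCHEMES, **(schemes or {}))
    usable = summaries["mean"].notna() & ~summaries["below_lod"].astype(bool)
    for metal in summaries.loc[usable, "metal"].unique():
        if metal not in background:
            raise ConfigurationError(f"no background concentration for metal {metal!r}")
        if metal not in toxicity:
            raise ConfigurationError(f"no toxicity coefficient for metal {metal!r}")
    ref = background.reference_metal

    rows: list[dict] = []
    for (site, season), grp in summaries.groupby(["site", "season"], sort=False):
        grp_usable = grp[grp["mean"].notna() & ~grp["below_lod"].astype(bool)]
        ref_rows = grp_usable[grp_usable["metal"] == ref]
        if ref_rows.empty or not ref_rows["mean"].iloc[0] > 0:
            raise ConfigurationError(
                f"reference metal {ref!r} not quantified at site {site} ({season})"
            )
        c_ref = float(ref_rows["mean"].iloc[0])
        cfs, ers = [], []
        for _, rec in grp.iterrows():
            metal = rec["metal"]
            if not np.isfinite(rec["mean"]) or rec["below_lod"]:
                # below-detection blank, mirroring published blank cells
                for idx_name in ("CF", "EF", "Igeo", "Er"):
                    rows.append(dict(site=site, season=season, metal=metal, index=idx_name,
                                     value=np.nan, label=None, n_metals_used=np.nan))
                continue
            c_n = float(rec["mean"])
            cf = contamination_factor(c_n, background[metal])
            ef = enrichment_factor(c_n, c_ref, background[metal], background[ref])
            igeo = geoaccumulation_index(c_n, background[metal]) if c_n > 0 else None
            er = ecological_risk_factor(toxicity[metal], cf)
            cfs.append(cf)
            ers.append(er)
            rows.extend(_per_metal_rows(site, season, metal, cf, ef, igeo, er, schemes))
        n_used = len(cfs)
        if n_used:
            pli = pollution_load_index(cfs)
            cd = contamination_degree(cfs)
            ri = risk_index(ers)
            cd_sch = cd_scheme(n_used)
            rows.append(dict(site=site, season=season, metal=None, index="PLI", value=pli,
                             label=schemes["PLI"].classify(pli), n_metals_used=n_used))
            rows.append(dict(site=site, season=season, metal=None, index="CD", value=cd,
                             label=cd_sch.classify(cd), n_metals_used=n_used))
            rows.append(dict(site=site, season=season, metal=None, index="RI", value=ri,
                             label=schemes["RI"].classify(ri), n_metals_used=n_used))
    return pd.DataFrame(rows)


def replicate_indices(
    table: SurveyTable,
    background: BackgroundSet,
    toxicity: ToxicityTable,
) -> pd.DataFrame:
    """Per-replicate index mode with simple uncertainty propagation.

    Computes CF/Igeo/Er per uncensored replicate (EF pairs each replicate
    with the same-numbered reference-metal replicate) and reports the mean
    and standard error of each index per site-season-metal.  Off the main
    assessment path; the published-table mode works from site-season means.
    """
    ref = background.reference_metal
    df = table.data[~table.data["censored"].astype(bool)]
    ref_vals = df[df["metal"] == ref].set_index(["site", "season", "replicate"])["value"]
    records = []
    for (site, season, metal), grp in df.groupby(["site", "season", "metal"], sort=False):
        per_rep: dict[str, list[float]] = {"CF": [], "EF": [], "Igeo": [], "Er": []}
        for _, rec in grp.iterrows():
            c_n = float(rec["value"])
            if c_n <= 0:
                continue
            cf = contamination_factor(c_n, background[metal])
            per_rep["CF"].append(cf)
            per_rep["Igeo"].append(geoaccumulation_index(c_n, background[metal]))
            per_rep["Er"].append(ecological_risk_factor(toxicity[metal], cf))
            key = (site, season, rec["replicate"])
            if key in ref_vals.index and ref_vals.loc[key] > 0:
                per_rep["EF"].append(
                    enrichment_factor(c_n, float(ref_vals.loc[key]),
                                      background[metal], background[ref])
                )
        for idx_name, vals in per_rep.items():
            if not vals:
                continue
            arr = np.asarray(vals)
            se = float(np.std(arr, ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan
            records.append(dict(site=site, season=season, metal=metal, index=idx_name,
                                value=float(arr.mean()), se=se, n=len(arr)))
    return pd.DataFrame(records)
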