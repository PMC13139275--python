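"""Bundled example data: a published 10-site longitudinal river survey.

The package ships the summary tables of a published sediment monitoring
study of a wastewater-impacted South African river — site-season mean
concentrations (mg/kg dry weight, mean +/- standard error over five 1 m^2
plots, with below-detection entries censored at 0.001 mg/kg) and the
published per-metal contamination indices (CF, EF, Igeo).  They serve as a
worked example and as the calibration anchor for the back-calculated
background preset.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_model import parse_concentration

__all__ = ["load_reference_means", "load_reference_indices", "reference_site_order"]

SITE_ORDER = tuple("ABCDEFGHIJ")


def reference_site_order() -> list[str]:
    """Upstream-to-downstream site order of the bundled survey."""
    return list(SITE_ORDER)


def _data_path(name: str):
    return resources.files("sedrisk.data").joinpath(name)


def load_reference_means() -> pd.DataFrame:
    """Site-season mean concentrations of the bundled survey.

    Columns: site, season, metal, mean, se, below_lod, lod.  Censored
    entries (reported as ``<0.001``) carry ``below_lod=True`` and a missing
    mean.
    """
    with resources.as_file(_data_path("survey_means.csv")) as p:
        raw = pd.read_csv(p, dtype={"site": str, "season": str, "metal": str})
    means, lods, below = [], [], []
    for token in raw["concentration"]:
        value, censored, lod = parse_concentration(token)
        below.append(censored)
        means.append(float("nan") if censored else value)
        lods.append(lod if censored else float("nan"))
    out = raw[["site", "season", "metal"]].copy()
    out["mean"] = means
    out["se"] = raw["se"]
    out["below_lod"] = below
    out["lod"] = lods
    return out


def load_reference_indices() -> pd.DataFrame:
    """Published per-metal indices (cf, ef, igeo) of the bundled survey;
    below-detection cells are missing, mirroring the published blanks."""
    with resources.as_file(_data_path("survey_indices.csv")) as p:
        return pd.read_csv(p, dtype={"site": str, "season": str, "metal": str})


def reference_means_as_survey():
    """The bundled mean table recast as a 1-replicate survey.

    Useful for pushing the published means through the assessment pipeline;
    the resulting single-replicate groups have no dispersion, so only the
    index values (not their uncertainties) are meaningful.
    """
    from .data_model import SurveyTable

    df = load_reference_means()
    data = pd.DataFrame(
        {
            "site": df["site"],
            "season": df["season"],
            "metal": df["metal"],
            "replicate": 1,
            "value": df["mean"].fillna(0.0),
            "censored": df["below_lod"],
            "lod": df["lod"],
        }
    )
    return SurveyTable(data, list(SITE_ORDER))
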