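"""TEL/PEL sediment quality guideline screening.

Each site-season mean is flagged against the threshold effect level (TEL,
below which adverse biological effects are not probable) and the probable
effect level (PEL, above which they are probable).  Boundary convention: a
mean exactly at the TEL counts as exceeding it (the TEL is the last safe
concentration), while a mean exactly at the PEL is not yet ``above_pel``.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .references import GuidelineSet

__all__ = ["ExceedanceStatus", "screen"]


class ExceedanceStatus(str, Enum):
    BELOW_TEL = "below_tel"
    ABOVE_TEL = "above_tel"
    ABOVE_PEL = "above_pel"
    NO_GUIDELINE = "no_guideline"


def _status(mean: float, below_lod: bool, metal: str, guidelines: GuidelineSet) -> str:
    tel = guidelines.tel.get(metal)
    pel = guidelines.pel.get(metal)
    if tel is None and pel is None:
        return ExceedanceStatus.NO_GUIDELINE.value
    if below_lod or not np.isfinite(mean):
        # a censored mean is bounded by the detection limit, far below any TEL
        return ExceedanceStatus.BELOW_TEL.value
    if pel is not None and mean > pel:
        return ExceedanceStatus.ABOVE_PEL.value
    if tel is not None and mean >= tel:
        return ExceedanceStatus.ABOVE_TEL.value
    if tel is None and pel is not None:
        return ExceedanceStatus.BELOW_TEL.value
    return ExceedanceStatus.BELOW_TEL.value


def screen(summaries: pd.DataFrame, guidelines: GuidelineSet) -> pd.DataFrame:
    """Flag every site-season-metal mean against the guideline set.

    ``summaries`` needs columns site, season, metal, mean and (optionally)
    below_lod.  Returns the same keys with the mean and a ``status`` column
    in {below_tel, above_tel, above_pel, no_guideline}.
    """
    below = (
        summaries["below_lod"].astype(bool)
        if "below_lod" in summaries.columns
        else pd.Series(False, index=summaries.index)
    )
    out = summaries[["site", "season", "metal", "mean"]].copy()
    out["status"] = [
        _status(m, b, metal, guidelines)
        for m, b, metal in zip(summaries["mean"], below, summaries["metal"])
    ]
    return out
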