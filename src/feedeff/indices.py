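"""Selection indices combining multi-trait breeding values.

Two published residual-feed-intake style indices are supported, both applied
post hoc to an (animal × trait) table of estimated breeding values for DMI,
ECM, MBW, BWL and BWG:

* the RFI index — same weights as the tailored energy-requirement equation,
  DMI minus its expected sinks; lower values are more feed-efficient;
* RZFE — the German Holstein feed-efficiency index, which omits the
  maintenance (MBW) term and reverses sign so that higher is more efficient.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .metrics import RFI_INDEX_WEIGHTS, RZFE_WEIGHTS


class IndexError_(ValueError):
    pass


def _weighted_index(bvs: pd.DataFrame, weights: dict, required) -> pd.Series:
    missing_cols = [t for t in required if t not in bvs.columns]
    if missing_cols:
        raise IndexError_(f"breeding-value table lacks traits {missing_cols}")
    incomplete = bvs[list(required)].isna().any(axis=1)
    if incomplete.any():
        raise IndexError_(
            f"missing trait EBVs for animals: {list(bvs.index[incomplete])[:10]}"
        )
    out = sum(weights[t] * bvs[t] for t in required)
    return pd.Series(out, index=bvs.index)


def rfi_index(bvs: pd.DataFrame) -> pd.Series:
    """RFI index: BV_DMI − 0.456·BV_ECM + 0.0508·BV_MBW − 3.25·BV_BWL + 3.25·BV_BWG.

    Lower is more efficient (less intake than the sinks require).
    """
    return _weighted_index(bvs, RFI_INDEX_WEIGHTS, ("dmi", "ecm", "mbw", "bwl", "bwg")).rename(
        "rfi_index"
    )


def rzfe(bvs: pd.DataFrame) -> pd.Series:
    """RZFE index: 0.4·BV_ECM − 4.5·BV_BWL + 4.5·BV_BWG − BV_DMI (higher = better)."""
    return _weighted_index(bvs, RZFE_WEIGHTS, ("dmi", "ecm", "bwl", "bwg")).rename("rzfe")


def _round_half_up(x: float, decimals: int = 1) -> float:
    f = 10**decimals
    return math.floor(abs(x) * f + 0.5) / f * (1 if x >= 0 else -1)


def coefficient_ratios() -> pd.DataFrame:
    """BWG/ECM coefficient ratios per metric, half-up rounded to one decimal.

    The ratio measures how much more intake the formulation allocates to a kg
    of body-tissue gain than to a kg of energy-corrected milk.
    """
    rows = []
    for name, weights in (("rfi_index", RFI_INDEX_WEIGHTS), ("rzfe", RZFE_WEIGHTS)):
        ratio = abs(weights["bwg"]) / abs(weights["ecm"])
        rows.append({"metric": name, "bwg_ecm_ratio": _round_half_up(ratio, 1), "raw": ratio})
    # the tailored requirement equation shares the RFI-index weights
    df = pd.DataFrame(rows).set_index("metric")
    df.loc["refi_rdc"] = df.loc["rfi_index"]
    return df.sort_index()
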