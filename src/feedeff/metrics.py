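"""Phenotype engineering for feed-efficiency evaluation.

All the deterministic trait formulas used before any model is fitted:

* energy-corrected milk (ECM) from milk yield and composition (Sjaunja-type
  formula, composition in g/kg),
* metabolic body weight MBW = BW^0.75,
* sign-split of daily body-weight change into loss (BWL) and gain (BWG),
* two expected-dry-matter-intake (eDMI) formulations: the Nordic Red tailored
  energy-requirement coefficients, and the NRC 2021 first-parity prediction
  equation,
* energy conversion efficiency ECE = ECM / MEI,
* the coefficient-system conversion that puts the NRC equation on the
  ECM/MBW sink scale.

Scalar functions accept numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: tailored Nordic Red energy-requirement coefficients (kg DM per sink unit)
RDC_COEFFS = {"ecm": 0.456, "mbw": 0.0508, "bwl": -3.25, "bwg": 3.25}

#: one-step RFI model also uses these as its generating/index weights
RFI_INDEX_WEIGHTS = {"dmi": 1.0, "ecm": -0.456, "mbw": 0.0508, "bwl": -3.25, "bwg": 3.25}

#: German RZFE index weights (higher = more efficient; no maintenance term)
RZFE_WEIGHTS = {"dmi": -1.0, "ecm": 0.4, "mbw": 0.0, "bwl": -4.5, "bwg": 4.5}

#: NEL content of 1 kg ECM (Mcal), used to convert milk energy to ECM scale
MCAL_NEL_PER_KG_ECM = 0.752

#: metabolizable energy required per kg ECM (kJ), for the minimal-energy bound
ME_KJ_PER_KG_ECM = 4765.0

#: default dietary energy density, MJ ME per kg DM
DEFAULT_ENERGY_DENSITY = 10.94


class DomainError(ValueError):
    pass


def ecm(milk, fat, protein, lactose):
    """Energy-corrected milk (kg/d) from yield (kg/d) and composition (g/kg).

    ECM = milk × (38.30·fat + 24.20·protein + 16.54·lactose + 20.7) / 3140.
    """
    milk, fat, protein, lactose = map(np.asarray, (milk, fat, protein, lactose))
    if (milk < 0).any() or (fat < 0).any() or (protein < 0).any() or (lactose < 0).any():
        raise DomainError("ECM inputs must be non-negative")
    out = milk * (38.30 * fat + 24.20 * protein + 16.54 * lactose + 20.7) / 3140.0
    return out if out.ndim else float(out)


def mbw(bw):
    """Metabolic body weight BW^0.75 (kg^0.75)."""
    bw = np.asarray(bw, dtype=float)
    if (bw <= 0).any():
        raise DomainError("body weight must be positive")
    out = bw**0.75
    return out if out.ndim else float(out)


def bw_from_mbw(m):
    """Inverse of :func:`mbw`: BW = MBW^(4/3)."""
    m = np.asarray(m, dtype=float)
    out = m ** (4.0 / 3.0)
    return out if out.ndim else float(out)


def split_bw_change(delta_bw):
    """Split daily BW change (kg/d) into (BWL, BWG) = (max(0,−Δ), max(0,Δ))."""
    d = np.asarray(delta_bw, dtype=float)
    bwl = np.maximum(0.0, -d)
    bwg = np.maximum(0.0, d)
    if d.ndim:
        return bwl, bwg
    return float(bwl), float(bwg)


def edmi_rdc(ecm_, mbw_, bwl, bwg):
    """Expected DMI (kg/d) from the tailored Nordic Red requirement equation.

    eDMI = 0.456·ECM + 0.0508·MBW − 3.25·BWL + 3.25·BWG.
    """
    out = (
        RDC_COEFFS["ecm"] * np.asarray(ecm_, dtype=float)
        + RDC_COEFFS["mbw"] * np.asarray(mbw_, dtype=float)
        + RDC_COEFFS["bwl"] * np.asarray(bwl, dtype=float)
        + RDC_COEFFS["bwg"] * np.asarray(bwg, dtype=float)
    )
    return out if np.ndim(out) else float(out)


def edmi_nrc2021(milk_energy, bw, bcs, dim):
    """Expected DMI (kg/d) from the NRC 2021 first-parity prediction equation.

    (3.7 + 0.305·MilkE + 0.022·BW − 0.689·BCS) × (1 − 0.212·e^(−0.053·DIM)),
    with MilkE in Mcal/d and the whole bracket carrying the days-in-milk
    multiplier (the published form of the equation).
    """
    dim = np.asarray(dim, dtype=float)
    if (dim < 1).any():
        raise DomainError("days in milk must be >= 1")
    bracket = (
        3.7
        + 0.305 * np.asarray(milk_energy, dtype=float)
        + 0.022 * np.asarray(bw, dtype=float)
        - 0.689 * np.asarray(bcs, dtype=float)
    )
    out = bracket * (1.0 - 0.212 * np.exp(-0.053 * dim))
    return out if np.ndim(out) else float(out)


def milk_energy_from_ecm(ecm_):
    """Milk energy (Mcal NEL/d) from ECM via 0.752 Mcal per kg ECM."""
    out = MCAL_NEL_PER_KG_ECM * np.asarray(ecm_, dtype=float)
    return out if np.ndim(out) else float(out)


def ece(ecm_, mei):
    """Energy conversion efficiency (kg ECM per MJ ME intake)."""
    mei = np.asarray(mei, dtype=float)
    if (mei <= 0).any():
        raise DomainError("metabolizable energy intake must be positive")
    out = np.asarray(ecm_, dtype=float) / mei
    return out if np.ndim(out) else float(out)


def nrc_to_sink_scale(mean_mbw: float) -> tuple[float, float]:
    """Convert NRC 2021 DMI-equation coefficients onto the ECM and MBW scales.

    The milk-energy coefficient 0.305 (kg DM per Mcal) becomes kg DM per kg
    ECM via 0.752 Mcal/kg; the body-weight coefficient 0.022 (kg DM per kg BW)
    becomes kg DM per kg^0.75 via the herd-mean ratio BW/MBW with
    BW = MBW^(4/3).  Returned rounded to 3 decimals, as reported.
    """
    if mean_mbw <= 0:
        raise DomainError("mean MBW must be positive")
    ecm_coeff = 0.305 * MCAL_NEL_PER_KG_ECM
    mean_bw = bw_from_mbw(mean_mbw)
    mbw_coeff = 0.022 * mean_bw / mean_mbw
    return round(ecm_coeff, 3), round(mbw_coeff, 3)


def minimal_energy_content(ecm_coeff: float = 0.30) -> float:
    """Feed energy density (kJ/kg DM) implied by an ECM regression coefficient.

    With 4,765 kJ ME per kg ECM, a partial coefficient of c kg DM per kg ECM
    requires a diet of at least 4765/c kJ/kg for lactation efficiency to stay
    below 100 % — the argument against very small fitted ECM coefficients.
    """
    if ecm_coeff <= 0:
        raise DomainError("coefficient must be positive")
    return ME_KJ_PER_KG_ECM / ecm_coeff


DEFAULT_PERIOD_BREAKS = ((1, 4), (5, 9), (10, 13), (14, 35), (36, 44))


def lactation_period_class(week, breaks=DEFAULT_PERIOD_BREAKS):
    """Map lactation week (1..44) to the residual-variance period class 1..5.

    Default bins approximate lactation months 1, 2, 3, 4–8 and 9–11.
    """
    w = np.asarray(week, dtype=int)
    out = np.zeros(w.shape, dtype=int)
    for k, (lo, hi) in enumerate(breaks, start=1):
        out[(w >= lo) & (w <= hi)] = k
    if (out == 0).any():
        raise DomainError("lactation week outside configured period classes")
    return out if out.ndim else int(out)


def derive_columns(records: pd.DataFrame, energy_density: float = DEFAULT_ENERGY_DENSITY) -> pd.DataFrame:
    """Append derived phenotype columns to a weekly record table.

    Expects columns: milk, fat, protein, lactose (g/kg), bw, delta_bw, bcs,
    dmi, week and either mei or dmi (MEI falls back to DMI × energy density).
    Adds: ecm, mbw, bwl, bwg, edmi_rdc, edmi_nrc2021, ece, dim, period.
    """
    df = records.copy()
    df["ecm"] = ecm(df["milk"], df["fat"], df["protein"], df["lactose"])
    df["mbw"] = mbw(df["bw"])
    bwl, bwg = split_bw_change(df["delta_bw"].to_numpy())
    df["bwl"], df["bwg"] = bwl, bwg
    df["edmi_rdc"] = edmi_rdc(df["ecm"], df["mbw"], df["bwl"], df["bwg"])
    if "dim" not in df.columns:
        df["dim"] = 7 * df["week"].astype(int) - 2
    if "mei" not in df.columns:
        df["mei"] = df["dmi"] * energy_density
    df["edmi_nrc2021"] = edmi_nrc2021(
        milk_energy_from_ecm(df["ecm"]), df["bw"], df["bcs"], df["dim"]
    )
    df["ece"] = ece(df["ecm"], df["mei"])
    df["period"] = lactation_period_class(df["week"])
    return df
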