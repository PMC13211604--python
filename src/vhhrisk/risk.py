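"""Point-estimate inhalation exposure and risk model with threshold classes.

The exposure concentration is

    EC = CA · ET · EF · ED / AT        [μg m⁻³]

with CA the ambient mass concentration, ET exposure time (h d⁻¹), EF exposure
frequency (d a⁻¹), ED exposure duration (a) and AT averaging time (h).  With
the resident-adult defaults (ET 24, EF 365, ED 74.8, AT = ED·365·24) the time
factor cancels to exactly 1, so EC equals CA.

Carcinogenic risk: LCR = EC · IUR (IUR per μg m⁻³).  Non-carcinogenic risk:
HQ = EC / (RfC · 1000) (RfC in mg m⁻³; the 1000 converts to μg m⁻³), and the
hazard index HI is the plain sum of HQs over assessed species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .registry import MOLAR_VOLUME_25C, SpeciesRegistry, pptv_to_ugm3

#: Lifetime-cancer-risk thresholds: below ACCEPTABLE is negligible, above
#: TOLERABLE is definite concern, the closed interval between is "potential".
LCR_ACCEPTABLE = 1e-6
LCR_TOLERABLE = 1e-4
#: Hazard quotients / indices above 1 flag potential non-carcinogenic risk.
HI_THRESHOLD = 1.0

NEGLIGIBLE = "negligible"
POTENTIAL_CANCER = "potential carcinogenic risk"
DEFINITE_CANCER = "definite carcinogenic concern"
POTENTIAL_NONCANCER = "potential non-carcinogenic risk"


@dataclass(frozen=True)
class ExposureParameters:
    """Resident-adult inhalation exposure defaults."""

    et: float = 24.0  # h d⁻¹
    ef: float = 365.0  # d a⁻¹
    ed: float = 74.8  # a
    at: float = 74.8 * 365.0 * 24.0  # h

    def __post_init__(self):
        for name in ("et", "ef", "ed", "at"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def exposure_concentration(ca, params: ExposureParameters = ExposureParameters()):
    """EC = CA·ET·EF·ED/AT; CA and the result in μg m⁻³."""
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0):
        raise ValueError("CA must be >= 0")
    out = ca_arr * params.et * params.ef * params.ed / params.at
    return out.item() if np.isscalar(ca) or out.ndim == 0 else out


def lifetime_cancer_risk(ec, iur: float):
    """LCR = EC × IUR (dimensionless)."""
    ec_arr = np.asarray(ec, dtype=float)
    if np.any(ec_arr < 0) or iur < 0:
        raise ValueError("EC and IUR must be >= 0")
    out = ec_arr * iur
    return out.item() if np.isscalar(ec) or out.ndim == 0 else out


def hazard_quotient(ec, rfc: float):
    """HQ = EC / (RfC·1000); RfC in mg m⁻³, EC in μg m⁻³."""
    if not rfc > 0:
        raise ValueError("RfC must be > 0")
    ec_arr = np.asarray(ec, dtype=float)
    if np.any(ec_arr < 0):
        raise ValueError("EC must be >= 0")
    out = ec_arr / (rfc * 1000.0)
    return out.item() if np.isscalar(ec) or out.ndim == 0 else out


def hazard_index(hqs: Iterable[float]) -> float:
    """HI = Σ HQᵢ over the assessed species."""
    values = [float(h) for h in hqs]
    if not values:
        raise ValueError("need at least one hazard quotient")
    return float(sum(values))


def classify_risk(value: float, kind: str = "cancer") -> str:
    """Threshold classification for an LCR (``kind='cancer'``) or an HQ/HI
    (``kind='hazard'``).  Values exactly at 1e-6 fall in the potential band
    (closed lower bound)."""
    v = float(value)
    if math.isnan(v) or v < 0:
        raise ValueError("risk value must be finite and >= 0")
    if kind == "cancer":
        if v < LCR_ACCEPTABLE:
            return NEGLIGIBLE
        if v <= LCR_TOLERABLE:
            return POTENTIAL_CANCER
        return DEFINITE_CANCER
    if kind == "hazard":
        return NEGLIGIBLE if v <= HI_THRESHOLD else POTENTIAL_NONCANCER
    raise ValueError(f"unknown kind {kind!r}")


def risk_table(
    registry: SpeciesRegistry,
    means_pptv: pd.Series,
    params: ExposureParameters = ExposureParameters(),
    molar_volume: float = MOLAR_VOLUME_25C,
) -> pd.DataFrame:
    """Per-species deterministic risk chain plus a totals row.

    LCR appears only for species with an IUR, HQ only for species with an
    RfC; the totals row carries the cumulative LCR and the HI with their
    classifications.
    """
    rows = []
    for rec in registry:
        if rec.name not in means_pptv.index:
            continue
        ca_pptv = float(means_pptv[rec.name])
        ca = pptv_to_ugm3(ca_pptv, rec.molecular_weight, molar_volume)
        ec = exposure_concentration(ca, params)
        lcr = lifetime_cancer_risk(ec, rec.iur) if rec.iur is not None else None
        hq = hazard_quotient(ec, rec.rfc) if rec.rfc is not None else None
        rows.append(
            {
                "species": rec.name,
                "CA_pptv": ca_pptv,
                "CA_ugm3": ca,
                "EC": ec,
                "LCR": lcr,
                "HQ": hq,
                "class": classify_risk(lcr, "cancer") if lcr is not None else
                (classify_risk(hq, "hazard") if hq is not None else ""),
            }
        )
    table = pd.DataFrame(rows)
    lcr_total = float(table["LCR"].dropna().sum()) if table["LCR"].notna().any() else None
    hi = hazard_index(table["HQ"].dropna()) if table["HQ"].notna().any() else None
    totals = {
        "species": "TOTAL",
        "CA_pptv": float(table["CA_pptv"].sum()),
        "CA_ugm3": float(table["CA_ugm3"].sum()),
        "EC": float(table["EC"].sum()),
        "LCR": lcr_total,
        "HQ": hi,
        "class": classify_risk(lcr_total, "cancer") if lcr_total is not None else "",
    }
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)
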