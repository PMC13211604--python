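"""Species metadata registry and mixing-ratio/mass-concentration conversions.

The campaign works in mixing ratios (pptv) while the inhalation risk
equations require mass concentrations (μg m⁻³).  Conversion uses the ideal-gas
molar volume; the packaged default is 24.45 L mol⁻¹ (25 °C, 1 atm), exposed as
a parameter because the field convention varies between 20 and 25 °C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional

import math

import pandas as pd

#: Ideal-gas molar volume at 25 °C and 1 atm, L mol⁻¹.
MOLAR_VOLUME_25C = 24.45

REGULATED = "regulated_CFC"
UNREGULATED = "unregulated_VSLS"
CATEGORIES = frozenset({REGULATED, UNREGULATED})


@dataclass(frozen=True)
class SpeciesRecord:
    """Physical and toxicological constants for one halocarbon.

    ``iur`` (inhalation unit risk, per μg m⁻³) and ``rfc`` (reference
    concentration, mg m⁻³) are optional: species lacking a published value are
    simply excluded from the corresponding risk sums.  ``campaign_mean`` and
    ``campaign_sd`` (pptv) carry the observed campaign moments when the record
    comes from a campaign summary table.
    """

    name: str
    category: str
    molecular_weight: float  # g mol⁻¹
    mdl: float  # pptv
    lifetime: Optional[float] = None  # years
    odp: Optional[float] = None
    gwp100: Optional[float] = None
    background: Optional[float] = None  # pptv
    iur: Optional[float] = None  # per (μg m⁻³)
    rfc: Optional[float] = None  # mg m⁻³
    campaign_mean: Optional[float] = None  # pptv
    campaign_sd: Optional[float] = None  # pptv

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for {self.name!r}; "
                f"expected one of {sorted(CATEGORIES)}"
            )
        if not self.molecular_weight > 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if self.mdl < 0:
            raise ValueError(f"{self.name}: mdl must be >= 0")
        if self.lifetime is not None and not self.lifetime > 0:
            raise ValueError(f"{self.name}: lifetime must be > 0")
        if self.iur is not None and self.iur < 0:
            raise ValueError(f"{self.name}: iur must be >= 0")
        if self.rfc is not None and not self.rfc > 0:
            raise ValueError(f"{self.name}: rfc must be > 0")


class SpeciesRegistry:
    """Ordered, name-keyed collection of :class:`SpeciesRecord`."""

    def __init__(self, records: Iterable[SpeciesRecord]):
        self._records: dict[str, SpeciesRecord] = {}
        for rec in records:
            if rec.name in self._records:
                raise ValueError(f"duplicate species name {rec.name!r}")
            self._records[rec.name] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self._records.values())

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __getitem__(self, name: str) -> SpeciesRecord:
        return self._records[name]

    @property
    def names(self) -> list[str]:
        return list(self._records)

    def subset(self, names: Iterable[str]) -> "SpeciesRegistry":
        return SpeciesRegistry(self._records[n] for n in names)

    def by_category(self, category: str) -> list[SpeciesRecord]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [r for r in self if r.category == category]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) | {} for r in self]).set_index("name")


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() in ("", "/"):
        return None
    return float(value)


def load_registry(table: pd.DataFrame) -> SpeciesRegistry:
    """Build a validated registry from a species parameter table.

    Required columns: ``name``, ``category``, ``mw``, ``mdl``.  All other
    columns are optional; empty cells become absent values.
    """
    required = {"name", "category", "mw", "mdl"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")

    def get(row, col):
        return _opt(row[col]) if col in table.columns else None

    records = []
    for _, row in table.iterrows():
        records.append(
            SpeciesRecord(
                name=str(row["name"]),
                category=str(row["category"]),
                molecular_weight=float(row["mw"]),
                mdl=float(row["mdl"]),
                lifetime=get(row, "lifetime"),
                odp=get(row, "odp"),
                gwp100=get(row, "gwp100"),
                background=get(row, "background"),
                iur=get(row, "iur"),
                rfc=get(row, "rfc"),
                campaign_mean=get(row, "campaign_mean"),
                campaign_sd=get(row, "campaign_sd"),
            )
        )
    return SpeciesRegistry(records)


def default_registry() -> SpeciesRegistry:
    """Load the packaged 14-species campaign fixture."""
    with resources.files("vhhrisk.data").joinpath("species.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    return load_registry(table)


def pptv_to_ugm3(mixing_ratio, molecular_weight: float, molar_volume: float = MOLAR_VOLUME_25C):
    """Convert a mixing ratio in pptv to a mass concentration in μg m⁻³.

    c[μg m⁻³] = x[pptv] · MW[g mol⁻¹] / (V_m[L mol⁻¹] · 1000).

    Accepts scalars or arrays; linear in ``mixing_ratio``.
    """
    import numpy as np

    x = np.asarray(mixing_ratio, dtype=float)
    if np.any(x < 0):
        raise ValueError("mixing_ratio must be >= 0")
    if not molar_volume > 0:
        raise ValueError("molar_volume must be > 0")
    out = x * molecular_weight / (molar_volume * 1000.0)
    return out.item() if np.isscalar(mixing_ratio) or out.ndim == 0 else out


def ugm3_to_pptv(concentration, molecular_weight: float, molar_volume: float = MOLAR_VOLUME_25C):
    """Inverse of :func:`pptv_to_ugm3`; roundtrips to ~1e-12 relative error."""
    import numpy as np

    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    if not molar_volume > 0:
        raise ValueError("molar_volume must be > 0")
    out = c * (molar_volume * 1000.0) / molecular_weight
    return out.item() if np.isscalar(concentration) or out.ndim == 0 else out
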