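"""Composition, diurnal, correlation, tracer-regression and background
enhancement statistics for a sample × species campaign matrix."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import REGULATED, UNREGULATED, SpeciesRegistry


@dataclass
class ConcentrationMatrix:
    """Samples × species mixing ratios (pptv) with time labels and MDL flags.

    ``values`` columns are species names in registry order; ``below_mdl`` has
    the same shape and marks measurements under the species detection limit.
    ``timestamps`` carries one row per sample with ``date`` and ``window``
    (diurnal window start label, e.g. "08:00").
    """

    values: pd.DataFrame
    timestamps: pd.DataFrame
    below_mdl: pd.DataFrame

    def __post_init__(self):
        if self.below_mdl.shape != self.values.shape:
            raise ValueError("below_mdl flags must match values shape")
        if len(self.timestamps) != len(self.values):
            raise ValueError("one timestamp row per sample required")
        finite = self.values.to_numpy(dtype=float)
        if np.any(finite[np.isfinite(finite)] < 0):
            raise ValueError("concentrations must be >= 0 or missing")

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def windows(self) -> list[str]:
        seen: list[str] = []
        for w in self.timestamps["window"]:
            if w not in seen:
                seen.append(w)
        return seen

    def to_csv(self, path) -> None:
        out = pd.concat(
            [self.timestamps.reset_index(drop=True), self.values.reset_index(drop=True)], axis=1
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, registry: SpeciesRegistry) -> "ConcentrationMatrix":
        raw = pd.read_csv(path)
        meta_cols = [c for c in ("date", "window") if c in raw.columns]
        species = [n for n in registry.names if n in raw.columns]
        values = raw[species].astype(float)
        mdls = pd.Series({n: registry[n].mdl for n in species})
        flags = values.lt(mdls, axis=1) | values.isna()
        return cls(values=values, timestamps=raw[meta_cols].copy(), below_mdl=flags)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.values.round(12).to_csv(index=False).encode())
        h.update(self.timestamps.to_csv(index=False).encode())
        return h.hexdigest()


@dataclass
class CompositionSummary:
    table: pd.DataFrame  # species, category, mean, sd, share_pct
    grand_total: float  # pptv, sum of per-species means
    group_totals: dict  # category -> pptv
    group_shares: dict  # category -> %


@dataclass
class EnhancementResult:
    species: str
    observed_mean: float  # pptv
    background: float  # pptv
    absolute_enhancement: float  # pptv
    percent_enhancement: float  # %


@dataclass
class DiurnalProfile:
    window_means: pd.DataFrame  # windows × species
    window_sds: pd.DataFrame  # windows × species
    sd_of_window_means: pd.Series  # per species; spread of the diurnal cycle


def detection_filter(
    matrix: ConcentrationMatrix, threshold: float = 0.60
) -> tuple[ConcentrationMatrix, list[str]]:
    """Retain species detected (above MDL, non-missing) in strictly more than
    ``threshold`` of samples.  Returns the filtered matrix and dropped names."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    detected = (~matrix.below_mdl) & matrix.values.notna()
    frac = detected.sum(axis=0) / matrix.n_samples
    keep = [s for s in matrix.species if frac[s] > threshold]
    dropped = [s for s in matrix.species if frac[s] <= threshold]
    filtered = ConcentrationMatrix(
        values=matrix.values[keep].copy(),
        timestamps=matrix.timestamps.copy(),
        below_mdl=matrix.below_mdl[keep].copy(),
    )
    return filtered, dropped


def composition_summary(
    matrix: ConcentrationMatrix, registry: SpeciesRegistry
) -> CompositionSummary:
    """Per-species means/SDs and shares of the grand total of means.

    Shares are computed on means-of-samples (the standard presentation for a
    campaign), not as averaged per-sample shares.
    """
    if matrix.n_samples < 1:
        raise ValueError("empty matrix")
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=1) if matrix.n_samples > 1 else means * 0.0
    grand = float(means.sum())
    if grand <= 0:
        raise ValueError("grand total must be positive")
    cats = {s: registry[s].category for s in matrix.species}
    table = pd.DataFrame(
        {
            "species": matrix.species,
            "category": [cats[s] for s in matrix.species],
            "mean": means.values,
            "sd": sds.values,
            "share_pct": 100.0 * means.values / grand,
        }
    )
    group_totals = {
        cat: float(means[[s for s in matrix.species if cats[s] == cat]].sum())
        for cat in (REGULATED, UNREGULATED)
    }
    group_shares = {cat: 100.0 * tot / grand for cat, tot in group_totals.items()}
    return CompositionSummary(table, grand, group_totals, group_shares)


def diurnal_profile(matrix: ConcentrationMatrix) -> DiurnalProfile:
    """Window means/SDs per species and the SD across window means (the
    amplitude statistic used to call a diurnal cycle flat or U-shaped)."""
    if "window" not in matrix.timestamps.columns:
        raise ValueError("samples need a window label")
    windows = matrix.windows
    grouped = matrix.values.groupby(matrix.timestamps["window"].values)
    means = grouped.mean().reindex(windows)
    sds = grouped.std(ddof=1).reindex(windows)
    sd_across = means.std(axis=0, ddof=1)
    return DiurnalProfile(means, sds, sd_across)


def correlation_matrix(
    matrix: ConcentrationMatrix, tracer: Optional[pd.Series] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson R with two-sided p-values (t-transform).

    Zero-variance columns yield NaN for their pairs (undefined, not a number
    pretending otherwise).  ``tracer`` is appended as an extra column.
    """
    data = matrix.values.copy()
    if tracer is not None:
        data[tracer.name or "tracer"] = np.asarray(tracer, dtype=float)
    cols = list(data.columns)
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    arr = data.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = arr[:, i], arr[:, j]
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 3 or np.std(xi[ok]) == 0 or np.std(xj[ok]) == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            res = stats.pearsonr(xi[ok], xj[ok])
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    return r, p


@dataclass
class TracerRegression:
    slope: float
    slope_se: float
    intercept: float
    r: float


def tracer_regression(species: Sequence[float], tracer: Sequence[float]) -> TracerRegression:
    """OLS of a species series on a tracer series (slope ± SE and Pearson R)."""
    y = np.asarray(species, dtype=float)
    x = np.asarray(tracer, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(x) == 0:
        raise ValueError("tracer series has zero variance")
    res = stats.linregress(x, y)
    return TracerRegression(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r=float(res.rvalue),
    )


def background_enhancement(
    species: str, observed_mean: float, background: float
) -> EnhancementResult:
    """Absolute (pptv) and percentage enhancement of a campaign mean over the
    concurrent hemispheric background level."""
    if not background > 0:
        raise ValueError("background must be > 0")
    absolute = observed_mean - background
    return EnhancementResult(
        species=species,
        observed_mean=float(observed_mean),
        background=float(background),
        absolute_enhancement=float(absolute),
        percent_enhancement=float(100.0 * absolute / background),
    )


def enhancement_table(registry: SpeciesRegistry, means: pd.Series) -> pd.DataFrame:
    """Enhancements for every species with a background record."""
    rows = []
    for rec in registry:
        if rec.background is None or rec.name not in means.index:
            continue
        e = background_enhancement(rec.name, float(means[rec.name]), rec.background)
        rows.append(
            {
                "species": e.species,
                "observed": e.observed_mean,
                "background": e.background,
                "abs_enhancement": e.absolute_enhancement,
                "pct_enhancement": e.percent_enhancement,
            }
        )
    return pd.DataFrame(rows)
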