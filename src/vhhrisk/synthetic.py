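"""Synthetic halocarbon campaign generator with planted ground truth.

The generator emulates the statistical structure of a short summer canister
campaign in an industrial basin city: 7 sampling days × 7 daylight windows,
14 species (6 regulated CFCs, 8 unregulated chlorinated VSLSs), a 4-source
latent structure (CFC-bank leakage, industrial processes, solvent use,
electronics-industry cleaning agents), lognormal concentration marginals,
near-constant regulated CFCs, a U-shaped VSLS diurnal cycle, and a CO tracer
coupled to the solvent-heavy source.

Every sample is an exact nonnegative factorization perturbed by multiplicative
lognormal noise,

    X = (G_true · F_true) ∘ N,   E[N] = 1,

so positive-matrix-factorization recovery can be scored against the planted
contribution and profile matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .descriptive import ConcentrationMatrix
from .distributions import lognormal_params_from_moments
from .registry import REGULATED, SpeciesRegistry, default_registry

DEFAULT_WINDOWS = ("08:00", "10:00", "12:00", "14:00", "16:00", "18:00", "20:00")
#: Campaign dates: seven rain-free days of a ten-day summer window.
DEFAULT_DATES = (
    "2019-08-15", "2019-08-16", "2019-08-17", "2019-08-18",
    "2019-08-22", "2019-08-23", "2019-08-24",
)

FACTOR_NAMES = ("cfc_banks", "industrial_process", "solvent_use", "electronics_cleaning")
#: Planted mass shares (%) for the four sources, in FACTOR_NAMES order.
DEFAULT_SHARES = (19.9, 27.8, 23.7, 28.6)


def _unit_mean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v / v.mean()


#: Afternoon-minimum diurnal multipliers (mean exactly 1 per source) for the
#: three industrial sources; the CFC-bank source stays flat.  Morning and
#: evening peaks reflect boundary-layer dynamics plus working-hour activity,
#: with a pronounced mid-afternoon minimum.
INDUSTRIAL_U_SHAPES = (
    _unit_mean((1.60, 1.35, 0.95, 0.70, 0.60, 0.80, 1.00)),  # industrial_process
    _unit_mean((1.50, 1.45, 1.00, 0.70, 0.60, 0.80, 0.95)),  # solvent_use
    _unit_mean((1.35, 1.25, 0.95, 0.72, 0.62, 0.90, 1.20)),  # electronics_cleaning
)

#: Default expected VSLS means (pptv), an urban summer campaign scale.
DEFAULT_VSLS_MEANS = {
    "Chloromethane": 450.0,
    "Methylene chloride": 520.0,
    "1,1-Dichloroethane": 150.0,
    "Chloroform": 110.0,
    "1,2-Dichloroethane": 420.0,
    "1,2-Dichloropropane": 130.0,
    "Trichloroethylene": 300.0,
    "Tetrachloroethylene": 200.0,
}

#: Relative regulated-CFC abundances.  The absolute CFC means are derived in
#: :func:`default_campaign_config` so that the CFC mass budget equals the
#: planted CFC-bank share exactly (the bank factor carries only CFCs, so the
#: two must be consistent; see docs/methods.md).
_CFC_PROPORTIONS = {
    "Freon-12": 563.0,
    "Freon-114": 17.0,
    "Bromomethane": 21.0,
    "Freon-11": 264.0,
    "Freon-113": 81.0,
    "Carbon tetrachloride": 92.0,
}

#: Allocation seed: fraction of each species' mass attributed to
#: (cfc_banks, industrial_process, solvent_use, electronics_cleaning) before
#: biproportional fitting.  Columns sum to 1.  The exact zeros are deliberate
#: sparsity anchors: each industrial source has at least one exclusive
#: species and the bank source carries only CFCs, which is what makes the
#: planted factorization (mostly) identifiable.
_ALLOCATION_SEED = {
    "Freon-12": (1.0, 0.0, 0.0, 0.0),
    "Freon-114": (1.0, 0.0, 0.0, 0.0),
    "Bromomethane": (1.0, 0.0, 0.0, 0.0),
    "Freon-11": (1.0, 0.0, 0.0, 0.0),
    "Freon-113": (1.0, 0.0, 0.0, 0.0),
    "Carbon tetrachloride": (1.0, 0.0, 0.0, 0.0),
    "Chloromethane": (0.0, 0.08, 0.10, 0.82),
    "Methylene chloride": (0.0, 0.0, 0.88, 0.12),
    "1,1-Dichloroethane": (0.0, 1.0, 0.0, 0.0),
    "Chloroform": (0.0, 0.22, 0.60, 0.18),
    "1,2-Dichloroethane": (0.0, 0.95, 0.0, 0.05),
    "1,2-Dichloropropane": (0.0, 0.92, 0.0, 0.08),
    "Trichloroethylene": (0.0, 0.0, 0.0, 1.0),
    "Tetrachloroethylene": (0.0, 0.0, 0.06, 0.94),
}

#: Temporal variability (lognormal sigma of the mean-1 activity series) per
#: source: bank leakage is nearly constant; industrial activity fluctuates
#: with the wide swings (CV near 1) seen in urban VSLS records.
DEFAULT_SOURCE_SIGMAS = (0.015, 0.8, 0.8, 0.8)

#: Measurement/representativeness noise scaling per regulatory class: the
#: long-lived regulated CFCs are well mixed and measured near the top of the
#: calibration range, so their effective noise is a fifth of the VSLS one.
REGULATED_NOISE_SCALE = 0.2


def _ipf(mass: np.ndarray, row_targets: np.ndarray, col_targets: np.ndarray,
         n_iter: int = 500) -> np.ndarray:
    """Biproportional (IPF/RAS) fit of a positive matrix to row/col totals."""
    t = mass.astype(float).copy()
    for _ in range(n_iter):
        t *= (row_targets / t.sum(axis=1))[:, None]
        t *= col_targets / t.sum(axis=0)
    return t


@dataclass
class CampaignConfig:
    """Full parameterisation of one synthetic campaign."""

    species: SpeciesRegistry
    source_profiles: np.ndarray  # sources × species, rows sum to 1
    source_scales: np.ndarray  # per-source (mean contribution pptv, lognormal sigma)
    source_diurnal: np.ndarray  # sources × windows multipliers, > 0
    n_days: int = 7
    windows: Sequence[str] = DEFAULT_WINDOWS
    dates: Sequence[str] = DEFAULT_DATES
    n_sources: int = 4
    source_names: Sequence[str] = FACTOR_NAMES
    noise_fraction: float = 0.1
    species_noise_scale: Optional[np.ndarray] = None  # per-species multiplier on noise
    tracer_coupling: np.ndarray = None  # per-source coefficient onto the CO tracer
    tracer_base: float = 150.0  # ppbv
    tracer_noise: float = 0.05
    seed: int = 1

    def __post_init__(self):
        p, m = self.source_profiles.shape
        if p != self.n_sources:
            raise ValueError("source_profiles rows must equal n_sources")
        if m != len(self.species):
            raise ValueError("source_profiles columns must match the registry")
        if np.any(self.source_profiles < 0):
            raise ValueError("source profiles must be nonnegative")
        if not np.allclose(self.source_profiles.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each source profile row must sum to 1")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if len(self.windows) < 2:
            raise ValueError("need at least 2 diurnal windows")
        if np.any(self.source_diurnal <= 0):
            raise ValueError("diurnal multipliers must be > 0")
        if self.species_noise_scale is None:
            self.species_noise_scale = np.ones(m)
        if self.tracer_coupling is None:
            self.tracer_coupling = np.zeros(p)

    @property
    def expected_shares(self) -> np.ndarray:
        """Planted mass shares (%) implied by the source scales."""
        s = self.source_scales[:, 0]
        return 100.0 * s / s.sum()


@dataclass
class SyntheticCampaign:
    concentrations: ConcentrationMatrix
    true_contributions: pd.DataFrame  # samples × sources, pptv
    true_profiles: pd.DataFrame  # sources × species, rows sum to 1
    tracer: pd.Series  # per-sample CO, ppbv
    config: CampaignConfig

    @property
    def true_shares(self) -> pd.Series:
        """Realized source mass shares (%) of this draw."""
        mass = self.true_contributions.sum(axis=0)
        return 100.0 * mass / mass.sum()

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.concentrations.to_csv(outdir / "campaign.csv")
        self.true_contributions.to_csv(outdir / "G_true.csv")
        self.true_profiles.to_csv(outdir / "F_true.csv")
        self.tracer.to_frame().to_csv(outdir / "tracer.csv", index=False)


def default_campaign_config(
    registry: Optional[SpeciesRegistry] = None,
    seed: int = 1,
    noise_fraction: float = 0.1,
) -> CampaignConfig:
    """Study-condition defaults: 49 samples, 14 species, 4 planted sources.

    Source profiles are derived once, deterministically, by biproportional
    fitting of the qualitative allocation seed to (a) the default species
    means and (b) the planted source shares, so the expected factor shares
    are exactly ``DEFAULT_SHARES``.  Regulated-CFC means are scaled so the
    CFC mass budget equals the planted CFC-bank share (the bank source
    carries only CFCs, so the budget must balance for the zeros to survive
    the fit).
    """
    registry = registry or default_registry()
    names = registry.names
    vsls_total = sum(DEFAULT_VSLS_MEANS.values())
    bank_share = DEFAULT_SHARES[0] / 100.0
    cfc_total = bank_share / (1.0 - bank_share) * vsls_total
    cfc_base = sum(_CFC_PROPORTIONS.values())
    means_map = {n: v / cfc_base * cfc_total for n, v in _CFC_PROPORTIONS.items()}
    means_map |= DEFAULT_VSLS_MEANS
    means = np.array([means_map[n] for n in names])
    alloc = np.array([_ALLOCATION_SEED[n] for n in names]).T  # sources × species
    total = means.sum()
    row_targets = np.asarray(DEFAULT_SHARES) / 100.0 * total
    mass = _ipf(alloc * means, row_targets, means)
    profiles = mass / mass.sum(axis=1, keepdims=True)
    scales = np.column_stack([mass.sum(axis=1), DEFAULT_SOURCE_SIGMAS])
    diurnal = np.vstack([np.ones(7), np.vstack(INDUSTRIAL_U_SHAPES)])
    noise_scale = np.array(
        [REGULATED_NOISE_SCALE if registry[n].category == REGULATED else 1.0 for n in names]
    )
    return CampaignConfig(
        species=registry,
        source_profiles=profiles,
        source_scales=scales,
        source_diurnal=diurnal,
        noise_fraction=noise_fraction,
        species_noise_scale=noise_scale,
        tracer_coupling=np.array([0.0, 0.03, 0.03, 0.25]),
        seed=seed,
    )


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Multiplicative lognormal factor with unit mean."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_campaign(config: CampaignConfig) -> SyntheticCampaign:
    """Draw one campaign; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    names = config.species.names
    n_w = len(config.windows)
    n = config.n_days * n_w
    p = config.n_sources

    dates = list(config.dates)[: config.n_days]
    if len(dates) < config.n_days:
        dates = [f"day{d+1:02d}" for d in range(config.n_days)]
    ts = pd.DataFrame(
        {
            "date": np.repeat(dates, n_w),
            "window": np.tile(list(config.windows), config.n_days),
        }
    )
    window_idx = np.tile(np.arange(n_w), config.n_days)

    scales = config.source_scales[:, 0]
    sigmas = config.source_scales[:, 1]
    activity = np.column_stack([_mean_one_lognormal(rng, s, n) for s in sigmas])
    g = activity * scales * config.source_diurnal[:, window_idx].T  # samples × sources
    x_clean = g @ config.source_profiles

    noise_sigma = config.noise_fraction * config.species_noise_scale
    noise = np.column_stack([_mean_one_lognormal(rng, s, n) for s in noise_sigma])
    x = x_clean * noise

    mdls = np.array([config.species[nm].mdl for nm in names])
    values = pd.DataFrame(x, columns=names)
    flags = pd.DataFrame(x < mdls, columns=names)

    tracer = pd.Series(
        config.tracer_base * _mean_one_lognormal(rng, config.tracer_noise, n)
        + g @ config.tracer_coupling,
        name="CO",
    )
    return SyntheticCampaign(
        concentrations=ConcentrationMatrix(values=values, timestamps=ts, below_mdl=flags),
        true_contributions=pd.DataFrame(g, columns=list(config.source_names)),
        true_profiles=pd.DataFrame(
            config.source_profiles, index=list(config.source_names), columns=names
        ),
        tracer=tracer,
        config=config,
    )


def generate_pmf_testcase(
    n_samples: int,
    n_species: int,
    n_sources: int,
    noise_fraction: float = 0.1,
    seed: int = 0,
    off_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Random planted factorization oracle for the PMF solver.

    Returns ``(X, U, G_true, F_true)`` where ``X = (G F) ∘ N`` with mean-one
    lognormal noise and ``U`` follows the proportional-error uncertainty rule
    with synthetic MDLs at 5% of each species' mean.

    The planted structure is identifiable by construction: every source has
    one exclusive marker species (exact zeros for the other sources) and is
    switched off in a random ``off_fraction`` of samples.  Without both kinds
    of zeros, exact nonnegative factorizations are non-unique — a rotation
    cone of equally valid solutions exists — and no solver could be expected
    to recover the planted factors.
    """
    if n_sources > min(n_samples, n_species):
        raise ValueError("n_sources must not exceed min(n_samples, n_species)")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.full(n_species, 0.8), size=n_sources)
    for k in range(n_sources):  # species k becomes the marker of source k
        marker = np.zeros(n_sources)
        marker[k] = f[:, k].sum()
        f[:, k] = marker
    f /= f.sum(axis=1, keepdims=True)
    scales = rng.uniform(50.0, 200.0, size=n_sources)
    g = scales * _mean_one_lognormal(rng, 0.5, (n_samples, n_sources))
    g[rng.uniform(size=g.shape) < off_fraction] = 0.0
    x_clean = g @ f
    x = x_clean * _mean_one_lognormal(rng, noise_fraction, x_clean.shape)
    mdl = 0.05 * x.mean(axis=0)
    u = np.sqrt((0.1 * x) ** 2 + mdl**2)
    return x, u, g, f


def generate_lognormal_series(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """Lognormal draws with parameters moment-matched to (mean, sd)."""
    if not mean > 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = lognormal_params_from_moments(mean, sd)
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=sigma, size=n)
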