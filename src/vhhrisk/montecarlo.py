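"""Replicated Monte-Carlo propagation of the risk chain with an MCE/SD
convergence diagnostic.

The design replicates the simulation: ``n_rep`` independent replications of
``n_iter`` draws each.  The Monte-Carlo error (MCE) of an output is the
standard deviation of the replication means; SD is the *minimum* within-
replication standard deviation (a conservative reading that inflates the
ratio); convergence is accepted when 100·MCE/SD falls below 5%.

Randomness uses one master ``SeedSequence`` spawning per-replication
substreams, so results are bit-reproducible and the first k replications do
not change when ``n_rep`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .distributions import DistributionSpec
from .registry import MOLAR_VOLUME_25C, SpeciesRegistry, pptv_to_ugm3

#: acceptance bound (%) on the MCE/SD convergence ratio
MCE_SD_ACCEPTANCE = 5.0

ModelFn = Callable[[Mapping[str, np.ndarray]], Mapping[str, np.ndarray]]


@dataclass
class MCConfig:
    input_specs: dict  # name -> DistributionSpec
    n_iter: int = 10_000
    n_rep: int = 100
    seed: int = 0
    at_rule: str = "derived"  # "derived": AT = ED·365·24 per draw; else spec "AT"

    def __post_init__(self):
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        if self.at_rule not in ("derived", "independent"):
            raise ValueError("at_rule must be 'derived' or 'independent'")
        if not self.input_specs:
            raise ValueError("no input specs supplied")
        for name, spec in self.input_specs.items():
            if not isinstance(spec, DistributionSpec):
                raise ValueError(f"input {name!r} is not a DistributionSpec")


@dataclass
class OutputSummary:
    mean: float
    median: float
    p95: float
    mce: float
    sd: Optional[float]  # minimum replication SD; None if undefined (zero spread)
    mce_sd_ratio: Optional[float]  # %, None when SD is undefined
    passed: Optional[bool]

    @property
    def converged(self) -> bool:
        return bool(self.passed)


@dataclass
class MCResult:
    outputs: dict  # name -> OutputSummary
    replication_means: pd.DataFrame  # n_rep × outputs
    replication_sds: pd.DataFrame
    n_iter: int
    n_rep: int
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.outputs.items():
            rows.append(
                {
                    "output": name,
                    "mean": s.mean,
                    "median": s.median,
                    "p95": s.p95,
                    "MCE": s.mce,
                    "SD": s.sd,
                    "mce_sd_ratio_pct": s.mce_sd_ratio,
                    "converged": s.passed,
                }
            )
        return pd.DataFrame(rows)


def summarize_draws(draws: np.ndarray) -> tuple[float, float, float]:
    """Empirical (mean, median, 95th percentile); p95 by linear interpolation."""
    d = np.asarray(draws, dtype=float)
    if d.size < 1:
        raise ValueError("empty draws")
    return float(np.mean(d)), float(np.median(d)), float(np.percentile(d, 95))


def mce_sd_ratio(
    replication_means: np.ndarray, replication_sds: np.ndarray
) -> tuple[float, Optional[float], Optional[float]]:
    """(MCE, SD, ratio%) from per-replication means and SDs.

    MCE is the SD of the replication means; SD is the minimum replication SD.
    A zero SD leaves the ratio undefined (returned as None, never infinity).
    """
    means = np.asarray(replication_means, dtype=float)
    sds = np.asarray(replication_sds, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 replications")
    mce = float(np.std(means, ddof=1))
    sd_min = float(np.min(sds))
    if sd_min == 0:
        return mce, None, None
    return mce, sd_min, 100.0 * mce / sd_min


def run_mc(model: ModelFn, config: MCConfig) -> MCResult:
    """Replicated Monte-Carlo run of ``model`` under ``config``.

    The model receives a dict of per-input draw vectors (length ``n_iter``)
    and returns a dict of output vectors.  Inputs are drawn in sorted name
    order within each replication so the stream layout is well defined.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_rep)
    names = sorted(config.input_specs)
    rep_means: dict[str, list] = {}
    rep_sds: dict[str, list] = {}
    pooled: dict[str, list] = {}
    for ss in streams:
        rng = np.random.default_rng(ss)
        draws = {n: config.input_specs[n].sample(rng, config.n_iter) for n in names}
        if config.at_rule == "derived" and "ED" in draws and "AT" not in draws:
            draws["AT"] = draws["ED"] * 365.0 * 24.0
        outputs = model(draws)
        for name, vec in outputs.items():
            vec = np.asarray(vec, dtype=float)
            rep_means.setdefault(name, []).append(float(np.mean(vec)))
            rep_sds.setdefault(name, []).append(float(np.std(vec, ddof=1)))
            pooled.setdefault(name, []).append(vec)

    means_df = pd.DataFrame(rep_means)
    sds_df = pd.DataFrame(rep_sds)
    summaries = {}
    for name in means_df.columns:
        all_draws = np.concatenate(pooled[name])
        mean, median, p95 = summarize_draws(all_draws)
        # spreads below fp resolution of the mean are exactly degenerate
        floor = 1e-12 * abs(mean)
        rep_m = means_df[name].to_numpy()
        rep_s = np.where(sds_df[name].to_numpy() <= floor, 0.0, sds_df[name].to_numpy())
        mce, sd, ratio = mce_sd_ratio(rep_m, rep_s)
        if mce <= floor:
            mce = 0.0
            ratio = None if sd is None else 0.0
        summaries[name] = OutputSummary(
            mean=mean,
            median=median,
            p95=p95,
            mce=mce,
            sd=sd,
            mce_sd_ratio=ratio,
            passed=None if ratio is None else bool(ratio < MCE_SD_ACCEPTANCE),
        )
    return MCResult(
        outputs=summaries,
        replication_means=means_df,
        replication_sds=sds_df,
        n_iter=config.n_iter,
        n_rep=config.n_rep,
        seed=config.seed,
    )


# -- the campaign risk model as an MC model ---------------------------------


def risk_input_specs(
    registry: SpeciesRegistry,
    species: Optional[list] = None,
    exposure_overrides: Optional[dict] = None,
) -> dict:
    """Default input specs for the probabilistic risk chain.

    Concentrations (CA, pptv) are lognormal, moment-matched to the campaign
    mean/SD of each species; exposure time and frequency are point values
    (continuous residential exposure); exposure duration is normal with 10%
    CV truncated to (0, 100] years; IUR/RfC are point toxicity values.
    All of these can be overridden.
    """
    specs: dict[str, DistributionSpec] = {}
    for rec in registry:
        if species is not None and rec.name not in species:
            continue
        if rec.campaign_mean is None:
            raise ValueError(f"{rec.name}: no campaign mean available")
        if rec.campaign_sd and rec.campaign_sd > 0:
            specs[f"CA_{rec.name}"] = DistributionSpec.lognormal_from_moments(
                rec.campaign_mean, rec.campaign_sd
            )
        else:
            specs[f"CA_{rec.name}"] = DistributionSpec.point(rec.campaign_mean)
    specs["ET"] = DistributionSpec.point(24.0)
    specs["EF"] = DistributionSpec.point(365.0)
    specs["ED"] = DistributionSpec.normal(74.8, 7.48, lower=0.0, upper=100.0)
    if exposure_overrides:
        specs.update(exposure_overrides)
    return specs


def build_risk_model(
    registry: SpeciesRegistry,
    species: Optional[list] = None,
    molar_volume: float = MOLAR_VOLUME_25C,
) -> ModelFn:
    """Vectorised risk chain over draw vectors.

    Outputs per-species LCR/HQ plus ``cumulative_LCR`` and ``HI``; species
    without an IUR (RfC) are simply absent from the respective outputs.
    """
    recs = [r for r in registry if species is None or r.name in species]

    def model(draws: Mapping[str, np.ndarray]) -> dict:
        et, ef, ed = draws["ET"], draws["EF"], draws["ED"]
        at = draws["AT"] if "AT" in draws else ed * 365.0 * 24.0
        time_factor = et * ef * ed / at
        out: dict[str, np.ndarray] = {}
        lcr_sum = None
        hq_sum = None
        for rec in recs:
            ca = pptv_to_ugm3(draws[f"CA_{rec.name}"], rec.molecular_weight, molar_volume)
            ec = ca * time_factor
            if rec.iur is not None:
                lcr = ec * rec.iur
                out[f"LCR_{rec.name}"] = lcr
                lcr_sum = lcr if lcr_sum is None else lcr_sum + lcr
            if rec.rfc is not None:
                hq = ec / (rec.rfc * 1000.0)
                out[f"HQ_{rec.name}"] = hq
                hq_sum = hq if hq_sum is None else hq_sum + hq
        if lcr_sum is not None:
            out["cumulative_LCR"] = lcr_sum
        if hq_sum is not None:
            out["HI"] = hq_sum
        return out

    return model
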