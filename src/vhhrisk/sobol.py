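"""Variance-based global sensitivity analysis: Sobol total-order indices.

The total-order index S_Tᵢ measures the fraction of output variance
attributable to input i alone or through any interaction.  Estimation uses
the Saltelli block design (base blocks A and B plus one column-swapped block
per input) with the Jansen estimator

    S_Tᵢ = (1/2N) Σ (f(A) − f(A_B⁽ⁱ⁾))² / Var(f),

with Var taken over the combined base evaluations f(A) ∪ f(B).  Inputs are
treated as independent.  When N is a power of two the base blocks come from a
scrambled Sobol' sequence (scipy.stats.qmc); otherwise plain pseudo-random
sampling is used.  Negative estimates (Monte-Carlo noise around zero) are
reported raw with their standard errors, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .distributions import DistributionSpec

ArrayModel = Callable[[np.ndarray], np.ndarray]
#: tolerance below which a negative S_T estimate is considered MC noise
NEGATIVE_TOL = 0.05


@dataclass
class SobolBlocks:
    names: list  # input order
    a: np.ndarray  # N × d
    b: np.ndarray  # N × d
    ab: list  # per input i: A with column i taken from B
    n: int
    seed: int


@dataclass
class SobolResult:
    names: list
    st: np.ndarray  # total-order indices, raw
    se: np.ndarray  # standard errors
    n: int
    seed: int
    degenerate: bool = False

    def table(self) -> pd.DataFrame:
        order = rank_inputs(self)
        rank = {name: i + 1 for i, name in enumerate(order)}
        return pd.DataFrame(
            {
                "input": self.names,
                "S_T": self.st,
                "stderr": self.se,
                "rank": [rank[n] for n in self.names],
            }
        ).sort_values("rank", ignore_index=True)


def _unit_samples(n: int, d: int, seed: int) -> np.ndarray:
    """2d-dimensional unit-cube sample: Sobol' QMC when n is a power of two."""
    if n >= 1 and (n & (n - 1)) == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
            return sampler.random(n)
    rng = np.random.default_rng(seed)
    return rng.uniform(size=(n, 2 * d))


def saltelli_matrices(
    input_specs: Mapping[str, DistributionSpec], n: int, seed: int = 0
) -> SobolBlocks:
    """Build the A/B/A_B⁽ⁱ⁾ blocks for the total-order estimator.

    Requires at least two inputs: a single-input model has S_T = 1 trivially
    and is answered directly by :func:`total_order_indices` without sampling.
    """
    names = list(input_specs)
    d = len(names)
    if d < 2:
        raise ValueError("need >= 2 inputs; a single input has S_T = 1 trivially")
    if n < 64:
        raise ValueError("base sample size must be >= 64")
    u = _unit_samples(n, d, seed)
    # clip away exact 0/1 so unbounded ppfs stay finite
    u = np.clip(u, 1e-12, 1 - 1e-12)
    a = np.column_stack([input_specs[nm].ppf(u[:, j]) for j, nm in enumerate(names)])
    b = np.column_stack([input_specs[nm].ppf(u[:, d + j]) for j, nm in enumerate(names)])
    ab = []
    for i in range(d):
        block = a.copy()
        block[:, i] = b[:, i]
        ab.append(block)
    return SobolBlocks(names=names, a=a, b=b, ab=ab, n=n, seed=seed)


def total_order_indices(model: ArrayModel, blocks: SobolBlocks) -> SobolResult:
    """Jansen total-order estimate for every input in ``blocks``.

    Standard errors come from the per-row spread of the Jansen summand
    (delta-method, variance of the numerator only).
    """
    fa = np.asarray(model(blocks.a), dtype=float)
    fb = np.asarray(model(blocks.b), dtype=float)
    var = float(np.var(np.concatenate([fa, fb]), ddof=1))
    d = len(blocks.names)
    st = np.empty(d)
    se = np.empty(d)
    if var == 0:
        return SobolResult(
            names=blocks.names,
            st=np.full(d, np.nan),
            se=np.full(d, np.nan),
            n=blocks.n,
            seed=blocks.seed,
            degenerate=True,
        )
    for i in range(d):
        fab = np.asarray(model(blocks.ab[i]), dtype=float)
        terms = 0.5 * (fa - fab) ** 2 / var
        st[i] = float(np.mean(terms))
        se[i] = float(np.std(terms, ddof=1) / np.sqrt(blocks.n))
        if st[i] < -NEGATIVE_TOL:
            warnings.warn(
                f"total-order index for {blocks.names[i]!r} is {st[i]:.3f} < 0 "
                "beyond MC noise; check the model/inputs"
            )
    return SobolResult(names=blocks.names, st=st, se=se, n=blocks.n, seed=blocks.seed)


def sobol_total_order(
    model: ArrayModel,
    input_specs: Mapping[str, DistributionSpec],
    n: int,
    seed: int = 0,
) -> SobolResult:
    """Convenience wrapper: blocks + estimation, with the 1-input shortcut."""
    names = list(input_specs)
    if len(names) == 1:
        return SobolResult(names=names, st=np.array([1.0]), se=np.array([0.0]), n=0, seed=seed)
    blocks = saltelli_matrices(input_specs, n, seed)
    return total_order_indices(model, blocks)


def rank_inputs(result: SobolResult) -> list:
    """Input names in descending S_T order; exact ties break alphabetically."""
    if result.degenerate or np.any(~np.isfinite(result.st)):
        raise ValueError("degenerate result: indices undefined")
    return [
        name
        for _, name in sorted(
            zip(result.st, result.names), key=lambda t: (-t[0], t[1])
        )
    ]


def lcr_model_for_species(
    molecular_weight: float,
    molar_volume: float = 24.45,
    at_hours: float = 74.8 * 365.0 * 24.0,
    iur: float = 1.0,
) -> ArrayModel:
    """LCR as a function of row-stacked (CA_pptv, ET, EF, ED[, IUR]) inputs.

    AT is held at an independent point value so that ED variance propagates
    (with AT derived from ED the duration cancels out of the chain).
    """

    def model(rows: np.ndarray) -> np.ndarray:
        ca = rows[:, 0] * molecular_weight / (molar_volume * 1000.0)
        ec = ca * rows[:, 1] * rows[:, 2] * rows[:, 3] / at_hours
        unit_risk = rows[:, 4] if rows.shape[1] > 4 else iur
        return ec * unit_risk

    return model
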