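"""Uncertainty-weighted positive matrix factorization (receptor model).

Decomposes a samples × species concentration matrix X into nonnegative source
contributions G and source profiles F by minimizing

    Q = Σᵢⱼ ((xᵢⱼ − Σₖ gᵢₖ fₖⱼ) / uᵢⱼ)²

with per-cell uncertainties u.  The solver uses weighted multiplicative
updates (monotone in Q) with multi-start; PMF solutions are identifiable only
up to permutation and scale, so :func:`match_factors` aligns a fitted solution
with a reference via the Hungarian assignment on cosine similarities.

Uncertainty preparation follows standard receptor-model practice: missing
cells are imputed with the species median (heavily down-weighted), below-MDL
values are replaced by MDL/2 with uncertainty 5/6·MDL, and quantified values
get u = sqrt((error_fraction·c)² + MDL²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .descriptive import ConcentrationMatrix
from .registry import SpeciesRegistry

_EPS = 1e-12

# provenance codes for prepared cells
QUANTIFIED, BELOW_MDL, IMPUTED = "quantified", "below_mdl", "imputed"


@dataclass
class UncertaintyMatrix:
    u: np.ndarray  # samples × species, concentration units, > 0
    provenance: np.ndarray  # same shape, object codes

    def __post_init__(self):
        if np.any(self.u <= 0) or not np.all(np.isfinite(self.u)):
            raise ValueError("uncertainties must be finite and > 0")


@dataclass
class PMFResult:
    G: np.ndarray  # samples × factors, nonnegative
    F: np.ndarray  # factors × species, nonnegative, rows sum to 1
    Q: float
    Q_expected: float  # data points minus fitted parameters (diagnostic)
    n_starts: int
    best_start: int
    converged: bool
    iteration_count: int
    q_trace: np.ndarray  # Q after every iteration of the winning start
    species: Optional[list] = None

    def reconstruction(self) -> np.ndarray:
        return self.G @ self.F


def assign_uncertainties(
    matrix: ConcentrationMatrix,
    registry: SpeciesRegistry,
    error_fraction: float = 0.1,
    missing_uncertainty_factor: float = 4.0,
) -> tuple[np.ndarray, UncertaintyMatrix]:
    """Prepare (X, U) for fitting from raw concentrations and MDL flags.

    - missing → species median, u = ``missing_uncertainty_factor`` × median
    - below MDL (flagged, or value < MDL) → MDL/2, u = (5/6)·MDL
    - quantified → u = sqrt((error_fraction·c)² + MDL²)

    ``error_fraction`` may be a scalar or a per-species vector (receptor-model
    practice assigns tighter fractions to species measured with better
    analytical precision).
    """
    names = matrix.species
    x = matrix.values.to_numpy(dtype=float).copy()
    flags = matrix.below_mdl.to_numpy(dtype=bool)
    mdls = np.array([registry[n].mdl for n in names])
    if np.any(mdls <= 0):
        bad = [n for n, m in zip(names, mdls) if m <= 0]
        raise ValueError(f"species lacking a positive MDL: {bad}")

    u = np.empty_like(x)
    prov = np.empty(x.shape, dtype=object)

    missing = ~np.isfinite(x)
    below = (~missing) & (flags | (x < mdls))
    quant = ~(missing | below)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(np.where(quant | below, x, np.nan), axis=0)
    medians = np.where(np.isfinite(medians), medians, mdls / 2.0)

    for j in range(x.shape[1]):
        col_missing = missing[:, j]
        x[col_missing, j] = medians[j]
        u[col_missing, j] = missing_uncertainty_factor * max(medians[j], mdls[j] / 2.0)
    x[below] = (np.broadcast_to(mdls, x.shape)[below]) / 2.0
    u[below] = (5.0 / 6.0) * np.broadcast_to(mdls, x.shape)[below]
    ef = np.broadcast_to(np.asarray(error_fraction, dtype=float), x.shape)
    u[quant] = np.sqrt(
        (ef[quant] * x[quant]) ** 2 + np.broadcast_to(mdls, x.shape)[quant] ** 2
    )
    prov[missing], prov[below], prov[quant] = IMPUTED, BELOW_MDL, QUANTIFIED
    return x, UncertaintyMatrix(u=u, provenance=prov)


def _multiplicative_fit(
    x: np.ndarray,
    w: np.ndarray,
    n_factors: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """One weighted-NMF run from a random start; returns (G, F, q_trace, conv)."""
    n, m = x.shape
    scale = np.sqrt(x.mean() / n_factors)
    g = rng.uniform(0.1, 1.0, size=(n, n_factors)) * scale
    f = rng.uniform(0.1, 1.0, size=(n_factors, m)) * scale
    wx = w * x
    trace = np.empty(max_iter)
    q_prev = np.inf
    converged = False
    for it in range(max_iter):
        gf = g @ f
        g *= (wx @ f.T) / ((w * gf) @ f.T + _EPS)
        np.maximum(g, _EPS, out=g)
        gf = g @ f
        f *= (g.T @ wx) / (g.T @ (w * gf) + _EPS)
        np.maximum(f, _EPS, out=f)
        resid = x - g @ f
        q = float(np.sum(w * resid * resid))
        trace[it] = q
        if it > 0 and q_prev - q <= tol * max(q_prev, _EPS):
            converged = True
            trace = trace[: it + 1]
            break
        q_prev = q
    else:
        trace = trace[:max_iter]
    return g, f, trace, converged


def fit_pmf(
    x: np.ndarray,
    u: np.ndarray,
    n_factors: int,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
    species: Optional[list] = None,
) -> PMFResult:
    """Best-of-``n_starts`` uncertainty-weighted factorization.

    Ties across starts break toward the lowest start index.  The returned F is
    row-normalized (profiles sum to 1) with G rescaled accordingly, so G
    carries the mass.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != u.shape:
        raise ValueError("X and U must have the same shape")
    if np.any(~np.isfinite(x)):
        raise ValueError("X contains NaN/inf after preparation")
    if np.any(u <= 0):
        raise ValueError("U must be strictly positive")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors > min(x.shape):
        raise ValueError("n_factors exceeds matrix dimensions")

    w = 1.0 / (u * u)
    seeds = np.random.SeedSequence(seed).spawn(n_starts)
    best = None
    for start, ss in enumerate(seeds):
        g, f, trace, conv = _multiplicative_fit(
            x, w, n_factors, np.random.default_rng(ss), tol, max_iter
        )
        q = trace[-1]
        if best is None or q < best[0]:
            best = (q, start, g, f, trace, conv)

    q, start, g, f, trace, conv = best
    row_mass = f.sum(axis=1)
    row_mass[row_mass == 0] = _EPS
    f_norm = f / row_mass[:, None]
    g_scaled = g * row_mass

    n, m = x.shape
    return PMFResult(
        G=g_scaled,
        F=f_norm,
        Q=float(q),
        Q_expected=float(n * m - n_factors * (n + m)),
        n_starts=n_starts,
        best_start=start,
        converged=bool(conv),
        iteration_count=len(trace),
        q_trace=trace,
        species=species,
    )


def factor_contributions(result: PMFResult) -> np.ndarray:
    """Each factor's % share of total reconstructed mass (sums to 100)."""
    mass = result.G.sum(axis=0) * result.F.sum(axis=1)
    total = mass.sum()
    if total <= 0:
        raise ValueError("all-zero factorization")
    return 100.0 * mass / total


def species_profile_percentages(result: PMFResult) -> np.ndarray:
    """Species × factor matrix: % of each species' mass carried by each factor
    (every species row sums to 100)."""
    mass = result.F * result.G.sum(axis=0)[:, None]  # factors × species
    totals = mass.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("species with zero total mass")
    return (100.0 * mass / totals).T


def match_factors(
    f_est: np.ndarray, f_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one factor matching by cosine similarity of profiles.

    Returns ``(perm, sims)`` where ``perm[k]`` is the index of the estimated
    factor assigned to true factor k.  Cosine similarity is scale-invariant,
    which is what PMF's scaling indeterminacy requires.
    """
    f_est = np.asarray(f_est, dtype=float)
    f_true = np.asarray(f_true, dtype=float)
    if f_est.shape != f_true.shape:
        raise ValueError("profile matrices must have identical shapes")

    def _unit(a):
        norms = np.linalg.norm(a, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return a / norms

    sim = _unit(f_true) @ _unit(f_est).T  # true × est
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm, sim[rows, cols]


def fit_report(result: PMFResult) -> dict:
    """JSON-ready fit diagnostics."""
    return {
        "Q": result.Q,
        "Q_expected": result.Q_expected,
        "Q_over_Q_expected": result.Q / result.Q_expected if result.Q_expected else None,
        "n_starts": result.n_starts,
        "best_start": result.best_start,
        "converged": result.converged,
        "iteration_count": result.iteration_count,
    }
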