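"""Uncertainty assignment and the weighted nonnegative factorization."""

import numpy as np
import pandas as pd
import pytest

from vhhrisk.descriptive import ConcentrationMatrix
from vhhrisk.pmf import (
    BELOW_MDL,
    IMPUTED,
    QUANTIFIED,
    assign_uncertainties,
    factor_contributions,
    fit_pmf,
    match_factors,
    species_profile_percentages,
)
from vhhrisk.synthetic import generate_pmf_testcase


def _matrix_from(values, registry, species=None):
    species = species or registry.names[: values.shape[1]]
    vals = pd.DataFrame(values, columns=species)
    ts = pd.DataFrame({"date": ["d"] * len(vals), "window": ["08:00"] * len(vals)})
    mdls = pd.Series({s: registry[s].mdl for s in species})
    flags = vals.lt(mdls) | vals.isna()
    return ConcentrationMatrix(values=vals, timestamps=ts, below_mdl=flags)


class TestAssignUncertainties:
    def test_quantified_error_formula(self, registry):
        # conc 100 with MDL 10: u = sqrt(10^2 + 10^2) = 14.142...
        name = "Methylene chloride"  # fixture MDL = 10
        m = _matrix_from(np.full((3, 1), 100.0), registry, [name])
        x, u = assign_uncertainties(m, registry)
        assert u.u[0, 0] == pytest.approx(np.sqrt(200.0), rel=1e-12)
        assert (u.provenance == QUANTIFIED).all()
        assert np.array_equal(x, np.full((3, 1), 100.0))

    def test_below_mdl_substitution(self, registry):
        name = "Methylene chloride"
        m = _matrix_from(np.full((3, 1), 4.0), registry, [name])
        x, u = assign_uncertainties(m, registry)
        assert np.allclose(x, 5.0)  # MDL/2
        assert np.allclose(u.u, 10.0 * 5.0 / 6.0)
        assert (u.provenance == BELOW_MDL).all()

    def test_exact_zero_treated_as_below_mdl(self, registry):
        name = "Methylene chloride"
        m = _matrix_from(np.array([[0.0], [100.0]]), registry, [name])
        x, u = assign_uncertainties(m, registry)
        assert x[0, 0] == 5.0 and u.provenance[0, 0] == BELOW_MDL

    def test_missing_imputed_with_downweighting(self, registry):
        name = "Methylene chloride"
        vals = np.array([[100.0], [300.0], [np.nan]])
        m = _matrix_from(vals, registry, [name])
        x, u = assign_uncertainties(m, registry)
        assert x[2, 0] == 200.0  # species median
        assert u.u[2, 0] == 4 * 200.0
        assert u.provenance[2, 0] == IMPUTED

    def test_campaign_matrix_all_positive_uncertainties(self, campaign, registry):
        _, u = assign_uncertainties(campaign.concentrations, registry)
        assert (u.u > 0).all()


class TestFitPMF:
    def test_noiseless_rank2_recovery(self):
        x, _, g_true, f_true = generate_pmf_testcase(30, 6, 2, noise_fraction=0.0, seed=3)
        u = np.full_like(x, x.mean() * 0.1)
        res = fit_pmf(x, u, 2, n_starts=10, seed=1)
        assert res.Q / res.Q_expected < 0.01
        _, sims = match_factors(res.F, f_true)
        assert (sims > 0.99).all()

    def test_rank1_exact_reconstruction(self):
        g = np.array([[1.0], [2.0], [3.0], [4.0]])
        f = np.array([[0.2, 0.3, 0.5]])
        x = g @ f
        res = fit_pmf(x, np.full_like(x, 0.1), 1, n_starts=5, seed=0)
        assert np.allclose(res.reconstruction(), x, rtol=1e-4)

    def test_q_trace_monotone_nonincreasing(self):
        x, u, _, _ = generate_pmf_testcase(40, 8, 3, seed=2)
        res = fit_pmf(x, u, 3, n_starts=3, seed=5)
        dq = np.diff(res.q_trace)
        assert (dq <= 1e-9 * np.abs(res.q_trace[:-1])).all()

    def test_matches_rank1_svd_optimum(self, rng):
        # with one factor and constant uncertainty the exact minimiser is the
        # rank-1 SVD truncation (Eckart-Young): independent closed-form oracle
        for seed in range(5):
            x = np.random.default_rng(seed).uniform(1, 10, (4, 3))
            u = np.full_like(x, 2.0)
            res = fit_pmf(x, u, 1, n_starts=8, seed=11, tol=1e-12, max_iter=20000)
            svals = np.linalg.svd(x, compute_uv=False)
            q_opt = np.sum(svals[1:] ** 2) / 4.0  # residual energy / u^2
            assert res.Q == pytest.approx(q_opt, rel=1e-4, abs=1e-9)

    def test_scaling_invariance_of_q(self):
        x, u, _, _ = generate_pmf_testcase(20, 5, 2, seed=8)
        r1 = fit_pmf(x, u, 2, n_starts=4, seed=3)
        r2 = fit_pmf(10 * x, 10 * u, 2, n_starts=4, seed=3)
        assert r1.Q == pytest.approx(r2.Q, rel=1e-6)

    def test_q_over_q_expected_order_one_for_matched_noise(self):
        x, u, _, _ = generate_pmf_testcase(60, 10, 3, noise_fraction=0.1, seed=4)
        res = fit_pmf(x, u, 3, n_starts=10, seed=2)
        assert 0.1 < res.Q / res.Q_expected < 2.0

    def test_input_validation(self):
        x = np.ones((4, 3))
        with pytest.raises(ValueError):
            fit_pmf(x, np.ones((3, 3)), 1)
        with pytest.raises(ValueError):
            fit_pmf(x, np.zeros_like(x), 1)
        with pytest.raises(ValueError):
            fit_pmf(x, np.ones_like(x), 0)
        with pytest.raises(ValueError):
            fit_pmf(np.full((4, 3), np.nan), np.ones((4, 3)), 1)

    def test_nonnegativity_of_solution(self):
        x, u, _, _ = generate_pmf_testcase(25, 6, 2, seed=6)
        res = fit_pmf(x, u, 2, n_starts=4, seed=9)
        assert (res.G >= 0).all() and (res.F >= 0).all()
        assert (res.reconstruction() >= 0).all()


class TestContributionsAndProfiles:
    def test_single_factor_is_100_percent(self):
        x, u, _, _ = generate_pmf_testcase(15, 5, 1, seed=1)
        res = fit_pmf(x, u, 1, n_starts=3, seed=4)
        assert factor_contributions(res) == pytest.approx([100.0])
        assert np.allclose(species_profile_percentages(res), 100.0)

    def test_contributions_sum_to_100(self):
        x, u, _, _ = generate_pmf_testcase(30, 8, 3, seed=7)
        res = fit_pmf(x, u, 3, n_starts=5, seed=2)
        assert factor_contributions(res).sum() == pytest.approx(100.0, abs=0.1)

    def test_profile_rows_sum_to_100(self):
        x, u, _, _ = generate_pmf_testcase(30, 8, 3, seed=7)
        res = fit_pmf(x, u, 3, n_starts=5, seed=2)
        assert np.allclose(species_profile_percentages(res).sum(axis=1), 100.0, atol=0.1)

    def test_exclusive_species_lands_on_matched_factor(self, campaign, registry):
        # trichloroethylene is planted exclusively on the electronics factor
        x, u = assign_uncertainties(campaign.concentrations, registry)
        res = fit_pmf(x, u.u, 4, n_starts=10, seed=0, species=campaign.concentrations.species)
        perm, _ = match_factors(res.F, campaign.true_profiles.to_numpy())
        pct = species_profile_percentages(res)
        tce = campaign.concentrations.species.index("Trichloroethylene")
        elec = perm[list(campaign.true_profiles.index).index("electronics_cleaning")]
        assert pct[tce, elec] > 80.0


class TestMatchFactors:
    def test_recovers_a_planted_permutation(self, rng):
        f = rng.dirichlet(np.ones(6), size=3)
        perm = np.array([2, 0, 1])
        p, sims = match_factors(f[perm], f)
        assert np.allclose(sims, 1.0)
        assert np.array_equal(p, np.argsort(perm))  # inverse permutation
        for k in range(3):
            assert np.allclose(f[perm][p[k]], f[k])

    def test_scale_invariance(self, rng):
        f = rng.dirichlet(np.ones(5), size=2)
        _, sims = match_factors(f * 10.0, f)
        assert np.allclose(sims, 1.0)

    def test_random_profiles_score_poorly(self):
        worse = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            f_true = r.dirichlet(np.ones(14) * 0.5, size=4)
            f_rand = r.dirichlet(np.ones(14) * 0.5, size=4)
            _, sims = match_factors(f_rand, f_true)
            worse += sims.mean() < 0.9
        assert worse >= 90

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_factors(np.ones((2, 3)), np.ones((3, 3)))
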