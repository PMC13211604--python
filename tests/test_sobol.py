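"""Saltelli block design and Jansen total-order Sobol indices."""

import numpy as np
import pytest
from scipy import stats

from vhhrisk.distributions import DistributionSpec
from vhhrisk.sobol import (
    lcr_model_for_species,
    rank_inputs,
    saltelli_matrices,
    sobol_total_order,
    total_order_indices,
)

_N2 = {"x1": DistributionSpec.normal(0.0, 1.0), "x2": DistributionSpec.normal(0.0, 1.0)}


class TestSaltelliMatrices:
    def test_block_shapes_and_column_swap(self):
        blocks = saltelli_matrices(_N2, 64, seed=0)
        assert blocks.a.shape == blocks.b.shape == (64, 2)
        assert len(blocks.ab) == 2
        for i in range(2):
            assert np.array_equal(blocks.ab[i][:, i], blocks.b[:, i])
            other = 1 - i
            assert np.array_equal(blocks.ab[i][:, other], blocks.a[:, other])

    def test_deterministic_given_seed(self):
        a = saltelli_matrices(_N2, 128, seed=4)
        b = saltelli_matrices(_N2, 128, seed=4)
        assert np.array_equal(a.a, b.a) and np.array_equal(a.b, b.b)

    def test_marginals_match_declared_specs(self):
        specs = {
            "u": DistributionSpec.uniform(2.0, 5.0),
            "ln": DistributionSpec.lognormal(1.0, 0.4),
            "t": DistributionSpec.triangular(0.0, 1.0, 4.0),
        }
        blocks = saltelli_matrices(specs, 10_000, seed=1)
        for j, name in enumerate(blocks.names):
            ks = stats.ks_1samp(blocks.a[:, j], lambda v: np.asarray(specs[name].cdf(v)))
            assert ks.statistic < 0.05

    def test_single_input_rejected_at_block_level(self):
        with pytest.raises(ValueError):
            saltelli_matrices({"x": DistributionSpec.normal(0, 1)}, 64)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            saltelli_matrices(_N2, 32)


class TestTotalOrderIndices:
    def test_additive_equal_variance_model(self):
        blocks = saltelli_matrices(_N2, 2**14, seed=7)
        res = total_order_indices(lambda rows: rows[:, 0] + rows[:, 1], blocks)
        assert res.st == pytest.approx([0.5, 0.5], abs=0.03)
        assert 0.95 < res.st.sum() < 1.05

    def test_inert_input_scores_zero(self):
        blocks = saltelli_matrices(_N2, 2**13, seed=2)
        res = total_order_indices(lambda rows: rows[:, 0], blocks)
        assert res.st[0] == pytest.approx(1.0, abs=0.02)
        assert res.st[1] == pytest.approx(0.0, abs=0.02)

    def test_ishigami_closed_form(self):
        # analytic variance decomposition of the Ishigami function:
        # V1 = (1 + b·π⁴/5)²/2, V2 = a²/8, V13 = b²·π⁸·(1/18 − 1/50),
        # Var = a²/8 + b·π⁴/5 + b²·π⁸/18 + 1/2; only the x1-x3 interaction
        # is nonzero, so S_T = ((V1+V13), V2, (V3+V13))/Var
        a, b = 7.0, 0.1
        v1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2
        v2 = a**2 / 8
        v13 = b**2 * np.pi**8 * (1 / 18 - 1 / 50)
        var = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
        st_exact = np.array([(v1 + v13) / var, v2 / var, v13 / var])
        assert st_exact == pytest.approx([0.5574, 0.4424, 0.2436], abs=5e-4)

        specs = {f"x{i}": DistributionSpec.uniform(-np.pi, np.pi) for i in (1, 2, 3)}

        def ishigami(rows):
            return (
                np.sin(rows[:, 0])
                + a * np.sin(rows[:, 1]) ** 2
                + b * rows[:, 2] ** 4 * np.sin(rows[:, 0])
            )

        res = sobol_total_order(ishigami, specs, 2**15, seed=3)
        assert res.st == pytest.approx([0.5574, 0.4424, 0.2436], abs=0.02)
        assert res.st == pytest.approx(st_exact, abs=0.02)

    def test_degenerate_output_reported(self):
        blocks = saltelli_matrices(_N2, 64, seed=0)
        res = total_order_indices(lambda rows: np.zeros(len(rows)), blocks)
        assert res.degenerate

    def test_single_input_shortcut(self):
        res = sobol_total_order(
            lambda rows: rows[:, 0], {"x": DistributionSpec.normal(0, 1)}, 64
        )
        assert res.st == pytest.approx([1.0])


class TestRankInputs:
    def test_descending_order(self):
        from vhhrisk.sobol import SobolResult

        res = SobolResult(
            names=["CA", "EF"], st=np.array([0.8, 0.1]), se=np.zeros(2), n=64, seed=0
        )
        assert rank_inputs(res) == ["CA", "EF"]

    def test_exact_tie_breaks_alphabetically(self):
        from vhhrisk.sobol import SobolResult

        res = SobolResult(
            names=["zeta", "alpha"], st=np.array([0.5, 0.5]), se=np.zeros(2), n=64, seed=0
        )
        assert rank_inputs(res) == ["alpha", "zeta"]

    def test_degenerate_rejected(self):
        from vhhrisk.sobol import SobolResult

        res = SobolResult(
            names=["a"], st=np.array([np.nan]), se=np.array([np.nan]), n=64, seed=0,
            degenerate=True,
        )
        with pytest.raises(ValueError):
            rank_inputs(res)


class TestRiskSensitivityRankings:
    def _specs(self, ca_mean, ca_sd, time_cv):
        return {
            "CA": DistributionSpec.lognormal_from_moments(ca_mean, ca_sd),
            "ET": DistributionSpec.normal(24.0, 24.0 * time_cv, lower=1.0, upper=24.0),
            "EF": DistributionSpec.normal(365.0, 365.0 * time_cv, lower=30.0, upper=365.0),
            "ED": DistributionSpec.normal(74.8, 74.8 * time_cv, lower=10.0, upper=100.0),
        }

    def test_wide_concentration_variance_dominates(self, registry):
        # 1,2-dichloroethane-style case: CA CV ≈ 1 vs narrow time parameters
        model = lcr_model_for_species(98.96, iur=2.6e-5)
        res = sobol_total_order(model, self._specs(265.0, 279.0, 0.05), 2**13, seed=11)
        assert rank_inputs(res)[0] == "CA"
        assert res.st[res.names.index("CA")] > 0.5

    def test_narrow_concentration_flips_ranking_to_time(self, registry):
        # carbon-tetrachloride-style case: CA CV ≈ 0.1, time parameters wide
        model = lcr_model_for_species(153.82, iur=6.0e-6)
        res = sobol_total_order(model, self._specs(92.0, 9.0, 0.20), 2**13, seed=11)
        assert rank_inputs(res)[0] in ("EF", "ED", "ET")
        assert res.st[res.names.index("CA")] < max(res.st)

    def test_convergence_spread_shrinks_with_n(self):
        spreads = []
        for n in (2**10, 2**12):
            ests = [
                sobol_total_order(
                    lambda rows: rows[:, 0] + rows[:, 1], _N2, n, seed=s
                ).st[0]
                for s in range(8)
            ]
            spreads.append(np.std(ests))
        assert spreads[1] < spreads[0]
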