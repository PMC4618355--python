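"""Flux-fitness landscape fitting and cross-property statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xenoflux.fitness_landscape import (
    FIT_EXCLUSION_PRESET,
    SEVERE_FITNESS_OUTLIERS,
    distribution_shift,
    dosage,
    fit_flux_model,
    flux_fitness,
    landscape_report,
    quadratic_charge_fit,
    spearman_matrix,
    spearman_with_p,
)
from xenoflux.synthetic_data import gen_strain_table


class TestDosage:
    def test_product_and_missing_propagation(self):
        out = dosage([1.0, 0.0, np.nan], [5.0, 7.0, 5.0])
        assert out[0] == 5.0 and out[1] == 0.0 and np.isnan(out[2])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dosage([-1.0], [5.0])


class TestFluxFitness:
    def test_zero_dosage_zero_fitness(self):
        assert flux_fitness(0.0, 0.6, 1.0) == 0.0

    def test_half_saturation_identity(self):
        assert flux_fitness(1.0, 0.6, 1.0) == pytest.approx(0.3, abs=1e-12)

    def test_plateau_limit(self):
        assert flux_fitness(99.0, 0.6, 1.0) == pytest.approx(0.6, rel=0.011)

    @given(b=st.floats(0.1, 10.0), a=st.floats(0.1, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_increasing_concave_diminishing_returns(self, a, b):
        d = np.linspace(0.0, 10 * b, 200)
        f = flux_fitness(d, a, b)
        assert np.all(np.diff(f) > 0)
        assert np.all(np.diff(f, 2) < 1e-12)
        assert flux_fitness(2 * b, a, b) - flux_fitness(b, a, b) < flux_fitness(b, a, b)


class TestFitFluxModel:
    def test_two_point_closed_form(self, two_point_table):
        # a/(b+1)=0.3 and 3a/(b+3)=0.45 solve to a=0.6, b=1.0
        fit = fit_flux_model(two_point_table)
        assert fit.a == pytest.approx(0.6, rel=1e-6)
        assert fit.b == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_round_trip(self, clean_strain_table):
        table, truth = clean_strain_table
        fit = fit_flux_model(table, phase="naive")
        assert fit.a == pytest.approx(truth.a, rel=1e-6)
        assert fit.b == pytest.approx(truth.b, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_reorder_and_duplicate_invariance(self, clean_strain_table):
        table, _ = clean_strain_table
        base = fit_flux_model(table)
        shuffled = fit_flux_model(table.sample(frac=1, random_state=0))
        doubled = fit_flux_model(pd.concat([table, table], ignore_index=True))
        for other in (shuffled, doubled):
            assert other.a == pytest.approx(base.a, rel=1e-9)
            assert other.b == pytest.approx(base.b, rel=1e-9)

    def test_exclusions_and_missing_reported(self, barrier_strain_table):
        table, truth = barrier_strain_table
        fit = fit_flux_model(table, exclude=truth.barrier_ids)
        assert fit.excluded_ids == truth.barrier_ids
        nd = set(table.loc[table["abundance_total_naive"].isna(), "strain_id"])
        assert set(fit.dropped_missing) == nd - set(truth.barrier_ids)

    def test_insufficient_points_rejected(self, two_point_table):
        with pytest.raises(ValueError, match="insufficient"):
            fit_flux_model(two_point_table.iloc[:2])

    def test_equal_dosages_unidentifiable(self):
        table = pd.DataFrame(
            {
                "strain_id": list("abcd"),
                "kcat_over_km": [1.0] * 4,
                "abundance_total_naive": [2.0] * 4,
                "growth_rate_naive": [0.3, 0.31, 0.29, 0.3],
            }
        )
        with pytest.raises(ValueError, match="identifiab"):
            fit_flux_model(table)

    def test_exclusion_presets_are_the_published_sets(self):
        assert set(SEVERE_FITNESS_OUTLIERS) - set(FIT_EXCLUSION_PRESET) == {"DHFR-37"}
        assert len(FIT_EXCLUSION_PRESET) == 5


class TestSpearman:
    @pytest.mark.parametrize(
        "y,expect", [([2, 4, 6, 8], 1.0), ([1, 3, 2, 4], 0.8), ([4, 3, 2, 1], -1.0)]
    )
    def test_four_point_examples(self, y, expect):
        r, _ = spearman_with_p(np.array([1, 2, 3, 4]), np.array(y))
        assert r == pytest.approx(expect)

    def test_exact_small_n_p_matches_enumeration(self):
        # enumeration over all 4! rank orders is itself done inside
        # spearman_with_p; cross-check against a direct brute force here
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        r, p = spearman_with_p(x, y)
        rhos = []
        for perm in itertools.permutations([1.0, 3.0, 2.0, 4.0]):
            rhos.append(np.corrcoef(x, perm)[0, 1])  # ranks equal values here
        expect = np.mean([abs(v) >= abs(r) - 1e-12 for v in rhos])
        assert p == pytest.approx(expect)

    def test_matrix_pairwise_deletion_and_symmetry(self, barrier_strain_table):
        table, _ = barrier_strain_table
        props = ["growth_rate_naive", "abundance_total_naive", "tm_c"]
        corr = spearman_matrix(table, props)
        n_complete = table[["growth_rate_naive", "abundance_total_naive"]].dropna().shape[0]
        assert corr.n_pairs.loc["growth_rate_naive", "abundance_total_naive"] == n_complete
        assert np.allclose(corr.r.to_numpy(), corr.r.to_numpy().T, equal_nan=True)
        assert np.all(np.diag(corr.r.to_numpy()) == 1.0)

    def test_constant_property_unavailable(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0] * 5})
        corr = spearman_matrix(table, ["a", "b"])
        assert np.isnan(corr.r.loc["a", "b"])

    def test_min_pairs_enforced(self):
        table = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 4]})
        corr = spearman_matrix(table, ["a", "b"], min_pairs=5)
        assert np.isnan(corr.r.loc["a", "b"])


class TestQuadraticChargeFit:
    def test_noiseless_free_offset_round_trip(self):
        q = np.array([-6.0, -3.5, -1.0, 0.0, 2.0])
        growth = 0.5 - 0.02 * (q + 3.5) ** 2
        fit = quadratic_charge_fit(q, growth, c=None)
        assert fit.c == pytest.approx(3.5, abs=1e-5)
        assert fit.beta1 == pytest.approx(-0.02, rel=1e-4)
        assert fit.beta0 == pytest.approx(0.5, rel=1e-4)

    def test_constant_growth_zero_curvature(self):
        fit = quadratic_charge_fit(np.array([-6.0, -3.5, 0.0, 2.0]), np.full(4, 0.4), c=3.5)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_data_centers_at_zero(self):
        q = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        growth = 0.6 - 0.05 * q**2
        fit = quadratic_charge_fit(q, growth, c=None)
        assert fit.c == pytest.approx(0.0, abs=1e-5)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            quadratic_charge_fit(np.full(5, -3.5), np.linspace(0, 1, 5), c=3.5)


class TestDistributionShift:
    def test_identical_samples(self):
        res = distribution_shift([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res == {"D": 0.0, "p": 1.0, "direction": 0}

    def test_exact_p_by_enumeration(self):
        # for [1,2] vs [3,4]: of the C(4,2)=6 equally likely label assignments,
        # exactly 2 give D=1, so the exact two-sided p is 1/3
        res = distribution_shift([1.0, 2.0], [3.0, 4.0])
        assert res["D"] == 1.0 and res["direction"] == 1
        assert res["p"] == pytest.approx(1 / 3)

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=20)
        res = distribution_shift(x, rng.permutation(x))
        assert res["D"] == 0.0

    def test_null_p_values_valid(self):
        # both samples from the same distribution at n=35, 1000 reps.
        # The two-sample KS statistic is discrete, so its null p-values are
        # stochastically *larger* than uniform (conservative); validity means
        # no excess in the small-p direction and calibrated rejection rates.
        rng = np.random.default_rng(42)
        pvals = np.array(
            [
                distribution_shift(rng.normal(size=35), rng.normal(size=35))["p"]
                for _ in range(1000)
            ]
        )
        from scipy import stats

        assert stats.kstest(pvals, "uniform", alternative="greater").pvalue > 0.01
        for alpha in (0.01, 0.05, 0.1):
            hi = stats.binom.ppf(0.995, 1000, alpha)
            assert (pvals <= alpha).sum() <= hi

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            distribution_shift([1.0], [2.0, 3.0])


class TestLandscapeReport:
    def test_on_curve_strain_not_flagged(self, clean_strain_table):
        table, _ = clean_strain_table
        fit = fit_flux_model(table)
        rep = landscape_report(table, fit)
        assert not rep["barrier_flag"].fillna(False).to_numpy().any()

    def test_barrier_strains_flagged_pre_not_post(self, barrier_strain_table):
        table, truth = barrier_strain_table
        barrier = table["strain_id"].isin(truth.barrier_ids)
        detectable = barrier & table["abundance_total_naive"].notna()
        fit_pre = fit_flux_model(table, phase="naive", exclude=truth.barrier_ids)
        rep_pre = landscape_report(table, fit_pre, phase="naive").set_index("strain_id")
        fit_post = fit_flux_model(table, phase="evolved", exclude=truth.barrier_ids)
        rep_post = landscape_report(table, fit_post, phase="evolved").set_index("strain_id")
        pre_flags = rep_pre.loc[table.loc[detectable, "strain_id"], "barrier_flag"]
        post_flags = rep_post.loc[table.loc[barrier, "strain_id"], "barrier_flag"]
        assert pre_flags.all()
        assert not post_flags.fillna(False).any()

    def test_empty_table_gives_empty_report(self, clean_strain_table):
        table, _ = clean_strain_table
        fit = fit_flux_model(table)
        assert landscape_report(table.iloc[0:0], fit).empty
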