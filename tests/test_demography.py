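"""Tests of the generation matrix, inclusion filters, survivorship OLS,
imputation and density-dependence diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cohortenv import (
    build_generation_matrix,
    density_dependence_diagnostics,
    filter_generations,
    fit_survivorship,
    impute_missing,
    last_detection_years,
    sample_ages,
    simulate_cohorts,
    simulate_environment,
)
from cohortenv.demography import fit_all_generations

from conftest import noise_free_config


def samples_df(rows):
    return pd.DataFrame(rows, columns=["sample_year", "age", "abundance"])


class TestGenerationMatrix:
    def test_birth_year_arithmetic(self):
        gm = build_generation_matrix(samples_df([(2005, 2, 10.0), (2005, 3, 5.0)]))
        assert gm.loc[2003, 2005] == 10.0
        assert gm.loc[2002, 2005] == 5.0

    def test_duplicate_cells_averaged(self):
        gm = build_generation_matrix(
            samples_df([(2005, 2, 8.0), (2005, 2, 12.0)])
        )
        assert gm.loc[2003, 2005] == 10.0

    def test_multi_year_fixture_matches_hand_built_table(self):
        # 4 generations x 6 sampling years, constructed by hand
        rows = []
        expected = {}
        for birth in (2000, 2001, 2002, 2003):
            for year in range(2003, 2009):
                age = year - birth
                if 1 <= age <= 8:
                    value = float(100 * birth % 97 + age)
                    rows.append((year, age, value))
                    expected[(birth, year)] = value
        gm = build_generation_matrix(samples_df(rows))
        for (birth, year), value in expected.items():
            assert gm.loc[birth, year] == value
        assert gm.notna().sum().sum() == len(expected)

    def test_bad_ages_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="rejected"):
            gm = build_generation_matrix(
                samples_df([(2005, 2, 1.0), (2005, 2.5, 9.0), (2005, -1, 3.0)])
            )
        assert gm.size == 1

    def test_all_rows_rejected_is_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="rejected"):
                build_generation_matrix(samples_df([(2005, 0.5, 1.0)]))

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_generation_matrix(samples_df([]))


class TestFilters:
    def make_gm(self, spec):
        """spec: {birth_year: [(sample_year, abundance), ...]}"""
        rows = [
            (year, year - birth, value)
            for birth, obs in spec.items()
            for year, value in obs
        ]
        return build_generation_matrix(samples_df(rows))

    def test_generation_born_at_boundary_year_excluded(self):
        # born 1998 with six record years: excluded by the birth-year rule
        gm = self.make_gm(
            {
                1998: [(1998 + a, 5.0) for a in range(2, 8)],
                2000: [(2000 + a, 5.0) for a in range(2, 8)],
            }
        )
        filtered, report = filter_generations(gm, min_birth_year=1999)
        assert 1998 not in filtered.index
        assert 2000 in filtered.index
        assert report.dropped_birth_year_rule == 1

    def test_three_record_years_excluded(self):
        gm = self.make_gm(
            {
                2000: [(2002, 9.0), (2003, 7.0), (2004, 5.0)],
                2001: [(2003, 9.0), (2004, 7.0), (2005, 5.0), (2006, 4.0)],
            }
        )
        filtered, report = filter_generations(gm)
        assert list(filtered.index) == [2001]
        assert report.dropped_record_years_rule == 1

    def test_age_window_cells_blanked(self):
        gm = self.make_gm(
            {2000: [(2001, 50.0)] + [(2000 + a, 5.0) for a in range(2, 7)] + [(2011, 1.0)]}
        )
        filtered, report = filter_generations(gm)
        ages = [int(c) - 2000 for c in filtered.columns if not np.isnan(filtered.loc[2000, c])]
        assert min(ages) >= 2 and max(ages) <= 10
        assert report.cells_dropped_age == 2

    def test_random_fixture_matches_independent_filter(self):
        # 20 generations with known record patterns vs. a set-based oracle
        rng = np.random.default_rng(7)
        spec = {}
        for birth in range(1995, 2015):
            years = sorted(
                rng.choice(range(birth + 1, birth + 12), size=rng.integers(1, 9), replace=False)
            )
            spec[birth] = [(int(y), float(rng.uniform(1, 50))) for y in years]
        gm = self.make_gm(spec)

        def oracle(spec):
            keep = set()
            for birth, obs in spec.items():
                if birth < 1999:
                    continue
                good_years = {y for y, _ in obs if 2 <= y - birth <= 10}
                if len(good_years) >= 4:
                    keep.add(birth)
            return keep

        try:
            filtered, _ = filter_generations(gm)
            surviving = set(filtered.index)
        except ValueError:
            surviving = set()
        assert surviving == oracle(spec)

    def test_report_counts_are_additive(self):
        rng = np.random.default_rng(11)
        spec = {}
        for birth in range(1994, 2016):
            years = sorted(
                rng.choice(range(birth + 1, birth + 13), size=rng.integers(1, 10), replace=False)
            )
            spec[birth] = [(int(y), float(rng.uniform(1, 50))) for y in years]
        gm = self.make_gm(spec)
        _, r = filter_generations(gm)
        assert (
            r.dropped_age_rule
            + r.dropped_birth_year_rule
            + r.dropped_record_years_rule
            + r.surviving
            == r.total
        )

    def test_zero_survivors_names_binding_rule(self):
        gm = self.make_gm({1990: [(1992, 4.0), (1993, 2.0), (1994, 1.0), (1995, 1.0)]})
        with pytest.raises(ValueError, match="birth-year"):
            filter_generations(gm)


class TestSurvivorshipFit:
    def test_exact_exponential_series(self):
        pairs = [(a, math.exp(5 - 0.5 * a)) for a in range(2, 7)]
        fit = fit_survivorship(pairs)
        assert fit.n0 == pytest.approx(5.0, abs=1e-12)
        assert fit.z == pytest.approx(-0.5, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series(self):
        fit = fit_survivorship([(a, 20.0) for a in range(2, 8)])
        assert fit.z == pytest.approx(0.0, abs=1e-12)
        assert fit.n0 == pytest.approx(math.log(20.0), abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        ages = np.arange(2.0, 9.0)
        abundances = np.exp(4.0 - 0.4 * ages + rng.normal(0, 0.3, len(ages)))
        fit = fit_survivorship(list(zip(ages, abundances)))
        # textbook normal equations
        y = np.log(abundances)
        sxx = np.sum((ages - ages.mean()) ** 2)
        slope = np.sum((ages - ages.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * ages.mean()
        assert fit.z == pytest.approx(slope, abs=1e-12)
        assert fit.n0 == pytest.approx(intercept, abs=1e-12)

    def test_configurable_log_base(self):
        pairs = [(a, 10 ** (3 - 0.2 * a)) for a in range(2, 6)]
        fit = fit_survivorship(pairs, log_base=10)
        assert fit.n0 == pytest.approx(3.0, abs=1e-10)
        assert fit.z == pytest.approx(-0.2, abs=1e-10)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_survivorship([(2, 5.0), (3, 4.0), (4, 3.0)])

    def test_nonpositive_abundance_cites_policy(self):
        with pytest.raises(ValueError, match="missing-data policy"):
            fit_survivorship([(2, 5.0), (3, 0.0), (4, 3.0), (5, 2.0)])

    @given(st.permutations(list(range(6))))
    @settings(max_examples=20, deadline=None)
    def test_order_invariance(self, order):
        base = [(a + 2, math.exp(5 - 0.4 * (a + 2)) * (1 + 0.1 * a)) for a in range(6)]
        shuffled = [base[i] for i in order]
        f1, f2 = fit_survivorship(base), fit_survivorship(shuffled)
        assert f1.z == pytest.approx(f2.z, abs=1e-12)
        assert f1.n0 == pytest.approx(f2.n0, abs=1e-12)

    def test_duplicate_observations_averaged_before_fit(self):
        # two samples of one (year, age) cell are merged to their mean by the
        # generation matrix, so the fit equals the pre-averaged fit
        dup = samples_df(
            [(2004, 2, 8.0), (2004, 2, 12.0), (2005, 3, 6.0), (2006, 4, 4.0), (2007, 5, 2.0)]
        )
        pre = samples_df(
            [(2004, 2, 10.0), (2005, 3, 6.0), (2006, 4, 4.0), (2007, 5, 2.0)]
        )
        fits = []
        for s in (dup, pre):
            gm = build_generation_matrix(s)
            row = gm.loc[2002].dropna()
            fits.append(
                fit_survivorship(
                    pd.Series(row.to_numpy(), index=[int(y) - 2002 for y in row.index])
                )
            )
        assert fits[0].z == pytest.approx(fits[1].z, abs=1e-12)
        assert fits[0].n0 == pytest.approx(fits[1].n0, abs=1e-12)


class TestImputation:
    def make_dm(self, gm_spec, fits=None):
        gm = build_generation_matrix(
            samples_df(
                [
                    (year, year - birth, value)
                    for birth, obs in gm_spec.items()
                    for year, value in obs
                ]
            )
        )
        if fits is None:
            fits = fit_all_generations(gm)
        return gm, fits

    def test_complete_generation_all_observed(self):
        spec = {2000: [(2000 + a, math.exp(5 - 0.5 * a)) for a in range(2, 11)]}
        gm, fits = self.make_dm(spec)
        dm = impute_missing(gm, fits)
        assert (dm.provenance.loc[2000] == "observed").all()
        for a in range(2, 11):
            assert dm.data.loc[2000, f"N{a}"] == pytest.approx(5 - 0.5 * a, abs=1e-12)

    def test_missing_age_filled_from_line(self):
        # N0 = 5, z = -0.5, age 7 absent: imputed N7 = 1.5
        spec = {
            2000: [
                (2000 + a, math.exp(5 - 0.5 * a)) for a in (2, 3, 4, 5, 6, 8, 9, 10)
            ]
        }
        gm, fits = self.make_dm(spec)
        dm = impute_missing(gm, fits)
        assert dm.provenance.loc[2000, "N7"] == "imputed"
        assert dm.data.loc[2000, "N7"] == pytest.approx(1.5, abs=1e-10)

    def test_imputed_equals_withheld_truth_on_exact_data(self):
        rng = np.random.default_rng(5)
        full = {2000 + g: [(2000 + g + a, math.exp(6 - (0.3 + 0.05 * g) * a)) for a in range(2, 11)] for g in range(4)}
        # withhold a random age per generation
        withheld = {}
        sparse = {}
        for birth, obs in full.items():
            drop = rng.integers(0, len(obs))
            withheld[birth] = obs[drop]
            sparse[birth] = [o for i, o in enumerate(obs) if i != drop]
        gm, fits = self.make_dm(sparse)
        dm = impute_missing(gm, fits)
        for birth, (year, value) in withheld.items():
            a = year - birth
            assert dm.data.loc[birth, f"N{a}"] == pytest.approx(math.log(value), abs=1e-9)

    def test_observed_cells_never_altered_and_counts_add_up(self, study):
        gm, dm = study["gm_filtered"], study["dm"]
        n_missing = 0
        for birth in gm.index:
            for a in range(2, 11):
                year = birth + a
                value = gm.loc[birth, year] if year in gm.columns else np.nan
                if pd.isna(value):
                    n_missing += 1
                else:
                    assert dm.data.loc[birth, f"N{a}"] == pytest.approx(
                        math.log(value), abs=1e-12
                    )
                    assert dm.provenance.loc[birth, f"N{a}"] == "observed"
        assert dm.n_imputed == n_missing

    def test_fitted_mode_uses_line_everywhere(self):
        spec = {2000: [(2000 + a, math.exp(5 - 0.5 * a)) for a in range(2, 11)]}
        gm, fits = self.make_dm(spec)
        dm = impute_missing(gm, fits, mode="fitted")
        assert (dm.provenance == "fitted").all().all()

    def test_missing_fit_is_error(self):
        spec = {2000: [(2000 + a, 5.0) for a in range(2, 7)]}
        gm, _ = self.make_dm(spec)
        with pytest.raises(ValueError, match="no survivorship fit"):
            impute_missing(gm, {})


class TestDiagnostics:
    def test_hand_computed_correlations(self):
        data = pd.DataFrame(
            {
                "N0": [5.0, 6.0, 4.0, 7.0],
                "z": [-0.5, -0.7, -0.4, -0.9],
                "N2": [4.0, 4.6, 3.2, 5.2],
            },
            index=[2000, 2001, 2002, 2003],
        )
        from cohortenv.demography import DemographicMatrix

        dm = DemographicMatrix(data=data, provenance=data[["N2"]].astype(str))
        diag = density_dependence_diagnostics(dm)
        for col in ("z", "N2"):
            expected = np.corrcoef(data["N0"], data[col])[0, 1]
            assert diag.loc[col, "r"] == pytest.approx(expected, abs=1e-12)

    def test_density_dependent_sign_pattern_on_noise_free_truth(self):
        cfg = noise_free_config(env_trend=0.08)
        env = simulate_environment(cfg)
        truth = simulate_cohorts(env, cfg)
        samples = sample_ages(truth, config=cfg)
        gm = build_generation_matrix(samples)
        gm_f, _ = filter_generations(gm)
        fits = fit_all_generations(gm_f)
        dm = impute_missing(gm_f, fits)
        diag = density_dependence_diagnostics(dm)
        assert diag.loc["z", "r"] < 0
        for col in ("N2", "N3", "N4"):
            assert diag.loc[col, "r"] > 0

    def test_zero_variance_flagged_undefined(self):
        data = pd.DataFrame(
            {"N0": [5.0, 6.0, 4.0, 7.0], "z": [-0.5] * 4, "N2": [4.0, 4.6, 3.2, 5.2]},
            index=range(4),
        )
        from cohortenv.demography import DemographicMatrix

        dm = DemographicMatrix(data=data, provenance=data[["N2"]].astype(str))
        with pytest.warns(UserWarning, match="zero variance"):
            diag = density_dependence_diagnostics(dm)
        assert np.isnan(diag.loc["z", "r"])


class TestRoundTrip:
    def test_noise_free_round_trip_recovers_truth_to_1e10(self):
        # simulate (noise 0) -> build -> filter -> fit recovers every
        # generation's (log N0, z) to <= 1e-10
        cfg = noise_free_config()
        env = simulate_environment(cfg)
        truth = simulate_cohorts(env, cfg)
        samples = sample_ages(truth, config=cfg)
        gm = build_generation_matrix(samples)
        gm_f, _ = filter_generations(gm)
        fits = fit_all_generations(gm_f)
        assert len(fits) >= 10
        for birth, fit in fits.items():
            assert abs(fit.n0 - truth.table.loc[birth, "true_log_n0"]) <= 1e-10
            assert abs(fit.z - truth.table.loc[birth, "true_z"]) <= 1e-10

    def test_last_detection_years(self):
        gm = build_generation_matrix(
            samples_df([(2003, 3, 5.0), (2005, 5, 2.0), (2004, 4, 3.0)])
        )
        last = last_detection_years(gm)
        assert last[2000] == 2005
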