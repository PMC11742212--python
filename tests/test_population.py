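import numpy as np
import pandas as pd
import pytest

from mixrisk.population import (
    CssTable,
    PopulationInputs,
    simulate_age,
    simulate_css,
    simulate_exposure,
    simulate_inhalation_rate,
    simulate_obesity,
    simulate_population,
)
from mixrisk.rng import substream


def age_dist(brackets):
    return pd.DataFrame(
        [("R", lo, hi, p) for lo, hi, p in brackets],
        columns=["region_id", "age_low", "age_high", "proportion"],
    )


def rng(seed=0):
    return np.random.default_rng(seed)


class TestSimulateAge:
    def test_single_bracket_support(self):
        ages = simulate_age(age_dist([(0, 4, 1.0)]), 500, rng())
        assert set(ages) <= {0, 1, 2, 3, 4}

    def test_bracket_frequencies_match_proportions(self):
        dist = age_dist([(0, 0, 0.5), (50, 50, 0.5)])
        ages = simulate_age(dist, 10_000, rng(1))
        frac_zero = np.mean(ages == 0)
        assert frac_zero == pytest.approx(0.5, abs=0.02)

    def test_empty_request(self):
        assert simulate_age(age_dist([(0, 4, 1.0)]), 0, rng()).size == 0

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_age(age_dist([(0, 4, 0.7)]), 10, rng())

    def test_open_top_bracket_capped(self):
        ages = simulate_age(age_dist([(85, 130, 1.0)]), 1000, rng(2))
        assert ages.min() >= 85 and ages.max() <= 99

    def test_chi_square_goodness_of_fit(self):
        from scipy import stats

        dist = age_dist([(0, 9, 0.3), (10, 19, 0.5), (20, 29, 0.2)])
        ages = simulate_age(dist, 100_000, rng(3))
        observed = [np.sum(ages <= 9), np.sum((ages >= 10) & (ages <= 19)),
                    np.sum(ages >= 20)]
        _, pval = stats.chisquare(observed, [30_000, 50_000, 20_000])
        assert pval > 0.01


class TestSimulateObesity:
    @pytest.mark.parametrize("prev,expected", [(0.0, "Normal"), (1.0, "Obese")])
    def test_degenerate_prevalence(self, prev, expected):
        flags = simulate_obesity(prev, 0.0, 100, rng())
        assert set(flags) == {expected}

    def test_prevalence_recovered(self):
        flags = simulate_obesity(0.35, 0.0, 10_000, rng(1))
        assert np.mean(flags == "Obese") == pytest.approx(0.35, abs=0.015)

    def test_out_of_range_mean_rejected(self):
        with pytest.raises(ValueError):
            simulate_obesity(1.2, 0.0, 10, rng())


class TestSimulateInhalationRate:
    ir_table = pd.DataFrame(
        {"age_low": [0, 18], "age_high": [17, 99],
         "ir_mean": [0.5, 0.3], "ir_sd": [0.0, 0.05]}
    )

    def test_zero_sd_gives_bracket_mean(self):
        ir = simulate_inhalation_rate(np.array([3, 10, 17]), self.ir_table, rng())
        assert np.all(ir == 0.5)

    def test_uncovered_age_errors_with_age(self):
        with pytest.raises(ValueError, match="100"):
            simulate_inhalation_rate(np.array([100]), self.ir_table, rng())

    def test_mean_recovered(self):
        ir = simulate_inhalation_rate(np.full(10_000, 30), self.ir_table, rng(1))
        assert ir.mean() == pytest.approx(0.3, abs=0.005)
        assert np.all(ir > 0)


class TestSimulateExposure:
    def exposure(self, mean, sd):
        return pd.DataFrame({"chemical_id": ["x"], "mean": [mean], "sd": [sd]})

    def test_zero_mean_zero_sd(self):
        draws = simulate_exposure(self.exposure(0.0, 0.0), 50, rng())
        assert np.all(draws == 0.0)

    def test_zero_sd_constant(self):
        draws = simulate_exposure(self.exposure(2.5, 0.0), 50, rng())
        assert np.all(draws == 2.5)

    def test_mean_recovered(self):
        draws = simulate_exposure(self.exposure(2.0, 0.5), 10_000, rng(1))
        assert draws.mean() == pytest.approx(2.0, abs=0.03)
        assert np.all(draws >= 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_exposure(self.exposure(-1.0, 0.5), 10, rng())


class TestSimulateCss:
    def css_table(self, samples):
        rows = [("x", g, w, v)
                for g in ("0-17", "18-44", "45-64", "65+")
                for w in ("Normal", "Obese")
                for v in samples]
        return CssTable(pd.DataFrame(
            rows, columns=["chemical_id", "age_group", "weight_class", "sample_value"]
        ))

    def test_single_sample_stratum_is_constant(self):
        table = self.css_table([7.0])
        draws, central = simulate_css(
            table, np.array([30, 40]), np.array(["Normal", "Obese"]), ["x"], rng()
        )
        assert np.all(draws == 7.0) and np.all(central == 7.0)

    def test_draws_within_stratum_support(self):
        table = self.css_table([1.0, 2.0, 3.0])
        draws, _ = simulate_css(
            table, np.full(500, 30), np.full(500, "Normal"), ["x"], rng(1)
        )
        assert set(np.unique(draws)) <= {1.0, 2.0, 3.0}

    def test_bootstrap_mean(self):
        table = self.css_table([1.0, 2.0, 3.0, 4.0])
        draws, _ = simulate_css(
            table, np.full(40_000, 30), np.full(40_000, "Normal"), ["x"], rng(2)
        )
        assert draws.mean() == pytest.approx(2.5, abs=0.02)

    def test_missing_stratum_names_offender(self):
        rows = [("x", "18-44", "Normal", 1.0)] * 3
        table = CssTable(pd.DataFrame(
            rows, columns=["chemical_id", "age_group", "weight_class", "sample_value"]
        ))
        with pytest.raises(ValueError, match="Obese"):
            simulate_css(table, np.array([30]), np.array(["Obese"]), ["x"], rng())


class TestDeterminismAndStreams:
    def test_population_bit_identical_under_seed(self, study):
        chems = sorted(study.exposure["chemical_id"].unique())
        sub = study.exposure[study.exposure["region_id"] == "R001"]
        a = simulate_population("R001", chems, sub, study.population_inputs,
                                study.css, 40, seed=123)
        b = simulate_population("R001", chems, sub, study.population_inputs,
                                study.css, 40, seed=123)
        assert np.array_equal(a.ages, b.ages)
        assert np.array_equal(a.weight_class, b.weight_class)
        assert np.array_equal(a.ir, b.ir)
        assert np.array_equal(a.exposure_draws, b.exposure_draws)
        assert np.array_equal(a.css_draws, b.css_draws)

    def test_region_order_independence(self, study):
        chems = sorted(study.exposure["chemical_id"].unique())

        def sim(region):
            sub = study.exposure[study.exposure["region_id"] == region]
            return simulate_population(region, chems, sub, study.population_inputs,
                                       study.css, 30, seed=5)

        first = sim("R001")
        _ = sim("R002")  # interleave another region
        again = sim("R001")
        assert np.array_equal(first.ages, again.ages)
        assert np.array_equal(first.exposure_draws, again.exposure_draws)

    def test_component_substreams_are_distinct(self):
        a = substream(1, "R001", "age").random(5)
        b = substream(1, "R001", "exposure").random(5)
        c = substream(1, "R002", "age").random(5)
        assert not np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_all_quantities_nonnegative(self, study):
        chems = sorted(study.exposure["chemical_id"].unique())
        sub = study.exposure[study.exposure["region_id"] == "R002"]
        pop = simulate_population("R002", chems, sub, study.population_inputs,
                                  study.css, 100, seed=9)
        assert pop.ages.min() >= 0
        assert pop.ir.min() > 0
        assert pop.exposure_draws.min() >= 0
        assert pop.css_draws.min() > 0
        assert pop.exposure_draws.shape == (100, len(chems))


class TestPopulationInputsValidation:
    def test_overlapping_brackets_rejected(self):
        dist = age_dist([(0, 10, 0.5), (5, 20, 0.5)])
        with pytest.raises(ValueError, match="overlap"):
            PopulationInputs(
                age_dist=dist,
                obesity=pd.DataFrame({"region_id": ["R"], "prev_mean": [0.3],
                                      "prev_sd": [0.0]}),
                ir_table=pd.DataFrame({"age_low": [0], "age_high": [99],
                                       "ir_mean": [0.3], "ir_sd": [0.0]}),
            )

    def test_ir_coverage_enforced(self):
        dist = age_dist([(0, 99, 1.0)])
        with pytest.raises(ValueError, match="cover"):
            PopulationInputs(
                age_dist=dist,
                obesity=pd.DataFrame({"region_id": ["R"], "prev_mean": [0.3],
                                      "prev_sd": [0.0]}),
                ir_table=pd.DataFrame({"age_low": [0], "age_high": [50],
                                       "ir_mean": [0.3], "ir_sd": [0.0]}),
            )

    def test_median_age_exact_on_two_point_distribution(self):
        dist = age_dist([(0, 0, 0.4), (80, 80, 0.6)])
        inputs = PopulationInputs(
            age_dist=dist,
            obesity=pd.DataFrame({"region_id": ["R"], "prev_mean": [0.3],
                                  "prev_sd": [0.0]}),
            ir_table=pd.DataFrame({"age_low": [0], "age_high": [99],
                                   "ir_mean": [0.3], "ir_sd": [0.0]}),
        )
        assert inputs.median_age("R") == 80
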