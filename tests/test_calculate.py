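import numpy as np
import pytest

from mixrisk.calculate import (
    _gca_closed_form,
    _gca_root,
    calc_hq,
    calc_internal_dose,
    calc_invitro_concentration,
    calc_response,
    response_gca,
    response_ia,
)
from mixrisk.dose_response import hill_response

from conftest import make_params


def random_slope1_mixture(rng, k=None):
    k = int(rng.integers(1, 11)) if k is None else k
    params = [make_params(tp=rng.uniform(50, 120), ac50=10 ** rng.uniform(-1, 1))
              for _ in range(k)]
    concs = rng.uniform(0, 5, k)
    return concs, params


class TestDoseChain:
    def test_internal_dose_arithmetic(self):
        assert calc_internal_dose(10.0, 0.2, 1.0, 1e-3) == pytest.approx(0.002, rel=1e-12)

    def test_zero_exposure_and_linearity(self):
        assert calc_internal_dose(0.0, 0.2) == 0.0
        d1 = calc_internal_dose(3.0, 0.25)
        d2 = calc_internal_dose(6.0, 0.25)
        assert d2 == 2.0 * d1

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            calc_internal_dose(-1.0, 0.2)

    def test_invitro_concentration(self):
        assert calc_invitro_concentration(0.002, 5.0) == pytest.approx(0.01, rel=1e-12)
        assert calc_invitro_concentration(0.0, 5.0) == 0.0
        d = np.array([0.1, 0.2])
        assert np.allclose(calc_invitro_concentration(d, np.ones(2)), d)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            calc_invitro_concentration(np.ones((2, 3)), np.ones((3, 2)))


class TestGCA:
    def test_two_chemical_closed_form(self):
        params = [make_params(100, 1.0), make_params(100, 1.0)]
        assert response_gca([1.0, 1.0], params) == pytest.approx(200.0 / 3.0, rel=1e-12)

    def test_single_chemical_reduces_to_hill(self):
        p = make_params(90, 0.5)
        assert response_gca([0.5], [p]) == pytest.approx(45.0, rel=1e-12)

    def test_zero_concentrations(self):
        params = [make_params(), make_params()]
        assert response_gca([0.0, 0.0], params) == 0.0

    def test_closed_form_matches_root_finder(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            concs, params = random_slope1_mixture(rng)
            tp = np.array([p.tp for p in params])
            ac50 = np.array([p.ac50 for p in params])
            closed = float(_gca_closed_form(concs[None, :], tp, ac50)[0])
            root = _gca_root(concs, tp, ac50, np.ones(len(params)))
            assert abs(closed - root) < 1e-8

    def test_concentration_splitting_invariance(self):
        rng = np.random.default_rng(1)
        concs, params = random_slope1_mixture(rng, k=3)
        base = response_gca(concs, params)
        split_params = params + [params[0]]
        split_concs = np.concatenate([[concs[0] / 2], concs[1:], [concs[0] / 2]])
        assert response_gca(split_concs, split_params) == pytest.approx(base, rel=1e-12)

    def test_partial_agonist_pulls_effect_toward_its_top(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            concs, params = random_slope1_mixture(rng, k=3)
            concs = concs + 0.1
            e0 = response_gca(concs, params)
            weak = make_params(tp=e0 * 0.5, ac50=1.0)
            strong = make_params(tp=min(e0 * 2.0, 150.0), ac50=1.0)
            lower = response_gca(np.append(concs, 1.0), params + [weak])
            higher = response_gca(np.append(concs, 1.0), params + [strong])
            assert lower < e0 < higher

    def test_general_slope_mixture_bounded_by_smallest_top(self):
        params = [make_params(60, 1.0, slope=2.0), make_params(100, 1.0, slope=3.0)]
        with pytest.warns(RuntimeWarning, match="no root"):
            e = response_gca([50.0, 50.0], params)
        assert 0 < e <= 60.0

    def test_unconverged_params_rejected(self):
        from mixrisk.dose_response import HillParams

        bad = HillParams("c", "a", tp=100, log10_ac50=0.0, converged=False)
        with pytest.raises(ValueError, match="converged"):
            response_gca([1.0], [bad])


class TestIA:
    def test_single_chemical_is_hill(self):
        p = make_params(80, 2.0)
        assert response_ia([2.0], [p]) == pytest.approx(40.0, rel=1e-12)

    def test_two_half_effects(self):
        params = [make_params(100, 1.0), make_params(100, 1.0)]
        # both at AC50 contribute 50 each with e_ref=100 -> 100*(1-0.25)
        assert response_ia([1.0, 1.0], params, e_ref=100.0) == pytest.approx(75.0)

    def test_zero_concentrations(self):
        assert response_ia([0.0, 0.0], [make_params(), make_params()]) == 0.0

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            concs, params = random_slope1_mixture(rng)
            e_ref = max(p.tp for p in params)
            e = response_ia(concs, params)
            singles = [
                hill_response(c, p) if c > 0 else 0.0
                for c, p in zip(concs, params)
            ]
            assert max(singles) - 1e-9 <= e <= e_ref + 1e-9
            bumped = concs.copy()
            j = int(rng.integers(len(concs)))
            bumped[j] += 1.0
            assert response_ia(bumped, params) >= e - 1e-12

    def test_bad_e_ref_rejected(self):
        with pytest.raises(ValueError):
            response_ia([1.0], [make_params()], e_ref=-1.0)


class TestHQ:
    def test_single_chemical_algebra(self):
        # f(sC) = 10 with tp=100, AC50=1, C=1 -> s=1/9 -> HQ=9
        assert calc_hq([1.0], [make_params(100, 1.0)], 10.0, "GCA") == pytest.approx(9.0, rel=1e-10)

    def test_zero_concentrations(self):
        assert calc_hq([0.0], [make_params()], 10.0, "GCA") == 0.0

    @pytest.mark.parametrize("method", ["GCA", "IA"])
    def test_doubling_concentration_doubles_hq(self, method):
        rng = np.random.default_rng(4)
        concs, params = random_slope1_mixture(rng, k=3)
        concs = concs + 0.01
        h1 = calc_hq(concs, params, 10.0, method)
        h2 = calc_hq(2.0 * concs, params, 10.0, method)
        assert h2 == pytest.approx(2.0 * h1, rel=1e-8)

    def test_gca_and_ia_agree_for_single_chemical(self):
        p = make_params(100, 2.0)
        hq_gca = calc_hq([0.5], [p], 10.0, "GCA")
        hq_ia = calc_hq([0.5], [p], 10.0, "IA")
        assert hq_gca == pytest.approx(hq_ia, rel=1e-8)

    def test_unreachable_target_returns_zero_with_warning(self):
        # top 15 of e_ref 100: a 50% reference response is unreachable
        params = [make_params(15, 1.0), make_params(100, 1.0)]
        with pytest.warns(RuntimeWarning, match="unreachable"):
            hq = calc_hq([1.0, 0.0], params, 50.0, "GCA", e_ref=100.0)
        assert hq == 0.0

    def test_bad_percent_rejected(self):
        with pytest.raises(ValueError):
            calc_hq([1.0], [make_params()], 0.0, "GCA")

    def test_hazard_index_convention(self):
        # single chemical at its own EC10 gives HI = 1
        p = make_params(100, 1.0)
        ec10 = 1.0 / 9.0
        assert calc_hq([ec10], [p], 10.0, convention="hazard_index") == pytest.approx(1.0, rel=1e-10)


class TestCalcResponse:
    def test_requires_population(self, fitted_model):
        with pytest.raises(ValueError, match="population"):
            calc_response(fitted_model)

    def test_results_schema_and_integrity(self, responded_model):
        res = responded_model.results
        assert {"region_id", "assay_id", "individual",
                "GCA_Eff", "IA_Eff", "GCA_HQ", "IA_HQ"} <= set(res.columns)
        assert set(res["region_id"]) <= set(responded_model.regions.region_ids)
        assert res["GCA_Eff"].min() >= 0
        assert res["GCA_HQ"].min() >= 0
        assert np.isfinite(res[["GCA_Eff", "IA_Eff", "GCA_HQ", "IA_HQ"]]).all().all()

    def test_ia_dominates_single_best_chemical(self, responded_model):
        res = responded_model.results
        # IA effect can never fall below the GCA effect's floor of 0 and must
        # stay below the assay reference maximum
        tops = {p.assay_id: [] for p in responded_model.hill_params}
        for p in responded_model.hill_params:
            if p.converged:
                tops[p.assay_id].append(p.tp)
        for assay, grp in res.groupby("assay_id"):
            assert grp["IA_Eff"].max() <= max(tops[assay]) + 1e-9

    def test_deterministic_no_rng_consumed(self, responded_model):
        first = responded_model.results.copy()
        again = calc_response(responded_model)
        assert first.equals(again)

    def test_end_to_end_hand_computation(self, study):
        """sd=0 everywhere and single-sample Css: metrics are pure arithmetic."""
        import pandas as pd

        from mixrisk.model import RunConfig, assemble_model
        from mixrisk.population import CssTable

        regions = study.regions
        exposure = pd.DataFrame(
            {"region_id": ["R001", "R002"], "chemical_id": "c1",
             "mean": [10.0, 20.0], "sd": [0.0, 0.0]}
        )
        concresp = None
        css = CssTable(pd.DataFrame(
            [("c1", g, w, 5.0) for g in ("0-17", "18-44", "45-64", "65+")
             for w in ("Normal", "Obese")],
            columns=["chemical_id", "age_group", "weight_class", "sample_value"],
        ))
        age_dist = pd.DataFrame(
            [(r, 30, 30, 1.0) for r in ("R001", "R002", "R003")],
            columns=["region_id", "age_low", "age_high", "proportion"],
        )
        obesity = pd.DataFrame(
            {"region_id": ["R001", "R002", "R003"], "prev_mean": 0.0, "prev_sd": 0.0}
        )
        ir_table = pd.DataFrame(
            {"age_low": [0], "age_high": [99], "ir_mean": [0.2], "ir_sd": [0.0]}
        )
        from mixrisk.population import PopulationInputs

        inputs = PopulationInputs(age_dist=age_dist, obesity=obesity, ir_table=ir_table)
        hp = [make_params(tp=100.0, ac50=0.01, chem="c1", assay="A")]
        cfg = RunConfig(seed=0, n_per_region=3)
        model = assemble_model(regions, exposure, concresp, css, inputs, cfg,
                               hill_params=hp)
        model.simulate()
        res = calc_response(model)
        # R001: C = 10 µg/m³ · 0.2 m³/kg/day · 1e-3 · 5 µM/(mg/kg/day) = 0.01 µM
        # GCA = IA = hill(0.01; tp=100, AC50=0.01) = 50
        r1 = res[res["region_id"] == "R001"]
        assert np.allclose(r1["GCA_Eff"], 50.0)
        assert np.allclose(r1["IA_Eff"], 50.0)
        # HQ: reference = 10 -> sC = AC50/9 -> s = 1/9... C=AC50 so HQ = 9
        assert np.allclose(r1["GCA_HQ"], 9.0)
        # R002 doubles the exposure: C = 0.02 µM -> E = 100·2/3, HQ doubles to 18
        r2 = res[res["region_id"] == "R002"]
        assert np.allclose(r2["GCA_Eff"], 200.0 / 3.0)
        assert np.allclose(r2["GCA_HQ"], 18.0)

    def test_mixture_method_subset_drops_columns(self, study):
        from mixrisk.model import RunConfig, assemble_model

        cfg = RunConfig(seed=11, n_per_region=10, mixture_methods=("GCA",))
        model = assemble_model(study.regions, study.exposure, study.concresp,
                               study.css, study.population_inputs, cfg)
        model.simulate()
        res = calc_response(model)
        assert "IA_Eff" not in res.columns and "IA_HQ" not in res.columns
        assert {"GCA_Eff", "GCA_HQ"} <= set(res.columns)
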