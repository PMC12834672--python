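"""Pointwise elpd: degenerate averages, hand oracles, stability, mode ordering."""



import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locscale.data import dataset_from_frame
from locscale.elpd import ElpdVector, elpd_conditional, elpd_marginal, elpd_total
from locscale.inference import fit
from locscale.models import ParameterSet, pointwise_log_lik, simulate_response, spec_model

from conftest import make_meta_frame
from oracles import draws_from_params, random_params


def _rename_studies(data, suffix="_new"):
    tab = data.table.copy()
    tab["study_id"] = tab["study_id"].astype(str) + suffix
    return dataset_from_frame(tab, data.kind, data.center_log_size)


class TestElpdTotal:
    def test_constant_values(self):
        total, se = elpd_total(ElpdVector(np.full(4, -1.0), "conditional", "m"))
        assert total == -4.0 and se == 0.0

    def test_hand_computed_se(self):
        total, se = elpd_total(ElpdVector(np.array([0.0, -2.0]), "conditional", "m"))
        assert total == -2.0
        assert se == pytest.approx(2.0)  # sd = sqrt(2), * sqrt(2)

    def test_single_value_se_zero(self):
        assert elpd_total(ElpdVector(np.array([-3.2]), "marginal", "m")) == (-3.2, 0.0)


class TestConditional:
    def test_single_draw_equals_pointwise_loglik(self, meta_toy):
        spec = spec_model("m1_2")
        rng = np.random.default_rng(0)
        params = random_params(spec, meta_toy, rng)
        draws = draws_from_params(spec, meta_toy, [params])
        vec = elpd_conditional(draws, spec, meta_toy)
        assert np.allclose(vec.values, pointwise_log_lik(spec, params, meta_toy),
                           atol=1e-12)

    def test_identical_draws_equal_one_draw(self, meta_toy):
        spec = spec_model("m1_2")
        rng = np.random.default_rng(1)
        params = random_params(spec, meta_toy, rng)
        one = elpd_conditional(draws_from_params(spec, meta_toy, [params]), spec, meta_toy)
        many = elpd_conditional(draws_from_params(spec, meta_toy, [params] * 5),
                                spec, meta_toy)
        assert np.allclose(one.values, many.values, atol=1e-12)

    def test_two_draws_match_log_mean_of_densities(self):
        """4-observation toy: ln(mean of two normal pdf values), by hand."""
        frame = make_meta_frame(n_studies=2, cases=2, seed=2)
        data = dataset_from_frame(frame, "meta")
        spec = spec_model("m1_2")
        rng = np.random.default_rng(2)
        p1, p2 = random_params(spec, data, rng), random_params(spec, data, rng)
        draws = draws_from_params(spec, data, [p1, p2])
        vec = elpd_conditional(draws, spec, data)
        codes = data.study_codes()
        for i in range(4):
            row = data.table.iloc[i]
            dens = []
            for p in (p1, p2):
                mu = (p.beta_loc[0] + p.beta_loc[1] * row["log_grain"]
                      + p.study_effects["loc_icpt"][codes[i]])
                sig = np.exp(p.beta_scale[0] + p.beta_scale[1] * row["log_grain"])
                dens.append(stats.norm.pdf(row["z"], mu, np.sqrt(row["var_z"] + sig ** 2)))
            assert vec.values[i] == pytest.approx(np.log(np.mean(dens)), abs=1e-12)

    def test_unseen_study_redirects_to_marginal(self, meta_toy):
        spec = spec_model("m1_2")
        rng = np.random.default_rng(3)
        draws = draws_from_params(spec, meta_toy, [random_params(spec, meta_toy, rng)])
        with pytest.raises(ValueError, match="elpd_marginal"):
            elpd_conditional(draws, spec, _rename_studies(meta_toy))


class TestMarginal:
    def test_no_varying_effects_equals_conditional(self, meta_toy):
        from test_inference import _fixed_effect_meta_spec

        spec = _fixed_effect_meta_spec()
        rng = np.random.default_rng(4)
        params = [ParameterSet(beta_loc=np.array([rng.normal()])) for _ in range(3)]
        draws = draws_from_params(spec, meta_toy, params)
        cond = elpd_conditional(draws, spec, meta_toy)
        marg = elpd_marginal(draws, spec, _rename_studies(meta_toy), re_draws=5, seed=0)
        assert np.allclose(cond.values, marg.values, atol=1e-12)

    def test_vanishing_sds_equal_conditional_at_zero_effects(self, meta_toy):
        spec = spec_model("m1_4")
        rng = np.random.default_rng(5)
        params = random_params(spec, meta_toy, rng)
        params.sd = {"loc_icpt": 1e-9, "scale_icpt": 1e-9}
        params.study_effects = {k: np.zeros(meta_toy.n_studies)
                                for k in params.study_effects}
        draws = draws_from_params(spec, meta_toy, [params])
        cond = elpd_conditional(draws, spec, meta_toy)
        marg = elpd_marginal(draws, spec, _rename_studies(meta_toy), re_draws=20, seed=1)
        assert np.allclose(cond.values, marg.values, atol=1e-6)

    def test_rejects_seen_studies_and_bad_re_draws(self, meta_toy):
        spec = spec_model("m1_4")
        rng = np.random.default_rng(6)
        draws = draws_from_params(spec, meta_toy, [random_params(spec, meta_toy, rng)])
        with pytest.raises(ValueError, match="elpd_conditional"):
            elpd_marginal(draws, spec, meta_toy, re_draws=10)
        with pytest.raises(ValueError, match="re_draws"):
            elpd_marginal(draws, spec, _rename_studies(meta_toy), re_draws=0)

    def test_matches_gauss_hermite_quadrature(self):
        """m1_4 marginal elpd vs 2-D quadrature over the new-study effects."""
        frame = pd.DataFrame({
            "study_id": ["snew"] * 3, "case_id": list("abc"),
            "z": [0.1, 0.5, -0.2], "var_z": [0.05, 0.02, 0.1],
            "log_grain": [0.0, 1.0, 2.0],
        })
        heldout = dataset_from_frame(frame, "meta")
        train = dataset_from_frame(make_meta_frame(3, 2, seed=7), "meta")
        spec = spec_model("m1_4")
        rng = np.random.default_rng(7)
        p_list = [random_params(spec, train, rng) for _ in range(2)]
        draws = draws_from_params(spec, train, p_list)
        vec = elpd_marginal(draws, spec, heldout, re_draws=40_000, seed=3)

        nodes, weights = np.polynomial.hermite_e.hermegauss(41)
        w = weights / np.sqrt(2 * np.pi)
        for i in range(3):
            row = frame.iloc[i]
            dens_per_draw = []
            for p in p_list:
                mu0 = p.beta_loc[0] + p.beta_loc[1] * row["log_grain"]
                dens = 0.0
                for a, wa in zip(nodes, w):
                    b0 = p.sd["loc_icpt"] * a
                    for b, wb in zip(nodes, w):
                        sig = np.exp(p.beta_scale[0] + p.sd["scale_icpt"] * b)
                        dens += wa * wb * stats.norm.pdf(
                            row["z"], mu0 + b0, np.sqrt(row["var_z"] + sig ** 2))
                dens_per_draw.append(dens)
            expected = np.log(np.mean(dens_per_draw))
            assert vec.values[i] == pytest.approx(expected, abs=5e-3)


def test_log_sum_exp_stability():
    """Densities as small as exp(-700) keep elpd finite."""
    frame = pd.DataFrame({
        "study_id": ["s0"], "case_id": ["c0"], "z": [37.0], "var_z": [1.0],
        "log_grain": [0.0],
    })
    data = dataset_from_frame(frame, "meta")
    spec = spec_model("m1_2")
    params = ParameterSet(beta_loc=np.array([0.0, 0.0]),
                          beta_scale=np.array([-20.0, 0.0]), sd={"loc_icpt": 0.1},
                          study_effects={"loc_icpt": np.zeros(1)})
    draws = draws_from_params(spec, data, [params, params])
    vec = elpd_conditional(draws, spec, data)
    assert np.isfinite(vec.values).all()
    assert vec.values[0] < -600


def test_conditional_beats_marginal_on_model_data(fast_config):
    """Within-study information should improve prediction on average."""
    spec = spec_model("m1_4")
    truth = ParameterSet(beta_loc=np.array([0.2, 0.05]), beta_scale=np.array([-1.0]),
                         sd={"loc_icpt": 0.3, "scale_icpt": 0.8})
    frame = make_meta_frame(n_studies=12, cases=4, seed=8)
    data = dataset_from_frame(frame, "meta")
    sim, _ = simulate_response(spec, truth, data, seed=9)
    study = sim.study_ids
    case = sim.table["case_id"]
    seen = ~np.isin(study, ["s10", "s11"])
    train = sim.subset(np.flatnonzero(seen & (case != "c3")))
    heldout_within = sim.subset(np.flatnonzero(seen & (case == "c3")))
    heldout_new = sim.subset(np.flatnonzero(~seen))
    draws = fit(spec, train, fast_config)
    cond = elpd_conditional(draws, spec, heldout_within).values
    marg = elpd_marginal(draws, spec, heldout_new, re_draws=200, seed=2).values
    assert np.mean(cond) > np.mean(marg) - 0.3
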