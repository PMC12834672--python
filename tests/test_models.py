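"""Model grammar, joint densities and the generative simulator."""

import numpy as np
import pandas as pd
import pytest

from locscale.data import EXTENT_BINS, dataset_from_frame
from locscale.models import (
    MODEL_NAMES,
    ParameterSet,
    log_joint,
    pointwise_log_lik,
    simulate_response,
    spec_model,
)

from oracles import naive_log_joint, random_params

HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


class TestSpecPresets:
    def test_m1_1_structure(self):
        spec = spec_model("m1_1")
        assert spec.case_level_intercept and not spec.has_scale
        assert spec.scale_terms == ()
        assert spec.sd_keys() == ["loc_icpt", "case"]

    def test_m1_2_drops_case_intercept(self):
        spec = spec_model("m1_2")
        assert not spec.case_level_intercept
        assert spec.scale_terms == ("log_grain",) and spec.scale_intercept

    def test_m1_3_cell_means_without_intercept(self):
        spec = spec_model("m1_3")
        assert spec.scale_terms == ("extent_bin",) and not spec.scale_intercept

    def test_m1_4_study_varying_scale(self):
        spec = spec_model("m1_4")
        assert [c for g in spec.groups for c in g] == [("loc", "icpt"), ("scale", "icpt")]

    @pytest.mark.parametrize("name, group_sizes", [
        ("m2_1", (2,)), ("m2_2", (2, 1)), ("m2_3", (2, 2)), ("m2_4", (3,)), ("m2_5", (4,)),
    ])
    def test_lognormal_group_structure(self, name, group_sizes):
        spec = spec_model(name)
        assert tuple(len(g) for g in spec.groups) == group_sizes

    def test_complexity_orders_homoscedastic_first(self):
        ranks = {m: spec_model(m).complexity_rank for m in MODEL_NAMES}
        assert ranks["m1_1"] < ranks["m1_2"]
        assert ranks["m2_1"] < ranks["m2_2"] < ranks["m2_4"] < ranks["m2_5"]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            spec_model("m9_9")


def _single_obs_meta():
    return dataset_from_frame(pd.DataFrame({
        "study_id": ["s0"], "case_id": ["c0"], "z": [0.0], "var_z": [1.0],
        "log_grain": [0.0], "extent_bin": [EXTENT_BINS[0]],
    }), "meta")


def _single_obs_fragment():
    return dataset_from_frame(pd.DataFrame({
        "study_id": ["s0"], "fragment_id": ["f0"], "richness": [1.0],
        "log_frag_size": [0.0],
    }), "fragment")


class TestObservationTerms:
    def test_standard_normal_point_meta(self):
        """z = 0, mu = 0, total variance 1: observation term is -0.5*ln(2*pi)."""
        spec = spec_model("m1_1")
        params = ParameterSet(
            beta_loc=np.array([0.0, 0.0]), sd={"loc_icpt": 0.5, "case": 0.3},
            study_effects={"loc_icpt": np.zeros(1)}, case_effects=np.zeros(1),
        )
        ll = pointwise_log_lik(spec, params, _single_obs_meta())
        assert ll.shape == (1,)
        assert ll[0] == pytest.approx(-HALF_LOG_2PI, abs=1e-10)

    def test_lognormal_at_one_equals_standard_normal_at_zero(self):
        spec = spec_model("m2_1")
        params = ParameterSet(
            beta_loc=np.array([0.0, 0.0]), beta_scale=np.array([0.0]),
            sd={"loc_icpt": 0.3, "loc_slope": 0.2}, corr={0: np.eye(2)},
            study_effects={"loc_icpt": np.zeros(1), "loc_slope": np.zeros(1)},
        )
        ll = pointwise_log_lik(spec, params, _single_obs_fragment())
        assert ll[0] == pytest.approx(-HALF_LOG_2PI, abs=1e-10)

    def test_duplicated_rows_double_only_observation_terms(self, meta_toy):
        spec = spec_model("m1_2")
        rng = np.random.default_rng(3)
        params = random_params(spec, meta_toy, rng)
        doubled = dataset_from_frame(
            pd.concat([meta_toy.table, meta_toy.table], ignore_index=True), "meta")
        obs = pointwise_log_lik(spec, params, meta_toy).sum()
        lj = log_joint(spec, params, meta_toy)
        lj2 = log_joint(spec, params, doubled)
        assert lj2 - lj == pytest.approx(obs, abs=1e-8)

    def test_pointwise_sums_to_observation_part(self, meta_toy):
        """log_joint minus its prior/effect terms equals the pointwise sum."""
        spec = spec_model("m1_4")
        rng = np.random.default_rng(4)
        params = random_params(spec, meta_toy, rng)
        lj = log_joint(spec, params, meta_toy)
        obs = pointwise_log_lik(spec, params, meta_toy).sum()
        # independent accounting: subtract the naive non-observation terms
        empty_obs = naive_log_joint(spec, params, meta_toy) - obs
        assert lj - obs == pytest.approx(empty_obs, abs=1e-8)


class TestNestingIdentities:
    def test_m1_2_reduces_to_constant_sigma(self, meta_toy):
        """With the grain scale-slope at 0, m1_2 is a constant-sigma model."""
        spec = spec_model("m1_2")
        rng = np.random.default_rng(5)
        params = random_params(spec, meta_toy, rng)
        params.beta_scale = np.array([params.beta_scale[0], 0.0])
        ll = pointwise_log_lik(spec, params, meta_toy)
        # direct recomputation with fixed sigma
        sigma = np.exp(params.beta_scale[0])
        mu = (params.beta_loc[0] + params.beta_loc[1] * meta_toy.table["log_grain"]
              + params.study_effects["loc_icpt"][meta_toy.study_codes()])
        var = meta_toy.table["var_z"].to_numpy() + sigma ** 2
        expected = -0.5 * (np.log(2 * np.pi * var)
                           + (meta_toy.table["z"].to_numpy() - mu) ** 2 / var)
        assert np.allclose(ll, expected, atol=1e-10)

    def test_m2_2_reduces_to_m2_1(self, fragment_toy):
        """Zero scale-intercept SD and zero departures recover m2_1 exactly."""
        s22, s21 = spec_model("m2_2"), spec_model("m2_1")
        rng = np.random.default_rng(6)
        params = random_params(s21, fragment_toy, rng)
        ll21 = pointwise_log_lik(s21, params, fragment_toy)
        params22 = ParameterSet(
            beta_loc=params.beta_loc, beta_scale=params.beta_scale,
            sd={**params.sd, "scale_icpt": 1e-9}, corr=params.corr,
            study_effects={**params.study_effects,
                           "scale_icpt": np.zeros(fragment_toy.n_studies)},
        )
        ll22 = pointwise_log_lik(s22, params22, fragment_toy)
        assert np.allclose(ll21, ll22, atol=1e-10)


class TestSimulateResponse:
    def test_same_seed_identical(self, meta_toy):
        spec = spec_model("m1_2")
        rng = np.random.default_rng(7)
        params = random_params(spec, meta_toy, rng)
        d1, _ = simulate_response(spec, params, meta_toy, seed=42)
        d2, _ = simulate_response(spec, params, meta_toy, seed=42)
        assert np.array_equal(d1.table["z"], d2.table["z"])

    def test_meta_mean_matches_clt(self):
        """m1_1 with all variation off: sample mean of z converges to beta0."""
        n = 100_000
        frame = pd.DataFrame({
            "study_id": ["s0"] * n, "case_id": [str(i) for i in range(n)],
            "z": 0.0, "var_z": 0.04, "log_grain": 0.0,
        })
        data = dataset_from_frame(frame, "meta")
        spec = spec_model("m1_1")
        params = ParameterSet(
            beta_loc=np.array([0.3, 0.0]), sd={"loc_icpt": 0.0, "case": 0.0},
            study_effects={"loc_icpt": np.zeros(1)}, case_effects=np.zeros(n),
        )
        sim, _ = simulate_response(spec, params, data, seed=0)
        z = sim.table["z"].to_numpy()
        assert np.mean(z) == pytest.approx(0.3, abs=3 * 0.2 / np.sqrt(n))

    def test_lognormal_log_mean(self):
        n = 50_000
        frame = pd.DataFrame({
            "study_id": ["s0"] * n, "fragment_id": [str(i) for i in range(n)],
            "richness": 1.0, "log_frag_size": 0.0,
        })
        data = dataset_from_frame(frame, "fragment", center_log_size=0.0)
        spec = spec_model("m2_1")
        params = ParameterSet(
            beta_loc=np.array([1.0, 0.0]), beta_scale=np.array([np.log(0.5)]),
            sd={"loc_icpt": 0.0, "loc_slope": 0.0}, corr={0: np.eye(2)},
            study_effects={"loc_icpt": np.zeros(1), "loc_slope": np.zeros(1)},
        )
        sim, _ = simulate_response(spec, params, data, seed=1)
        log_s = np.log(sim.table["richness"].to_numpy())
        assert np.mean(log_s) == pytest.approx(1.0, abs=3 * 0.5 / np.sqrt(n))
        # lognormal mean identity E[S] = exp(mu + sigma^2/2)
        assert np.mean(sim.table["richness"]) == pytest.approx(
            np.exp(1.0 + 0.125), rel=0.02)

    def test_missing_covariate_rejected(self, fragment_toy):
        spec = spec_model("m1_2")  # expects meta covariates
        rng = np.random.default_rng(8)
        params = random_params(spec_model("m2_1"), fragment_toy, rng)
        with pytest.raises(Exception):
            simulate_response(spec, params, fragment_toy, seed=0)
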