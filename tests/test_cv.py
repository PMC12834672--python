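"""Fold assignment invariants, CV orchestration and the one-SE rule."""

import dataclasses

import numpy as np
import pytest

from locscale.cv import assign_stratified_kfold, compare, run_kfold, run_logo
from locscale.data import dataset_from_frame
from locscale.elpd import elpd_conditional
from locscale.inference import McmcConfig, fit
from locscale.models import ParameterSet, simulate_response, spec_model

from conftest import make_meta_frame


class TestFoldAssignment:
    def test_balanced_design_gives_one_case_per_study_per_fold(self):
        data = dataset_from_frame(make_meta_frame(n_studies=20, cases=10, seed=0), "meta")
        fa = assign_stratified_kfold(data, k=10, seed=1)
        study = data.study_codes()
        for f in range(10):
            rows = np.flatnonzero(fa.labels == f)
            assert rows.size == 20
            assert len(set(study[rows])) == 20  # exactly one case per study

    def test_single_study_spread_evenly(self):
        data = dataset_from_frame(make_meta_frame(n_studies=1, cases=10, seed=0), "meta")
        fa = assign_stratified_kfold(data, k=10, seed=2)
        counts = np.bincount(fa.labels, minlength=10)
        assert np.all(counts == 1)

    def test_small_study_lands_in_distinct_folds(self):
        import pandas as pd

        big = make_meta_frame(n_studies=4, cases=10, seed=0)
        small = make_meta_frame(n_studies=1, cases=3, seed=1)
        small["study_id"] = "tiny"
        data = dataset_from_frame(pd.concat([big, small], ignore_index=True), "meta")
        fa = assign_stratified_kfold(data, k=10, seed=3)
        tiny_rows = np.flatnonzero(data.study_ids == "tiny")
        assert len(set(fa.labels[tiny_rows])) == 3

    def test_assignment_is_a_partition(self):
        data = dataset_from_frame(make_meta_frame(n_studies=7, cases=5, seed=4), "meta")
        fa = assign_stratified_kfold(data, k=4, seed=5)
        all_rows = np.concatenate([rows for _, rows in fa.folds()])
        assert sorted(all_rows) == list(range(data.n_obs))

    def test_per_study_fold_counts_differ_by_at_most_one(self):
        data = dataset_from_frame(make_meta_frame(n_studies=9, cases=7, seed=6), "meta")
        fa = assign_stratified_kfold(data, k=4, seed=7)
        study = data.study_codes()
        for si in range(data.n_studies):
            counts = np.bincount(fa.labels[study == si], minlength=4)
            assert counts.max() - counts.min() <= 1

    def test_invalid_k_rejected(self):
        data = dataset_from_frame(make_meta_frame(n_studies=2, cases=2, seed=0), "meta")
        with pytest.raises(ValueError):
            assign_stratified_kfold(data, k=1)
        with pytest.raises(ValueError):
            assign_stratified_kfold(data, k=5)


class TestOneSeRule:
    def _specs(self):
        return [spec_model("m1_1"), spec_model("m1_2")]  # ranks 4 < 5

    def test_simpler_model_within_one_se_is_selected(self):
        simple, complex_ = self._specs()
        best = np.zeros(4)
        worse = best - np.array([2.0, 0.0, 0.0, 0.0])  # diff 2, sd(d)=1, SE=2
        rep = compare({complex_.name: best, simple.name: worse}, self._specs())
        assert rep.best_model == complex_.name
        assert rep.selected_model == simple.name

    def test_simpler_model_beyond_one_se_is_not_selected(self):
        simple, complex_ = self._specs()
        worse = np.zeros(4) - np.array([4.0, 1.0, 1.0, 1.0])  # diff 7, SE=3
        rep = compare({complex_.name: np.zeros(4), simple.name: worse}, self._specs())
        assert rep.selected_model == complex_.name

    def test_all_identical_selects_simplest(self):
        vals = np.full(5, -1.3)
        specs = [spec_model(m) for m in ("m1_2", "m1_1", "m1_4")]
        rep = compare({s.name: vals.copy() for s in specs}, specs)
        assert rep.selected_model == "m1_1"

    def test_selection_invariant_to_model_order(self):
        rng = np.random.default_rng(8)
        vals = {m: rng.normal(size=30) for m in ("m1_1", "m1_2", "m1_4")}
        specs = [spec_model(m) for m in vals]
        a = compare(dict(vals), specs)
        b = compare(dict(reversed(list(vals.items()))), list(reversed(specs)))
        assert a.selected_model == b.selected_model
        assert a.best_model == b.best_model

    def test_misaligned_vectors_rejected(self):
        specs = self._specs()
        with pytest.raises(ValueError, match="misaligned"):
            compare({specs[0].name: np.zeros(3), specs[1].name: np.zeros(4)}, specs)

    def test_one_se_prefers_truth_more_often_than_raw_max(self):
        """When two models predict identically in expectation, the one-SE rule
        recovers the simpler one far more often than picking the raw maximum
        (selection noise makes the complex model 'win' about half the time)."""
        rng = np.random.default_rng(9)
        simple, complex_ = self._specs()
        one_se_simple = raw_simple = 0
        for _ in range(50):
            base = rng.normal(-1.0, 1.0, size=40)
            jitter = rng.normal(0.0, 0.05, size=40)
            point = {simple.name: base, complex_.name: base + jitter}
            rep = compare(point, [simple, complex_])
            one_se_simple += rep.selected_model == simple.name
            raw_simple += rep.best_model == simple.name
        assert one_se_simple > raw_simple + 10
        assert one_se_simple >= 40


class TestOrchestration:
    def test_kfold_with_k_equal_n_is_exact_loo(self):
        """Single study, k = n: the scheme degenerates to leave-one-out."""
        data = dataset_from_frame(make_meta_frame(n_studies=1, cases=12, seed=10), "meta")
        spec = spec_model("m1_2")
        truth = ParameterSet(beta_loc=np.array([0.2, 0.05]),
                             beta_scale=np.array([-1.2, 0.0]), sd={"loc_icpt": 0.2})
        sim, _ = simulate_response(spec, truth, data, seed=11)
        cfg = McmcConfig(chains=1, warmup=100, samples=100, seed=12,
                         adapt_target=0.85, max_treedepth=7)
        rep = run_kfold([spec], sim, k=12, config=cfg, seed=13)

        # independent loo loop using the same per-fold seed derivation
        fa = assign_stratified_kfold(sim, 12, seed=13)
        fold_seeds = np.random.SeedSequence(13).spawn(12)
        manual = np.empty(12)
        for f, rows in fa.folds():
            assert rows.size == 1
            train = sim.subset(np.setdiff1d(np.arange(12), rows))
            fit_seed = int(fold_seeds[f].generate_state(1)[0] % (2 ** 31))
            draws = fit(spec, train, dataclasses.replace(cfg, seed=fit_seed))
            manual[rows[0]] = elpd_conditional(draws, spec, sim.subset(rows)).values[0]
        assert np.allclose(rep.pointwise[spec.name], manual, atol=1e-10)

    def test_duplicate_structure_gives_identical_vectors(self, fast_config):
        data = dataset_from_frame(make_meta_frame(n_studies=6, cases=3, seed=14), "meta")
        spec = spec_model("m1_2")
        truth = ParameterSet(beta_loc=np.array([0.2, 0.05]),
                             beta_scale=np.array([-1.2, 0.0]), sd={"loc_icpt": 0.2})
        sim, _ = simulate_response(spec, truth, data, seed=15)
        clone = dataclasses.replace(spec, name="m1_2_clone")
        rep = run_kfold([spec, clone], sim, k=3, config=fast_config, seed=16)
        assert np.array_equal(rep.pointwise["m1_2"], rep.pointwise["m1_2_clone"])

    def test_logo_three_studies_three_folds(self, fast_config):
        data = dataset_from_frame(make_meta_frame(n_studies=3, cases=4, seed=17), "meta")
        spec = spec_model("m1_2")
        truth = ParameterSet(beta_loc=np.array([0.2, 0.05]),
                             beta_scale=np.array([-1.2, 0.0]), sd={"loc_icpt": 0.2})
        sim, _ = simulate_response(spec, truth, data, seed=18)
        rep = run_logo([spec], sim, config=fast_config, seed=19, re_draws=30)
        assert rep.scheme_meta["n_heldout_studies"] == 3
        assert np.isfinite(rep.pointwise[spec.name]).all()
        assert rep.pointwise[spec.name].size == sim.n_obs

    def test_logo_requires_two_studies(self, fast_config):
        data = dataset_from_frame(make_meta_frame(n_studies=1, cases=4, seed=20), "meta")
        with pytest.raises(ValueError, match="at least 2 studies"):
            run_logo([spec_model("m1_2")], data, config=fast_config)

    def test_empty_spec_list_rejected(self, meta_toy, fast_config):
        with pytest.raises(ValueError):
            run_kfold([], meta_toy, config=fast_config)
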