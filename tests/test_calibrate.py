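"""Calibration: WSSR, normalization schemes, PSO, best-set selection."""

import numpy as np
import pandas as pd
import pytest

from fvmapk.calibrate import (
    wssr, normalize_prediction, training_objective, pso_minimize,
    select_best, baseline_parameter_set, ParameterSet, FitResult,
    load_best_fit_ensemble, dataset_wssr,
)
from fvmapk.synth import generate_training_like


class TestWssr:
    def test_perfect_fit_is_zero(self):
        assert wssr([0.3, 0.7, 1.0], [0.3, 0.7, 1.0]) == 0.0

    def test_single_term_arithmetic(self):
        assert wssr([2.0], [1.0]) == pytest.approx(1.0)

    def test_matches_elementwise_accumulation(self):
        rng = np.random.default_rng(3)
        pred = rng.uniform(0.1, 1, 20)
        obs = rng.uniform(0.1, 1, 20)
        manual = sum(((p - o) / o) ** 2 for p, o in zip(pred, obs))
        assert wssr(pred, obs) == pytest.approx(manual, rel=1e-12)

    def test_zero_observation_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wssr([1.0], [0.0])


class TestNormalization:
    def test_per_condition_every_curve_attains_one(self):
        curves = {"a": np.array([1.0, 3.0]), "b": np.array([0.2, 0.1])}
        out = normalize_prediction(curves, "per_condition")
        for v in out.values():
            assert v.max() == pytest.approx(1.0)

    def test_panel_max_exactly_one_curve_attains_one(self):
        curves = {"a": np.array([1.0, 3.0]), "b": np.array([0.2, 2.0])}
        out = normalize_prediction(curves, "panel_max")
        maxima = sorted(v.max() for v in out.values())
        assert maxima[-1] == pytest.approx(1.0)
        assert maxima[0] < 1.0

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        curves = {f"c{i}": rng.uniform(0, 2, 7) for i in range(4)}
        out = normalize_prediction(curves, "panel_max")
        gmax = max(v.max() for v in curves.values())
        for k in curves:
            assert np.allclose(out[k], curves[k] / gmax)

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_prediction({"a": np.zeros(3)}, "per_condition")


class TestObjective:
    @pytest.fixture(scope="class")
    def noise_free_study(self, main_model):
        return generate_training_like(noise_cv=0.0, seed=11,
                                      model=main_model)

    def test_self_consistency_on_noise_free_data(self, main_model,
                                                 noise_free_study):
        """Data generated from theta itself scores an objective ~ 0."""
        base = baseline_parameter_set(main_model)
        obj = training_objective(main_model, base.values,
                                 noise_free_study.training,
                                 rtol=1e-8, atol=1e-6)
        assert obj <= 1e-6

    def test_objective_invariant_to_dataset_order(self, main_model,
                                                  noise_free_study):
        base = baseline_parameter_set(main_model)
        fwd = training_objective(main_model, base.values,
                                 noise_free_study.training)
        rev = training_objective(main_model, base.values,
                                 noise_free_study.training[::-1])
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_perturbed_parameters_score_worse(self, main_model,
                                              noise_free_study):
        base = baseline_parameter_set(main_model)
        worse = dict(base.values)
        worse["init:FRS2"] *= 5.0
        worse["ked2"] /= 5.0
        assert (training_objective(main_model, worse,
                                   noise_free_study.training)
                > training_objective(main_model, base.values,
                                     noise_free_study.training) + 0.1)


class TestPso:
    def test_sphere_optimum_recovered(self):
        res = pso_minimize(lambda x: float((x ** 2).sum()),
                           [(-5.0, 5.0)] * 5, n_particles=40,
                           n_iterations=300, seed=1)
        pos = np.array([res.parameter_set.values[f"x{i}"] for i in range(5)])
        assert np.linalg.norm(pos) <= 1e-3
        assert res.wssr <= 1e-6

    def test_trace_monotone_nonincreasing(self):
        res = pso_minimize(lambda x: float(np.cos(x).sum() + (x ** 2).sum()),
                           [(-3.0, 3.0)] * 3, n_particles=10,
                           n_iterations=50, seed=2)
        assert np.all(np.diff(res.trace) <= 0)

    def test_same_seed_identical_result(self):
        f = lambda x: float(((x - 1.3) ** 2).sum())
        a = pso_minimize(f, [(-2.0, 2.0)] * 2, n_particles=8,
                         n_iterations=30, seed=9)
        b = pso_minimize(f, [(-2.0, 2.0)] * 2, n_particles=8,
                         n_iterations=30, seed=9)
        assert a.wssr == b.wssr
        assert a.parameter_set.values == b.parameter_set.values

    def test_positions_stay_in_bounds(self):
        seen = []
        def f(x):
            seen.append(x.copy())
            return float((x ** 2).sum())
        pso_minimize(f, [(0.5, 1.0), (-1.0, -0.2)], n_particles=6,
                     n_iterations=20, seed=3)
        arr = np.array(seen)
        assert arr[:, 0].min() >= 0.5 and arr[:, 0].max() <= 1.0
        assert arr[:, 1].min() >= -1.0 and arr[:, 1].max() <= -0.2


class TestSelection:
    def _fit(self, id_, train):
        ps = ParameterSet(values={"k": 1.0}, id=id_)
        return FitResult(ps, train, np.array([train]), seed=0)

    def test_returns_exactly_k(self):
        fits = [self._fit(f"f{i}", float(i)) for i in range(72)]
        best = select_best(fits, k=16)
        assert len(best) == 16
        assert [p.id for p in best] == [f"f{i}" for i in range(16)]

    def test_ties_break_by_id(self):
        fits = [self._fit(f"f{i:02d}", 1.0) for i in range(20)]
        best = select_best(fits, k=16)
        assert [p.id for p in best] == [f"f{i:02d}" for i in range(16)]

    def test_selected_dominate_unselected(self):
        rng = np.random.default_rng(8)
        fits = [self._fit(f"f{i}", float(rng.uniform(0, 100)))
                for i in range(40)]
        vals = {f.parameter_set.id: float(rng.uniform(0, 10)) for f in fits}
        best = select_best(fits, vals, k=16)
        chosen = {p.id for p in best}
        combined = {f.parameter_set.id: f.wssr + vals[f.parameter_set.id]
                    for f in fits}
        worst_chosen = max(combined[i] for i in chosen)
        best_rejected = min(combined[i] for i in combined if i not in chosen)
        assert worst_chosen <= best_rejected

    def test_fewer_than_k_warns_and_returns_all(self):
        fits = [self._fit(f"f{i}", float(i)) for i in range(5)]
        with pytest.warns(UserWarning):
            best = select_best(fits, k=16)
        assert len(best) == 5


class TestPackagedEnsemble:
    def test_sixteen_sets_with_39_free_quantities(self, main_model,
                                                  ensemble):
        assert len(ensemble) == 16
        free = set(main_model.free_quantities)
        for ps in ensemble:
            assert set(ps.values) == free
            ps.check_bounds()

    def test_ensemble_scores_are_genuine_fits(self, main_model, ensemble):
        """Every packaged set reproduces the packaged synthetic training
        data far below the failure penalty, and the pool contains
        near-truth fits."""
        study = generate_training_like(noise_cv=0.10, seed=2026,
                                       model=main_model)
        scores = [training_objective(main_model, ps, study.training)
                  for ps in ensemble]
        assert max(scores) < 100.0
        assert min(scores) < 2.0

    def test_fitting_reduces_the_prior_spread(self, ensemble):
        """The ensemble's mean per-quantity spread is narrower than the
        log-uniform prior over the two-decade box (sd = 2/sqrt(12)
        decades): the fit shrinks the bounds on average. Individual
        quantities remain sloppy (independent swarm runs scatter), so no
        per-quantity pinning is claimed."""
        prior_sd = 2.0 / np.sqrt(12.0)
        names = list(ensemble[0].values)
        sds = np.array([np.log10([ps.values[n] for ps in ensemble]).std(
            ddof=1) for n in names])
        assert sds.mean() < prior_sd
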