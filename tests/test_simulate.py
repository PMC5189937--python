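"""Bifurcation simulator: fixed points, determinism, labels, slowing down."""

import numpy as np
import pytest
from scipy import optimize

from icindex.simulate import (GrnModel, classify_attractor, default_scenario,
                              default_scenario_config, find_fixed_points,
                              model_from_config, predicted_relaxation_time,
                              progenitor_fixed_point, relaxation_time,
                              simulate_ensemble, slow_eigenvector,
                              stable_fixed_points)


@pytest.fixture(scope="module")
def model():
    return model_from_config(default_scenario_config())


@pytest.fixture(scope="module")
def schedule():
    cfg = default_scenario_config()
    return [(s["time"], s["mu"]) for s in cfg["simulation"]["schedule"]]


class TestFixedPoints:
    def test_noise_free_ensemble_converges_to_root_finder_fixed_point(self, model):
        quiet = GrnModel(**{**model.__dict__, "noise_sigma": 0.0})
        mu = 1.0
        ens = simulate_ensemble(quiet, 10, [("t0", mu)], seed=0, t_segment=30.0)
        final = ens.snapshots[0].raw_state
        # independent oracle: direct root find on the master drift
        sol = optimize.root(lambda v: quiet.drift_masters(np.asarray(v), mu),
                            np.array([1.0, 1.0]))
        assert sol.success
        assert np.abs(final[:, :2] - sol.x).max() < 1e-6
        drift = quiet.drift(final, mu)
        assert np.abs(drift).max() < 1e-6

    def test_symmetric_model_preserves_symmetry_without_noise(self):
        sym = GrnModel(bias=0.0, noise_sigma=0.0)
        # start at the symmetric progenitor, ramp past the pitchfork
        ens = simulate_ensemble(sym, 10, [("t0", 0.9), ("t1", 0.6)], seed=0,
                                t_segment=10.0)
        xy = ens.snapshots[-1].raw_state[:, :2]
        # started on the symmetric invariant line, stays there exactly
        assert np.abs(xy[:, 0] - xy[:, 1]).max() == 0.0

    def test_progenitor_destabilizes_past_the_fold(self, model):
        assert any(abs(f.xy[0] - f.xy[1]) < 0.5 for f in stable_fixed_points(model, 1.0))
        post = stable_fixed_points(model, 0.6)
        assert all(abs(f.xy[0] - f.xy[1]) > 0.5 for f in post)
        assert len(post) == 2

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            GrnModel(a=-1.0)


class TestDeterminism:
    def test_same_seed_bit_identical(self, model, schedule):
        e1 = simulate_ensemble(model, 12, schedule[:2], seed=7, t_segment=2.0)
        e2 = simulate_ensemble(model, 12, schedule[:2], seed=7, t_segment=2.0)
        for s1, s2 in zip(e1.snapshots, e2.snapshots):
            np.testing.assert_array_equal(s1.raw_state, s2.raw_state)

    def test_cell_count_change_preserves_shared_trajectories(self, model):
        small = simulate_ensemble(model, 10, [("t0", 1.0)], seed=3, t_segment=1.0)
        large = simulate_ensemble(model, 14, [("t0", 1.0)], seed=3, t_segment=1.0)
        np.testing.assert_array_equal(small.snapshots[0].raw_state,
                                      large.snapshots[0].raw_state[:10])

    def test_non_monotone_schedule_rejected(self, model):
        with pytest.raises(ValueError, match="monotone"):
            simulate_ensemble(model, 10, [("a", 1.0), ("b", 0.8), ("c", 0.9)],
                              seed=0, t_segment=0.1)


class TestClassifyAttractor:
    def test_state_at_fixed_point_gets_its_label(self, model):
        fps = stable_fixed_points(model, 0.6)
        for f in fps:
            label = classify_attractor(model.slaved_state(f.xy), model, 0.6)
            assert label == ("intended" if f.xy[0] > f.xy[1] else "rebellious")

    def test_progenitor_label_pre_bifurcation(self, model):
        fp = progenitor_fixed_point(model, 1.0)
        assert classify_attractor(model.slaved_state(fp.xy), model, 1.0) \
            == "progenitor"

    def test_state_far_from_attractors_is_undecided(self, model):
        state = model.slaved_state(np.array([1.0, 1.0]))
        assert classify_attractor(state, model, 0.6) == "undecided"

    def test_disfavored_attractor_is_rebellious_under_positive_bias(self, model):
        assert model.bias > 0
        y_branch = [f for f in stable_fixed_points(model, 0.6)
                    if f.xy[1] > f.xy[0]][0]
        assert classify_attractor(model.slaved_state(y_branch.xy), model, 0.6) \
            == "rebellious"


class TestRelaxation:
    def test_threshold_one_returns_zero_time(self, model):
        quiet = GrnModel(**{**model.__dict__, "noise_sigma": 0.0})
        pert = 0.05 * slow_eigenvector(quiet, 1.0)
        res = relaxation_time(quiet, 1.0, pert, threshold=1.0)
        assert res.time == 0.0 and not res.censored

    def test_noise_free_time_matches_jacobian_prediction(self, model):
        quiet = GrnModel(**{**model.__dict__, "noise_sigma": 0.0})
        for mu in (1.0, 0.92, 0.86):
            pert = 0.05 * slow_eigenvector(quiet, mu)
            measured = relaxation_time(quiet, mu, pert, threshold=0.1).time
            predicted = predicted_relaxation_time(quiet, mu, threshold=0.1)
            assert measured == pytest.approx(predicted, rel=0.2)

    def test_relaxation_slows_approaching_the_bifurcation(self, model):
        quiet = GrnModel(**{**model.__dict__, "noise_sigma": 0.0})
        times = []
        for mu in (1.0, 0.92, 0.86):
            pert = 0.05 * slow_eigenvector(quiet, mu)
            times.append(relaxation_time(quiet, mu, pert, threshold=0.1).time)
        assert times[0] < times[1] < times[2]
        # eigenvalue oracle agrees on the ordering
        preds = [predicted_relaxation_time(quiet, mu, 0.1)
                 for mu in (1.0, 0.92, 0.86)]
        assert preds[0] < preds[1] < preds[2]


class TestEnsemblePhenomenology:
    def test_snapshots_are_valid_expression_matrices(self):
        ens = default_scenario(seed=2)
        for snap in ens.snapshots:
            x = snap.expression
            assert x.n_cells == 500 and x.n_genes == 12
            assert not x.values.isna().any().any()
        concat = ens.to_expression_matrix()
        assert concat.n_cells == 4 * 500

    def test_master_subspace_variance_grows_toward_bifurcation(self, model):
        # 3-point monotonicity of fluctuation amplitude below the fold
        variances = []
        for mu in (1.0, 0.92, 0.86):
            ens = simulate_ensemble(model, 200, [("t", mu)], seed=5,
                                    t_segment=15.0)
            xy = ens.snapshots[0].raw_state[:, :2]
            variances.append(np.trace(np.cov(xy.T)))
        assert variances[0] < variances[1] < variances[2]

    def test_pinned_seed_regression_values(self):
        ens = default_scenario(seed=1)
        from icindex.index import ic_timecourse
        res = ic_timecourse(ens.to_expression_matrix(), b_sem=0)
        ics = {r.group: r.ic for r in res}
        assert ics["t2"] / ics["t0"] >= 1.5
        reb = float((ens.snapshots[-1].labels == "rebellious").mean())
        assert 0 < reb < 0.5

    def test_stationary_ensemble_shows_no_ic_trend(self, model):
        # in-attractor snapshots at fixed mu: the I_C slope over sampling
        # index has no systematic sign (binomial bounds over 10 seeds)
        from icindex.index import ic_timecourse
        positive = 0
        for seed in range(30, 40):
            ens = simulate_ensemble(
                model, 200, [("s0", 1.0), ("s1", 1.0), ("s2", 1.0)],
                seed=seed, t_segment=10.0)
            ics = [r.ic for r in ic_timecourse(ens.to_expression_matrix(),
                                               b_sem=0)]
            slope = np.polyfit(np.arange(3), ics, 1)[0]
            positive += slope > 0
        assert 1 <= positive <= 9

    def test_symmetric_model_splits_evenly_without_bias(self):
        from scipy.stats import binomtest
        sym = GrnModel(bias=0.0, noise_sigma=0.05,
                       downstream=model_from_config(
                           default_scenario_config()).downstream)
        ens = simulate_ensemble(sym, 2000, [("t0", 1.0), ("t1", 0.6)], seed=11,
                                t_segment=10.0)
        labels = ens.snapshots[-1].labels
        # bias = 0 makes "intended" the x-branch by convention
        n_x = int((labels == "intended").sum())
        n_y = int((labels == "rebellious").sum())
        assert binomtest(n_x, n_x + n_y, 0.5).pvalue > 0.01
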