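"""Global fitting: self-consistency, confidence intervals, information content."""

import numpy as np
import pytest

from dscfit.fitting import (
    FitOptions,
    build_problem,
    confidence_intervals,
    global_fit,
    initial_model_from_data,
    predict_scans,
)
from dscfit.io import Experiment, ExperimentSet
from dscfit.synthetic import make_reheat_experiments, protein_preset

DBJA_TRUTH = dict(E=418e3, Tf=337.6, dH=337e3, dCp=5.4e3)


def _dbja_data(noise_sd, seed, grid=0.5, t_primes=(331.0,), T_max=353.15):
    m = protein_preset("DbjA").with_baseline(0, 0)
    return make_reheat_experiments(m, 293.15, T_max, 1 / 60, t_primes,
                                   noise_sd=noise_sd, seed=seed, grid_step=grid,
                                   include_full_first=False)


def _fit_dbja(noise_sd, seed, **kw):
    data = _dbja_data(noise_sd, seed, **kw)
    problem = build_problem(data, initial_model_from_data(data, "B"))
    return global_fit(problem, FitOptions(grid_step=0.5, n_starts=1))


class TestGlobalFit:
    def test_noise_free_self_consistency(self):
        data = _dbja_data(0.0, 0, grid=0.4)
        truth = protein_preset("DbjA").with_baseline(0, 0)
        problem = build_problem(data, truth)
        res = global_fit(problem, FitOptions(grid_step=0.4, n_starts=1))
        assert res.ssr < 1e-10
        for s in res.scans:
            assert np.abs(s.residual).max() < 1e-8
        assert res.value("s1_E") == pytest.approx(418e3, rel=1e-6)

    def test_objective_not_worse_than_initial(self):
        data = _dbja_data(0.5e3, 3)
        problem = build_problem(data, initial_model_from_data(data, "B"))
        obs = np.concatenate([s.Cp for s in data.scans])
        init_pred = np.concatenate(predict_scans(problem, problem.params, 0.5))
        res = global_fit(problem, FitOptions(grid_step=0.5, n_starts=1))
        assert res.ssr <= np.sum((obs - init_pred) ** 2)

    def test_parameter_recovery_from_data_driven_start(self):
        res = _fit_dbja(0.5e3, 11, t_primes=(327.0, 331.0))
        assert res.value("s1_E") == pytest.approx(DBJA_TRUTH["E"], rel=0.02)
        assert res.value("s1_Tf") == pytest.approx(DBJA_TRUTH["Tf"], abs=0.5)
        assert res.value("s1_dH") == pytest.approx(DBJA_TRUTH["dH"], rel=0.02)
        assert res.value("s1_dCp") == pytest.approx(DBJA_TRUTH["dCp"], rel=0.15)

    def test_reheat_curves_come_from_propagation_not_free_fit(self):
        # the predicted reheat peak must shrink according to the losses of
        # the first run, even when the fit would prefer otherwise
        data = _dbja_data(0.0, 0, t_primes=(342.0,))
        truth = protein_preset("DbjA").with_baseline(0, 0)
        problem = build_problem(data, truth)
        preds = predict_scans(problem, problem.params, 0.4)
        first, reheat = preds
        assert reheat.max() < 0.25 * first.max()

    def test_at_least_one_free_parameter_required(self):
        data = _dbja_data(0.0, 0)
        truth = protein_preset("DbjA").with_baseline(0, 0)
        vary = {k: False for k in
                ("s1_E", "s1_Tf", "s1_dH", "s1_dCp", "B0_g0", "B1_g0")}
        with pytest.raises(ValueError, match="must be free"):
            build_problem(data, truth, vary=vary)

    def test_deterministic_given_data_and_options(self):
        a = _fit_dbja(0.5e3, 5)
        b = _fit_dbja(0.5e3, 5)
        assert a.ssr == b.ssr
        assert a.value("s1_E") == b.value("s1_E")


class TestConfidenceIntervals:
    def test_zero_noise_half_widths_vanish(self):
        res = _fit_dbja(0.0, 0)
        ci = confidence_intervals(res)
        assert ci["s1_E"] is not None
        assert ci["s1_E"] < 1e-2 * res.value("s1_E")

    def test_half_widths_scale_with_noise(self):
        lo = _fit_dbja(0.25e3, 7, grid=0.3)
        hi = _fit_dbja(0.5e3, 7, grid=0.3)
        r = confidence_intervals(hi)["s1_E"] / confidence_intervals(lo)["s1_E"]
        assert r == pytest.approx(2.0, rel=0.35)

    def test_monte_carlo_coverage_of_E(self):
        # empirical coverage of the linearized 95% interval
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            res = _fit_dbja(0.5e3, 1000 + seed, grid=0.4, T_max=349.15)
            half = confidence_intervals(res)["s1_E"]
            hits += abs(res.value("s1_E") - DBJA_TRUTH["E"]) <= half
        assert 0.88 * n_rep <= hits <= 0.99 * n_rep


def test_two_state_fit_misses_reheats_of_reversible_kinetic_data():
    # three-state truth with a fast reverse rate: much protein refolds on
    # cooling, so the irreversible two-state fit, whose reheats can only
    # decay, misses the reheat peaks while matching the first runs
    import math

    from dscfit.models import UnfoldingModel, Baseline, irreversible_step, two_rate_step
    from dscfit.diagnostics import refold_statistics
    from dscfit.thermo import R

    def tf(E, T, k):  # Tf such that the rate equals k at T
        return 1.0 / (1.0 / T + R * math.log(k) / E)

    c = 0.05  # first-step rates at 330 K, fast against the ~1e-3 drain
    truth = UnfoldingModel(
        (two_rate_step(E_fwd=480e3, Tf_fwd=tf(480e3, 330.0, c),
                       E_rev=80e3, Tf_rev=tf(80e3, 330.0, c), dH=400e3),
         irreversible_step(E=75e3, Tf=436.0, dH=50e3)),
        Baseline(0.0, 0.0))
    data = make_reheat_experiments(truth, 293.15, 363.15, 1 / 60, (331.0, 335.0),
                                   noise_sd=0.5e3, seed=13, grid_step=0.5)
    res = global_fit(build_problem(data, initial_model_from_data(data, "B")),
                     FitOptions(grid_step=0.55, n_starts=1))
    rep = refold_statistics(res)
    assert rep.sd_ratio > 2.0


def test_multi_scan_rate_global_fit_with_per_rate_baselines():
    from dscfit.io import ExperimentSet

    m = protein_preset("DbjA").with_baseline(0, 0)
    slow = make_reheat_experiments(m, 293.15, 353.15, 0.5 / 60, (330.0,),
                                   noise_sd=0.5e3, seed=19, grid_step=0.5,
                                   include_full_first=False)
    fast = make_reheat_experiments(m, 293.15, 353.15, 2.0 / 60, (334.0,),
                                   noise_sd=0.5e3, seed=20, grid_step=0.5,
                                   include_full_first=False)
    data = ExperimentSet(slow.experiments + fast.experiments)
    problem = build_problem(data, initial_model_from_data(data, "B"))
    assert {"B0_g0", "B1_g0", "B0_g1", "B1_g1"} <= set(problem.params)
    res = global_fit(problem, FitOptions(grid_step=0.5, n_starts=1))
    assert res.value("s1_E") == pytest.approx(418e3, rel=0.02)
    assert res.value("s1_Tf") == pytest.approx(337.6, abs=0.5)


def test_reheats_sharpen_second_step_parameters():
    # partially reversible truth: adding reheats to the fit must narrow the
    # drain-step confidence intervals (the reheat carries the irreversibility
    # information)
    m = protein_preset("DhaA").with_baseline(0, 0)
    data = make_reheat_experiments(m, 293.15, 353.15, 1 / 60, (327.5, 339.5),
                                   noise_sd=0.5e3, seed=17, grid_step=0.4)
    stripped = ExperimentSet(
        [Experiment(e.experiment_id, e.first, []) for e in data.experiments])
    opts = FitOptions(grid_step=0.45, n_starts=1)
    vary = {"s2_dCp": False, "s2_dH": False}
    full = global_fit(build_problem(data, m, vary=vary), opts)
    first_only = global_fit(build_problem(stripped, m, vary=vary), opts)
    ci_full = confidence_intervals(full)
    ci_first = confidence_intervals(first_only)
    assert ci_full["s2_E"] < ci_first["s2_E"]
    assert ci_full["s2_Tf"] < ci_first["s2_Tf"]
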