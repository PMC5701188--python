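"""Forward simulation: decay factors, state propagation, heat-capacity synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dscfit.thermo import R, ArrheniusParams
from dscfit.models import (
    Baseline,
    ModelValidationError,
    TemperatureProgram,
    ScanSegment,
    UnfoldingModel,
    apparent_heat_capacity,
    decay_factor_irreversible,
    equilibrium_step,
    heat_cool_reheat,
    irreversible_step,
    make_model,
    simulate_fractions,
    simulate_thermogram,
    single_scan,
    two_rate_step,
)
from dscfit.synthetic import protein_preset

from conftest import brute_force_native_fraction


class TestMakeModel:
    def test_presets(self):
        assert [s.kind for s in make_model("A").steps] == ["equilibrium"]
        assert [s.kind for s in make_model("B").steps] == ["irreversible"]
        assert [s.kind for s in make_model("C").steps] == ["equilibrium", "irreversible"]
        assert [s.kind for s in make_model("D").steps] == ["two_rate", "irreversible"]

    def test_appended_exothermic_step_accepted_silently(self, recwarn):
        # chain with a separate negative high-temperature peak
        make_model([
            equilibrium_step(345.0, 516e3, 7.5e3),
            irreversible_step(200e3, 350.0, 50e3),
            irreversible_step(100e3, 390.0, -40e3),
        ])
        assert not any("conservative" in str(w.message) for w in recwarn.list)

    def test_warns_when_one_peak_gets_three_steps(self):
        with pytest.warns(UserWarning, match="conservative"):
            make_model([
                equilibrium_step(345.0, 300e3),
                irreversible_step(200e3, 348.0, 100e3),
                irreversible_step(150e3, 352.0, 100e3),
            ])

    def test_invalid_chains_rejected(self):
        with pytest.raises(ModelValidationError):
            make_model([])
        with pytest.raises(ModelValidationError):
            make_model([irreversible_step(300e3, 340.0),
                        two_rate_step(300e3, 340.0, 100e3, 360.0, 400e3)])
        with pytest.raises(ModelValidationError):
            make_model([irreversible_step(300e3, 340.0),
                        equilibrium_step(345.0, 300e3)])


class TestDecayFactor:
    def test_empty_path_is_unity(self):
        p = ArrheniusParams(E=300e3, Tf=360.0)
        assert decay_factor_irreversible(p, 330.0, 330.0, 1 / 60) == 1.0

    def test_quadrature_value(self):
        # high-resolution quadrature oracle of exp(-(1/v) int k dT)
        p = ArrheniusParams(E=300e3, Tf=360.0)
        X = decay_factor_irreversible(p, 293.15, 342.0, 1 / 60)
        assert X == pytest.approx(0.3764, abs=2e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(E=st.floats(50e3, 800e3), Tf=st.floats(320.0, 400.0),
           T1=st.floats(290.0, 330.0), dT=st.floats(1.0, 60.0),
           v=st.floats(0.2 / 60, 4.0 / 60))
    def test_path_reversal_identity(self, E, Tf, T1, dT, v):
        p = ArrheniusParams(E=E, Tf=Tf)
        fwd = decay_factor_irreversible(p, T1, T1 + dT, v)
        rev = decay_factor_irreversible(p, T1 + dT, T1, -v)
        assert fwd == pytest.approx(rev, rel=1e-9)
        assert 0.0 <= fwd <= 1.0  # may underflow to 0 for very fast kinetics

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            decay_factor_irreversible(ArrheniusParams(300e3, 360.0), 300.0, 310.0, 0.0)

    def test_inconsistent_direction_rejected(self):
        with pytest.raises(ValueError):
            decay_factor_irreversible(ArrheniusParams(300e3, 360.0), 300.0, 310.0, -1 / 60)


class TestSimulateFractions:
    def test_reversible_model_is_history_free(self):
        m = make_model([equilibrium_step(330.0, 400e3, 2e3)])
        prog = heat_cool_reheat(293.15, 353.15, 1 / 60)
        traj = simulate_fractions(m, prog)
        first, reheat = traj.segment("first"), traj.segment("reheat")
        np.testing.assert_allclose(first.x, reheat.x, atol=1e-12)
        # and x_d = K/(1+K) pointwise
        from dscfit.thermo import equilibrium_constant

        K = np.array([equilibrium_constant(m.steps[0].params, T) for T in first.T])
        np.testing.assert_allclose(first.x[:, 1], K / (1 + K), rtol=1e-10)

    def test_irreversible_cool_gives_squared_decay(self):
        m = make_model([irreversible_step(418e3, 337.6, 337e3)])
        Tp = 342.0
        prog = heat_cool_reheat(293.15, Tp, 1 / 60)
        traj = simulate_fractions(m, prog)
        X = decay_factor_irreversible(m.steps[0].params, 293.15, Tp, 1 / 60)
        assert traj.segment("cool").x[-1, 0] == pytest.approx(X**2, abs=1e-6)

    def test_matches_brute_force_integration(self):
        # closed-form propagation vs fixed-step RK4 at 0.001 K
        m = make_model([irreversible_step(300e3, 360.0, 800e3)])
        traj = simulate_fractions(m, single_scan(293.15, 373.15, 1 / 60))
        seg = traj.segment("first")
        idx = np.linspace(0, seg.T.size - 1, 9, dtype=int)
        oracle = brute_force_native_fraction(
            m.steps[0].params, seg.T[idx], 1 / 60)
        np.testing.assert_allclose(seg.x[idx, 0], oracle, atol=1e-6)

    def test_partially_reversible_preserves_most_below_tm(self):
        # DhaA-like first peak: heat to 50 degC and cool keeps ~80-90% native
        m = protein_preset("DhaA")
        traj = simulate_fractions(m, heat_cool_reheat(293.15, 323.15, 1 / 60))
        xn = traj.segment("reheat").x[0, 0]
        assert 0.7 <= xn <= 0.95

    @pytest.mark.parametrize("protein", ["SpA", "DbjA", "DhaA", "DhaA115", "lysozyme"])
    def test_fraction_conservation_all_chains(self, protein):
        m = protein_preset(protein)
        traj = simulate_fractions(m, heat_cool_reheat(293.15, 350.0, 1 / 60,
                                                      T_reheat_end=370.0))
        for seg in traj.segments:
            np.testing.assert_allclose(seg.x.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(seg.x > -1e-9) and np.all(seg.x < 1 + 1e-9)

    def test_fractions_continuous_across_segments(self):
        m = protein_preset("DhaA115")
        traj = simulate_fractions(m, heat_cool_reheat(293.15, 350.0, 1 / 60))
        for a, b in zip(traj.segments, traj.segments[1:]):
            np.testing.assert_allclose(a.x[-1], b.x[0], atol=1e-8)


class TestApparentHeatCapacity:
    def test_baseline_only_before_transition(self):
        m = UnfoldingModel((irreversible_step(300e3, 360.0, 800e3),),
                           Baseline(10e3, 50.0))
        traj = simulate_fractions(m, single_scan(293.15, 373.15, 1 / 60))
        T, Cp = apparent_heat_capacity(m, traj, "first")
        assert Cp[0] == pytest.approx(10e3 + 50.0 * 293.15, rel=1e-6)

    def test_total_heat_equals_enthalpy(self):
        m = make_model([irreversible_step(300e3, 360.0, 800e3)])
        traj = simulate_fractions(m, single_scan(293.15, 373.15, 1 / 60))
        T, Cp = apparent_heat_capacity(m, traj, "first")
        assert np.trapezoid(Cp, T) == pytest.approx(800e3, rel=5e-3)

    def test_reduces_to_explicit_two_state_formula(self):
        # Cp = B0 + B1 T + (1 - x_n) dCp + (k/v) x_n dH(T) for one irreversible step
        from dscfit.thermo import rate_constant

        m = UnfoldingModel((irreversible_step(300e3, 360.0, 800e3, 4e3),),
                           Baseline(2e3, 10.0))
        v = 1 / 60
        traj = simulate_fractions(m, single_scan(293.15, 373.15, v))
        T, Cp = apparent_heat_capacity(m, traj, "first")
        seg = traj.segment("first")
        p = m.steps[0].params
        k = np.array([rate_constant(p, t) for t in T])
        dH = p.dH_ref + p.dCp * (T - p.Tf)
        explicit = 2e3 + 10.0 * T + (1 - seg.x[:, 0]) * p.dCp + (k / v) * seg.x[:, 0] * dH
        np.testing.assert_allclose(Cp, explicit, rtol=1e-10)

    def test_reversible_reheat_identical_to_first(self):
        m = make_model([equilibrium_step(328.44, 102.4e3, 1.38e3, dH_vh=169e3)])
        scans = simulate_thermogram(m, heat_cool_reheat(293.15, 363.15, 4 / 60))
        first, reheat = scans
        np.testing.assert_allclose(first.Cp, reheat.Cp, atol=1e-9)

    def test_reheat_baseline_shift_equals_converted_fraction_times_dcp(self):
        # partial denaturation with dCp > 0 lifts the reheat start by x_d(T0) dCp
        m = UnfoldingModel((irreversible_step(418e3, 337.6, 337e3, 5.4e3),),
                           Baseline(0.0, 0.0))
        prog = heat_cool_reheat(293.15, 340.0, 1 / 60)
        traj = simulate_fractions(m, prog)
        Tf_, Cp_first = apparent_heat_capacity(m, traj, "first")
        Tr_, Cp_reheat = apparent_heat_capacity(m, traj, "reheat")
        x_d0 = traj.segment("reheat").x[0, 1]
        assert x_d0 > 0.05
        assert Cp_reheat[0] - Cp_first[0] == pytest.approx(x_d0 * 5.4e3, rel=1e-6)

    def test_reheat_peak_nonincreasing_in_terminal_temperature(self):
        m = protein_preset("DbjA").with_baseline(0, 0)
        heights = []
        for tp in (320.0, 327.0, 331.0, 336.0, 342.0):
            scans = simulate_thermogram(
                m, heat_cool_reheat(293.15, tp, 1 / 60, T_reheat_end=353.15))
            reheat = [s for s in scans if s.role == "reheat"][0]
            heights.append(reheat.Cp.max())
        assert np.all(np.diff(heights) <= 1e-9)


class TestLimitingCases:
    def test_two_rate_with_zero_reverse_reduces_to_irreversible(self):
        b = UnfoldingModel((irreversible_step(418e3, 337.6, 337e3, 5.4e3),),
                           Baseline(0.0, 0.0))
        # reverse rate ~ exp(-111) and an energetically silent drain: the
        # first step carries B's k, dH and dCp, so N -> I is B's N -> D
        d = UnfoldingModel(
            (two_rate_step(418e3, 337.6, 500e3, 1000.0, 337e3, 5.4e3),
             irreversible_step(100e3, 2000.0, 0.0)),
            Baseline(0.0, 0.0),
        )
        prog = heat_cool_reheat(293.15, 342.0, 1 / 60, T_reheat_end=353.15)
        tb = simulate_fractions(b, prog, 0.05)
        td = simulate_fractions(d, prog, 0.05)
        peak = apparent_heat_capacity(b, tb, "first")[1].max()
        for role in ("first", "reheat"):
            _, cb = apparent_heat_capacity(b, tb, role)
            _, cd = apparent_heat_capacity(d, td, role)
            assert np.max(np.abs(cb - cd)) < 5e-3 * peak

    def test_two_rate_with_fast_first_step_reduces_to_equilibrium_chain(self):
        c = protein_preset("DhaA").with_baseline(0, 0)
        eq, dr = c.steps[0].params, c.steps[1].params
        scale = 1e4
        # k1/k-1 sharing K(T): E1 - Erev = dH, k1(Tm) = k-1(Tm) = scale * k2(Tm)
        from dscfit.thermo import rate_constant

        k2_tm = rate_constant(dr, eq.Tm)
        kref = scale * k2_tm
        Erev = 100e3
        E1 = eq.dH_ref + Erev

        def tf(E, T, k):
            return 1.0 / (1.0 / T + R * np.log(k) / E)

        # note: dCp of the first step omitted from K here; compare on dCp=0 copies
        c0 = UnfoldingModel((equilibrium_step(eq.Tm, eq.dH_ref),
                             irreversible_step(dr.E, dr.Tf, dr.dH_ref)),
                            Baseline(0.0, 0.0))
        d0 = UnfoldingModel(
            (two_rate_step(E1, tf(E1, eq.Tm, kref), Erev, tf(Erev, eq.Tm, kref),
                           eq.dH_ref),
             irreversible_step(dr.E, dr.Tf, dr.dH_ref)),
            Baseline(0.0, 0.0),
        )
        prog = heat_cool_reheat(293.15, 330.0, 1 / 60, T_reheat_end=353.15)
        tc = simulate_fractions(c0, prog, 0.1)
        td = simulate_fractions(d0, prog, 0.1)
        peak = apparent_heat_capacity(c0, tc, "first")[1].max()
        for role in ("first", "reheat"):
            _, cc = apparent_heat_capacity(c0, tc, role)
            _, cd = apparent_heat_capacity(d0, td, role)
            assert np.max(np.abs(cc - cd)) < 5e-3 * peak


class TestSimulateThermogram:
    def test_seeded_determinism(self):
        m = protein_preset("DbjA")
        prog = heat_cool_reheat(293.15, 340.0, 1 / 60)
        a = simulate_thermogram(m, prog, noise_sd=2.1e3, seed=42)
        b = simulate_thermogram(m, prog, noise_sd=2.1e3, seed=42)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.Cp, s2.Cp)

    def test_cooling_emits_no_thermogram(self):
        m = protein_preset("DbjA")
        scans = simulate_thermogram(m, heat_cool_reheat(293.15, 340.0, 1 / 60))
        assert [s.role for s in scans] == ["first", "reheat"]
        assert scans[1].T_prime == pytest.approx(340.0)

    def test_complete_transition_leaves_no_reheat_signal(self):
        m = make_model([irreversible_step(300e3, 360.0, 800e3)])
        scans = simulate_thermogram(m, heat_cool_reheat(293.15, 373.15, 1 / 60))
        first, reheat = scans
        assert reheat.Cp.max() < 1e-3 * first.Cp.max()

    def test_negative_noise_rejected(self):
        m = protein_preset("DbjA")
        with pytest.raises(ValueError):
            simulate_thermogram(m, single_scan(293.15, 340.0, 1 / 60), noise_sd=-1.0)


def test_segment_validation():
    with pytest.raises(ValueError):
        ScanSegment(300.0, 350.0, -1 / 60, "first")
    with pytest.raises(ValueError):
        ScanSegment(300.0, 350.0, 0.0, "first")
    with pytest.raises(ValueError):
        TemperatureProgram((ScanSegment(300.0, 350.0, 1 / 60, "first"),
                            ScanSegment(349.0, 300.0, -1 / 60, "cool")))
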