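"""Voltage-stretch equilibrium, sweeps, snap-through, and drift simulators."""

import numpy as np
import pytest

from stretchlab.actuation import (
    DriftModel,
    InstabilityError,
    MembraneGeometry,
    default_drift,
    prestretch_thickness,
    simulate_cyclic,
    simulate_static_tests,
    snap_through_voltage,
    solve_actuation,
    voltage_sweep,
)
from stretchlab.materials import VHB4910, YeohMaterial, equibiaxial_cauchy_stress, maxwell_stress


class TestGeometry:
    @pytest.mark.parametrize(
        "t_init,lam_p,expected_mm",
        [(1e-3, 1.0, 1.0), (1e-3, 3.0, 1.0 / 9.0), (2e-3, 2.0, 0.5)],
    )
    def test_prestretch_thickness(self, t_init, lam_p, expected_mm):
        geom = MembraneGeometry(t_init=t_init, lam_p=lam_p)
        assert prestretch_thickness(geom) * 1e3 == pytest.approx(expected_mm)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            MembraneGeometry(lam_p=0.5)
        with pytest.raises(ValueError):
            MembraneGeometry(electrode_radius=0.05, frame_radius=0.03)


class TestSolveActuation:
    def test_zero_voltage_is_prestretch(self, mat, geom):
        for conv in ("initial", "true"):
            res = solve_actuation(mat, geom, 0.0, conv)
            assert res.lam_total == geom.lam_p
            assert res.strain_act == 0.0
            assert res.stable

    def test_1kv_strain_below_one_percent(self, mat, geom):
        res = solve_actuation(mat, geom, 1000.0, "initial")
        assert res.strain_act == pytest.approx(0.0018988254, rel=1e-6)
        assert res.strain_act < 0.01

    def test_5kv_strain_level(self, mat, geom):
        res = solve_actuation(mat, geom, 5000.0, "initial")
        assert res.strain_act == pytest.approx(0.045421738, rel=1e-6)

    def test_root_satisfies_force_balance(self, mat, geom):
        res = solve_actuation(mat, geom, 4000.0, "initial")
        lhs = equibiaxial_cauchy_stress(mat, res.lam_total)
        rhs = equibiaxial_cauchy_stress(mat, geom.lam_p) + res.sigma_m * 1e-6
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_strain_strictly_increasing_and_convex_in_voltage(self, mat, geom):
        volts = np.linspace(0.0, 5000.0, 21)
        s = np.array([solve_actuation(mat, geom, v).strain_act for v in volts])
        assert np.all(np.diff(s) > 0)
        assert np.all(np.diff(s, 2) > -1e-12)  # convex: sigma_M ~ V^2

    def test_conventions_agree_at_low_voltage(self, mat, geom):
        a = solve_actuation(mat, geom, 500.0, "initial").strain_act
        b = solve_actuation(mat, geom, 500.0, "true").strain_act
        assert abs(a - b) / b < 0.01

    def test_domain_errors(self, mat, geom):
        with pytest.raises(ValueError):
            solve_actuation(mat, geom, -10.0)
        with pytest.raises(ValueError):
            solve_actuation(mat, geom, 100.0, "wrong")

    def test_oracle_dense_grid_agreement(self, geom):
        """Root finder matches a dense-grid scan to one 1e-4 stretch step."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = YeohMaterial(
                c10=rng.uniform(0.03, 0.12),
                c20=rng.uniform(-1e-3, -1e-4),
                c30=rng.uniform(2e-5, 5e-5),
            )
            lam_p = rng.uniform(2.0, 3.5)
            v = rng.uniform(500.0, 5000.0)
            g = MembraneGeometry(lam_p=lam_p)
            res = solve_actuation(m, g, v, "initial")
            lams = np.arange(lam_p, 4.0, 1e-4)
            t0 = prestretch_thickness(g)
            vals = (
                equibiaxial_cauchy_stress(m, lams)
                - equibiaxial_cauchy_stress(m, lam_p)
                - maxwell_stress(m, v, t0) * 1e-6
            )
            cross = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            assert cross.size >= 1
            assert abs(res.lam_total - lams[cross[0]]) <= 1e-4


class TestVoltageSweep:
    def test_empty_sweep(self, mat, geom):
        assert voltage_sweep(mat, geom, []) == []

    def test_standard_grid_monotone(self, mat, geom):
        volts = [500 * k for k in range(1, 11)]
        res = voltage_sweep(mat, geom, volts)
        strains = [r.strain_act for r in res]
        assert np.all(np.diff(strains) > 0)

    def test_zero_voltages(self, mat, geom):
        res = voltage_sweep(mat, geom, [0.0, 0.0])
        assert all(r.strain_act == 0.0 for r in res)

    def test_instability_identifies_voltage(self, mat, geom):
        with pytest.raises(InstabilityError) as err:
            voltage_sweep(mat, geom, [1000.0, 15000.0], "true")
        assert err.value.voltage == 15000.0


class TestSnapThrough:
    def test_initial_convention_never_snaps(self, mat, geom):
        assert snap_through_voltage(mat, geom, "initial", 20000.0) is None

    def test_true_convention_finite_snap(self, mat, geom):
        v = snap_through_voltage(mat, geom, "true", 20000.0)
        assert v is not None and v >= 5000.0
        with pytest.raises(InstabilityError):
            solve_actuation(mat, geom, v + 50.0, "true")
        assert solve_actuation(mat, geom, v - 50.0, "true").strain_act > 0

    def test_stiffer_material_snaps_later(self, mat, geom):
        v_soft = snap_through_voltage(mat, geom, "true", 60000.0)
        stiff = YeohMaterial(c10=mat.c10 * 10, c20=mat.c20, c30=mat.c30)
        v_stiff = snap_through_voltage(stiff, geom, "true", 60000.0)
        assert v_stiff > v_soft


class TestDriftModel:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"g": (0.5, 0.6), "tau": (1.0, 2.0)},  # sum >= 1
            {"g": (1.2,), "tau": (1.0,)},
            {"g": (0.5,), "tau": (-1.0,)},
            {"g": (0.5,), "tau": (1.0, 2.0)},
            {"cond0": 0.0},
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DriftModel(**kwargs)

    def test_default_profile_valid(self):
        d = default_drift()
        assert sum(d.g) < 1 and d.n_terms == 3


class TestStaticTests:
    def test_elastic_limit_all_tests_identical(self, mat, geom):
        eq = solve_actuation(mat, geom, 4000.0).strain_act
        out = simulate_static_tests(mat, geom, DriftModel(), 4000.0, 5)
        assert np.allclose(out, eq, rtol=1e-12)

    def test_warm_up_converges_by_test_six(self, mat, geom):
        drift = default_drift()
        tests = simulate_static_tests(mat, geom, drift, 5000.0, 9)
        asym = simulate_static_tests(mat, geom, drift, 5000.0, 80)[-1]
        inc = np.diff(tests)
        assert np.all(inc > 0)
        assert np.all(np.diff(inc) < 0)  # increments strictly decreasing
        assert np.all(np.abs(tests[5:] - asym) < 0.05 * asym)

    def test_full_recovery_limit(self, mat, geom):
        # single fast Prony term, relaxation much longer than tau: no memory
        drift = DriftModel(g=(0.3,), tau=(5.0,))
        out = simulate_static_tests(
            mat, geom, drift, 5000.0, 6, hold_s=60.0, relax_s=600.0
        )
        assert np.allclose(out, out[0], rtol=1e-9)


class TestCyclic:
    def test_elastic_limit_square_wave(self, mat, geom):
        eq = solve_actuation(mat, geom, 5000.0).strain_act * 100
        tr = simulate_cyclic(mat, geom, DriftModel(), 0, 5000, 1.0, 0.5, 10, 50)
        levels = np.unique(np.round(tr.strain, 9))
        assert levels.size == 2
        assert levels[0] == 0.0 and levels[1] == pytest.approx(eq)
        # duty cycle: half the samples high
        assert np.mean(tr.strain > eq / 2) == pytest.approx(0.5, abs=0.01)

    def test_single_cycle_has_one_max_one_min(self, mat, geom):
        tr = simulate_cyclic(mat, geom, default_drift(), 0, 5000, 1.0, 0.5, 1.0, 100)
        assert tr.strain.max() > tr.strain.min()
        assert tr.time.size == 100

    def test_maxima_and_minima_drift_upward(self, mat, geom):
        tr = simulate_cyclic(mat, geom, default_drift(), 0, 5000, 1.0, 0.5, 30, 50)
        per = 50
        maxs = [tr.strain[i * per : (i + 1) * per].max() for i in range(30)]
        mins = [tr.strain[i * per : (i + 1) * per].min() for i in range(30)]
        assert np.all(np.diff(maxs) > 0)
        assert np.all(np.diff(mins[1:]) > 0)  # first off-phase starts from rest

    def test_higher_frequency_stabilizes_earlier(self, mat, geom):
        drift = default_drift()
        duration = 400.0
        settle = {}
        for freq in (1.0, 0.15):
            tr = simulate_cyclic(mat, geom, drift, 0, 5000, freq, 0.5, duration, 30)
            per = int(round(30 / freq))
            ncyc = int(duration * freq)
            means = np.array(
                [tr.strain[i * per : (i + 1) * per].mean() for i in range(ncyc)]
            )
            within = np.abs(means - means[-1]) <= 0.05 * means[-1]
            first = next(i for i in range(ncyc) if within[i:].all())
            settle[freq] = (first + 1) / freq
        assert settle[1.0] < settle[0.15]

    def test_undersampled_rejected(self, mat, geom):
        with pytest.raises(ValueError):
            simulate_cyclic(mat, geom, DriftModel(), 0, 5000, 10.0, 0.5, 1.0, 15.0)

    def test_elastic_cyclic_matches_equilibrium_pointwise(self, mat, geom):
        """Oracle equivalence: zero drift reproduces solve_actuation per sample."""
        tr = simulate_cyclic(mat, geom, DriftModel(), 1000, 3000, 0.5, 0.4, 6, 25)
        hi = solve_actuation(mat, geom, 3000.0).strain_act * 100
        lo = solve_actuation(mat, geom, 1000.0).strain_act * 100
        # half-open segments: 50 samples per 2 s cycle, first 20 at v_high
        idx = np.arange(tr.time.size) % 50
        expected = np.where(idx < 20, hi, lo)
        assert np.allclose(tr.strain, expected, atol=1e-10)
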