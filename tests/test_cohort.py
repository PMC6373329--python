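import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, solve_ivp

import netpet as nx
from netpet.cohort import (
    CohortConfig,
    InputFunctionParams,
    RegionSpec,
    add_noise,
    default_regions,
    feng_input,
    generate_cohort,
    simulate_reference_tac,
    simulate_target_tac,
)
from netpet.framing import TimeActivityCurve


class TestInputFunction:
    def test_vanishes_at_appearance_time(self):
        p = InputFunctionParams()
        t = np.array([0.0, p.t0, p.t0 + 1e-9])
        vals = feng_input(p, t)
        assert vals[0] == 0.0 and vals[1] == 0.0

    def test_default_curve_nonnegative_unimodal(self):
        p = InputFunctionParams()
        t = np.arange(0, 120.0001, 0.01)
        c = feng_input(p, t)
        assert np.all(c >= 0)
        peak = int(np.argmax(c))
        # single early peak: rising before, non-increasing after (to tolerance)
        assert t[peak] < 2.0
        rising = c[: peak + 1]
        assert np.all(np.diff(rising[rising > 0]) > 0)
        assert np.all(np.diff(c[peak:]) <= 1e-9)

    def test_pure_ramp_peaks_at_inverse_rate(self):
        p = InputFunctionParams(a1=1.0, a2=0.0, a3=0.0, lam1=1.0, lam2=0.5, lam3=1e-4, t0=0.0)
        t = np.arange(0, 10.0001, 0.001)
        c = feng_input(p, t)
        assert t[np.argmax(c)] == pytest.approx(1.0, abs=1e-3)

    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError):
            feng_input(InputFunctionParams(), np.array([0.0, 2.0, 1.0]))

    def test_rejects_bad_rate_ordering(self):
        with pytest.raises(ValueError):
            InputFunctionParams(lam1=0.5, lam2=4.0)


class TestReferenceSimulation:
    def test_matches_ode_oracle(self, paper_schedule):
        """Exponential-kernel convolution vs an adaptive ODE solution of
        dC_R/dt = K1' C_p - k2' C_R at all frame mid-times."""
        kin = nx.default_subject_kinetics(k2p=0.0322)
        t = np.arange(0, 120.0001, 0.0025)
        ref = simulate_reference_tac(kin, t)

        def cp(x):
            return feng_input(kin.input, np.atleast_1d(x))[0]

        sol = solve_ivp(
            lambda x, y: kin.k1p * cp(x) - kin.k2p * y,
            (0, 120),
            [0.0],
            t_eval=paper_schedule.mid_times_min,
            rtol=1e-10,
            atol=1e-13,
            max_step=0.25,
        )
        ours = np.interp(paper_schedule.mid_times_min, t, ref)
        nonzero = sol.y[0] > 1e-9
        rel = np.abs(ours[nonzero] - sol.y[0][nonzero]) / sol.y[0][nonzero]
        assert rel.max() < 1e-4

    def test_linearity_in_k1p(self):
        t = np.arange(0, 120.0001, 0.01)
        base = simulate_reference_tac(nx.default_subject_kinetics(k1p=0.3), t)
        double = simulate_reference_tac(nx.default_subject_kinetics(k1p=0.6), t)
        assert np.allclose(double, 2 * base, rtol=1e-12)

    def test_refuses_coarse_grid(self):
        kin = nx.default_subject_kinetics()
        with pytest.raises(ValueError, match="resolution"):
            simulate_reference_tac(kin, np.arange(0, 121, 0.1))


class TestTargetSimulation:
    def test_zero_binding_unit_delivery_equals_reference(self):
        kin = nx.default_subject_kinetics()
        t = np.arange(0, 120.0001, 0.01)
        ref = simulate_reference_tac(kin, t)
        tgt = simulate_target_tac(RegionSpec("x", 0.0, 1.0), ref, kin.k2p, t)
        assert np.allclose(tgt, ref, rtol=1e-12)

    def test_matches_two_ode_oracle(self, paper_schedule):
        """SRTM2-generated target equals the equivalent one-tissue solution."""
        kin = nx.default_subject_kinetics(k2p=0.0322)
        region = RegionSpec("lc", 0.19, 0.9)
        t = np.arange(0, 120.0001, 0.0025)
        ref = simulate_reference_tac(kin, t)
        tgt = simulate_target_tac(region, ref, kin.k2p, t)
        k2a = region.r1 * kin.k2p / (1 + region.true_bp)

        def cp(x):
            return feng_input(kin.input, np.atleast_1d(x))[0]

        sol = solve_ivp(
            lambda x, y: region.r1 * kin.k1p * cp(x) - k2a * y,
            (0, 120),
            [0.0],
            t_eval=paper_schedule.mid_times_min,
            rtol=1e-10,
            atol=1e-13,
            max_step=0.25,
        )
        ours = np.interp(paper_schedule.mid_times_min, t, tgt)
        nonzero = sol.y[0] > 1e-9
        rel = np.abs(ours[nonzero] - sol.y[0][nonzero]) / sol.y[0][nonzero]
        assert rel.max() < 1e-4

    def test_late_ratio_approaches_true_bp_from_below(self):
        """On a 600-min extension the tissue/reference ratio minus one climbs
        to the true BPND of 0.24 (transient-equilibrium mechanism)."""
        kin = nx.default_subject_kinetics(k2p=0.0322)
        t = np.arange(0, 600.0001, 0.01)
        ref = simulate_reference_tac(kin, t)
        tgt = simulate_target_tac(RegionSpec("thal", 0.24, 1.0), ref, kin.k2p, t)
        ratio = tgt[1:] / ref[1:] - 1.0
        at = lambda x: float(np.interp(x, t[1:], ratio))
        assert at(90) < at(180) < at(300) < at(600)
        assert at(90) < 0.24
        assert at(600) == pytest.approx(0.24, abs=0.005)

    def test_rejects_nonpositive_k2a(self):
        t = np.arange(0, 10.001, 0.01)
        with pytest.raises(ValueError):
            simulate_target_tac(RegionSpec("x", 0.1), np.ones_like(t), -0.01, t)

    def test_forward_model_operational_consistency(self):
        """Noiseless curves satisfy the multilinear operational equation
        C_T(T) = R1 k2' ∫C_R - k2a ∫C_T + R1 C_R(T) to 1e-6 relative."""
        kin = nx.default_subject_kinetics(k2p=0.0322)
        region = RegionSpec("put", 0.25, 1.0)
        t = np.arange(0, 120.0001, 0.0025)
        ref = simulate_reference_tac(kin, t)
        tgt = simulate_target_tac(region, ref, kin.k2p, t)
        k2a = region.r1 * kin.k2p / (1 + region.true_bp)
        icr = np.concatenate([[0.0], cumulative_trapezoid(ref, t)])
        ict = np.concatenate([[0.0], cumulative_trapezoid(tgt, t)])
        pred = region.r1 * kin.k2p * icr - k2a * ict + region.r1 * ref
        scale = np.max(np.abs(tgt))
        assert np.max(np.abs(pred - tgt)) / scale < 1e-6


class TestNoise:
    def test_zero_alpha_is_identity(self, paper_schedule):
        tac = TimeActivityCurve("a", paper_schedule, np.linspace(1, 5, 33))
        assert add_noise(tac, 0.0, 1) is tac

    def test_noise_sd_follows_stated_law(self):
        """Monte-Carlo: SD of a 5-min frame of value 1.0 at alpha = 0.5 is
        0.5 * sqrt(1/5) within 2%."""
        sched = nx.build_schedule("10000x300")
        tac = TimeActivityCurve("a", sched, np.ones(10000))
        noisy = add_noise(tac, 0.5, np.random.default_rng(42))
        sd = np.std(noisy.values - tac.values, ddof=1)
        assert sd == pytest.approx(0.5 * np.sqrt(1 / 5), rel=0.02)

    def test_same_seed_bit_identical(self, paper_schedule):
        tac = TimeActivityCurve("a", paper_schedule, np.linspace(1, 5, 33))
        a = add_noise(tac, 0.3, 7)
        b = add_noise(tac, 0.3, 7)
        assert np.array_equal(a.values, b.values)

    def test_negative_alpha_rejected(self, paper_schedule):
        tac = TimeActivityCurve("a", paper_schedule, np.ones(33))
        with pytest.raises(ValueError):
            add_noise(tac, -0.1, 1)


class TestCohortGeneration:
    def test_registry_counts(self):
        regions = default_regions()
        targets = [r for r in regions if not r.is_reference]
        atlas_targets = [r for r in targets if r.name != "locus_coeruleus"]
        assert len(atlas_targets) == 17
        assert len(targets) == 18
        assert sum(r.is_reference for r in regions) == 1

    def test_degenerate_config_gives_identical_subjects(self):
        cfg = CohortConfig(n_subjects=3, noise_alpha=0.0, k2p_sd=0.0, bp_jitter_sd=0.0, seed=5)
        cohort = generate_cohort(cfg)
        a, b, c = cohort.subjects
        for name in a.tacs:
            assert np.array_equal(a.tacs[name].values, b.tacs[name].values)
            assert np.array_equal(a.tacs[name].values, c.tacs[name].values)

    def test_seeded_determinism(self):
        cfg = CohortConfig(n_subjects=2, seed=1)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        for s1, s2 in zip(c1, c2):
            assert s1.kinetics.k2p == s2.kinetics.k2p
            for name in s1.tacs:
                assert np.array_equal(s1.tacs[name].values, s2.tacs[name].values)

    def test_adding_subject_preserves_earlier_subjects(self):
        small = generate_cohort(CohortConfig(n_subjects=2, seed=3))
        big = generate_cohort(CohortConfig(n_subjects=3, seed=3))
        for s1, s2 in zip(small, big):
            assert s1.kinetics.k2p == s2.kinetics.k2p
            for name in s1.tacs:
                assert np.array_equal(s1.tacs[name].values, s2.tacs[name].values)

    def test_sampled_k2p_within_three_se_of_population_mean(self):
        cohort = generate_cohort(CohortConfig(seed=11))
        k2ps = np.array([s.kinetics.k2p for s in cohort])
        se = 0.0105 / np.sqrt(10)
        assert abs(k2ps.mean() - 0.0322) < 3 * se

    def test_input_scaling_propagates_linearly(self):
        """Scaling the plasma input scales every TAC by the same factor."""
        base_in = nx.InputFunctionParams()
        scaled_in = nx.InputFunctionParams(a1=base_in.a1 * 3, a2=base_in.a2 * 3, a3=base_in.a3 * 3)
        kin_a = nx.default_subject_kinetics(input_params=base_in)
        kin_b = nx.default_subject_kinetics(input_params=scaled_in)
        sched = nx.build_schedule(nx.PAPER_SCHEDULE_SPEC)
        sa = nx.simulate_subject(kin_a, sched)
        sb = nx.simulate_subject(kin_b, sched)
        for name in sa.tacs:
            assert np.allclose(sb.tacs[name].values, 3 * sa.tacs[name].values, rtol=1e-10)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=0)
        with pytest.raises(ValueError):
            CohortConfig(noise_alpha=-1)
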