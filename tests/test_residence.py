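"""Survival correlation function, brief-return rule, bi-exponential fits
and residence times."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porewater.model import BiExpFit, SurvivalCurve
from porewater.residence import (
    average_survival,
    domain_statistics,
    fit_biexponential,
    residence_time,
    shell_occupancy,
    survival_correlation,
    survival_from_occupancy,
)
from porewater.synthetic import GeneratorConfig, gen_shell_telegraph, occupancy_to_trajectory

from oracles import survival_enumeration, tau_res_quadrature

DT = 0.25  # ps, the standard frame cadence


def _curve_from(occ, t0=2.0, mode="multi"):
    return survival_from_occupancy(np.asarray(occ, bool), DT, t0=t0, mode=mode)


class TestSurvivalFunction:
    def test_permanent_resident_stays_at_one(self):
        occ = np.ones((40, 1), bool)
        curve = _curve_from(occ)
        np.testing.assert_allclose(curve.values, 1.0)

    def test_N0_equals_mean_occupancy_exactly(self):
        rng = np.random.default_rng(0)
        occ = rng.uniform(size=(60, 7)) < 0.4
        curve = _curve_from(occ)
        assert curve.N0 == pytest.approx(occ.sum(axis=1).mean(), abs=1e-12)

    def test_survivor_counts_non_increasing(self):
        """The number of surviving (origin, water) pairs can only fall with
        lag; the per-origin-normalised curve inherits this in the
        well-sampled region."""
        rng = np.random.default_rng(1)
        occ = rng.uniform(size=(80, 5)) < 0.6
        curve = _curve_from(occ)
        n_frames = occ.shape[0]
        counts = curve.values * (n_frames - np.round(curve.lags / DT))
        assert np.all(np.diff(counts) <= 1e-9)

    @pytest.mark.parametrize(
        "gap_frames,survives",
        [(7, True), (8, True), (9, False)],  # t0 = 2 ps = 8 frames at 0.25 ps
    )
    def test_brief_return_boundary(self, gap_frames, survives):
        """An excursion of 1.75 or 2.0 ps is tolerated; 2.25 ps terminates
        the residency at the exit."""
        n = 40
        col = np.ones(n, bool)
        col[10 : 10 + gap_frames] = False
        curve = _curve_from(col[:, None])
        # survival across the whole excursion from origin 0 to the last frame
        full_span = curve.values[-1]
        if survives:
            assert full_span == pytest.approx(1.0)
        else:
            assert full_span == 0.0
        oracle = survival_enumeration(col[:, None], DT, t0=2.0)
        np.testing.assert_allclose(curve.values, oracle, atol=1e-12)

    def test_trailing_excursion_terminates(self):
        """A water that leaves and never returns is not 'briefly away'."""
        col = np.ones(30, bool)
        col[27:] = False  # 3-frame excursion truncated by trajectory end
        curve = _curve_from(col[:, None])
        assert curve.values[-1] == 0.0

    def test_t0_zero_equals_strict_continuous_residence(self):
        rng = np.random.default_rng(3)
        occ = rng.uniform(size=(50, 6)) < 0.7
        strict = _curve_from(occ, t0=0.0)
        oracle = survival_enumeration(occ, DT, t0=0.0)
        np.testing.assert_allclose(strict.values, oracle, atol=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(10, 45),
        st.integers(1, 5),
        st.sampled_from(["multi", "single"]),
        st.sampled_from([0.0, 0.5, 1.0, 2.0]),
    )
    def test_matches_enumeration_oracle(self, seed, n_frames, n_w, mode, t0):
        """Optimized survival equals brute-force interval enumeration for
        random occupancy patterns, under both excursion-counting rules."""
        rng = np.random.default_rng(seed)
        occ = rng.uniform(size=(n_frames, n_w)) < rng.uniform(0.2, 0.9)
        curve = survival_from_occupancy(occ, DT, t0=t0, mode=mode)
        oracle = survival_enumeration(occ, DT, t0=t0, mode=mode)
        np.testing.assert_allclose(curve.values, oracle, atol=1e-12)

    def test_telegraph_decay_matches_analytic(self):
        """Markov shell kinetics with exit rate k decay as N0·e^(−kt)."""
        cfg = GeneratorConfig(seed=11, dt=DT, n_frames=2000, n_waters=150, k_exit=0.05, k_entry=0.01)
        occ, atoms, traj = gen_shell_telegraph(cfg)
        curve = survival_from_occupancy(occ, DT, t0=0.0, max_lag=60.0)
        t = curve.lags
        ref = curve.N0 * np.exp(-0.05 * t)
        sel = t <= 40.0
        np.testing.assert_allclose(curve.values[sel], ref[sel], rtol=0.12)

    def test_pipeline_recovers_occupancy_from_coordinates(self):
        """Distance-based shell detection on the generated trajectory
        reproduces the generator's exact occupancy series."""
        cfg = GeneratorConfig(seed=5, dt=DT, n_frames=100, n_waters=20, k_exit=0.1, k_entry=0.05)
        occ, atoms, traj = gen_shell_telegraph(cfg)
        from porewater.io import classify_groups

        (group,) = classify_groups(atoms, traj.coords[0].astype(float))
        got = shell_occupancy(atoms, traj, group, shell_radius=3.5)
        np.testing.assert_array_equal(got, occ)

    def test_max_lag_truncation_warns(self):
        occ = np.ones((20, 1), bool)
        with pytest.warns(UserWarning):
            survival_from_occupancy(occ, DT, max_lag=100.0)


class TestBiExponentialFit:
    def _noiseless_curve(self, n_f=1.0, tau_f=2.0, n_s=0.5, tau_s=20.0, t_max=100.0):
        t = np.arange(0, t_max + DT / 2, DT)
        y = n_f * np.exp(-t / tau_f) + n_s * np.exp(-t / tau_s)
        return SurvivalCurve(lags=t, values=y, group_id="test")

    def test_recovers_exact_parameters(self):
        curve = self._noiseless_curve()
        fit = fit_biexponential(curve, floor=0.0)
        assert fit.converged
        assert fit.n_f == pytest.approx(1.0, rel=0.01)
        assert fit.tau_f == pytest.approx(2.0, rel=0.01)
        assert fit.n_s == pytest.approx(0.5, rel=0.01)
        assert fit.tau_s == pytest.approx(20.0, rel=0.01)

    def test_dehydrated_group_rejected(self):
        curve = self._noiseless_curve(n_f=0.05, n_s=0.05)
        assert curve.N0 < 0.2
        assert fit_biexponential(curve) is None

    def test_single_exponential_limit(self):
        t = np.arange(0, 80 + DT / 2, DT)
        y = 1.5 * np.exp(-t / 8.0)
        fit = fit_biexponential(SurvivalCurve(lags=t, values=y), floor=0.0)
        assert fit.tau_res == pytest.approx(8.0, rel=0.02)

    def test_floor_truncates_fast_decays(self):
        curve = self._noiseless_curve(n_f=1.0, tau_f=1.0, n_s=0.0, tau_s=1.0, t_max=100.0)
        fit = fit_biexponential(curve)
        assert fit.fit_window[1] < 10.0  # data below 0.1 excluded

    def test_tau_ordering_enforced(self):
        curve = self._noiseless_curve(n_f=0.5, tau_f=30.0, n_s=1.0, tau_s=3.0)
        fit = fit_biexponential(curve, floor=0.0)
        assert fit.tau_f <= fit.tau_s

    def test_too_short_curve_raises(self):
        c = SurvivalCurve(lags=np.array([0.0]), values=np.array([1.0]))
        with pytest.raises(ValueError):
            fit_biexponential(c)


class TestResidenceTime:
    def test_single_component_limit(self):
        fit = BiExpFit(1.2, 7.0, 0.0, 7.0, (0, 1), 0.0, True)
        assert residence_time(fit) == pytest.approx(7.0)

    def test_worked_example(self):
        fit = BiExpFit(1.0, 2.0, 1.0, 10.0, (0, 1), 0.0, True)
        assert residence_time(fit) == pytest.approx(104.0 / 12.0)

    def test_closed_form_equals_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_f, n_s = rng.uniform(0.05, 3.0, 2)
            tau_f = rng.uniform(0.5, 30.0)
            tau_s = tau_f * rng.uniform(1.0, 20.0)
            fit = BiExpFit(n_f, tau_f, n_s, tau_s, (0, 1), 0.0, True)
            closed = residence_time(fit)
            quad = tau_res_quadrature(n_f, tau_f, n_s, tau_s)
            assert abs(closed - quad) / quad < 1e-9

    def test_zero_amplitudes_undefined(self):
        fit = BiExpFit(0.0, 1.0, 0.0, 2.0, (0, 1), 0.0, True)
        with pytest.raises(ValueError):
            residence_time(fit)


class TestAggregation:
    def test_average_of_identical_curves_is_identity(self):
        c = SurvivalCurve(lags=np.arange(5.0), values=np.exp(-np.arange(5.0)))
        avg = average_survival([c, c, c])
        np.testing.assert_allclose(avg.values, c.values)

    def test_average_of_decay_and_zero(self):
        t = np.arange(5.0)
        c1 = SurvivalCurve(lags=t, values=np.exp(-t))
        c2 = SurvivalCurve(lags=t, values=np.zeros(5))
        avg = average_survival([c1, c2])
        np.testing.assert_allclose(avg.values, 0.5 * np.exp(-t))

    def test_mismatched_grids_rejected(self):
        c1 = SurvivalCurve(lags=np.arange(0, 2, 0.5), values=np.ones(4))
        c2 = SurvivalCurve(lags=np.arange(0, 4, 1.0), values=np.ones(4))
        with pytest.raises(ValueError):
            average_survival([c1, c2])

    def test_domain_statistics_median_and_merge(self):
        samples = [
            ("pore", "polar", 5.0),
            ("filter", "polar", 7.0),
            ("pore", "polar", 9.0),
            ("TRP", "nonpolar", 3.0),
        ]
        stats = {(s.domain, s.polarity): s for s in domain_statistics(samples)}
        merged = stats[("pore+filter", "polar")]
        assert merged.median == pytest.approx(7.0)
        assert sorted(merged.tau_res_samples) == [5.0, 7.0, 9.0]
        assert stats[("TRP", "nonpolar")].median == pytest.approx(3.0)
        unmerged = domain_statistics(samples, merge_pore_filter=False)
        assert {(s.domain, s.polarity) for s in unmerged} == {
            ("pore", "polar"), ("filter", "polar"), ("TRP", "nonpolar")
        }
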