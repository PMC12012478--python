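import numpy as np
import pytest

from otrna.assign import DwellRecord
from otrna.constants import KT_ROOM_PN_NM
from otrna.kinetics import (
    InsufficientDataError,
    compute_kd,
    conformational_rates,
    detect_multiexponential,
    fit_exponential,
    protein_off_rates,
    protein_on_rates,
)


class TestFitExponential:
    def test_rate_is_inverse_mean(self):
        fit = fit_exponential([1.0, 2.0, 3.0, 4.0, 5.0])
        assert fit.rate == pytest.approx(1.0 / 3.0)
        assert fit.n_dwells == 5
        assert fit.ci95[0] < fit.rate < fit.ci95[1]

    def test_dead_time_correction(self):
        # truncated-exponential MLE: k = 1/(mean - t_dead)
        fit = fit_exponential([1.2, 2.2, 3.2, 4.2, 5.2], dead_time=0.2)
        assert fit.rate == pytest.approx(1.0 / 3.0)

    def test_too_few_dwells(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential([1.0, 2.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, -0.5, 2.0, 3.0, 4.0])

    def test_excessive_dead_time_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0.1] * 10, dead_time=0.2)

    def test_ci_coverage(self):
        """Exact Γ CI: empirical 95% coverage in [93%, 97%] over 500 draws."""
        k_true, n = 2.0, 40
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(500):
            t = rng.exponential(1.0 / k_true, size=n)
            fit = fit_exponential(t)
            hits += fit.ci95[0] <= k_true <= fit.ci95[1]
        assert 0.93 <= hits / 500 <= 0.97


class TestDetectMultiexponential:
    def test_single_population_not_split(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(0.5, size=400)
        fit = detect_multiexponential(t)
        assert fit.n_components == 1
        assert fit.rates[0] == pytest.approx(2.0, rel=0.15)

    def test_two_populations_detected(self):
        rng = np.random.default_rng(1)
        t = np.concatenate([
            rng.exponential(1.0 / 0.5, size=300),
            rng.exponential(1.0 / 20.0, size=300),
        ])
        fit = detect_multiexponential(t)
        assert fit.n_components == 2
        assert fit.delta_bic > 6.0
        assert fit.rates[0] == pytest.approx(0.5, rel=0.3)
        assert fit.rates[1] == pytest.approx(20.0, rel=0.3)
        assert sum(fit.weights) == pytest.approx(1.0)

    def test_too_few_dwells(self):
        with pytest.raises(InsufficientDataError):
            detect_multiexponential(np.ones(20))


def _dwell_seq(states_durations):
    t, out = 0.0, []
    for s, dur in states_durations:
        out.append(DwellRecord(state=s, t_start=t, duration=dur,
                               mean_force=10.0))
        t += dur
    return out


class TestConformationalRates:
    def test_counts_over_occupancy(self):
        # 2 transitions 0->1 over 4 s in state 0; 2 transitions 1->0 over 1 s
        dwells = _dwell_seq([(0, 2.0), (1, 0.5), (0, 2.0), (1, 0.5), (0, 1.0)])
        kab, kba = conformational_rates(dwells, 0, 1)
        assert kab.rate == pytest.approx(2.0 / 5.0)
        assert kba.rate == pytest.approx(2.0 / 1.0)
        assert kab.ci95[0] < kab.rate < kab.ci95[1]

    def test_zero_events_one_sided(self):
        dwells = _dwell_seq([(0, 3.0), (2, 1.0), (1, 2.0)])
        kab, _ = conformational_rates(dwells, 0, 1)
        assert kab.rate == 0.0
        assert kab.ci95[0] == 0.0
        assert kab.ci95[1] > 0.0

    def test_phase_filtering(self):
        dwells = _dwell_seq([(0, 1.0), (1, 1.0), (0, 1.0), (1, 1.0)])
        labels = np.array([True, True, False, False])
        kab_bound, _ = conformational_rates(dwells, 0, 1,
                                            phase_labels=labels,
                                            phase_filter="bound")
        assert kab_bound.rate == pytest.approx(1.0)
        kab_unb, _ = conformational_rates(dwells, 0, 1,
                                          phase_labels=labels,
                                          phase_filter="unbound")
        assert kab_unb.rate == pytest.approx(1.0)

    def test_filter_requires_labels(self):
        dwells = _dwell_seq([(0, 1.0), (1, 1.0)])
        with pytest.raises(ValueError):
            conformational_rates(dwells, 0, 1, phase_filter="bound")

    def test_absent_state_rejected(self):
        dwells = _dwell_seq([(0, 1.0), (1, 1.0)])
        with pytest.raises(ValueError):
            conformational_rates(dwells, 0, 3)


def _synthetic_lifetimes(k_ind, k0, dx, forces, n_per_force, seed):
    """Exponential bound lifetimes under k_off(F) = k_ind + k0·e^{FΔx/kT}."""
    rng = np.random.default_rng(seed)
    out = []
    for f in forces:
        k = k_ind + k0 * np.exp(f * dx / KT_ROOM_PN_NM)
        out.append((f, rng.exponential(1.0 / k, size=n_per_force)))
    return out


class TestProteinOffRates:
    def test_recovers_two_contribution_rate(self):
        """Module example: k_ind=0.02, k0=0.005, Δx=3 nm probed at
        8/11/14 pN; the zero-force extrapolate CI covers the truth."""
        k_ind, k0, dx = 0.02, 0.005, 3.0
        data = _synthetic_lifetimes(k_ind, k0, dx, (8.0, 11.0, 14.0),
                                    n_per_force=60, seed=3)
        points, fit = protein_off_rates(data, seed=1)
        assert len(points) == 3
        truth_zero = k_ind + k0
        # the zero-force extrapolate spans e^(8·Δx/kT) ≈ 340× below the
        # probed window, so only the calibrated CI is informative here
        assert fit.ci_zero[0] <= truth_zero <= fit.ci_zero[1]
        # fitted curve matches the truth inside the probed window
        for f in (8.0, 11.0, 14.0):
            k_true = k_ind + k0 * np.exp(f * dx / KT_ROOM_PN_NM)
            assert fit(f) == pytest.approx(k_true, rel=0.35)

    def test_force_independent_pin(self):
        data = _synthetic_lifetimes(0.05, 0.0, 0.0, (8.0, 11.0, 14.0),
                                    n_per_force=60, seed=4)
        _, fit = protein_off_rates(data, force_independent_only=True)
        assert fit.dx == 0.0
        assert fit.k0 == pytest.approx(0.0, abs=1e-12)
        assert fit.k_off_zero == pytest.approx(0.05, rel=0.3)

    def test_flat_data_prefers_small_dx(self):
        data = _synthetic_lifetimes(0.05, 0.0, 0.0, (8.0, 11.0, 14.0),
                                    n_per_force=200, seed=5)
        _, fit = protein_off_rates(data, seed=2)
        # the Bell contribution at 14 pN must stay small vs the constant
        assert fit.k0 * np.exp(14.0 * fit.dx / KT_ROOM_PN_NM) < 0.5 * fit.k_independent \
            or fit.dx < 1.0

    def test_two_points_refuse_fit(self):
        data = _synthetic_lifetimes(0.02, 0.005, 3.0, (8.0, 11.0),
                                    n_per_force=30, seed=6)
        with pytest.warns(UserWarning, match="fewer than 3"):
            points, fit = protein_off_rates(data)
        assert fit is None
        assert len(points) == 2

    def test_dead_time_shifts_rate(self):
        taus = [(10.0, [0.6, 0.8, 1.0, 1.2, 1.4])]
        pts_raw, _ = protein_off_rates(taus)
        pts_dt, _ = protein_off_rates(taus, dead_time=0.2)
        assert pts_dt[0][1] > pts_raw[0][1]
        assert pts_dt[0][1] == pytest.approx(1.0 / 0.8)


class TestProteinOnRates:
    def test_occupancy_correction_doubles_rate(self):
        waits = [(10.0, np.full(40, 2.0))]
        _, fit_full = protein_on_rates(waits, 1.0, 50e-9)
        _, fit_half = protein_on_rates(waits, 0.5, 50e-9)
        assert fit_half.k_bind == pytest.approx(2 * fit_full.k_bind)
        assert fit_full.k_on == pytest.approx(0.5 / 50e-9)

    def test_ci_and_slope(self):
        rng = np.random.default_rng(7)
        waits = [(f, rng.exponential(2.0, size=50)) for f in (6.0, 8.0, 10.0)]
        _, fit = protein_on_rates(waits, 1.0, 50e-9)
        assert fit.ci_k_on[0] < fit.k_on < fit.ci_k_on[1]
        # force-independent truth: slope CI includes zero
        assert fit.slope_ci[0] <= 0.0 <= fit.slope_ci[1]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            protein_on_rates([(10.0, [1.0])], 0.0, 50e-9)
        with pytest.raises(ValueError):
            protein_on_rates([(10.0, [1.0])], 0.5, 0.0)
        with pytest.raises(InsufficientDataError):
            protein_on_rates([], 0.5, 50e-9)


class TestComputeKd:
    def test_five_nanomolar_example(self):
        """k_off(0)=0.05 s⁻¹ against k_on=1e7 M⁻¹s⁻¹ gives K_D = 5 nM."""
        from otrna.kinetics import OffRateFit, OnRateFit

        off = OffRateFit(k_independent=0.02, k0=0.03, dx=2.0,
                         k_off_zero=0.05, ci_zero=(0.03, 0.08))
        on = OnRateFit(k_bind=0.5, k_on=1e7, ci_k_on=(0.8e7, 1.25e7))
        kd, ci = compute_kd(off, on)
        assert kd == pytest.approx(5e-9)
        assert ci[0] == pytest.approx(0.03 / 1.25e7)
        assert ci[1] == pytest.approx(0.08 / 0.8e7)
        assert ci[0] < kd < ci[1]

    def test_nan_ci_propagates(self):
        from otrna.kinetics import OffRateFit, OnRateFit

        off = OffRateFit(0.02, 0.03, 2.0, 0.05, ci_zero=(np.nan, np.nan))
        on = OnRateFit(0.5, 1e7, (0.8e7, 1.25e7))
        kd, ci = compute_kd(off, on)
        assert kd == pytest.approx(5e-9)
        assert np.isnan(ci[0]) and np.isnan(ci[1])
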