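import numpy as np
import pytest

from otrna.assign import (
    DwellRecord,
    StateAssignment,
    extract_dwells,
    fit_hmm,
    segment_bound_phases,
)
from otrna.simulate import Trace, simulate_passive_trace


def _trace_and_truth(scheme, model, d, noise_sd, seed=7, duration=30.0):
    tr = simulate_passive_trace(
        scheme, model, d, duration, noise_sd=noise_sd, seed=seed,
        sampling_hz=6000.0, downsample=3,
    )
    return tr


class TestFitHmm:
    def test_accuracy_at_6_sigma_separation(self, two_state_scheme, model,
                                            two_state_separation):
        """Levels 6 sd apart: ≥99% of samples assigned correctly."""
        levels = two_state_scheme.state_forces(model, two_state_separation)
        gap = abs(levels[0] - levels[1])
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=gap / 6.0)
        asn = fit_hmm(tr, n_states=2, seed=0)
        acc = np.mean(asn.path == tr.truth_state)
        assert acc >= 0.99

    def test_noiseless_trace_exact(self, two_state_scheme, model,
                                   two_state_separation):
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.0)
        asn = fit_hmm(tr, n_states=2, seed=0)
        assert np.array_equal(asn.path, tr.truth_state)

    def test_loglik_monotone_nondecreasing(self, two_state_scheme, model,
                                           two_state_separation):
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.35)
        asn = fit_hmm(tr, n_states=2, seed=0)
        hist = np.asarray(asn.loglik_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) >= -1e-6 * np.abs(hist[:-1]))

    def test_levels_sorted_descending(self, two_state_scheme, model,
                                      two_state_separation):
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.35)
        asn = fit_hmm(tr, n_states=2, seed=0)
        assert asn.means[0] > asn.means[1]
        levels = two_state_scheme.state_forces(model, two_state_separation)
        assert asn.means[0] == pytest.approx(max(levels), abs=0.05)
        assert asn.means[1] == pytest.approx(min(levels), abs=0.05)

    def test_constant_offset_invariance(self, two_state_scheme, model,
                                        two_state_separation):
        """Shifting the whole force signal shifts means, not the path."""
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.35)
        shifted = Trace(
            force=tr.force + 3.0,
            sampling_hz=tr.sampling_hz,
            downsample_factor=tr.downsample_factor,
            mode=tr.mode,
            trap_separation=tr.trap_separation,
            model=tr.model,
        )
        a0 = fit_hmm(tr, n_states=2, seed=0)
        a1 = fit_hmm(shifted, n_states=2, seed=0)
        assert np.array_equal(a0.path, a1.path)
        assert np.allclose(a1.means, a0.means + 3.0, atol=1e-6)

    def test_single_state_shortcut(self, two_state_scheme, model,
                                   two_state_separation):
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.35)
        asn = fit_hmm(tr, n_states=1)
        assert asn.n_states == 1
        assert np.all(asn.path == 0)
        assert asn.means[0] == pytest.approx(float(np.mean(tr.force)))

    def test_bic_selects_two_states(self, two_state_scheme, model,
                                    two_state_separation):
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.35, duration=6.0)
        asn = fit_hmm(tr, n_states=None, seed=0, n_iter=100)
        assert asn.n_states == 2

    def test_init_levels_length_checked(self, two_state_scheme, model,
                                        two_state_separation):
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.35, duration=5.0)
        with pytest.raises(ValueError):
            fit_hmm(tr, n_states=2, init_levels=[10.0])

    def test_rejects_pulling_trace(self, model):
        tr = Trace(
            force=np.linspace(2, 15, 100),
            sampling_hz=1000.0,
            downsample_factor=1,
            mode="constant_velocity",
            trap_separation=np.linspace(600, 700, 100),
            model=model,
        )
        with pytest.raises(ValueError):
            fit_hmm(tr, n_states=2)


def _synthetic_assignment(path):
    path = np.asarray(path, dtype=int)
    n = int(path.max()) + 1
    return StateAssignment(
        path=path,
        means=np.arange(n, dtype=float)[::-1],
        sds=np.full(n, 0.3),
        transition_counts=np.zeros((n, n), dtype=int),
        log_likelihood=0.0,
        n_states=n,
    )


def _flat_trace(n, dt=0.001):
    return Trace(
        force=np.full(n, 10.0),
        sampling_hz=1.0 / dt,
        downsample_factor=1,
        mode="passive",
        trap_separation=650.0,
    )


class TestExtractDwells:
    def test_durations_tile_trace(self, two_state_scheme, model,
                                  two_state_separation):
        tr = _trace_and_truth(two_state_scheme, model, two_state_separation,
                              noise_sd=0.35)
        asn = fit_hmm(tr, n_states=2, seed=0)
        dwells = extract_dwells(asn, tr)
        assert sum(d.duration for d in dwells) == pytest.approx(tr.duration)
        # run-length encoding: consecutive dwells alternate states
        for a, b in zip(dwells, dwells[1:]):
            assert a.state != b.state
            assert b.t_start == pytest.approx(a.t_start + a.duration)

    def test_blip_merged_into_longer_neighbor(self):
        path = [0] * 50 + [1] * 2 + [0] * 30 + [1] * 40
        asn = _synthetic_assignment(path)
        tr = _flat_trace(len(path))
        dwells = extract_dwells(asn, tr, min_dwell_samples=5)
        assert [d.state for d in dwells] == [0, 1]
        assert dwells[0].duration == pytest.approx(0.082)
        assert dwells[1].duration == pytest.approx(0.040)

    def test_no_dwell_below_threshold_remains(self, rng):
        path = rng.integers(0, 2, size=400)
        asn = _synthetic_assignment(path)
        tr = _flat_trace(len(path))
        dwells = extract_dwells(asn, tr, min_dwell_samples=4)
        durations = np.array([d.duration for d in dwells])
        assert np.all(durations >= 4 * tr.dt - 1e-12)
        assert sum(durations) == pytest.approx(tr.duration)

    def test_mean_force_per_dwell(self):
        force = np.concatenate([np.full(10, 12.0), np.full(10, 9.0)])
        tr = Trace(force=force, sampling_hz=1000.0, downsample_factor=1,
                   mode="passive", trap_separation=650.0)
        asn = _synthetic_assignment([0] * 10 + [1] * 10)
        dwells = extract_dwells(asn, tr)
        assert dwells[0].mean_force == pytest.approx(12.0)
        assert dwells[1].mean_force == pytest.approx(9.0)


def _dw(state, t0, dur):
    return DwellRecord(state=state, t_start=t0, duration=dur, mean_force=10.0)


def _chain(states_durations):
    t, out = 0.0, []
    for s, dur in states_durations:
        out.append(_dw(s, t, dur))
        t += dur
    return out


class TestSegmentBoundPhases:
    def test_long_stabilized_dwell_marks_phase(self):
        dwells = _chain([(1, 0.1), (0, 0.05), (1, 2.0), (0, 0.05), (1, 0.1),
                         (2, 0.5), (1, 0.05)])
        seg = segment_bound_phases(dwells, state=1, min_duration=1.0)
        # the maximal run of states ≤1 containing the 2.0 s dwell spans
        # indices 0–4; the state-2 dwell terminates it
        assert list(seg.labels) == [True] * 5 + [False, False]
        assert seg.bound_intervals == [(0.0, pytest.approx(2.3))]

    def test_no_qualifying_dwell_all_unbound(self):
        dwells = _chain([(1, 0.2), (0, 0.1), (1, 0.3)])
        seg = segment_bound_phases(dwells, state=1, min_duration=1.0)
        assert not seg.labels.any()
        assert seg.bound_intervals == []

    def test_missing_state_rejected(self):
        dwells = _chain([(0, 1.0), (1, 1.0)])
        with pytest.raises(ValueError):
            segment_bound_phases(dwells, state=2, min_duration=0.5)

    def test_force_band_filters(self):
        dwells = [
            DwellRecord(0, 0.0, 2.0, mean_force=12.0),
            DwellRecord(1, 2.0, 0.5, mean_force=9.0),
            DwellRecord(0, 2.5, 2.0, mean_force=8.0),
        ]
        seg = segment_bound_phases(dwells, state=0, min_duration=1.0,
                                   force_band=(11.0, 13.0),
                                   allowed_states=[0])
        assert list(seg.labels) == [True, False, False]

    def test_merge_gap_bridges_brief_unbound(self):
        dwells = _chain([
            (0, 2.0),          # bound phase 1
            (2, 0.1),          # brief excursion (shorter than merge_gap)
            (0, 2.0),          # bound phase 2
            (2, 5.0),          # long unbound
            (0, 2.0),
        ])
        apart = segment_bound_phases(dwells, state=0, min_duration=1.0,
                                     allowed_states=[0])
        assert len(apart.bound_intervals) == 3
        merged = segment_bound_phases(dwells, state=0, min_duration=1.0,
                                      allowed_states=[0], merge_gap=0.3)
        assert len(merged.bound_intervals) == 2
        assert merged.bound_intervals[0] == (0.0, pytest.approx(4.1))

    def test_recovers_true_bound_fraction(self):
        """End-to-end: ≥90% of truth bound time recovered on a synthetic
        binding trace."""
        from otrna.presets import load_preset

        scheme, model, defaults = load_preset("ADE_extROQ_binding")
        from otrna.simulate import simulate_binding_trace

        tr = simulate_binding_trace(
            scheme, model, defaults["trap_separation_nm"], 120.0,
            noise_sd=0.35, seed=5, sampling_hz=15000.0, downsample=3,
        )
        levels = scheme.state_forces(model, defaults["trap_separation_nm"])
        asn = fit_hmm(tr, n_states=len(levels), init_levels=levels, seed=0)
        dwells = extract_dwells(asn, tr, min_dwell_samples=3)
        stab = scheme.index(scheme.binding.competent_state)
        seg = segment_bound_phases(dwells, state=stab, min_duration=0.25,
                                   merge_gap=0.3)
        t_bound_true = float(np.sum(tr.truth_bound)) * tr.dt
        t_bound_est = sum(b - a for a, b in seg.bound_intervals)
        assert t_bound_true > 5.0  # the fixture must actually bind
        assert t_bound_est >= 0.9 * t_bound_true
        assert t_bound_est <= 1.2 * t_bound_true
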