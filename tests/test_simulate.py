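import numpy as np
import pytest

from otrna.elasticity import ElasticModel, trap_separation_for_force
from otrna.simulate import (
    FoldingState,
    KineticScheme,
    Transition,
    simulate_binding_trace,
    simulate_melting_curve,
    simulate_passive_trace,
    simulate_pulling_cycles,
    simulate_state_path,
    simulate_titration,
)
from otrna.presets import available_presets, load_preset


def symmetric_two_state():
    return KineticScheme(
        states=[FoldingState("A", 0, 0.0), FoldingState("B", 10, 0.0)],
        transitions=[
            Transition("A", "B", 10.0, 0.0, 1),
            Transition("B", "A", 10.0, 0.0, 1),
        ],
        name="sym",
    )


class TestStatePath:
    def test_exponential_mean_dwell(self):
        path = simulate_state_path(
            symmetric_two_state(), {"A": 10.0, "B": 9.0}, duration=1000.0, seed=4
        )
        dwells = np.array([d for _, _, d in path[:-1]])  # last is truncated
        sem = dwells.std() / np.sqrt(len(dwells))
        assert dwells.mean() == pytest.approx(0.1, abs=3 * sem)

    def test_single_state_full_duration(self):
        scheme = KineticScheme(
            states=[FoldingState("A", 0)], transitions=[], name="one"
        )
        with pytest.warns(UserWarning, match="absorbing"):
            path = simulate_state_path(scheme, {"A": 10.0}, 5.0, seed=0)
        assert len(path) == 1
        assert path[0][2] == pytest.approx(5.0)

    def test_seed_determinism(self):
        a = simulate_state_path(symmetric_two_state(), {"A": 10, "B": 9}, 10, seed=3)
        b = simulate_state_path(symmetric_two_state(), {"A": 10, "B": 9}, 10, seed=3)
        c = simulate_state_path(symmetric_two_state(), {"A": 10, "B": 9}, 10, seed=4)
        assert a == b
        assert a != c

    def test_duration_validation(self):
        with pytest.raises(ValueError):
            simulate_state_path(symmetric_two_state(), {"A": 1, "B": 1}, 0.0)


class TestPassiveTrace:
    def test_zero_noise_single_level(self, model):
        scheme = KineticScheme(
            states=[FoldingState("F", 0)], transitions=[], name="flat"
        )
        # a lone state with the maximal released-nt count carries no
        # closed stem, so the separation is computed with 0 stems
        d = trap_separation_for_force(10.0, model, 0, 0)
        with pytest.warns(UserWarning, match="absorbing"):
            tr = simulate_passive_trace(scheme, model, d, 0.01, noise_sd=0.0,
                                        seed=0)
        assert np.allclose(tr.force, tr.force[0])
        assert tr.force[0] == pytest.approx(10.0, abs=1e-6)

    def test_level_ordering_matches_folding(self, three_state_scheme, model):
        d = trap_separation_for_force(11.5, model, 0, 1)
        forces = three_state_scheme.state_forces(model, d)
        # more folded (fewer unfolded nt) -> strictly higher force
        assert forces[0] > forces[1] > forces[2]

    def test_occupancies_match_boltzmann(self, three_state_scheme, model):
        """Dwell-time ratios converge to the Boltzmann weights of the total
        (folding + mechanical) state energies — the energetics oracle."""
        d = trap_separation_for_force(11.0, model, 0, 1)
        tr = simulate_passive_trace(
            three_state_scheme, model, d, 150.0, noise_sd=0.0, seed=8,
            sampling_hz=2000, downsample=1,
        )
        _, g = three_state_scheme.total_energies(model, d)
        occ = np.bincount(tr.truth_state, minlength=3) / len(tr)
        # compare pairwise log-ratios within ~3 sigma (dwell-count based)
        path = tr.truth_state
        n_visits = np.array(
            [max(1, (np.diff((path == s).astype(int)) == 1).sum()) for s in range(3)]
        )
        for j in (1, 2):
            expected = -(g[j] - g[0]) / model.kT
            observed = np.log(occ[j] / occ[0])
            sigma = np.sqrt(1 / n_visits[j] + 1 / n_visits[0])
            assert observed == pytest.approx(expected, abs=3 * sigma)

    def test_close_levels_warn(self, model):
        scheme = KineticScheme(
            states=[FoldingState("A", 0), FoldingState("B", 1)],
            transitions=[Transition("A", "B", 5.0, 0.0, 1),
                         Transition("B", "A", 5.0, 0.0, 1)],
            name="close",
        )
        d = trap_separation_for_force(10.0, model, 0, 1)
        with pytest.warns(UserWarning, match="indistinguishable"):
            simulate_passive_trace(scheme, model, d, 0.01, noise_sd=2.0, seed=0)

    def test_seed_reproducibility(self, two_state_scheme, model,
                                  two_state_separation):
        kw = dict(sampling_hz=2000, downsample=1)
        a = simulate_passive_trace(two_state_scheme, model, two_state_separation,
                                   1.0, seed=5, **kw)
        b = simulate_passive_trace(two_state_scheme, model, two_state_separation,
                                   1.0, seed=5, **kw)
        c = simulate_passive_trace(two_state_scheme, model, two_state_separation,
                                   1.0, seed=6, **kw)
        assert np.array_equal(a.force, b.force)
        assert not np.array_equal(a.force, c.force)


class TestBindingTrace:
    @pytest.fixture(scope="class")
    @staticmethod
    def binding_setup():
        scheme, model, defaults = load_preset("ADE_extROQ_binding")
        return scheme, model, defaults["trap_separation_nm"]

    def test_zero_concentration_never_binds(self, binding_setup):
        scheme, model, d = binding_setup
        from dataclasses import replace

        zero = KineticScheme(
            states=scheme.states, transitions=scheme.transitions,
            binding=replace(scheme.binding, protein_conc=0.0),
            detailed_balance=True, name="zero",
        )
        tr = simulate_binding_trace(zero, model, d, 20.0, seed=1,
                                    sampling_hz=1000, downsample=1)
        assert tr.truth_bound.sum() == 0

    def test_bound_lifetime_matches_off_rate(self, binding_setup):
        """Mean bound-phase lifetime ≈ 1/k_off at the bound state's force."""
        scheme, model, d = binding_setup
        from dataclasses import replace

        # block conformational exits while bound so phases end by unbinding
        b = replace(scheme.binding, protein_conc=1e-7,
                    blocked_while_bound=(("I3", "U"), ("I3", "I1")),
                    slowed_while_bound=())
        fast = KineticScheme(states=scheme.states, transitions=scheme.transitions,
                             binding=b, detailed_balance=True, name="fastbind")
        tr = simulate_binding_trace(fast, model, d, 600.0, seed=2,
                                    sampling_hz=1000, downsample=1)
        tb = tr.truth_bound
        edges = np.flatnonzero(np.diff(tb))
        starts = np.concatenate([[0], edges + 1])
        ends = np.concatenate([edges + 1, [len(tb)]])
        durs = np.array([(e - s) / 1000 for s, e in zip(starts, ends) if tb[s]])
        f_i3 = fast.state_forces(model, d)[fast.index("I3")]
        k_off = fast.binding.k_off(f_i3, model.kT)
        sem = durs.std() / np.sqrt(len(durs))
        assert durs.mean() == pytest.approx(1.0 / k_off, abs=3.5 * sem)

    def test_binding_flux_balance(self, binding_setup):
        """Binding frequency ≈ k_on·c × time spent unbound in the competent
        state (conformational selection: no binding from other states)."""
        scheme, model, d = binding_setup
        tr = simulate_binding_trace(scheme, model, d, 2000.0, seed=3,
                                    sampling_hz=1000, downsample=1)
        tb, ts = tr.truth_bound, tr.truth_state
        n_bind = int(((tb[1:] == 1) & (tb[:-1] == 0)).sum())
        comp = scheme.index(scheme.binding.competent_state)
        t_comp_unbound = float(((tb == 0) & (ts == comp)).sum()) / 1000.0
        expected = scheme.binding.k_on * scheme.binding.protein_conc * t_comp_unbound
        assert n_bind == pytest.approx(expected, abs=3.5 * np.sqrt(expected))


class TestPullingCycles:
    def test_stable_fold_no_rips(self, model):
        scheme = KineticScheme(
            states=[FoldingState("F", 0), FoldingState("U", 15, 50.0)],
            transitions=[Transition("F", "U", 1e-12, 0.1, 1)],
            detailed_balance=True, name="stable",
        )
        (tr,) = simulate_pulling_cycles(scheme, model, 400.0, (2, 15), 1,
                                        seed=0, noise_sd=0.0,
                                        sampling_hz=5000, downsample=1)
        assert np.all(tr.truth_state == 0)
        # smooth WLC-shaped stretch: force strictly increases with separation
        n2 = tr.meta["turnaround_index"]
        assert np.all(np.diff(tr.force[:n2]) > -1e-9)

    def test_two_state_gain_recoverable(self, model, two_state_scheme):
        from otrna.pulling import contour_gain_from_cycles

        traces = simulate_pulling_cycles(
            two_state_scheme, model, 150.0, (2.0, 18.0), 3, seed=21,
            noise_sd=0.35, sampling_hz=20000, downsample=1,
        )
        mean, sd, _ = contour_gain_from_cycles(traces, model)
        assert mean == pytest.approx(7.75, abs=0.3)

    def test_faster_pulling_higher_unfolding_force(self, model,
                                                   two_state_scheme):
        from otrna.pulling import unfolding_force

        def mean_rip(velocity, seed):
            traces = simulate_pulling_cycles(
                two_state_scheme, model, velocity, (2.0, 18.0), 8, seed=seed,
                noise_sd=0.0, sampling_hz=10000, downsample=1,
            )
            return np.mean([unfolding_force(t) for t in traces])

        assert mean_rip(2000.0, 3) >= mean_rip(50.0, 3) - 0.2


class TestBulkGenerators:
    def test_titration_midpoint_and_zero(self):
        table = simulate_titration(100.0, 1.0, [0.0, 100.0], noise_sd=0.0)
        assert table["fraction_bound"].iloc[0] == 0.0
        assert table["fraction_bound"].iloc[1] == pytest.approx(0.5)

    def test_titration_hill2_value(self):
        table = simulate_titration(100.0, 2.0, [200.0], noise_sd=0.0)
        assert table["fraction_bound"].iloc[0] == pytest.approx(0.8)

    def test_titration_noise_clipped(self):
        table = simulate_titration(100.0, 1.0, np.linspace(0, 1e4, 50),
                                   noise_sd=0.5, seed=1)
        assert table["fraction_bound"].between(0, 1).all()

    def test_melting_monotone_and_single_sigmoid(self):
        table = simulate_melting_curve(65.0, 76.7, amplitudes=(0.3, 0.0),
                                       noise_sd=0.0)
        s = table["signal"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        # amplitude-zero second transition: single inflection near tm1
        d2 = np.gradient(np.gradient(s))
        t = table["temperature_C"].to_numpy()
        assert abs(t[np.argmin(np.gradient(s))] - 65.0) <= 1.0

    def test_melting_inflections_at_tms(self):
        table = simulate_melting_curve(60.0, 80.0, amplitudes=(1.0, 1.0),
                                       widths=(2.0, 2.0), noise_sd=0.0)
        t = table["temperature_C"].to_numpy()
        ds = np.gradient(table["signal"].to_numpy(), t)
        lower = ds[(t > 50) & (t < 70)]
        upper = ds[(t > 70) & (t < 90)]
        assert abs(t[(t > 50) & (t < 70)][np.argmin(lower)] - 60.0) <= 1.0
        assert abs(t[(t > 70) & (t < 90)][np.argmin(upper)] - 80.0) <= 1.0


class TestPresets:
    def test_all_presets_load(self):
        for name in available_presets():
            scheme, model, defaults = load_preset(name)
            assert scheme.n_states >= 2
            assert "trap_separation_nm" in defaults

    def test_binding_preset_has_channel(self):
        scheme, _, _ = load_preset("ADE_extROQ_binding")
        assert scheme.binding is not None
        assert scheme.binding.competent_state == "I3"

    def test_six_state_misfold_topology(self):
        scheme, _, _ = load_preset("ADE_six_state")
        # M is connected only through I2 in the transition list
        partners = {t.target for t in scheme.transitions if t.source == "M"}
        partners |= {t.source for t in scheme.transitions if t.target == "M"}
        assert partners == {"I2"}
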