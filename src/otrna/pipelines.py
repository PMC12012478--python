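"""End-to-end parameter-recovery experiments.

Each function builds a synthetic condition with a known ground truth,
runs the full analysis pipeline (simulate → assign → segment → estimate)
and returns both the recovered quantity and the truth it should match.
These are the reference workflows of the package: the same code paths a
user would run on measured traces, exercised on generator output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assign import extract_dwells, fit_hmm, segment_bound_phases
from .constants import KT_ROOM_KCAL_MOL
from .elasticity import ElasticModel, passive_force, trap_separation_for_force
from .energetics import delta_delta_G, mechanical_energy, population_dG, zero_force_dG
from .kinetics import compute_kd, protein_off_rates, protein_on_rates
from .presets import load_preset
from .pulling import contour_gain_from_cycles
from .bulk import hill_fit, melt_derivative, melt_fit
from .simulate import (
    BindingModel,
    FoldingState,
    KineticScheme,
    Transition,
    simulate_binding_trace,
    simulate_melting_curve,
    simulate_pulling_cycles,
    simulate_titration,
)

__all__ = [
    "cde_contour_gain_experiment",
    "BindingCondition",
    "KD_CONDITIONS",
    "make_binding_scheme",
    "kd_recovery_experiment",
    "ddg_recovery_experiment",
    "titration_recovery_experiment",
    "melting_recovery_experiment",
    "zero_force_dg_experiment",
]


# ---------------------------------------------------------------------------
# Contour-length gain from pulling cycles
# ---------------------------------------------------------------------------

def cde_contour_gain_experiment(
    seed: int,
    n_cycles: int = 20,
    sampling_hz: float = 26041.0,
) -> dict:
    """Stretch–relax cycles of the two-state hairpin; WLC branch fits.

    Ground truth: 15 nt released on unfolding with the default elasticity
    constants, i.e. an expected gain of 15·0.65 − 2.0 = 7.75 nm.
    """
    scheme, model, defaults = load_preset("CDE_two_state")
    traces = simulate_pulling_cycles(
        scheme,
        model,
        velocity=defaults.get("velocity_nm_per_s", 100.0),
        f_range=tuple(defaults.get("f_range_pN", (2.0, 18.0))),
        n_cycles=n_cycles,
        seed=seed,
        noise_sd=defaults.get("noise_sd_pN", 0.35),
        sampling_hz=sampling_hz,
        downsample=1,
    )
    mean_gain, sd_gain, fits = contour_gain_from_cycles(traces, model)
    return {
        "mean_gain_nm": mean_gain,
        "sd_gain_nm": sd_gain,
        "n_cycles": n_cycles,
        "truth_gain_nm": 15 * model.ss_contour_per_nt - model.folded_offset,
        "fits": fits,
    }


# ---------------------------------------------------------------------------
# Zero-force K_D recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingCondition:
    """One protein/RNA condition for K_D recovery.

    ``kd_truth_nM`` fixes k_off(0) = K_D·k_on, split 40% force-independent
    and 60% Bell with transition distance ``dx_off_nm``.  Forces are the
    competent-state levels of the three passive-mode steps.
    """

    name: str
    kd_truth_nM: float
    delta_n_nt: int  # nt released between competent state and unfolded
    forces_pN: tuple
    dx_off_nm: float
    k_on: float = 1.0e7  # M^-1 s^-1
    protein_conc: float = 50e-9  # M
    n_events_per_force: int = 12
    hop_rate_per_s: float = 35.0  # competent-state unfolding rate at mid force

    @property
    def k_off_zero(self) -> float:
        return self.kd_truth_nM * 1e-9 * self.k_on

    @property
    def k_off_independent(self) -> float:
        return 0.4 * self.k_off_zero

    @property
    def k_off0(self) -> float:
        return 0.6 * self.k_off_zero


#: The four recovered dissociation constants (protein/element pairs).
KD_CONDITIONS = {
    "coreROQ_ADE": BindingCondition(
        "coreROQ_ADE", kd_truth_nM=4.8, delta_n_nt=21,
        forces_pN=(4.0, 6.0, 8.0), dx_off_nm=2.0,
    ),
    "extROQ_ADE": BindingCondition(
        "extROQ_ADE", kd_truth_nM=1.67, delta_n_nt=21,
        forces_pN=(5.0, 7.0, 9.0), dx_off_nm=2.0,
    ),
    "coreROQ_CDE": BindingCondition(
        "coreROQ_CDE", kd_truth_nM=33.0, delta_n_nt=15,
        forces_pN=(6.0, 8.0, 10.0), dx_off_nm=1.0,
    ),
    "extROQ_CDE": BindingCondition(
        "extROQ_CDE", kd_truth_nM=2.0, delta_n_nt=15,
        forces_pN=(5.0, 7.0, 9.0), dx_off_nm=2.0,
    ),
}


def make_binding_scheme(
    cond: BindingCondition, model: ElasticModel, trap_separation: float
) -> KineticScheme:
    """Two-state folded/unfolded scheme + binding channel for a condition.

    The unfolded-state energy is calibrated so both conformations are
    populated at the given trap separation (equal total energies); the
    binding-competent folded state blocks unfolding while bound.
    """
    f_fold = passive_force(trap_separation, model, 0, 1)
    f_unf = passive_force(trap_separation, model, cond.delta_n_nt, 0)
    g_fold = mechanical_energy(f_fold, model, 0)
    g_unf = mechanical_energy(f_unf, model, cond.delta_n_nt)
    dg0_u = (g_fold - g_unf) / 6.948  # equal totals at this separation
    dx_u = 1.5
    k0_u = cond.hop_rate_per_s / np.exp(f_fold * dx_u / model.kT)
    return KineticScheme(
        states=[
            FoldingState("C", 0, 0.0),
            FoldingState("U", cond.delta_n_nt, dg0_u),
        ],
        transitions=[Transition("C", "U", k0_u, dx_u, 1)],
        binding=BindingModel(
            k_on=cond.k_on,
            protein_conc=cond.protein_conc,
            k_off0=cond.k_off0,
            dx_off=cond.dx_off_nm,
            k_off_force_independent=cond.k_off_independent,
            competent_state="C",
            blocked_while_bound=(("C", "U"),),
        ),
        detailed_balance=True,
        name=f"binding_{cond.name}",
    )


def kd_recovery_experiment(
    cond: BindingCondition,
    seed: int,
    sampling_hz: float = 5000.0,
    min_duration: float = 0.25,
) -> dict:
    """Full binding pipeline for one condition: simulate → assign →
    segment → off/on rates → K_D at zero force."""
    import zlib

    model = ElasticModel()
    # decorrelate conditions: each gets its own independent stream
    rng = np.random.default_rng([seed, zlib.crc32(cond.name.encode())])
    off_points_input = []
    on_points_input = []
    occupancies = []
    n_bound_total = 0
    for f_target in cond.forces_pN:
        d = trap_separation_for_force(f_target, model, 0, 1)
        scheme = make_binding_scheme(cond, model, d)
        # duration sized for ~n_events binding/unbinding events
        k_off_mid = cond.k_off_independent + cond.k_off0 * np.exp(
            f_target * cond.dx_off_nm / model.kT
        )
        occ_guess = 0.5
        wait = 1.0 / (cond.k_on * cond.protein_conc * occ_guess)
        duration = cond.n_events_per_force * (wait + 1.0 / k_off_mid) * 1.35
        trace = simulate_binding_trace(
            scheme, model, d, duration,
            seed=int(rng.integers(2**31 - 1)),
            sampling_hz=sampling_hz, downsample=1,
        )
        assignment = fit_hmm(
            trace, 2, init_levels=trace.meta["levels_pN"],
            seed=int(rng.integers(2**31 - 1)),
        )
        dwells = extract_dwells(assignment, trace, min_dwell_samples=3)
        seg = segment_bound_phases(
            dwells, state=0, min_duration=min_duration, merge_gap=0.3
        )
        bound_taus, bound_forces = [], []
        for t0, t1 in seg.bound_intervals:
            bound_taus.append(t1 - t0)
        if not bound_taus:
            continue
        n_bound_total += len(bound_taus)
        forces_bound = [
            d_.mean_force for d_, lab in zip(dwells, seg.labels) if lab
        ]
        f_bound = float(np.mean(forces_bound))
        off_points_input.append((f_bound, bound_taus))
        # unbound waiting times between bound phases; bound phases shorter
        # than the detection threshold are missed, so the observed binding
        # rate is low by the detection probability exp(-min_duration*k_off)
        # (exponential bound lifetimes) — correct with this level's k_off.
        k_off_level = 1.0 / max(np.mean(bound_taus) - min_duration, 1e-6)
        p_detect = float(np.exp(-min_duration * k_off_level))
        waits = []
        for (b0, b1), (c0, c1) in zip(
            seg.bound_intervals[:-1], seg.bound_intervals[1:]
        ):
            waits.append((c0 - b1) * p_detect)
        # competent-state occupancy during unbound phases
        t_comp = sum(
            d_.duration
            for d_, lab in zip(dwells, seg.labels)
            if not lab and d_.state == 0
        )
        t_unb = sum(d_.duration for d_, lab in zip(dwells, seg.labels) if not lab)
        occ = t_comp / t_unb if t_unb > 0 else np.nan
        occupancies.append(occ)
        if waits:
            on_points_input.append((f_bound, waits, occ))
    off_points, off_fit = protein_off_rates(
        off_points_input, kT=model.kT, dead_time=min_duration,
        dx_grid=np.linspace(0.0, 6.0, 25),
    )
    # per-force-level occupancy correction (k_bind = k_obs/occ, i.e. the
    # effective waiting clock only runs while competent), then pool
    on_points, on_fit = protein_on_rates(
        [(f, [w * occ for w in waits]) for (f, waits, occ) in on_points_input],
        competent_state_occupancy=1.0,  # correction already applied per point
        protein_conc=cond.protein_conc,
    )
    if off_fit is None:
        raise RuntimeError("off-rate fit unavailable (too few force points)")
    kd, kd_ci = compute_kd(off_fit, on_fit)
    return {
        "kd_nM": kd * 1e9,
        "kd_ci_nM": (kd_ci[0] * 1e9, kd_ci[1] * 1e9),
        "kd_truth_nM": cond.kd_truth_nM,
        "k_off_zero": off_fit.k_off_zero,
        "k_on": on_fit.k_on,
        "off_points": off_points,
        "on_points": on_points,
        "n_bound_events": n_bound_total,
        "occupancies": occupancies,
    }


# ---------------------------------------------------------------------------
# ΔΔG population-shift recovery
# ---------------------------------------------------------------------------

def ddg_recovery_experiment(
    ddg_truth_kcal: float,
    seed: int,
    protein: str = "extROQ",
    duration: float = 700.0,
    sampling_hz: float = 500.0,
    min_duration: float = 1.0,
) -> dict:
    """Population-shift ΔΔG of the more-folded state under protein binding.

    The bound phase slows refolding I3→I1 by exp(ΔΔG/kT) while leaving
    unfolding untouched, so the recovered population-ratio shift should
    equal ``ddg_truth_kcal``.  Pipeline: binding trace → HMM → dwells →
    phase segmentation → bootstrap ΔΔG.
    """
    scheme, model, defaults = load_preset("ADE_extROQ_binding")
    factor = float(np.exp(ddg_truth_kcal / KT_ROOM_KCAL_MOL))
    binding = BindingModel(
        k_on=scheme.binding.k_on,
        protein_conc=scheme.binding.protein_conc if protein == "extROQ" else 2e-8,
        k_off0=scheme.binding.k_off0,
        dx_off=scheme.binding.dx_off,
        k_off_force_independent=scheme.binding.k_off_force_independent,
        competent_state=scheme.binding.competent_state,
        blocked_while_bound=scheme.binding.blocked_while_bound,
        slowed_while_bound=((("I3", "I1"), factor),),
    )
    scheme = KineticScheme(
        states=scheme.states, transitions=scheme.transitions, binding=binding,
        detailed_balance=True, name=f"ddG_{protein}",
    )
    d = defaults["trap_separation_nm"]
    trace = simulate_binding_trace(
        scheme, model, d, duration, seed=seed,
        sampling_hz=sampling_hz, downsample=1,
    )
    assignment = fit_hmm(trace, 3, init_levels=trace.meta["levels_pN"], seed=seed)
    dwells = extract_dwells(assignment, trace, min_dwell_samples=3)
    i3 = 1  # levels are force-ordered: I1 (0), I3 (1), U (2)
    seg = segment_bound_phases(dwells, state=i3, min_duration=min_duration)
    bound = [d_ for d_, lab in zip(dwells, seg.labels) if lab]
    unbound = [d_ for d_, lab in zip(dwells, seg.labels) if not lab]
    ddg, ci = delta_delta_G(
        bound, unbound, state_hi=0, state_lo=i3, kT=model.kT,
        n_bootstrap=1000, seed=seed,
    )
    return {
        "ddg_kcal": ddg,
        "ddg_ci_kcal": ci,
        "ddg_truth_kcal": ddg_truth_kcal,
        "n_bound_dwells": len(bound),
        "n_unbound_dwells": len(unbound),
    }


# ---------------------------------------------------------------------------
# Bulk-assay recoveries
# ---------------------------------------------------------------------------

#: printed gel-shift concentration series, nM
EMSA_CONCENTRATIONS_NM = (0, 100, 200, 400, 700, 1000, 2000, 3000, 5000, 20000)


def titration_recovery_experiment(
    seed: int,
    kd_truth_nM: float = 307.0,
    noise_sd: float = 0.03,
    n_replicates: int = 3,
) -> dict:
    """Hill-fit K_D from noisy titrations at the printed EMSA series.

    Triplicates are fit individually and summarized as mean ± SD, the
    same convention as the bench analysis this emulates.
    """
    rng = np.random.default_rng(seed)
    kds = []
    for _ in range(n_replicates):
        table = simulate_titration(
            kd_truth_nM, 1.0, EMSA_CONCENTRATIONS_NM, noise_sd=noise_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        fit = hill_fit(table["conc_nM"], table["fraction_bound"])
        kds.append(fit.kd)
    return {
        "kd_mean_nM": float(np.mean(kds)),
        "kd_sd_nM": float(np.std(kds, ddof=1)),
        "kd_replicates_nM": kds,
        "kd_truth_nM": kd_truth_nM,
    }


def melting_recovery_experiment(
    seed: int,
    tm1_truth: float = 65.0,
    tm2_truth: float = 76.7,
    noise_sd: float = 0.02,
) -> dict:
    """Upper melting temperature via derivative-initialized double-Boltzmann.

    Simulates a two-transition curve on the 5–95 °C grid at 1 °C steps
    with 2% of the total amplitude as Gaussian noise.
    """
    table = simulate_melting_curve(
        tm1_truth, tm2_truth, amplitudes=(0.35, 1.0), widths=(2.5, 2.5),
        temps=np.arange(5.0, 96.0, 1.0), noise_sd=noise_sd, seed=seed,
    )
    deriv, extrema = melt_derivative(table["temperature_C"], table["signal"])
    fit = melt_fit(table["temperature_C"], table["signal"])
    return {
        "tm1_C": fit.tm1,
        "tm2_C": fit.tm2,
        "tm2_truth_C": tm2_truth,
        "derivative_extrema_C": extrema,
        "single_transition": fit.single_transition,
    }


# ---------------------------------------------------------------------------
# Zero-force free-energy recovery
# ---------------------------------------------------------------------------

def zero_force_dg_experiment(
    seed: int,
    trap_separations: Optional[list] = None,
    duration: float = 60.0,
    sampling_hz: float = 5000.0,
) -> dict:
    """Recover injected zero-force ΔG₀ values of the six-state network.

    Runs the passive-mode pipeline at one or several trap separations;
    the mechanical-energy correction must return the same injected ΔG₀
    regardless of the separation.  Returns per-pair recovered values
    (relative to the fully folded state) and the injected truth.
    """
    from .simulate import simulate_passive_trace

    scheme, model, defaults = load_preset("ADE_six_state")
    if trap_separations is None:
        trap_separations = [defaults["trap_separation_nm"]]
    rng = np.random.default_rng(seed)
    results = []
    for d in trap_separations:
        trace = simulate_passive_trace(
            scheme, model, d, duration,
            seed=int(rng.integers(2**31 - 1)),
            sampling_hz=sampling_hz, downsample=1,
        )
        assignment = fit_hmm(
            trace, scheme.n_states, init_levels=trace.meta["levels_pN"],
            seed=int(rng.integers(2**31 - 1)),
        )
        dwells = extract_dwells(assignment, trace, min_dwell_samples=3)
        forces, _ = scheme.total_energies(model, d)
        order = np.argsort(-forces)  # HMM state 0 = highest force
        recovered = {}
        for hmm_j in range(1, scheme.n_states):
            i_sch, j_sch = order[0], order[hmm_j]
            dg_f = population_dG(dwells, 0, hmm_j, kT=model.kT)
            dg0 = zero_force_dG(
                dg_f, d, model,
                scheme.states[i_sch].n_unfolded_nt,
                scheme.states[j_sch].n_unfolded_nt,
                assignment.means[0], assignment.means[hmm_j],
                n_closed_i=scheme.n_closed(i_sch),
                n_closed_j=scheme.n_closed(j_sch),
            )
            truth = scheme.states[j_sch].dG0 - scheme.states[i_sch].dG0
            recovered[scheme.states[j_sch].name] = (dg0, truth)
        results.append({"trap_separation_nm": d, "pairs": recovered})
    return {"results": results}
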