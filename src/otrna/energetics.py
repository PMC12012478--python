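"""State free energies from passive-mode populations.

At fixed trap separation the occupancy times of two states give their
total free-energy difference by Boltzmann inversion.  Removing the
mechanical energy stored in the stretched construct — released ssRNA,
dsDNA handles, and the trapped beads — extrapolates the difference to
zero force.  Comparing populations between protein-bound and unbound
phases of the same trace yields the binding-induced stability shift ΔΔG.

Energies are reported in kcal/mol (1 kcal/mol = 6.948 pN·nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import pn_nm_to_kcal
from .elasticity import ElasticModel, passive_force, stretch_free_energy

__all__ = [
    "EnergyResult",
    "population_dG",
    "mechanical_energy",
    "zero_force_dG",
    "delta_delta_G",
]


@dataclass
class EnergyResult:
    """Pairwise free-energy differences, at force and extrapolated to zero."""

    pairs: list = field(default_factory=list)
    # entries: (state_i, state_j, dG_at_force, dG_zero_force, ci)
    reference_state: int = 0
    kT_used: float = 4.114


def _occupancy_times(dwells: Sequence, states: Sequence[int]) -> dict:
    t = {s: 0.0 for s in states}
    n = {s: 0 for s in states}
    for d in dwells:
        if d.state in t:
            t[d.state] += d.duration
            n[d.state] += 1
    return t, n


def population_dG(
    dwells: Sequence,
    state_i: int,
    state_j: int,
    kT: float = 4.114,
) -> float:
    """ΔG(i→j) = −kT·ln(T_j/T_i) from total occupancy times, kcal/mol.

    Occupancy times (not dwell counts) define populations, which is
    robust to missed fast events.  A state with zero occupancy yields an
    infinite ΔG (flagged by a warning, not an exception).
    """
    t, _ = _occupancy_times(dwells, (state_i, state_j))
    if t[state_i] <= 0 or t[state_j] <= 0:
        warnings.warn("zero occupancy: free-energy difference is infinite")
        return np.inf if t[state_j] <= 0 else -np.inf
    return pn_nm_to_kcal(-kT * np.log(t[state_j] / t[state_i]))


def mechanical_energy(
    force: float,
    model: ElasticModel,
    n_unfolded_nt: int,
) -> float:
    """Energy stored in released ssRNA + handles + traps at force F, pN·nm."""
    e = stretch_free_energy(
        force,
        model.handle_contour,
        model.handle_persistence,
        model.kT,
        model.handle_stretch_modulus,
    )
    if n_unfolded_nt > 0:
        e += stretch_free_energy(
            force,
            n_unfolded_nt * model.ss_contour_per_nt,
            model.ss_persistence,
            model.kT,
        )
    return float(e + force * force / (2.0 * model.trap_stiffness))


def zero_force_dG(
    dG_at_force: float,
    trap_separation: float,
    model: ElasticModel,
    n_nt_i: int,
    n_nt_j: int,
    F_i: float,
    F_j: float,
    n_closed_i: int = 1,
    n_closed_j: int = 1,
) -> float:
    """Extrapolate a population ΔG to zero force, kcal/mol.

    ΔG₀ = ΔG_at_force − [G_mech(j) − G_mech(i)] with
    G_mech(s) = stretch energy of the released ssRNA and the handles at
    the state's force plus the trap energy F²/(2k).  Positive ΔG₀ means
    the more unfolded state j is higher in free energy.  A warning is
    raised when the supplied per-state forces disagree with the dumbbell
    force balance by more than 1 pN.
    """
    for n_nt, f_obs, n_closed in ((n_nt_i, F_i, n_closed_i), (n_nt_j, F_j, n_closed_j)):
        try:
            f_pred = passive_force(trap_separation, model, n_nt, n_closed)
            if abs(f_pred - f_obs) > 1.0:
                warnings.warn(
                    f"state force {f_obs:.2f} pN deviates from the force-balance "
                    f"prediction {f_pred:.2f} pN by more than 1 pN"
                )
        except Exception:
            pass
    g_i = mechanical_energy(F_i, model, n_nt_i)
    g_j = mechanical_energy(F_j, model, n_nt_j)
    return dG_at_force - pn_nm_to_kcal(g_j - g_i)


def delta_delta_G(
    dwells_bound: Sequence,
    dwells_unbound: Sequence,
    state_hi: int,
    state_lo: int,
    kT: float = 4.114,
    n_bootstrap: int = 1000,
    seed: Optional[int] = None,
    force_shift_warn: float = 0.5,
) -> tuple[float, tuple[float, float]]:
    """Protein-induced stability shift of the more-folded state, kcal/mol.

    ΔΔG = kT·ln[(T_hi/T_lo)_unbound / (T_hi/T_lo)_bound]; positive values
    mean the protein destabilizes the more-folded ``state_hi`` relative to
    ``state_lo``.  The CI is a seeded bootstrap over dwells (percentile,
    95%).  Both phases must contain both states; populations are compared
    at the same trap separation, and a warning is raised when the mean
    forces of the two phases differ by more than ``force_shift_warn`` pN
    (a force shift between phases biases the comparison).
    """
    for name, dw in (("bound", dwells_bound), ("unbound", dwells_unbound)):
        t, _ = _occupancy_times(dw, (state_hi, state_lo))
        if t[state_hi] <= 0 or t[state_lo] <= 0:
            missing = state_hi if t[state_hi] <= 0 else state_lo
            raise ValueError(f"state {missing} absent from the {name} phase")

    def mean_force(dw):
        tot = sum(d.duration for d in dw)
        return sum(d.mean_force * d.duration for d in dw) / tot

    if abs(mean_force(dwells_bound) - mean_force(dwells_unbound)) > force_shift_warn:
        warnings.warn(
            "mean force differs between bound and unbound phases by more than "
            f"{force_shift_warn} pN; the population comparison may be biased"
        )

    def log_ratio(dw) -> float:
        t, _ = _occupancy_times(dw, (state_hi, state_lo))
        return np.log(t[state_hi] / t[state_lo])

    point = pn_nm_to_kcal(kT * (log_ratio(dwells_unbound) - log_ratio(dwells_bound)))

    rng = np.random.default_rng(seed)
    boot = []
    b_arr = list(dwells_bound)
    u_arr = list(dwells_unbound)
    for _ in range(n_bootstrap):
        bs = [b_arr[i] for i in rng.integers(0, len(b_arr), len(b_arr))]
        us = [u_arr[i] for i in rng.integers(0, len(u_arr), len(u_arr))]
        tb, _ = _occupancy_times(bs, (state_hi, state_lo))
        tu, _ = _occupancy_times(us, (state_hi, state_lo))
        if min(tb.values()) <= 0 or min(tu.values()) <= 0:
            continue
        boot.append(
            pn_nm_to_kcal(
                kT
                * (
                    np.log(tu[state_hi] / tu[state_lo])
                    - np.log(tb[state_hi] / tb[state_lo])
                )
            )
        )
    if boot:
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    else:
        ci = (np.nan, np.nan)
    return float(point), ci
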