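"""Synthetic single-molecule data generator.

Emulates every input the analysis pipeline consumes: passive-mode and
constant-velocity force traces produced by a continuous-time Markov scheme
of folding states with Bell-type force-dependent rates embedded in the
dumbbell mechanics, protein bound/unbound phases under conformational
selection, Hill-shaped binding titrations, and double-sigmoid melting
curves.

The generator is the ground truth for every parameter-recovery test:
traces carry per-sample truth labels (state index, bound flag) alongside
the noisy force signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DOWNSAMPLE_FACTOR,
    RAW_SAMPLING_HZ,
    kcal_to_pn_nm,
)
from .elasticity import (
    ElasticModel,
    passive_force,
    stretch_free_energy,
    construct_extension,
)

__all__ = [
    "FoldingState",
    "Transition",
    "BindingModel",
    "KineticScheme",
    "Trace",
    "simulate_state_path",
    "simulate_passive_trace",
    "simulate_binding_trace",
    "simulate_pulling_cycles",
    "simulate_titration",
    "simulate_melting_curve",
]


# ---------------------------------------------------------------------------
# Scheme types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldingState:
    """One folding state: name, released nucleotides, folding free energy.

    ``dG0`` is the zero-force folding free energy in kcal/mol relative to
    the fully folded state (positive = less stable at zero force).
    ``n_closed_stems`` defaults to 1 for any partially folded state and 0
    for the fully unfolded one (set explicitly to override, e.g. for
    misfolds without a native stem).
    """

    name: str
    n_unfolded_nt: int
    dG0: float = 0.0
    n_closed_stems: Optional[int] = None


@dataclass(frozen=True)
class Transition:
    """Directed Bell-model transition: k(F) = k0·exp(sign·F·dx/kT)."""

    source: str
    target: str
    k0: float
    dx: float = 0.0
    sign: int = 1

    def rate(self, force: float, kT: float) -> float:
        return self.k0 * float(np.exp(self.sign * force * self.dx / kT))


@dataclass(frozen=True)
class BindingModel:
    """Protein-binding channel under conformational selection.

    Binding occurs exclusively from the competent (folded stem-loop)
    state at rate k_on·c; unbinding follows
    k_off(F) = k_off_force_independent + k_off0·exp(F·dx_off/kT).
    While bound, the listed conformational transitions are blocked
    (both directions) or slowed by the given factors.
    """

    k_on: float  # M^-1 s^-1
    protein_conc: float  # M
    k_off0: float  # s^-1
    dx_off: float  # nm
    k_off_force_independent: float = 0.0  # s^-1
    competent_state: str = ""
    blocked_while_bound: tuple = ()
    slowed_while_bound: tuple = ()  # ((state_a, state_b), factor) pairs

    def k_off(self, force: float, kT: float) -> float:
        return self.k_off_force_independent + self.k_off0 * float(
            np.exp(force * self.dx_off / kT)
        )


@dataclass
class KineticScheme:
    """Folding states plus force-dependent transitions.

    With ``detailed_balance=True`` transitions are listed in the unfolding
    direction only; the reverse (refolding) rate is derived at run time
    from detailed balance against the total state energy at the given trap
    separation, which guarantees Boltzmann occupancies by construction.
    """

    states: list
    transitions: list
    binding: Optional[BindingModel] = None
    detailed_balance: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("state names must be unique")
        if min(s.n_unfolded_nt for s in self.states) != 0:
            raise ValueError("the fully folded state must have n_unfolded_nt = 0")
        for tr in self.transitions:
            if tr.k0 < 0:
                raise ValueError("rates must be non-negative")
            if tr.source not in names or tr.target not in names:
                raise ValueError(f"unknown state in transition {tr}")
        if self.binding is not None and self.binding.competent_state not in names:
            raise ValueError("binding competent_state not among states")

    # -- helpers --------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, name: str) -> int:
        for i, s in enumerate(self.states):
            if s.name == name:
                return i
        raise KeyError(name)

    def n_closed(self, i: int) -> int:
        s = self.states[i]
        if s.n_closed_stems is not None:
            return s.n_closed_stems
        n_max = max(st.n_unfolded_nt for st in self.states)
        return 0 if s.n_unfolded_nt == n_max else 1

    def state_forces(self, model: ElasticModel, trap_separation: float) -> np.ndarray:
        return np.array(
            [
                passive_force(
                    trap_separation, model, s.n_unfolded_nt, self.n_closed(i)
                )
                for i, s in enumerate(self.states)
            ]
        )

    def mechanical_energy(self, i: int, force: float, model: ElasticModel) -> float:
        """Mechanical energy stored in ssRNA + handles + traps at F, pN·nm."""
        s = self.states[i]
        e = stretch_free_energy(
            force,
            model.handle_contour,
            model.handle_persistence,
            model.kT,
            model.handle_stretch_modulus,
        )
        if s.n_unfolded_nt > 0:
            e += stretch_free_energy(
                force,
                s.n_unfolded_nt * model.ss_contour_per_nt,
                model.ss_persistence,
                model.kT,
            )
        e += force * force / (2.0 * model.trap_stiffness)
        return float(e)

    def total_energies(
        self, model: ElasticModel, trap_separation: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-state forces and total energies (folding + mechanical), pN·nm."""
        forces = self.state_forces(model, trap_separation)
        g = np.array(
            [
                kcal_to_pn_nm(s.dG0) + self.mechanical_energy(i, forces[i], model)
                for i, s in enumerate(self.states)
            ]
        )
        return forces, g

    def rate_matrix(
        self, model: ElasticModel, trap_separation: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Q, forces, energies) at fixed trap separation.

        Q[i, j] is the i→j rate; Bell rates are evaluated at the departing
        state's force.  Under detailed balance the reverse of each listed
        transition is filled in from the energy difference.
        """
        forces, g = self.total_energies(model, trap_separation)
        n = self.n_states
        q = np.zeros((n, n))
        for tr in self.transitions:
            i, j = self.index(tr.source), self.index(tr.target)
            q[i, j] += tr.rate(forces[i], model.kT)
            if self.detailed_balance:
                # reverse rate from π_i k_ij = π_j k_ji, π ∝ exp(−G/kT)
                q[j, i] += q[i, j] * float(np.exp((g[j] - g[i]) / model.kT))
        return q, forces, g

    def boltzmann_weights(
        self, model: ElasticModel, trap_separation: float
    ) -> np.ndarray:
        _, g = self.total_energies(model, trap_separation)
        w = np.exp(-(g - g.min()) / model.kT)
        return w / w.sum()


# ---------------------------------------------------------------------------
# Trace container
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Uniformly sampled force time series with acquisition metadata.

    ``sampling_hz`` is the raw acquisition rate; the stored grid spacing
    is ``downsample_factor / sampling_hz``.  Synthetic traces carry truth
    labels (per-sample state index and bound flag).
    """

    force: np.ndarray
    sampling_hz: float = RAW_SAMPLING_HZ
    downsample_factor: int = DOWNSAMPLE_FACTOR
    mode: str = "passive"
    trap_separation: float | np.ndarray = 0.0
    model: Optional[ElasticModel] = None
    extension: Optional[np.ndarray] = None
    truth_state: Optional[np.ndarray] = None
    truth_bound: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force must be finite")
        for name in ("extension", "truth_state", "truth_bound"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.force):
                raise ValueError(f"{name} length must match force")

    @property
    def dt(self) -> float:
        return self.downsample_factor / self.sampling_hz

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.force)) * self.dt

    @property
    def duration(self) -> float:
        return len(self.force) * self.dt

    def __len__(self) -> int:
        return len(self.force)


# ---------------------------------------------------------------------------
# Continuous-time Markov simulation
# ---------------------------------------------------------------------------

def _gillespie(
    q: np.ndarray,
    duration: float,
    rng: np.random.Generator,
    start_state: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact stochastic simulation; returns (states, t_start, dwell)."""
    exit_rates = q.sum(axis=1)
    states, starts, dwells = [], [], []
    t, s = 0.0, start_state
    while t < duration:
        k_exit = exit_rates[s]
        if k_exit <= 0:
            warnings.warn(f"absorbing state {s}: total exit rate is 0")
            tau = duration - t
        else:
            tau = rng.exponential(1.0 / k_exit)
        tau = min(tau, duration - t)
        states.append(s)
        starts.append(t)
        dwells.append(tau)
        t += tau
        if t >= duration:
            break
        s = int(rng.choice(len(q), p=q[s] / k_exit))
    return np.array(states), np.array(starts), np.array(dwells)


def simulate_state_path(
    scheme: KineticScheme,
    force_of_state: dict,
    duration: float,
    seed: Optional[int] = None,
    kT: float = 4.114,
    start_state: Optional[str] = None,
) -> list[tuple[str, float, float]]:
    """Simulate state hopping at fixed per-state forces (explicit rates).

    Returns a dwell sequence [(state_name, t_start, duration), ...].
    Reproducible for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = scheme.n_states
    q = np.zeros((n, n))
    for tr in scheme.transitions:
        i, j = scheme.index(tr.source), scheme.index(tr.target)
        q[i, j] += tr.rate(force_of_state[tr.source], kT)
    s0 = scheme.index(start_state) if start_state is not None else 0
    states, starts, dwells = _gillespie(q, duration, rng, s0)
    return [
        (scheme.states[s].name, float(t0), float(d))
        for s, t0, d in zip(states, starts, dwells)
    ]


def _sample_path_on_grid(
    states: np.ndarray, starts: np.ndarray, n_samples: int, dt: float
) -> np.ndarray:
    """State index at each grid time (state holding at sample instant)."""
    t_grid = np.arange(n_samples) * dt
    idx = np.searchsorted(starts, t_grid, side="right") - 1
    return states[np.clip(idx, 0, len(states) - 1)]


def _draw_start(weights: np.ndarray, rng: np.random.Generator) -> int:
    return int(rng.choice(len(weights), p=weights))


def simulate_passive_trace(
    scheme: KineticScheme,
    model: ElasticModel,
    trap_separation: float,
    duration: float,
    noise_sd: float = 0.35,
    seed: Optional[int] = None,
    sampling_hz: float = RAW_SAMPLING_HZ,
    downsample: int = DOWNSAMPLE_FACTOR,
) -> Trace:
    """Passive-mode trace: per-state force levels + Gaussian noise.

    Force levels come from the dumbbell force balance, so more-folded
    states sit at strictly higher force.  Noise is additive i.i.d.
    Gaussian on the stored (downsampled) grid.  The initial state is drawn
    from the Boltzmann weights of the total state energies.
    """
    rng = np.random.default_rng(seed)
    q, forces, g = scheme.rate_matrix(model, trap_separation)
    levels = forces
    gaps = np.diff(np.sort(levels))
    if noise_sd > 0 and len(gaps) and gaps.min() < noise_sd / 2:
        warnings.warn(
            "some force levels are closer than noise_sd/2; "
            "states may be indistinguishable"
        )
    w = np.exp(-(g - g.min()) / model.kT)
    start = _draw_start(w / w.sum(), rng)
    states, starts, dwells = _gillespie(q, duration, rng, start)
    dt = downsample / sampling_hz
    n_samples = int(round(duration / dt))
    path = _sample_path_on_grid(states, starts, n_samples, dt)
    force = levels[path]
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=n_samples)
    return Trace(
        force=force,
        sampling_hz=sampling_hz,
        downsample_factor=downsample,
        mode="passive",
        trap_separation=trap_separation,
        model=model,
        truth_state=path.astype(int),
        meta={
            "scheme": scheme.name,
            "levels_pN": levels.tolist(),
            "noise_sd_pN": noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# Protein binding (conformational selection)
# ---------------------------------------------------------------------------

def _binding_rate_matrix(
    scheme: KineticScheme, model: ElasticModel, trap_separation: float
) -> tuple[np.ndarray, np.ndarray]:
    """Generator over the doubled state space (conf × bound flag).

    Index layout: 0..n-1 unbound, n..2n-1 bound.
    """
    b = scheme.binding
    if b is None:
        raise ValueError("scheme has no binding block")
    q, forces, _ = scheme.rate_matrix(model, trap_separation)
    n = scheme.n_states
    blocked = {frozenset(e) for e in b.blocked_while_bound}
    slowed = {tuple(e): fac for e, fac in b.slowed_while_bound}  # directed
    qb = q.copy()
    for i in range(n):
        for j in range(n):
            pair = (scheme.states[i].name, scheme.states[j].name)
            if frozenset(pair) in blocked:
                qb[i, j] = 0.0
            elif pair in slowed:
                qb[i, j] /= slowed[pair]
    big = np.zeros((2 * n, 2 * n))
    big[:n, :n] = q
    big[n:, n:] = qb
    comp = scheme.index(b.competent_state)
    big[comp, n + comp] = b.k_on * b.protein_conc
    for i in range(n):
        big[n + i, i] = b.k_off(forces[i], model.kT)
    return big, forces


def simulate_binding_trace(
    scheme: KineticScheme,
    model: ElasticModel,
    trap_separation: float,
    duration: float,
    noise_sd: float = 0.35,
    seed: Optional[int] = None,
    sampling_hz: float = RAW_SAMPLING_HZ,
    downsample: int = DOWNSAMPLE_FACTOR,
) -> Trace:
    """Passive-mode trace with protein bound/unbound phases.

    Binding only occurs from the competent folded state (conformational
    selection); while bound, the configured transitions are blocked or
    slowed, and unbinding follows the two-contribution off-rate at the
    current state's force.  With protein_conc = 0 the trace is
    statistically identical to :func:`simulate_passive_trace`.
    """
    rng = np.random.default_rng(seed)
    n = scheme.n_states
    big, forces = _binding_rate_matrix(scheme, model, trap_separation)
    _, g = scheme.total_energies(model, trap_separation)
    w = np.exp(-(g - g.min()) / model.kT)
    start = _draw_start(w / w.sum(), rng)  # start unbound
    states, starts, dwells = _gillespie(big, duration, rng, start)
    dt = downsample / sampling_hz
    n_samples = int(round(duration / dt))
    path = _sample_path_on_grid(states, starts, n_samples, dt)
    conf = path % n
    bound = (path >= n).astype(int)
    force = forces[conf]
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=n_samples)
    return Trace(
        force=force,
        sampling_hz=sampling_hz,
        downsample_factor=downsample,
        mode="passive",
        trap_separation=trap_separation,
        model=model,
        truth_state=conf.astype(int),
        truth_bound=bound,
        meta={
            "scheme": scheme.name,
            "levels_pN": forces.tolist(),
            "noise_sd_pN": noise_sd,
            "protein_conc_M": scheme.binding.protein_conc,
        },
    )


# ---------------------------------------------------------------------------
# Constant-velocity pulling
# ---------------------------------------------------------------------------

def _state_force_interpolators(
    scheme: KineticScheme, model: ElasticModel, f_grid: np.ndarray
) -> list[np.ndarray]:
    """Per-state trap-separation grid D_s(F) for fast F(D) interpolation."""
    tables = []
    for i, s in enumerate(scheme.states):
        x = construct_extension(f_grid, model, s.n_unfolded_nt, scheme.n_closed(i))
        tables.append(x + f_grid / model.trap_stiffness)
    return tables


def simulate_pulling_cycles(
    scheme: KineticScheme,
    model: ElasticModel,
    velocity: float,
    f_range: tuple[float, float] = (2.0, 18.0),
    n_cycles: int = 1,
    seed: Optional[int] = None,
    noise_sd: float = 0.35,
    sampling_hz: float = RAW_SAMPLING_HZ,
    downsample: int = DOWNSAMPLE_FACTOR,
) -> list[Trace]:
    """Constant-velocity stretch–relax cycles.

    The trap separation ramps linearly between the separations at which
    the most-folded state reaches f_min and the most-unfolded state
    reaches f_max.  State hopping is integrated along the ramp by
    time-inhomogeneous sampling of the per-edge cumulative hazards
    (rates evaluated on the sample grid).  Each cycle is returned as one
    Trace whose ``trap_separation`` is the per-sample ramp;
    ``meta['turnaround_index']`` marks the stretch→relax switch.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    rng = np.random.default_rng(seed)
    f_min, f_max = f_range
    dt = downsample / sampling_hz
    f_grid = np.linspace(max(0.05, f_min / 4), f_max * 1.5, 1200)
    d_tables = _state_force_interpolators(scheme, model, f_grid)
    n_nt = np.array([s.n_unfolded_nt for s in scheme.states])
    i_folded = int(np.argmin(n_nt))
    i_unfolded = int(np.argmax(n_nt))
    d_lo = float(np.interp(f_min, f_grid, d_tables[i_folded]))
    d_hi = float(np.interp(f_max, f_grid, d_tables[i_unfolded]))
    n_half = max(2, int(round((d_hi - d_lo) / velocity / dt)))
    d_ramp = np.concatenate(
        [
            np.linspace(d_lo, d_hi, n_half, endpoint=False),
            np.linspace(d_hi, d_lo, n_half),
        ]
    )
    n_samp = len(d_ramp)
    # per-state force along the ramp
    f_states = np.stack(
        [np.interp(d_ramp, d_tables[i], f_grid) for i in range(scheme.n_states)]
    )
    # per-state energies along the ramp (needed for detailed balance)
    if scheme.detailed_balance:
        g_rows = []
        for i, s in enumerate(scheme.states):
            fi = f_states[i]
            g = stretch_free_energy(
                fi,
                model.handle_contour,
                model.handle_persistence,
                model.kT,
                model.handle_stretch_modulus,
            )
            if s.n_unfolded_nt > 0:
                g = g + stretch_free_energy(
                    fi,
                    s.n_unfolded_nt * model.ss_contour_per_nt,
                    model.ss_persistence,
                    model.kT,
                )
            g = g + fi * fi / (2.0 * model.trap_stiffness)
            g_rows.append(kcal_to_pn_nm(s.dG0) + g)
        g_states = np.stack(g_rows)
    # directed edge rates along the ramp
    edges: list[tuple[int, int, np.ndarray]] = []
    for tr in scheme.transitions:
        i, j = scheme.index(tr.source), scheme.index(tr.target)
        k_fwd = tr.k0 * np.exp(tr.sign * f_states[i] * tr.dx / model.kT)
        edges.append((i, j, k_fwd))
        if scheme.detailed_balance:
            k_rev_at_j = (
                tr.k0
                * np.exp(tr.sign * f_states[i] * tr.dx / model.kT)
                * np.exp((g_states[j] - g_states[i]) / model.kT)
            )
            edges.append((j, i, k_rev_at_j))
    # cumulative exit hazards per state
    exit_rate = np.zeros((scheme.n_states, n_samp))
    for i, _, k in edges:
        exit_rate[i] += k
    cum_hazard = np.cumsum(exit_rate * dt, axis=1)

    traces: list[Trace] = []
    for _ in range(n_cycles):
        s = i_folded
        idx = 0
        path = np.empty(n_samp, dtype=int)
        while idx < n_samp:
            base = cum_hazard[s, idx - 1] if idx > 0 else 0.0
            target = base - np.log(rng.uniform())
            j = int(np.searchsorted(cum_hazard[s], target))
            j = min(j, n_samp)
            path[idx:j] = s
            if j >= n_samp:
                break
            # choose destination by edge rates at the jump sample
            rates = np.array([k[j] for (i2, _, k) in edges if i2 == s])
            targets = [t for (i2, t, _) in edges if i2 == s]
            if rates.sum() <= 0:
                path[j:] = s
                break
            s = targets[int(rng.choice(len(targets), p=rates / rates.sum()))]
            idx = j
        force = f_states[path, np.arange(n_samp)]
        if noise_sd > 0:
            force = force + rng.normal(0.0, noise_sd, size=n_samp)
        ext = d_ramp - force / model.trap_stiffness
        traces.append(
            Trace(
                force=force,
                sampling_hz=sampling_hz,
                downsample_factor=downsample,
                mode="constant_velocity",
                trap_separation=d_ramp,
                model=model,
                extension=ext,
                truth_state=path,
                meta={
                    "scheme": scheme.name,
                    "velocity_nm_per_s": velocity,
                    "turnaround_index": n_half,
                    "noise_sd_pN": noise_sd,
                },
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Bulk-assay generators
# ---------------------------------------------------------------------------

def simulate_titration(
    kd: float,
    hill_n: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Hill-shaped binding titration: f = cⁿ/(K_Dⁿ + cⁿ) + noise, clipped.

    Concentrations and K_D in nM; noise_sd is an absolute Gaussian sd on
    the bound fraction.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(list(concentrations), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(c > 0, c**hill_n / (kd**hill_n + c**hill_n), 0.0)
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, noise_sd, size=len(c)), 0.0, 1.0)
    return pd.DataFrame({"conc_nM": c, "fraction_bound": f})


def simulate_melting_curve(
    tm1: float,
    tm2: float,
    amplitudes: tuple[float, float] = (0.3, 1.0),
    widths: tuple[float, float] = (2.5, 2.5),
    baseline: float = 0.0,
    temps: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Two-transition melting curve: sum of two descending Boltzmann sigmoids.

    signal(T) = baseline + A1/(1+exp((T−Tm1)/w1)) + A2/(1+exp((T−Tm2)/w2))
    with the inflection points at Tm1 and Tm2.  Temperatures in °C.
    """
    rng = np.random.default_rng(seed)
    if temps is None:
        temps = np.arange(5.0, 96.0, 1.0)
    t = np.asarray(list(temps), dtype=float)
    a1, a2 = amplitudes
    w1, w2 = widths
    s = (
        baseline
        + a1 / (1.0 + np.exp((t - tm1) / w1))
        + a2 / (1.0 + np.exp((t - tm2) / w2))
    )
    if noise_sd > 0:
        s = s + rng.normal(0.0, noise_sd, size=len(t))
    return pd.DataFrame({"temperature_C": t, "signal": s})
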