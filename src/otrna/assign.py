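"""Hidden-Markov state assignment of passive-mode traces.

Passive-mode data encode the folding state in discrete force levels:
more-folded states pull the beads further out of the traps and sit at
higher force.  A Gaussian-emission HMM on the force signal assigns every
sample to a state; run-length encoding of the Viterbi path yields dwell
records, and long dwells of a protein-stabilized state segment the trace
into bound and unbound phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simulate import Trace

__all__ = [
    "StateAssignment",
    "DwellRecord",
    "BoundSegmentation",
    "fit_hmm",
    "extract_dwells",
    "segment_bound_phases",
]

#: emission sd floor, pN — prevents collapse onto single samples
MIN_EMISSION_SD = 0.05


@dataclass
class StateAssignment:
    """Viterbi path plus per-state Gaussian levels.

    States are relabeled so levels are sorted descending by mean force
    (state 0 = most folded = highest force).
    """

    path: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    transition_counts: np.ndarray
    log_likelihood: float
    n_states: int
    loglik_history: list = field(default_factory=list)

    @property
    def levels(self) -> list[tuple[float, float]]:
        return list(zip(self.means.tolist(), self.sds.tolist()))


@dataclass(frozen=True)
class DwellRecord:
    """One visit to a state: index, start time, duration, mean force."""

    state: int
    t_start: float
    duration: float
    mean_force: float


class _FullHistoryMonitor:
    """Convergence monitor recording the complete log-likelihood history."""

    def __init__(self, tol: float, n_iter: int, verbose: bool = False):
        self.tol = tol
        self.n_iter = n_iter
        self.verbose = verbose
        self.history: list[float] = []
        self.iter = 0

    def _reset(self) -> None:
        self.iter = 0
        self.history = []

    def report(self, log_prob: float) -> None:
        self.history.append(log_prob)
        self.iter += 1

    @property
    def converged(self) -> bool:
        return self.iter == self.n_iter or (
            len(self.history) >= 2
            and abs(self.history[-1] - self.history[-2]) < self.tol
        )


def _transition_counts(path: np.ndarray, n_states: int) -> np.ndarray:
    counts = np.zeros((n_states, n_states), dtype=int)
    a, b = path[:-1], path[1:]
    np.add.at(counts, (a[a != b], b[a != b]), 1)
    return counts


def fit_hmm(
    trace: Trace,
    n_states: Optional[int] = None,
    init_levels: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    n_iter: int = 500,
    tol_rel: float = 1e-6,
    min_sd: float = MIN_EMISSION_SD,
) -> StateAssignment:
    """Fit a Gaussian-emission HMM to the force signal and Viterbi-decode.

    EM runs to convergence (relative log-likelihood change < ``tol_rel``
    or ``n_iter`` iterations).  Means are initialized on quantile-spaced
    levels unless ``init_levels`` is given; per-state emission sds are
    floored at ``min_sd``.  With ``n_states=None`` the state count is
    chosen by BIC over 2–8 states.
    """
    if trace.mode != "passive":
        raise ValueError("HMM assignment expects a passive-mode trace")
    x = np.asarray(trace.force, dtype=float).reshape(-1, 1)

    if n_states is None:
        best = None
        for k in range(2, 9):
            cand = fit_hmm(trace, k, seed=seed, n_iter=n_iter, tol_rel=tol_rel)
            n_params = 2 * k + k * (k - 1) + (k - 1)
            bic = -2.0 * cand.log_likelihood + n_params * np.log(len(x))
            if best is None or bic < best[0]:
                best = (bic, cand)
        return best[1]

    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states == 1:
        mean = float(x.mean())
        sd = max(float(x.std()), min_sd)
        path = np.zeros(len(x), dtype=int)
        ll = float(
            np.sum(-0.5 * ((x - mean) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi)))
        )
        return StateAssignment(
            path=path,
            means=np.array([mean]),
            sds=np.array([sd]),
            transition_counts=np.zeros((1, 1), dtype=int),
            log_likelihood=ll,
            n_states=1,
            loglik_history=[ll],
        )

    from hmmlearn.hmm import GaussianHMM

    if init_levels is not None:
        means0 = np.sort(np.asarray(init_levels, dtype=float))[::-1]
        if len(means0) != n_states:
            raise ValueError("init_levels length must equal n_states")
    else:
        qs = (np.arange(n_states) + 0.5) / n_states
        means0 = np.quantile(x, 1.0 - qs)  # descending
    sd0 = max(float(x.std()) / n_states, min_sd)

    tol = tol_rel * max(1.0, float(len(x)))
    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        min_covar=min_sd**2,
        n_iter=n_iter,
        tol=tol,
        init_params="",
        params="stmc",
        random_state=seed,
    )
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    transmat = np.full((n_states, n_states), 0.01 / max(1, n_states - 1))
    np.fill_diagonal(transmat, 0.99)
    model.transmat_ = transmat
    model.means_ = means0.reshape(-1, 1)
    model.covars_ = np.full((n_states, 1), sd0**2)
    model.monitor_ = _FullHistoryMonitor(tol, n_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x)
        path = model.predict(x)
    ll = float(model.monitor_.history[-1])

    means = model.means_.ravel()
    sds = np.sqrt(np.maximum(model.covars_.ravel(), min_sd**2))
    order = np.argsort(-means)  # descending force: state 0 most folded
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(n_states)
    path = relabel[path]
    means, sds = means[order], sds[order]

    occ = np.bincount(path, minlength=n_states)
    for s in np.where(occ < 10)[0]:
        warnings.warn(
            f"state {s} occupies only {occ[s]} samples; consider merging "
            f"it with its nearest level"
        )
    return StateAssignment(
        path=path,
        means=means,
        sds=sds,
        transition_counts=_transition_counts(path, n_states),
        log_likelihood=ll,
        n_states=n_states,
        loglik_history=list(model.monitor_.history),
    )


# ---------------------------------------------------------------------------
# Dwell extraction
# ---------------------------------------------------------------------------

def _run_lengths(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(start_index, length) of maximal constant runs."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [len(path)]]))
    return starts, lengths


def extract_dwells(
    assignment: StateAssignment,
    trace: Trace,
    min_dwell_samples: int = 0,
) -> list[DwellRecord]:
    """Run-length encode the Viterbi path into dwell records.

    Runs shorter than ``min_dwell_samples`` (sub-dead-time blips) are
    merged into the longer neighboring run; adjacent same-state runs are
    then coalesced.  Dwell durations tile the trace exactly; the mean
    force per dwell is computed from the raw samples.
    """
    path = np.asarray(assignment.path).copy()
    starts, lengths = _run_lengths(path)
    states = path[starts].astype(int)

    if min_dwell_samples > 1:
        states, lengths = list(states), list(lengths)
        changed = True
        while changed and len(states) > 1:
            changed = False
            i = int(np.argmin(lengths))
            if lengths[i] < min_dwell_samples:
                # merge into the longer neighbor (previous on tie/edge)
                if i == 0:
                    j = 1
                elif i == len(states) - 1:
                    j = i - 1
                else:
                    j = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
                lengths[j] += lengths[i]
                del states[i], lengths[i]
                # coalesce equal-state neighbors
                m = 0
                while m < len(states) - 1:
                    if states[m] == states[m + 1]:
                        lengths[m] += lengths[m + 1]
                        del states[m + 1], lengths[m + 1]
                    else:
                        m += 1
                changed = True
        states = np.array(states, dtype=int)
        lengths = np.array(lengths, dtype=int)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])

    dt = trace.dt
    force = np.asarray(trace.force)
    dwells = []
    for s, i0, ln in zip(states, starts, lengths):
        dwells.append(
            DwellRecord(
                state=int(s),
                t_start=float(i0 * dt),
                duration=float(ln * dt),
                mean_force=float(force[i0 : i0 + ln].mean()),
            )
        )
    return dwells


# ---------------------------------------------------------------------------
# Bound/unbound segmentation
# ---------------------------------------------------------------------------

@dataclass
class BoundSegmentation:
    """Per-dwell bound labels plus bound/unbound interval lists."""

    labels: np.ndarray  # bool per dwell
    bound_intervals: list[tuple[float, float]]
    unbound_intervals: list[tuple[float, float]]


def segment_bound_phases(
    dwells: Sequence[DwellRecord],
    state: int,
    min_duration: float,
    force_band: Optional[tuple[float, float]] = None,
    allowed_states: Optional[Sequence[int]] = None,
    merge_gap: float = 0.0,
) -> BoundSegmentation:
    """Label protein-bound phases from stabilized-state dwell durations.

    A bound phase is a maximal run of dwells in ``allowed_states``
    (default: the stabilized state and every more-folded state, i.e.
    indices ≤ ``state``) that contains at least one dwell of the
    stabilized state longer than ``min_duration`` (and, when given, with
    mean force inside ``force_band``).  Everything else is unbound.  An
    empty bound list is a valid result, not an error.
    """
    states_present = {d.state for d in dwells}
    if state not in states_present:
        raise ValueError(f"criteria state {state} not present in dwells")
    if allowed_states is None:
        allowed = {s for s in states_present if s <= state}
    else:
        allowed = set(allowed_states)

    n = len(dwells)
    labels = np.zeros(n, dtype=bool)
    compatible = np.array([d.state in allowed for d in dwells])

    def qualifies(d: DwellRecord) -> bool:
        if d.state != state or d.duration < min_duration:
            return False
        if force_band is not None and not (
            force_band[0] <= d.mean_force <= force_band[1]
        ):
            return False
        return True

    i = 0
    while i < n:
        if not compatible[i]:
            i += 1
            continue
        j = i
        while j < n and compatible[j]:
            j += 1
        if any(qualifies(dwells[m]) for m in range(i, j)):
            labels[i:j] = True
        i = j

    if merge_gap > 0:
        # brief unbound excursions between bound runs (assignment blips)
        # do not terminate a phase: relabel gaps shorter than merge_gap
        i = 0
        while i < n:
            if labels[i]:
                i += 1
                continue
            j = i
            while j < n and not labels[j]:
                j += 1
            gap = sum(dwells[m].duration for m in range(i, j))
            if 0 < i and j < n and gap < merge_gap:
                labels[i:j] = True
            i = j

    def intervals(mask: np.ndarray) -> list[tuple[float, float]]:
        out = []
        m = 0
        while m < n:
            if mask[m]:
                k = m
                while k < n and mask[k]:
                    k += 1
                out.append(
                    (dwells[m].t_start, dwells[k - 1].t_start + dwells[k - 1].duration)
                )
                m = k
            else:
                m += 1
        return out

    return BoundSegmentation(
        labels=labels,
        bound_intervals=intervals(labels),
        unbound_intervals=intervals(~labels),
    )
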