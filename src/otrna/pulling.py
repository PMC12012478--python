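"""Force-extension (constant-velocity) cycle analysis.

Fits the two branches of a stretch curve with the dumbbell elasticity
model — handles plus a rigid folded stem before the rip, handles plus
free ssRNA contour after it — and reports the contour-length gain of the
unfolding transition.  The transition force is located on the smoothed
implied-contour trajectory, which is robust to the rapid
folding/unfolding hopping ("hump") of near-equilibrium two-state
elements; branch fits stay clear of the hopping window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .elasticity import ElasticModel, construct_extension, _ss_rel_extension
from .simulate import Trace

__all__ = ["CycleFit", "fit_stretch_branches", "contour_gain_from_cycles",
           "unfolding_force"]


@dataclass
class CycleFit:
    """Result of a two-branch WLC fit to one stretch curve."""

    contour_gain: float  # nm, folded-offset bookkeeping applied
    ss_contour_unfolded: float  # nm, fitted free ssRNA contour above the rip
    split_force: float  # pN separating the folded and unfolded branches
    rms_residual: float  # nm


def fit_stretch_branches(
    trace: Trace,
    model: Optional[ElasticModel] = None,
    f_fit_range: tuple[float, float] = (4.0, 17.0),
    exclusion_halfwidth: float = 1.5,
    unfolded_exclusion: float = 3.5,
    n_closed_stems: int = 1,
) -> CycleFit:
    """Fit folded and unfolded WLC branches of the stretch half-cycle.

    The folded branch is the handles-plus-closed-stem model (no free
    parameter); the unfolded branch adds ssRNA whose contour length L is
    solved linearly.  Samples within ``exclusion_halfwidth`` pN below and
    ``unfolded_exclusion`` pN above the detected transition are excluded:
    near-equilibrium elements keep hopping around the transition, and the
    folded admixture decays over a few pN above it.  The reported contour
    gain is L minus the folded offset, i.e. the same bookkeeping as
    ``nt_from_contour_gain`` with ``closes_hairpin=True``.
    """
    if model is None:
        model = trace.model
    if model is None:
        raise ValueError("an ElasticModel is required")
    if trace.mode != "constant_velocity":
        raise ValueError("expected a constant-velocity trace")
    n_half = trace.meta.get("turnaround_index", len(trace) // 2)
    force = np.asarray(trace.force[:n_half])
    d = np.asarray(trace.trap_separation)[:n_half]
    ext = d - force / model.trap_stiffness

    lo, hi = f_fit_range
    sel = (force > lo) & (force < hi)
    force, ext = force[sel], ext[sel]
    if len(force) < 50:
        raise ValueError("too few samples inside the fit force range")

    x_folded = construct_extension(force, model, 0, n_closed_stems)
    x_handles = construct_extension(force, model, 0, 0)
    z_ss = _ss_rel_extension(force, model)

    # locate the transition on the smoothed implied-contour trajectory:
    # ℓ(t) = (x − x_handles)/z_ss steps from the folded to the unfolded
    # plateau; the split force is where it crosses the plateau midpoint
    ell = (ext - x_handles) / np.maximum(z_ss, 1e-6)
    win = max(5, len(ell) // 100)
    kernel = np.ones(win) / win
    ell_s = np.convolve(ell, kernel, mode="same")
    n10 = max(10, len(ell) // 10)
    ell_lo = float(np.median(ell_s[win:n10 + win]))
    ell_hi = float(np.median(ell_s[-n10 - win:-win]))
    if ell_hi - ell_lo < 1.0:
        raise ValueError("no unfolding transition detected on the stretch")
    above = (ell_s > 0.5 * (ell_lo + ell_hi)).astype(float)
    # persistent crossing: the next `win` samples must stay above the
    # midpoint, so brief noise excursions at low force do not trigger
    frac_above = np.convolve(above, kernel, mode="full")[win - 1 : win - 1 + len(above)]
    cross = np.flatnonzero(frac_above[: len(above) - win] > 0.95)
    if len(cross) == 0:
        raise ValueError("no unfolding transition detected on the stretch")
    f_mid = float(force[cross[0]])

    fold = force < f_mid - exclusion_halfwidth
    unf = force > f_mid + unfolded_exclusion
    if fold.sum() < 20 or unf.sum() < 20:
        raise ValueError("too few samples on a branch after exclusion")
    r_fold = ext[fold] - x_folded[fold]
    # linear LS for the ssRNA contour on the unfolded branch; residual
    # folded-state admixture near the transition produces one-sided
    # negative outliers, removed by an asymmetric trim + refit
    y = ext[unf] - x_handles[unf]
    z = z_ss[unf]
    l_ss = float(np.dot(z, y) / np.dot(z, z))
    for _ in range(3):
        r = y - l_ss * z
        mad = np.median(np.abs(r - np.median(r))) * 1.4826
        keep = r > -2.5 * max(mad, 1e-9)
        if keep.all() or keep.sum() < 20:
            break
        l_ss = float(np.dot(z[keep], y[keep]) / np.dot(z[keep], z[keep]))
        y, z = y[keep], z[keep]
    r_unf = y - l_ss * z
    ssr = float(np.dot(r_fold, r_fold) + np.dot(r_unf, r_unf))
    n_used = int(fold.sum() + len(y))
    return CycleFit(
        contour_gain=l_ss - n_closed_stems * model.folded_offset,
        ss_contour_unfolded=l_ss,
        split_force=f_mid,
        rms_residual=float(np.sqrt(ssr / n_used)),
    )


def contour_gain_from_cycles(
    traces: list[Trace],
    model: Optional[ElasticModel] = None,
    **kwargs,
) -> tuple[float, float, list[CycleFit]]:
    """Mean ± sd of the WLC contour-length gain over stretch cycles."""
    fits = [fit_stretch_branches(tr, model, **kwargs) for tr in traces]
    gains = np.array([f.contour_gain for f in fits])
    return float(gains.mean()), float(gains.std(ddof=1)), fits


def unfolding_force(trace: Trace) -> float:
    """Force at the first folded→unfolded truth transition on the stretch.

    Defined for synthetic traces carrying truth labels; the first-passage
    rip force is the statistic whose mean grows with loading rate, so it
    is the one to compare across pulling velocities (hopping elements
    keep re-crossing afterwards, which would scramble a last-passage
    definition).
    """
    if trace.truth_state is None:
        raise ValueError("requires truth labels")
    n_half = trace.meta.get("turnaround_index", len(trace) // 2)
    path = np.asarray(trace.truth_state[:n_half])
    u = path.max()
    into_u = np.flatnonzero((path[1:] == u) & (path[:-1] != u))
    if len(into_u) == 0:
        raise ValueError("no unfolding transition on the stretch branch")
    return float(trace.force[into_u[0]])
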