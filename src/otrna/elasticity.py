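"""Polymer mechanics of the dual-trap dumbbell assay.

A single RNA molecule is held between two optically trapped beads through
double-stranded DNA handles.  Unfolding part of the RNA releases
single-stranded contour, lengthening the construct; at constant trap
separation this relaxes the beads into their traps and the measured force
drops.  This module provides the worm-like chain (WLC) force–extension
relations, the series elasticity of trap + handles + released ssRNA, and
conversions between force jumps, contour-length gains, and numbers of
unfolded nucleotides.

Forces are in pN, lengths in nm, energies in pN·nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from typing import NamedTuple

import numpy as np

from .constants import KT_ROOM_PN_NM

__all__ = [
    "ElasticModel",
    "WlcDomainError",
    "ConfigurationError",
    "wlc_force",
    "wlc_extension",
    "construct_extension",
    "passive_force",
    "contour_gain_from_force_jump",
    "nt_from_contour_gain",
    "expected_contour_gain",
    "stretch_free_energy",
]


class WlcDomainError(ValueError):
    """Relative extension outside [0, 1): finite extensibility violated."""


class ConfigurationError(ValueError):
    """Mechanically impossible dumbbell configuration (no force-balance root)."""


_SERIAL_KEYS = {
    "kT": "kT_pN_nm",
    "trap_stiffness": "trap_stiffness_pN_per_nm",
    "handle_contour": "handle_contour_nm",
    "handle_persistence": "handle_persistence_nm",
    "handle_stretch_modulus": "handle_stretch_modulus_pN",
    "ss_contour_per_nt": "ss_contour_per_nt_nm",
    "ss_persistence": "ss_persistence_nm",
    "folded_offset": "folded_offset_nm",
}


@dataclass(frozen=True)
class ElasticModel:
    """All mechanical parameters of the dumbbell construct.

    The two traps are collapsed into a single effective stiffness
    ``k_eff = k1·k2/(k1+k2)``; with per-trap stiffnesses in the usual
    0.25–0.40 pN/nm band the effective value defaults to 0.15 pN/nm.
    Handle defaults correspond to two ~900-bp dsDNA amplicons in series
    (600 nm contour, 40 nm persistence, 1000 pN stretch modulus); ssRNA
    uses 0.65 nm/nt contour and 1.0 nm persistence.  ``folded_offset`` is
    the ~2 nm end-to-end span of one closed stem terminus, replaced by
    ssRNA contour upon full opening.
    """

    kT: float = KT_ROOM_PN_NM
    trap_stiffness: float = 0.15
    handle_contour: float = 600.0
    handle_persistence: float = 40.0
    handle_stretch_modulus: float = 1000.0
    ss_contour_per_nt: float = 0.65
    ss_persistence: float = 1.0
    folded_offset: float = 2.0
    #: set False to bypass the sanity band on trap stiffness
    check_bounds: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        for name in (
            "kT",
            "trap_stiffness",
            "handle_contour",
            "handle_persistence",
            "handle_stretch_modulus",
            "ss_contour_per_nt",
            "ss_persistence",
            "folded_offset",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ElasticModel.{name} must be strictly positive")
        if self.check_bounds and not (0.01 <= self.trap_stiffness <= 10.0):
            raise ValueError(
                "trap_stiffness outside the sane 0.01–10 pN/nm band; "
                "pass check_bounds=False to override"
            )

    # -- flat key/value (de)serialization, units in key names ------------
    def to_config(self) -> dict:
        d = asdict(self)
        d.pop("check_bounds")
        return {_SERIAL_KEYS[k]: v for k, v in d.items()}

    @classmethod
    def from_config(cls, config: dict) -> "ElasticModel":
        inv = {v: k for k, v in _SERIAL_KEYS.items()}
        kwargs = {}
        for key, value in config.items():
            if key not in inv:
                raise KeyError(f"unknown ElasticModel config key: {key!r}")
            kwargs[inv[key]] = float(value)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Worm-like chain
# ---------------------------------------------------------------------------

def wlc_force(rel_extension, persistence: float, kT: float = KT_ROOM_PN_NM):
    """Marko–Siggia interpolation F(z) = (kT/p)·[1/(4(1−z)²) − 1/4 + z].

    ``rel_extension`` is z = x/L in [0, 1); scalar or array.
    """
    z = np.asarray(rel_extension, dtype=float)
    if np.any(z < 0) or np.any(z >= 1):
        raise WlcDomainError("relative extension must lie in [0, 1)")
    f = (kT / persistence) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return float(f) if np.isscalar(rel_extension) else f


def _ms_inverse(f_scaled):
    """Invert the Marko–Siggia relation: z such that F·p/kT = f_scaled.

    Vectorized bisection (the relation is strictly increasing on [0, 1))
    followed by Newton polishing; accurate to ~1e-14 relative.
    """
    f = np.atleast_1d(np.asarray(f_scaled, dtype=float))
    if np.any(f < 0):
        raise WlcDomainError("force must be non-negative")
    lo = np.zeros_like(f)
    hi = np.full_like(f, 1.0 - 1e-12)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = 0.25 / (1.0 - mid) ** 2 - 0.25 + mid
        high = val > f
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    z = 0.5 * (lo + hi)
    for _ in range(3):  # Newton polish
        g = 0.25 / (1.0 - z) ** 2 - 0.25 + z - f
        dg = 0.5 / (1.0 - z) ** 3 + 1.0
        z = np.clip(z - g / dg, 0.0, 1.0 - 1e-12)
    return z


def wlc_extension(
    force,
    contour: float,
    persistence: float,
    kT: float = KT_ROOM_PN_NM,
    stretch_modulus: float = math.inf,
):
    """Extension x(F) of a WLC of given contour length.

    Numeric inverse of :func:`wlc_force`; with a finite ``stretch_modulus``
    K the extensible-WLC correction x = L·(z(F) + F/K) is applied
    (switchless — the enthalpic term is negligible at low force and becomes
    relevant above ~10 pN, standard practice for dsDNA handles).
    """
    f = np.asarray(force, dtype=float)
    z = _ms_inverse(f * persistence / kT)
    x = contour * (z + f / stretch_modulus)
    return x.ravel()[0].item() if np.isscalar(force) else np.reshape(x, f.shape)


def _ss_rel_extension(force, model: ElasticModel):
    return _ms_inverse(np.asarray(force, dtype=float) * model.ss_persistence / model.kT)


def construct_extension(
    force,
    model: ElasticModel,
    n_unfolded_nt: int = 0,
    n_closed_stems: int = 1,
):
    """Series extension of handles + released ssRNA + closed-stem offsets.

    Each fully closed stem contributes one rigid ``folded_offset``; partial
    openings only add ssRNA contour (``n_unfolded_nt`` released
    nucleotides).  Monotone increasing in force and, at fixed force > 0, in
    the number of unfolded nucleotides.
    """
    if n_unfolded_nt < 0:
        raise ValueError("n_unfolded_nt must be >= 0")
    f = np.asarray(force, dtype=float)
    x = wlc_extension(
        f,
        model.handle_contour,
        model.handle_persistence,
        model.kT,
        model.handle_stretch_modulus,
    )
    x = np.asarray(x, dtype=float)
    if n_unfolded_nt > 0:
        x = x + wlc_extension(
            f,
            n_unfolded_nt * model.ss_contour_per_nt,
            model.ss_persistence,
            model.kT,
        )
    x = x + n_closed_stems * model.folded_offset
    return float(x) if np.isscalar(force) else x


def passive_force(
    trap_separation: float,
    model: ElasticModel,
    n_unfolded_nt: int = 0,
    n_closed_stems: int = 1,
    f_max: float = 200.0,
) -> float:
    """Force at fixed trap separation D: solves F = k·(D − x_total(F)).

    The construct extension is monotone in F, so the root is unique.
    Raises :class:`ConfigurationError` when D does not exceed the
    zero-force slack length.
    """
    from scipy.optimize import brentq

    k = model.trap_stiffness

    def g(f: float) -> float:
        return f - k * (
            trap_separation
            - construct_extension(f, model, n_unfolded_nt, n_closed_stems)
        )

    if g(0.0) >= 0.0:
        raise ConfigurationError(
            "trap separation does not exceed the zero-force construct length"
        )
    if g(f_max) <= 0.0:
        raise ConfigurationError("no force-balance root below f_max")
    return float(brentq(g, 0.0, f_max, xtol=1e-10, rtol=1e-12))


def trap_separation_for_force(
    force: float,
    model: ElasticModel,
    n_unfolded_nt: int = 0,
    n_closed_stems: int = 1,
) -> float:
    """Trap separation that puts the given state at the given force."""
    return (
        construct_extension(force, model, n_unfolded_nt, n_closed_stems)
        + force / model.trap_stiffness
    )


def _implied_ss_contour(
    force: float, trap_separation: float, model: ElasticModel, n_closed_stems: int
) -> float:
    """ssRNA contour length consistent with a measured passive-mode force."""
    x_ss = (
        trap_separation
        - force / model.trap_stiffness
        - construct_extension(force, model, 0, n_closed_stems)
    )
    z = float(_ms_inverse(force * model.ss_persistence / model.kT)[0])
    if z <= 0:
        raise ValueError("cannot infer contour at zero force")
    return x_ss / z


def contour_gain_from_force_jump(
    force_high: float,
    force_low: float,
    trap_separation: float,
    model: ElasticModel,
    n_closed_stems: int = 1,
) -> float:
    """Gain in ssRNA contour length implied by a passive-mode force drop.

    Inverse of :func:`passive_force` in the contour argument: finds the
    ΔL_ss such that at fixed trap separation the construct with extra
    contour ΔL_ss balances at ``force_low`` given that ``force_high``
    balances without it.  Closed-stem offsets are assumed unchanged; the
    replacement of a folded offset on full opening is handled by
    :func:`nt_from_contour_gain` via ``closes_hairpin``.
    """
    if force_high == force_low:
        return 0.0
    if not (force_high > force_low > 0):
        raise ValueError("require force_high > force_low > 0")
    l_high = _implied_ss_contour(force_high, trap_separation, model, n_closed_stems)
    l_low = _implied_ss_contour(force_low, trap_separation, model, n_closed_stems)
    delta = l_low - l_high
    if delta <= 0:
        raise ValueError("forces inconsistent with a positive contour gain")
    return delta


class NtEstimate(NamedTuple):
    n_nt: int
    n_nt_raw: float


def nt_from_contour_gain(
    delta_contour: float, model: ElasticModel, closes_hairpin: bool = False
) -> NtEstimate:
    """Number of nucleotides released by a contour-length gain.

    When the transition opens a complete hairpin, the rigid folded offset
    is replaced by contour, so n = (ΔL + folded_offset)/ℓ_nt; partial
    openings use n = ΔL/ℓ_nt.
    """
    if delta_contour <= 0:
        raise ValueError("delta_contour must be positive")
    raw = (
        delta_contour + (model.folded_offset if closes_hairpin else 0.0)
    ) / model.ss_contour_per_nt
    return NtEstimate(int(round(raw)), raw)


def expected_contour_gain(
    n_nt: int, model: ElasticModel, closes_hairpin: bool = False
) -> float:
    """Inverse of :func:`nt_from_contour_gain`: expected ΔL for n released nt."""
    return n_nt * model.ss_contour_per_nt - (
        model.folded_offset if closes_hairpin else 0.0
    )


# ---------------------------------------------------------------------------
# Stretching free energy
# ---------------------------------------------------------------------------

def _ms_energy(z, contour: float, persistence: float, kT: float):
    """∫₀^z F dz' · L for Marko–Siggia, closed form."""
    z = np.asarray(z, dtype=float)
    return (kT * contour / persistence) * (
        0.25 / (1.0 - z) - 0.25 - 0.25 * z + 0.5 * z * z
    )


def stretch_free_energy(
    force,
    contour: float,
    persistence: float,
    kT: float = KT_ROOM_PN_NM,
    stretch_modulus: float = math.inf,
):
    """Elastic energy ∫₀^{x(F)} F'(x′) dx′ stored in a stretched WLC, pN·nm.

    Uses the closed-form Marko–Siggia integral plus the enthalpic term
    L·F²/(2K) when a finite stretch modulus is given.  Non-negative and
    increasing in force.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise WlcDomainError("force must be non-negative")
    z = _ms_inverse(f * persistence / kT)
    e = _ms_energy(z, contour, persistence, kT)
    if math.isfinite(stretch_modulus):
        e = e + contour * f * f / (2.0 * stretch_modulus)
    return e.ravel()[0].item() if np.isscalar(force) else np.reshape(e, f.shape)
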