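"""Shipped fixture presets: kinetic schemes + measurement defaults.

Three reference conditions cover the pipeline end to end:

* ``CDE_two_state`` — a 15-nt hairpin hopping between folded and unfolded
  around 11.5 pN (rapid near-equilibrium two-state element).
* ``ADE_six_state`` — a six-state folding network F, I1, I2, M, I3, U
  with the misfold M reachable only from I2 (off-pathway pendant).
* ``ADE_extROQ_binding`` — a three-state low-force network I1, I3, U with
  a protein-binding channel: binding only from the folded stem-loop I3
  (conformational selection), unfolding of I3 blocked and refolding
  I3→I1 slowed while bound.

State energies and Bell parameters are synthetic calibrations chosen so
the fixtures exchange on observable timescales at the preset trap
separations; they are not measured values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .elasticity import ElasticModel
from .simulate import BindingModel, FoldingState, KineticScheme, Transition

__all__ = ["load_preset", "scheme_from_dict", "available_presets"]

_DATA_PACKAGE = "otrna.data"


def available_presets() -> list[str]:
    root = resources.files(_DATA_PACKAGE)
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def scheme_from_dict(raw: dict) -> tuple[KineticScheme, ElasticModel, dict]:
    """(scheme, elastic model, measurement defaults) from a config mapping."""
    states = [
        FoldingState(
            name=s["name"],
            n_unfolded_nt=int(s["n_unfolded_nt"]),
            dG0=float(s.get("dG0_kcal_per_mol", 0.0)),
            n_closed_stems=s.get("n_closed_stems"),
        )
        for s in raw["states"]
    ]
    transitions = [
        Transition(
            source=t["source"],
            target=t["target"],
            k0=float(t["k0_per_s"]),
            dx=float(t.get("dx_nm", 0.0)),
            sign=int(t.get("sign", 1)),
        )
        for t in raw["transitions"]
    ]
    binding = None
    if "binding" in raw:
        b = raw["binding"]
        binding = BindingModel(
            k_on=float(b["k_on_per_M_per_s"]),
            protein_conc=float(b["protein_conc_M"]),
            k_off0=float(b["k_off0_per_s"]),
            dx_off=float(b["dx_off_nm"]),
            k_off_force_independent=float(b.get("k_off_independent_per_s", 0.0)),
            competent_state=b["competent_state"],
            blocked_while_bound=tuple(
                tuple(e) for e in b.get("blocked_while_bound", [])
            ),
            slowed_while_bound=tuple(
                (tuple(e["edge"]), float(e["factor"]))
                for e in b.get("slowed_while_bound", [])
            ),
        )
    scheme = KineticScheme(
        states=states,
        transitions=transitions,
        binding=binding,
        detailed_balance=bool(raw.get("detailed_balance", False)),
        name=raw.get("name", ""),
    )
    model = (
        ElasticModel.from_config(raw["elastic"]) if "elastic" in raw else ElasticModel()
    )
    return scheme, model, dict(raw.get("defaults", {}))


def load_preset(name: str) -> tuple[KineticScheme, ElasticModel, dict]:
    """Load a shipped preset (or a path to a user scheme YAML)."""
    candidate = Path(name)
    if candidate.suffix in (".yaml", ".yml") and candidate.exists():
        raw = yaml.safe_load(candidate.read_text())
    else:
        ref = resources.files(_DATA_PACKAGE) / f"{name}.yaml"
        if not ref.is_file():
            raise KeyError(
                f"unknown preset {name!r}; available: {available_presets()}"
            )
        raw = yaml.safe_load(ref.read_text())
    return scheme_from_dict(raw)
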