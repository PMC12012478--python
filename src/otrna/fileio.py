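"""File formats: trace TSV with metadata header, dot-bracket structures,
tables, and the run configuration.

The canonical trace container is a plain TSV with ``#key=value`` header
lines followed by a ``#columns:`` declaration — portable, diffable, and
lossless to six decimals.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .elasticity import ElasticModel
from .network import SecondaryStructure
from .simulate import Trace

__all__ = [
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_structure",
    "write_structure",
    "RunConfig",
    "sha256_file",
]

SCHEMA_VERSION = "1"
_KNOWN_COLUMNS = ["time_s", "force_pN", "extension_nm", "truth_state", "truth_bound"]


class TraceParseError(ValueError):
    pass


def write_trace(trace: Trace, path, precision: int = 6) -> None:
    """Write a trace as header + TSV; lossless round-trip to `precision`."""
    path = Path(path)
    header = {
        "schema_version": SCHEMA_VERSION,
        "sampling_hz": trace.sampling_hz,
        "downsample_factor": trace.downsample_factor,
        "mode": trace.mode,
    }
    ramped = isinstance(trace.trap_separation, np.ndarray)
    if not ramped:
        header["trap_separation_nm"] = float(trace.trap_separation)
    if trace.model is not None:
        header["trap_stiffness_pN_per_nm"] = trace.model.trap_stiffness
        header["temperature_C"] = 25.0
    for key, value in trace.meta.items():
        if isinstance(value, (int, float, str)):
            header[f"meta_{key}"] = value
    cols = {"time_s": trace.time, "force_pN": trace.force}
    if trace.extension is not None:
        cols["extension_nm"] = trace.extension
    if ramped:
        cols["trap_separation_nm"] = trace.trap_separation
    if trace.truth_state is not None:
        cols["truth_state"] = trace.truth_state
    if trace.truth_bound is not None:
        cols["truth_bound"] = trace.truth_bound
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"#{key}={value}\n")
        fh.write("#columns:" + "\t".join(cols) + "\n")
        df = pd.DataFrame(cols)
        float_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
        df[float_cols] = df[float_cols].round(precision)
        df.to_csv(fh, sep="\t", index=False, header=False,
                  float_format=f"%.{precision}f")


def read_trace(path, model: Optional[ElasticModel] = None) -> Trace:
    """Parse a trace file; malformed headers or non-uniform time raise
    :class:`TraceParseError` with the offending line number."""
    path = Path(path)
    header: dict = {}
    columns: list[str] = []
    n_header = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if body.startswith("columns:"):
                columns = body[len("columns:"):].split("\t")
            elif "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
            else:
                raise TraceParseError(f"{path}:{lineno}: malformed header line")
    if "sampling_hz" not in header:
        raise TraceParseError(f"{path}: missing required header key sampling_hz")
    if not columns:
        raise TraceParseError(f"{path}: missing #columns: declaration")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=columns)
    if df.shape[1] != len(columns):
        raise TraceParseError(f"{path}: column count does not match declaration")
    unknown = [c for c in columns if c not in _KNOWN_COLUMNS + ["trap_separation_nm"]]
    if unknown:
        warnings.warn(f"unknown columns preserved in meta: {unknown}")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt):
        # atol covers the 1e-6 s quantisation of the written time column
        bad = np.flatnonzero(~np.isclose(dt, dt[0], rtol=1e-3, atol=2e-6))
        if len(bad):
            raise TraceParseError(
                f"{path}:{n_header + int(bad[0]) + 2}: non-uniform time grid"
            )
        if dt[0] <= 0:
            raise TraceParseError(f"{path}: time must be strictly increasing")
    sampling_hz = float(header["sampling_hz"])
    downsample = int(float(header.get("downsample_factor", 1)))
    trap_sep: float | np.ndarray
    if "trap_separation_nm" in df.columns:
        trap_sep = df["trap_separation_nm"].to_numpy()
    else:
        trap_sep = float(header.get("trap_separation_nm", 0.0))
    meta = {k[len("meta_"):]: v for k, v in header.items() if k.startswith("meta_")}
    for c in unknown:
        meta[f"column_{c}"] = df[c].to_numpy()
    return Trace(
        force=df["force_pN"].to_numpy(),
        sampling_hz=sampling_hz,
        downsample_factor=downsample,
        mode=header.get("mode", "passive"),
        trap_separation=trap_sep,
        model=model,
        extension=df["extension_nm"].to_numpy() if "extension_nm" in df else None,
        truth_state=(
            df["truth_state"].to_numpy().astype(int) if "truth_state" in df else None
        ),
        truth_bound=(
            df["truth_bound"].to_numpy().astype(int) if "truth_bound" in df else None
        ),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Dot-bracket structure dialect
# ---------------------------------------------------------------------------

def read_structure(path) -> SecondaryStructure:
    """3-line record: '>name offset=52', sequence, dot-bracket."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != 3 or not lines[0].startswith(">"):
        raise ValueError(f"{path}: expected a 3-line record starting with '>'")
    head = lines[0][1:].split()
    name = head[0] if head else ""
    offset = 1
    for token in head[1:]:
        if token.startswith("offset="):
            offset = int(token[len("offset="):])
    return SecondaryStructure(
        sequence=lines[1].upper(), dot_bracket=lines[2],
        numbering_offset=offset, name=name,
    )


def write_structure(structure: SecondaryStructure, path) -> None:
    Path(path).write_text(
        f">{structure.name or 'structure'} offset={structure.numbering_offset}\n"
        f"{structure.sequence}\n{structure.dot_bracket}\n"
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SECTION_KEYS = {
    "elastic": set(ElasticModel().to_config()),
    "hmm": {"n_states", "seed", "min_dwell_samples"},
    "kinetics": {"dead_time_s", "n_force_bins"},
    "energetics": {"bootstrap_n", "seed"},
    "network": {"tolerance_nm", "min_count"},
}


@dataclass
class RunConfig:
    """Structured key-value configuration for the CLI pipeline.

    Unknown sections or keys are rejected so typos fail loudly; every
    field has a documented default.
    """

    elastic: ElasticModel = field(default_factory=ElasticModel)
    hmm: dict = field(
        default_factory=lambda: {"n_states": None, "seed": 0, "min_dwell_samples": 3}
    )
    kinetics: dict = field(
        default_factory=lambda: {"dead_time_s": 0.0, "n_force_bins": 0}
    )
    energetics: dict = field(default_factory=lambda: {"bootstrap_n": 1000, "seed": 0})
    network: dict = field(
        default_factory=lambda: {"tolerance_nm": 1.5, "min_count": 3}
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_SECTION_KEYS)
        if unknown:
            raise KeyError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls()
        for section, values in raw.items():
            bad = set(values) - _SECTION_KEYS[section]
            if bad:
                raise KeyError(f"unknown keys in [{section}]: {sorted(bad)}")
            if section == "elastic":
                base = cfg.elastic.to_config()
                base.update(values)
                cfg.elastic = ElasticModel.from_config(base)
            else:
                getattr(cfg, section).update(values)
        return cfg

    def to_yaml(self, path) -> None:
        data = {
            "elastic": self.elastic.to_config(),
            "hmm": self.hmm,
            "kinetics": self.kinetics,
            "energetics": self.energetics,
            "network": self.network,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def digest(self) -> str:
        payload = {
            "elastic": self.elastic.to_config(),
            "hmm": self.hmm,
            "kinetics": self.kinetics,
            "energetics": self.energetics,
            "network": self.network,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
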