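"""Folding-network reconstruction and structural interpretation.

Builds the observed transition graph from assigned dwell sequences,
classifies off-pathway (misfolded) states by their connectivity, and
matches observed contour-length gains against the intermediates expected
from sequential outside-in unzipping of a dot-bracket secondary
structure: force propagates from the closing helix inward, and each
unfolding step disrupts a stem region together with its adjacent
interior bulge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .elasticity import ElasticModel, expected_contour_gain

__all__ = [
    "SecondaryStructure",
    "UnzippingIntermediate",
    "FoldingNetwork",
    "MatchResult",
    "UnsupportedStructureError",
    "DisconnectedGraphError",
    "parse_dot_bracket",
    "build_transition_graph",
    "classify_off_pathway",
    "enumerate_unzipping_intermediates",
    "match_intermediates",
    "compare_candidate_structures",
]


class UnsupportedStructureError(ValueError):
    pass


class DisconnectedGraphError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    """RNA sequence with dot-bracket structure and residue numbering offset."""

    sequence: str
    dot_bracket: str
    numbering_offset: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dot_bracket):
            raise ValueError("sequence and dot-bracket lengths differ")
        if set(self.sequence.upper()) - set("AUGC"):
            raise ValueError("sequence must contain only A, U, G, C")
        if set(self.dot_bracket) - set("().-"):
            raise UnsupportedStructureError(
                "only '(', ')' and '.' are supported (no pseudoknots)"
            )
        parse_dot_bracket(self.dot_bracket)  # validates balance

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return parse_dot_bracket(self.dot_bracket)

    def residue_number(self, index0: int) -> int:
        return index0 + self.numbering_offset


def parse_dot_bracket(db: str) -> list[tuple[int, int]]:
    """Base-pair list (0-based, sorted by opening index) from dot-bracket."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Transition graph and off-pathway classification
# ---------------------------------------------------------------------------

def build_transition_graph(dwells: Sequence) -> np.ndarray:
    """Counts of consecutive state pairs (no self-edges by construction)."""
    states = [d.state for d in dwells]
    if len(set(states)) < 2:
        raise ValueError("need at least 2 distinct states")
    n = max(states) + 1
    counts = np.zeros((n, n), dtype=int)
    for a, b in zip(states[:-1], states[1:]):
        if a != b:
            counts[a, b] += 1
    return counts


@dataclass
class FoldingNetwork:
    """Observed transition graph with per-state pathway classification."""

    counts: np.ndarray
    classification: dict = field(default_factory=dict)  # state -> label
    termini: tuple = ()
    sensitivity_notes: list = field(default_factory=list)


def classify_off_pathway(
    graph: np.ndarray,
    min_count: int = 3,
    termini: Optional[tuple[int, int]] = None,
) -> FoldingNetwork:
    """Label pendant states as off-pathway misfolds.

    A state whose pooled (both-direction) transition counts exceed
    ``min_count`` with exactly one partner, and which is neither the
    fully folded nor the fully unfolded terminus, cannot lie on the
    productive folding path.  Termini default to the lowest and highest
    state index (levels are force-ordered, so these are the most- and
    least-folded states).  A graph that splits into disconnected
    components above threshold raises, listing the components.
    """
    graph = np.asarray(graph)
    pooled = graph + graph.T
    present = np.flatnonzero(pooled.sum(axis=1) > 0)
    if termini is None:
        termini = (int(present.min()), int(present.max()))
    strong = pooled >= min_count

    # connectivity over above-threshold edges
    comp = {}
    for s in present:
        if s in comp:
            continue
        stack, members = [s], set()
        while stack:
            u = stack.pop()
            if u in members:
                continue
            members.add(u)
            stack.extend(v for v in np.flatnonzero(strong[u]) if v not in members)
        for m in members:
            comp[m] = s
    components = {}
    for s in present:
        components.setdefault(comp[s], []).append(int(s))
    if len(components) > 1:
        raise DisconnectedGraphError(
            f"transition graph disconnected above min_count={min_count}: "
            f"components {sorted(components.values())}"
        )

    classification = {}
    notes = []
    for s in present:
        partners = np.flatnonzero(strong[s])
        weak = [int(v) for v in np.flatnonzero(pooled[s] > 0) if not strong[s, v]]
        if int(s) in termini:
            classification[int(s)] = "on_pathway"
        elif len(partners) == 1:
            classification[int(s)] = "off_pathway"
            if weak:
                notes.append(
                    f"state {int(s)}: partners {weak} have counts below "
                    f"min_count={min_count}; classification is threshold-sensitive"
                )
        else:
            classification[int(s)] = "on_pathway"
    return FoldingNetwork(
        counts=graph, classification=classification, termini=termini,
        sensitivity_notes=notes,
    )


# ---------------------------------------------------------------------------
# Unzipping intermediates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnzippingIntermediate:
    """A prefix of the outside-in unzipping coordinate ending at a boundary."""

    name: str
    n_opened_pairs: int
    n_unfolded_nt: int
    expected_delta_contour: float
    is_full_unfold: bool
    opened_residues: tuple = ()


def enumerate_unzipping_intermediates(
    structure: SecondaryStructure,
    model: ElasticModel,
) -> list[UnzippingIntermediate]:
    """Intermediates of sequential outside-in unzipping of a single stem.

    Base pairs are ordered along the force-propagation coordinate (the
    closing helix opens first); intermediates are the prefixes ending at
    helix/bulge boundaries, with interior bulge or loop nucleotides
    released together with the helix on their terminus-proximal side.
    The last intermediate (full unfolding, hairpin loop released) swaps
    the rigid folded offset for ssRNA contour.
    """
    pairs = structure.pairs
    if not pairs:
        raise UnsupportedStructureError("structure contains no base pairs")
    # verify single-stem nesting: opening indices increase, closing decrease
    for (i1, j1), (i2, j2) in zip(pairs[:-1], pairs[1:]):
        if not (i2 > i1 and j2 < j1):
            raise UnsupportedStructureError(
                "multibranch structures are not supported: intermediates are "
                "only defined along a single unzipping coordinate"
            )
    # group stacked pairs into helices
    helices: list[list[tuple[int, int]]] = [[pairs[0]]]
    for prev, cur in zip(pairs[:-1], pairs[1:]):
        if cur[0] == prev[0] + 1 and cur[1] == prev[1] - 1:
            helices[-1].append(cur)
        else:
            helices.append([cur])

    span_first = pairs[0]
    intermediates = []
    cum_nt = 0
    cum_pairs = 0
    opened: list[int] = []
    for h_idx, helix in enumerate(helices):
        n_bp = len(helix)
        cum_pairs += n_bp
        helix_res = [r for i, j in helix for r in (i, j)]
        inner_i, inner_j = helix[-1]
        if h_idx + 1 < len(helices):
            next_i, next_j = helices[h_idx + 1][0]
            bulge_res = list(range(inner_i + 1, next_i)) + list(
                range(next_j + 1, inner_j)
            )
            full = False
        else:
            bulge_res = list(range(inner_i + 1, inner_j))  # hairpin loop
            full = True
        released = sorted(helix_res + bulge_res)
        cum_nt += len(released)
        opened.extend(released)
        intermediates.append(
            UnzippingIntermediate(
                name=f"I{h_idx + 1}" if not full else "U",
                n_opened_pairs=cum_pairs,
                n_unfolded_nt=cum_nt,
                expected_delta_contour=expected_contour_gain(
                    cum_nt, model, closes_hairpin=full
                ),
                is_full_unfold=full,
                opened_residues=tuple(
                    structure.residue_number(r) for r in sorted(opened)
                ),
            )
        )
    # conservation: everything inside the outermost pair is released
    assert cum_nt == span_first[1] - span_first[0] + 1
    return intermediates


@dataclass
class MatchResult:
    """Assignment of observed contour gains to enumerated intermediates."""

    matches: list  # (observed ΔL, intermediate or None, residual, ambiguous)
    unmatched: list  # observed ΔL values without a candidate (misfold candidates)
    total_abs_residual: float


def match_intermediates(
    observed: Sequence[float],
    enumerated: Sequence[UnzippingIntermediate],
    tolerance: float = 1.5,
) -> MatchResult:
    """Map observed ΔL values onto expected intermediates (nearest within tol).

    The default 1.5 nm tolerance corresponds to 2–3 nt.  Observations with
    two candidates inside the tolerance are flagged ambiguous; those with
    none are reported as misfold candidates.  Deterministic and
    order-independent.
    """
    if not len(observed) or not len(enumerated):
        raise ValueError("both observed and enumerated lists must be non-empty")
    expected = np.array([it.expected_delta_contour for it in enumerated])
    matches = []
    unmatched = []
    total = 0.0
    for obs in sorted(observed):
        resid = np.abs(expected - obs)
        within = np.flatnonzero(resid <= tolerance)
        if len(within) == 0:
            unmatched.append(float(obs))
            matches.append((float(obs), None, float(resid.min()), False))
            continue
        best = int(within[np.argmin(resid[within])])
        ambiguous = len(within) > 1
        matches.append((float(obs), enumerated[best], float(resid[best]), ambiguous))
        total += float(resid[best])
    return MatchResult(matches=matches, unmatched=unmatched, total_abs_residual=total)


def compare_candidate_structures(
    observed: Sequence[float],
    candidates: dict,
    model: ElasticModel,
    tolerance: float = 1.5,
) -> dict:
    """Score competing secondary-structure predictions against observed ΔLs.

    For each named candidate structure the unzipping intermediates are
    enumerated and matched; the structure with the smallest sum of
    absolute residuals (unmatched observations count the distance to the
    nearest candidate) better explains the data.
    """
    scores = {}
    for name, structure in candidates.items():
        inter = enumerate_unzipping_intermediates(structure, model)
        result = match_intermediates(observed, inter, tolerance)
        penalty = sum(
            min(abs(it.expected_delta_contour - o) for it in inter)
            for o in result.unmatched
        )
        scores[name] = {
            "match": result,
            "score": result.total_abs_residual + penalty,
            "n_unmatched": len(result.unmatched),
        }
    best = min(scores, key=lambda k: scores[k]["score"])
    return {"scores": scores, "best": best}
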