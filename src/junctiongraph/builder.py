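"""Construct scaled planar tree graphs for junctions from their topology.

Distance parameterization: the gap between coaxially stacked helices is
s0 = 2.75*L + 3.91 Å (L = intervening nucleotides), helix edge length is
2.87*(b-1) Å (b = base pairs), and unstacked helices sit at class-specific
lateral distances from the stack axis (parallel 20.48 Å, perpendicular
19.95 Å, diagonal 21.17 Å) with their edge at the class angle (0°/90°/45°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .graph import CENTROID, DISTAL, PROXIMAL, TreeGraph, vertex_label
from .secondary import Junction
from .topology import JunctionTopology, normalize_family


@dataclass(frozen=True)
class ScalingParameters:
    """Published scaling constants plus layout conventions."""

    s0_slope: float = 2.75  # Å per intervening nt
    s0_intercept: float = 3.91  # Å
    base_rise: float = 2.87  # Å per bp step
    d_parallel: float = 20.48  # Å
    d_perpendicular: float = 19.95  # Å
    d_diagonal: float = 21.17  # Å
    angle_parallel: float = 0.0  # degrees, vs stack axis
    angle_perpendicular: float = 90.0
    angle_diagonal: float = 45.0
    side_sign: float = 1.0  # +1: unstacked helices on +y of the stack axis
    radial_radius: float = 10.0  # Å, stackless fallback layout
    unstacked_spread: float = 10.0  # Å between multiple unstacked proximal x-offsets

    def __post_init__(self):
        for name in ("d_parallel", "d_perpendicular", "d_diagonal", "base_rise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_parallel", "angle_perpendicular", "angle_diagonal"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180] degrees")


DEFAULT_PARAMETERS = ScalingParameters()

ARRANGEMENT_CLASSES = ("parallel", "perpendicular", "diagonal")

#: 3-way family -> arrangement class of the unstacked helix.
FAMILY_ARRANGEMENT_3WAY = {"A": "perpendicular", "B": "diagonal", "C": "parallel"}

#: 4-way two-stack family -> (inter-stack angle class used for both the
#: direction of the second stack axis and the center offset distance).
FAMILY_STACK_ANGLE_4WAY = {
    "H": "parallel",
    "cH": "parallel",
    "cL": "perpendicular",
    "cX": "diagonal",
    "X": "diagonal",
}

#: 4-way single-stack family -> arrangement classes of the two unstacked helices.
FAMILY_ARRANGEMENT_4WAY = {
    "cK": ("diagonal", "diagonal"),
    "pi": ("perpendicular", "perpendicular"),
    "cW": ("perpendicular", "parallel"),
    "psi": ("diagonal", "perpendicular"),
}


def coaxial_spacing(L: int, params: ScalingParameters = DEFAULT_PARAMETERS) -> float:
    """Gap (Å) between the proximal vertices of two coaxially stacked helices."""
    if L < 0:
        raise ValueError("intervening nucleotide count must be >= 0")
    return params.s0_slope * L + params.s0_intercept


def helix_edge_length(b: int, params: ScalingParameters = DEFAULT_PARAMETERS) -> float:
    """Edge length (Å) of a helix of b base pairs; requires b >= 2."""
    if b < 2:
        raise ValueError("a helix requires at least two base pairs")
    return params.base_rise * (b - 1)


def arrangement_distance(cls: str, params: ScalingParameters = DEFAULT_PARAMETERS) -> float:
    if cls == "parallel":
        return params.d_parallel
    if cls == "perpendicular":
        return params.d_perpendicular
    if cls == "diagonal":
        return params.d_diagonal
    raise ValueError(f"unknown arrangement class {cls!r}")


def arrangement_angle(cls: str, params: ScalingParameters = DEFAULT_PARAMETERS) -> float:
    if cls == "parallel":
        return params.angle_parallel
    if cls == "perpendicular":
        return params.angle_perpendicular
    if cls == "diagonal":
        return params.angle_diagonal
    raise ValueError(f"unknown arrangement class {cls!r}")


def intervening_loop_nt(junction: Junction, hid_a: str, hid_b: str) -> int:
    """Nucleotides between two stacked helices along the junction loop.

    For helices adjacent around the loop this is the single loop segment
    between them; for diagonal 4-way stacks the shorter around-the-loop path
    sum is used.
    """
    ids = junction.helix_ids
    a, b = sorted((ids.index(hid_a), ids.index(hid_b)))
    n = junction.degree
    if b == a + 1:
        return junction.loops[a].length
    if a == 0 and b == n - 1:
        return junction.loops[b].length
    fwd = sum(junction.loops[k % n].length for k in range(a, b))
    bwd = sum(junction.loops[k % n].length for k in range(b, a + n))
    return min(fwd, bwd)


def _direction(angle_deg: float, side: float) -> np.ndarray:
    rad = math.radians(angle_deg)
    return np.array([math.cos(rad), side * math.sin(rad), 0.0])


def _place_stack(vertices, ids, lengths, gap, center, axis):
    """Two antiparallel collinear helix edges about ``center`` along ``axis``."""
    lo, hi = sorted(ids, key=lambda h: int(h[1:]))
    axis = np.asarray(axis, float)
    vertices[vertex_label(lo, PROXIMAL)] = center - (gap / 2.0) * axis
    vertices[vertex_label(lo, DISTAL)] = center - (gap / 2.0 + lengths[lo]) * axis
    vertices[vertex_label(hi, PROXIMAL)] = center + (gap / 2.0) * axis
    vertices[vertex_label(hi, DISTAL)] = center + (gap / 2.0 + lengths[hi]) * axis


def _place_unstacked(vertices, ids, lengths, classes, params):
    m = len(ids)
    for k, (hid, cls) in enumerate(zip(ids, classes)):
        d = arrangement_distance(cls, params)
        theta = arrangement_angle(cls, params)
        x_off = (k - (m - 1) / 2.0) * params.unstacked_spread
        prox = np.array([x_off, params.side_sign * d, 0.0])
        direction = _direction(theta, params.side_sign)
        vertices[vertex_label(hid, PROXIMAL)] = prox
        vertices[vertex_label(hid, DISTAL)] = prox + lengths[hid] * direction


def build_graph(
    junction: Junction,
    topology: JunctionTopology,
    params: ScalingParameters = DEFAULT_PARAMETERS,
) -> TreeGraph:
    """Scaled planar tree graph (z = 0) realizing a junction topology."""
    n = junction.degree
    ids = junction.helix_ids
    topology.validate_for_degree(n)
    for stack in topology.stacks:
        for hid in stack:
            if hid not in ids:
                raise ValueError(f"stacked helix {hid!r} absent from junction {ids}")
    family = normalize_family(topology.family)
    lengths = {h.id: helix_edge_length(h.bp_count, params) for h in junction.helices}
    stacks = sorted(
        (tuple(sorted(s, key=lambda h: int(h[1:]))) for s in topology.stacks),
        key=lambda s: int(s[0][1:]),
    )
    vertices: dict = {}

    if not stacks:
        for k, hid in enumerate(ids):
            ang = 2.0 * math.pi * k / n
            u = np.array([math.cos(ang), math.sin(ang), 0.0])
            vertices[vertex_label(hid, PROXIMAL)] = params.radial_radius * u
            vertices[vertex_label(hid, DISTAL)] = (params.radial_radius + lengths[hid]) * u
    else:
        primary = stacks[0]
        gap0 = coaxial_spacing(intervening_loop_nt(junction, *primary), params)
        _place_stack(vertices, primary, lengths, gap0, np.zeros(3), np.array([1.0, 0.0, 0.0]))
        unstacked = [h for h in ids if not any(h in s for s in stacks)]
        if len(stacks) == 2:
            cls = FAMILY_STACK_ANGLE_4WAY.get(family, "perpendicular")
            gap1 = coaxial_spacing(intervening_loop_nt(junction, *stacks[1]), params)
            center = np.array([0.0, params.side_sign * arrangement_distance(cls, params), 0.0])
            axis = _direction(arrangement_angle(cls, params), params.side_sign)
            _place_stack(vertices, stacks[1], lengths, gap1, center, axis)
        elif unstacked:
            if n == 3:
                classes = [FAMILY_ARRANGEMENT_3WAY.get(family, "perpendicular")]
            else:
                classes = list(
                    FAMILY_ARRANGEMENT_4WAY.get(family, ("perpendicular",) * len(unstacked))
                )
            _place_unstacked(vertices, unstacked, lengths, classes, params)

    graph = TreeGraph(
        helix_ids=list(ids),
        vertices={**vertices, CENTROID: np.zeros(3)},
        bp_counts={h.id: h.bp_count for h in junction.helices},
        meta={
            "source": "model",
            "family": family,
            "stacks": topology.stack_label,
            "loop_lengths": list(junction.loop_lengths),
        },
    )
    graph.recenter_centroid()
    return graph


# ---------------------------------------------------------------------------
# data-driven family templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyTemplate:
    """Mean unit helix-edge directions per helix slot for one family."""

    family: str
    directions: dict  # helix id -> unit np.ndarray(3,)
    degenerate: frozenset  # helix ids whose mean direction was ill-defined


class TemplateError(ValueError):
    pass


def derive_family_template(graphs, min_norm: float = 0.2) -> dict:
    """Per-family mean helix directions after mutual superposition.

    Input graphs carry their family in ``meta['family']``. Graphs of each
    family are superposed onto the first member; helix slots whose averaged
    direction nearly cancels (norm < ``min_norm``) are flagged degenerate.
    """
    from .compare import superpose  # local import: avoid cycle at module load

    by_family: dict = {}
    for g in graphs:
        fam = normalize_family(g.meta.get("family", ""))
        if not fam:
            raise TemplateError("graph lacks a family label in meta['family']")
        by_family.setdefault(fam, []).append(g)
    templates = {}
    for fam, members in by_family.items():
        ref = members[0]
        sums = {h: np.zeros(3) for h in ref.helix_ids}
        for g in members:
            rot, _ = superpose(ref, g)
            for h in ref.helix_ids:
                v = rot @ g.helix_vector(h)
                norm = np.linalg.norm(v)
                if norm == 0:
                    raise TemplateError(f"zero-length helix edge {h} in family {fam}")
                sums[h] += v / norm
        directions = {}
        degenerate = set()
        for h, s in sums.items():
            mean = s / len(members)
            norm = np.linalg.norm(mean)
            if norm < min_norm:
                degenerate.add(h)
                directions[h] = mean
            else:
                directions[h] = mean / norm
        templates[fam] = FamilyTemplate(fam, directions, frozenset(degenerate))
    return templates


def parameters_with(overrides: dict) -> ScalingParameters:
    """ScalingParameters with a dict of field overrides (unknown keys rejected)."""
    return replace(DEFAULT_PARAMETERS, **overrides)
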