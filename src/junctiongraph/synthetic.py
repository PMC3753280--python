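"""Ideal A-form-like helices and composed junction structures with known graphs.

These are geometry fixtures, not physical models: each base pair carries only
the atoms the pipeline consumes (C1', C8/C6, and the canonical hydrogen-bond
atoms), laid out so that the constructed vertex of every pair falls exactly
on the helical axis and the WC-detection windows are satisfied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import TreeGraph
from .secondary import SecondaryStructure, find_junctions
from .translate import BasePair, Residue, ResidueTable

CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}
PURINES = {"A", "G"}

# Local pair frame: the helical axis passes through the origin (z out of the
# pair plane). M = C1' midpoint = (0,-4,0); the C8-C6 line is y=0, so the
# projected vertex O' = M + 4*unit(P-M) lands exactly at the origin.
_PURINE_TEMPLATE = {
    "A": {"C1'": (-5.2, -4.0, 0.0), "C8": (-2.2, 0.0, 0.0), "N1": (-0.7, 0.5, 0.0), "N6": (-0.7, 1.6, 0.0)},
    "G": {"C1'": (-5.2, -4.0, 0.0), "C8": (-2.2, 0.0, 0.0), "N1": (-0.7, 0.5, 0.0), "O6": (-0.7, 1.6, 0.0), "N2": (-0.7, -0.6, 0.0)},
}
_PYRIMIDINE_TEMPLATE = {
    "C": {"C1'": (5.2, -4.0, 0.0), "C6": (2.2, 0.0, 0.0), "N3": (0.7, 0.5, 0.0), "N4": (0.7, 1.6, 0.0), "O2": (0.7, -0.6, 0.0)},
    "U": {"C1'": (5.2, -4.0, 0.0), "C6": (2.2, 0.0, 0.0), "N3": (0.7, 0.5, 0.0), "O4": (0.7, 1.6, 0.0), "O2": (0.7, -0.6, 0.0)},
}


@dataclass(frozen=True)
class HelixSpec:
    """Watson-Crick pair letters plus rise/twist of an ideal helix."""

    pair_letters: tuple  # ((five_prime, three_prime), ...) length b
    rise: float = 2.87  # Å per bp step, matches the helix edge-length scale
    twist: float = 32.7  # degrees per bp step

    def __post_init__(self):
        if len(self.pair_letters) < 2:
            raise ValueError("a helix requires at least two base pairs")
        for five, three in self.pair_letters:
            if five + three not in CANONICAL:
                raise ValueError(f"non-canonical pair {five}{three}")

    @property
    def bp_count(self) -> int:
        return len(self.pair_letters)

    @classmethod
    def gc(cls, b: int, **kw) -> "HelixSpec":
        return cls(tuple(("G", "C") for _ in range(b)), **kw)


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking the +z axis onto ``direction`` (unit)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, d))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _pair_atoms(five: str, three: str, k: int, spec: HelixSpec):
    """Atoms of pair k (5'-strand residue, 3'-strand residue) in helix frame."""
    if five in PURINES:
        tmpl5, tmpl3 = _PURINE_TEMPLATE[five], _PYRIMIDINE_TEMPLATE[three]
    else:
        tmpl5, tmpl3 = _PYRIMIDINE_TEMPLATE[five], _PURINE_TEMPLATE[three]
    ang = math.radians(k * spec.twist)
    rot = np.array(
        [[math.cos(ang), -math.sin(ang), 0.0], [math.sin(ang), math.cos(ang), 0.0], [0.0, 0.0, 1.0]]
    )
    lift = np.array([0.0, 0.0, k * spec.rise])

    def place(tmpl):
        return {name: rot @ np.asarray(xyz) + lift for name, xyz in tmpl.items()}

    return place(tmpl5), place(tmpl3)


def ideal_helix(spec: HelixSpec, rotation=None, translation=None) -> ResidueTable:
    """Duplex whose helical axis is the (transformed) z-axis through the origin.

    Pair k sits at axial height k*rise; residues are ordered 5'-strand then
    3'-strand, pairing (k, 2b-1-k), chain A, residue numbers 1..2b.
    """
    b = spec.bp_count
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, float)
    res5: list = []
    res3: list = []
    for k, (five, three) in enumerate(spec.pair_letters):
        a5, a3 = _pair_atoms(five, three, k, spec)
        a5 = {n: rot @ v + trans for n, v in a5.items()}
        a3 = {n: rot @ v + trans for n, v in a3.items()}
        res5.append(Residue(("A", k + 1, " "), five, a5))
        res3.append(Residue(("A", 2 * b - k, " "), three, a3))
    return ResidueTable(res5 + list(reversed(res3)))


def ideal_helix_pairs(spec: HelixSpec) -> list:
    b = spec.bp_count
    return [
        BasePair(k, 2 * b - 1 - k, "".join(sorted((f, t))).replace("CG", "GC"))
        for k, (f, t) in enumerate(spec.pair_letters)
    ]


# ---------------------------------------------------------------------------
# junction layout (secondary structure) and full synthesis
# ---------------------------------------------------------------------------

def _layout(bp_counts, loop_lens, cap_len=4, letters=None):
    """Sequence/brackets of an n-way junction (H1 closing, children hairpins).

    Returns (sequence, brackets, per-helix (strand5 start, strand3 start)).
    """
    n = len(bp_counts)
    if len(loop_lens) != n:
        raise ValueError("need one loop length per helix")
    if letters is None:
        letters = [tuple(("G", "C") for _ in range(b)) for b in bp_counts]
    seq: list = []
    db: list = []
    starts = [[None, None] for _ in range(n)]

    def emit(chars, brackets):
        seq.extend(chars)
        db.extend(brackets)

    def strand5(slot):
        starts[slot][0] = len(seq)
        emit([p[0] for p in letters[slot]], "(" * bp_counts[slot])

    def strand3(slot):
        starts[slot][1] = len(seq)
        emit([p[1] for p in reversed(letters[slot])], ")" * bp_counts[slot])

    strand5(0)
    emit("A" * loop_lens[0], "." * loop_lens[0])
    for slot in range(1, n):
        strand5(slot)
        emit("A" * cap_len, "." * cap_len)
        strand3(slot)
        ll = loop_lens[slot] if slot < n - 1 else loop_lens[n - 1]
        emit("A" * ll, "." * ll)
    strand3(0)
    return "".join(seq), "".join(db), [tuple(s) for s in starts]


def make_junction_ss(bp_counts, loop_lens, cap_len=4):
    """Dot-bracket text of an n-way junction with given helix/loop sizes."""
    seq, db, _ = _layout(list(bp_counts), list(loop_lens), cap_len)
    return seq + "\n" + db + "\n"


@dataclass
class SyntheticJunction:
    """A composed junction structure plus all its ground truth."""

    table: ResidueTable
    pairs: list  # BasePair, sequence indices
    ss: SecondaryStructure
    junction: object  # secondary.Junction
    blueprint: TreeGraph


def synthesize_junction(
    blueprint: TreeGraph, specs=None, cap_len: int = 4, length_tolerance: float = 0.5
) -> SyntheticJunction:
    """Place ideal helices on a blueprint's edges; loop residues are spacers.

    ``specs`` maps helix id -> HelixSpec (default: GC helices with the
    blueprint's bp counts). Blueprint edge lengths must equal (b-1)*rise
    within ``length_tolerance`` Å.
    """
    ids = list(blueprint.helix_ids)
    n = len(ids)
    if specs is None:
        specs = {}
    specs = {h: specs.get(h, HelixSpec.gc(blueprint.bp_counts[h])) for h in ids}
    for h in ids:
        expected = (specs[h].bp_count - 1) * specs[h].rise
        actual = float(np.linalg.norm(blueprint.helix_vector(h)))
        if abs(actual - expected) > length_tolerance:
            raise ValueError(
                f"helix {h}: blueprint edge {actual:.2f} Å incompatible with "
                f"{specs[h].bp_count} bp at rise {specs[h].rise} ({expected:.2f} Å)"
            )
    loop_lens = blueprint.meta.get("loop_lengths") or [4] * n
    bp_counts = [specs[h].bp_count for h in ids]
    letters = [specs[h].pair_letters for h in ids]
    sequence, brackets, starts = _layout(bp_counts, list(loop_lens), cap_len, letters)

    residues: dict = {}
    pairs: list = []
    centroid = blueprint.proximal_mean()
    for slot, hid in enumerate(ids):
        spec = specs[hid]
        b = spec.bp_count
        s5, s3 = starts[slot]
        prox = blueprint.proximal(hid)
        direction = blueprint.helix_vector(hid)
        rot = _rotation_to(direction)
        closing = slot == 0  # H1's proximal terminal pair is its inner pair
        for k in range(b):
            m = (b - 1 - k) if closing else k  # outer->inner pair index
            five, three = spec.pair_letters[m]
            a5, a3 = _pair_atoms(five, three, k, spec)
            i5 = s5 + m
            i3 = s3 + (b - 1 - m)
            residues[i5] = Residue(("A", i5 + 1, " "), five, {nm: rot @ v + prox for nm, v in a5.items()})
            residues[i3] = Residue(("A", i3 + 1, " "), three, {nm: rot @ v + prox for nm, v in a3.items()})
        for m in range(b):
            i5, i3 = s5 + m, s3 + (b - 1 - m)
            f, t = spec.pair_letters[m]
            pairs.append(BasePair(i5, i3, "".join(sorted((f, t))).replace("CG", "GC")))
    # unpaired loop/cap residues: inert C1'-only spacers below the graph plane
    for idx, base in enumerate(sequence):
        if idx not in residues:
            pos = centroid + np.array([0.6 * idx, 0.0, -15.0])
            residues[idx] = Residue(("A", idx + 1, " "), base, {"C1'": pos})
    table = ResidueTable([residues[i] for i in range(len(sequence))])
    ss = SecondaryStructure(sequence, frozenset((p.i, p.j) for p in pairs))
    junctions = find_junctions(ss)
    if len(junctions) != 1:
        raise RuntimeError(f"synthesis produced {len(junctions)} junctions, expected 1")
    pairs.sort(key=lambda p: p.i)
    return SyntheticJunction(table, pairs, ss, junctions[0], blueprint)


def write_pdb(table: ResidueTable) -> str:
    """Minimal PDB text (ATOM records only) for a ResidueTable."""
    lines = []
    serial = 1
    for res in table.residues:
        chain, resnum, icode = res.key
        for name, xyz in res.atoms.items():
            pdb_name = name if len(name) >= 4 else f" {name:<3s}"
            element = next(c for c in name if c.isalpha())
            lines.append(
                f"ATOM  {serial:5d} {pdb_name:<4s} {res.name:>3s} {chain:1s}"
                f"{resnum:4d}{icode:1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
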