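"""Translate solved RNA 3D structures into the tree-graph representation.

Each helix vertex is built from a terminal base pair in three steps: the
midpoint M of the two C1' atoms, the orthogonal projection P of M onto the
line through the purine C8 and pyrimidine C6 atoms, and the vertex
O' = M + 4 Å * unit(P - M). The junction centroid is the mean of the n
proximal vertices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import CENTROID, TreeGraph, vertex_label
from .secondary import Junction, SecondaryStructure

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

_RESNAME_MAP = {
    "A": "A", "ADE": "A", "RA": "A", "A3": "A", "A5": "A",
    "G": "G", "GUA": "G", "RG": "G", "G3": "G", "G5": "G",
    "C": "C", "CYT": "C", "RC": "C", "C3": "C", "C5": "C",
    "U": "U", "URA": "U", "URI": "U", "RU": "U", "U3": "U", "U5": "U",
}

#: donor/acceptor atom pairs (purine atom, pyrimidine atom) per WC class.
HBOND_ATOMS = {
    "AU": (("N1", "N3"), ("N6", "O4")),
    "GC": (("N1", "N3"), ("O6", "N4"), ("N2", "O2")),
    "GU": (("O6", "N3"), ("N1", "O2")),
}

C1C1_DISTANCE = 10.4
C1C1_TOLERANCE = 1.5
HBOND_CUTOFF = 3.5


class TranslationError(ValueError):
    pass


class DegenerateGeometryError(TranslationError):
    pass


class MissingAtomError(TranslationError):
    """Signals that a base pair lacks atoms needed for vertex placement."""


@dataclass
class Residue:
    """One nucleotide: chain/number key, one-letter name, atom coordinates."""

    key: tuple  # (chain id, residue number, insertion code)
    name: str
    atoms: dict  # normalized atom name -> np.ndarray(3,)

    def atom(self, name: str):
        return self.atoms.get(name)


@dataclass
class ResidueTable:
    """Ordered nucleotide residues of a structure; index = sequence position."""

    residues: list

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    @property
    def sequence(self) -> str:
        return "".join(r.name for r in self.residues)

    def index_of(self, chain: str, resnum: int, icode: str = " ") -> int:
        for i, r in enumerate(self.residues):
            if r.key == (chain, resnum, icode):
                return i
        raise KeyError((chain, resnum, icode))


@dataclass(frozen=True)
class BasePair:
    """Sequence-index base pair with its Watson-Crick class (AU/GC/GU)."""

    i: int
    j: int
    klass: str

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a base pair joins two distinct residues")


def _normalize_atom_name(name: str) -> str:
    return name.strip().replace("*", "'")


def load_structure(path) -> ResidueTable:
    """Read a PDB or mmCIF file into a ResidueTable (first model, altloc A)."""
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(iter(structure))
    residues = []
    for chain in model:
        for res in chain:
            name = _RESNAME_MAP.get(res.get_resname().strip())
            if name is None:
                continue
            atoms = {}
            for atom in res:
                coord = np.asarray(atom.get_coord(), dtype=float)
                if not np.all(np.isfinite(coord)):
                    raise TranslationError(f"non-finite coordinates in residue {res.get_id()}")
                atoms[_normalize_atom_name(atom.get_name())] = coord
            het, resnum, icode = res.get_id()
            residues.append(Residue((chain.get_id(), resnum, icode), name, atoms))
    return ResidueTable(residues)


def basepair_vertex(
    c1_a: np.ndarray, c1_b: np.ndarray, c8: np.ndarray, c6: np.ndarray
) -> np.ndarray:
    """Vertex origin O' = M + 4 Å toward the projection of M on the C8-C6 line."""
    c1_a, c1_b, c8, c6 = (np.asarray(x, float) for x in (c1_a, c1_b, c8, c6))
    m = (c1_a + c1_b) / 2.0
    axis = c6 - c8
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise DegenerateGeometryError("C8 and C6 atoms coincide")
    u = axis / norm
    p = c8 + np.dot(m - c8, u) * u
    w = p - m
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise DegenerateGeometryError("midpoint lies on the C8-C6 line")
    return m + 4.0 * w / wn


def _vertex_from_pair(res_i: Residue, res_j: Residue) -> np.ndarray:
    if res_i.name in PURINES and res_j.name in PYRIMIDINES:
        pur, pyr = res_i, res_j
    elif res_j.name in PURINES and res_i.name in PYRIMIDINES:
        pur, pyr = res_j, res_i
    else:
        raise MissingAtomError(
            f"pair {res_i.name}{res_j.name} lacks a purine/pyrimidine partition"
        )
    needed = (res_i.atom("C1'"), res_j.atom("C1'"), pur.atom("C8"), pyr.atom("C6"))
    if any(a is None for a in needed):
        raise MissingAtomError("missing C1'/C8/C6 atom")
    return basepair_vertex(*needed)


def _pair_class(name_i: str, name_j: str):
    combo = "".join(sorted((name_i, name_j)))
    return {"AU": "AU", "CG": "GC", "GU": "GU"}.get(combo)


def detect_wc_pairs(table: ResidueTable) -> list:
    """Geometric Watson-Crick pair detection (AU/GC/GU), one partner per residue.

    A candidate pair needs a C1'-C1' distance of 10.4 +/- 1.5 Å and all
    canonical donor-acceptor distances below 3.5 Å; among conflicting
    candidates the best-scoring (smallest mean H-bond distance) is kept.
    """
    candidates = []
    for i in range(len(table)):
        ri = table[i]
        c1i = ri.atom("C1'")
        if c1i is None:
            continue
        for j in range(i + 1, len(table)):
            rj = table[j]
            klass = _pair_class(ri.name, rj.name)
            if klass is None:
                continue
            c1j = rj.atom("C1'")
            if c1j is None:
                continue
            if abs(np.linalg.norm(c1i - c1j) - C1C1_DISTANCE) > C1C1_TOLERANCE:
                continue
            pur, pyr = (ri, rj) if ri.name in PURINES else (rj, ri)
            dists = []
            ok = True
            for pur_atom, pyr_atom in HBOND_ATOMS[klass]:
                a, b = pur.atom(pur_atom), pyr.atom(pyr_atom)
                if a is None or b is None:
                    ok = False
                    break
                d = float(np.linalg.norm(a - b))
                if d >= HBOND_CUTOFF:
                    ok = False
                    break
                dists.append(d)
            if ok and dists:
                candidates.append((sum(dists) / len(dists), i, j, klass))
    candidates.sort()
    used: set = set()
    pairs = []
    for _, i, j, klass in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(BasePair(i, j, klass))
    pairs.sort(key=lambda p: (p.i, p.j))
    return pairs


def read_pair_table(text: str, table: ResidueTable) -> list:
    """Parse a tab-separated annotation (chain, resnum, chain, resnum, class)."""
    pairs = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split("\t") if "\t" in ln else ln.split()
        if len(cols) < 5:
            raise ValueError(f"annotation line needs 5 columns: {ln!r}")
        i = table.index_of(cols[0], int(cols[1]))
        j = table.index_of(cols[2], int(cols[3]))
        pairs.append(BasePair(min(i, j), max(i, j), cols[4]))
    return pairs


def write_pair_table(pairs, table: ResidueTable) -> str:
    lines = []
    for p in pairs:
        ci, ni, _ = table[p.i].key
        cj, nj, _ = table[p.j].key
        lines.append(f"{ci}\t{ni}\t{cj}\t{nj}\t{p.klass}")
    return "\n".join(lines) + "\n"


def secondary_structure_from_pairs(table: ResidueTable, pairs) -> SecondaryStructure:
    """Assemble the SecondaryStructure whose junctions map this structure."""
    return SecondaryStructure(table.sequence, frozenset((p.i, p.j) for p in pairs))


def structure_to_graph(table: ResidueTable, junction: Junction) -> TreeGraph:
    """Native tree graph of a junction: 2n+1 vertices, 2n edges.

    For each junction helix the two terminal base pairs give the proximal and
    distal vertices; pairs with missing atoms are skipped toward the helix
    interior (a helix with fewer than two usable pairs is an error).
    """
    vertices: dict = {}
    for jh in junction.helices:
        usable = []
        for (i, j) in jh.pairs_proximal_first:
            try:
                usable.append(_vertex_from_pair(table[i], table[j]))
            except MissingAtomError:
                usable.append(None)
        present = [k for k, v in enumerate(usable) if v is not None]
        if len(present) < 2:
            raise TranslationError(
                f"helix {jh.id}: fewer than two base pairs with usable atoms"
            )
        vertices[vertex_label(jh.id, "proximal")] = usable[present[0]]
        vertices[vertex_label(jh.id, "distal")] = usable[present[-1]]
    graph = TreeGraph(
        helix_ids=list(junction.helix_ids),
        vertices={**vertices, CENTROID: np.zeros(3)},
        bp_counts={h.id: h.bp_count for h in junction.helices},
        meta={"source": "native"},
    )
    graph.recenter_centroid()
    return graph


def structure_junction_graphs(table: ResidueTable, pairs=None) -> list:
    """All junction graphs of a structure; pairs detected when not supplied."""
    from .secondary import find_junctions, remove_pseudoknots

    if pairs is None:
        pairs = detect_wc_pairs(table)
    ss = remove_pseudoknots(secondary_structure_from_pairs(table, pairs))
    return [(j, structure_to_graph(table, j)) for j in find_junctions(ss)]
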