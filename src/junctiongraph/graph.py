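"""Tree-graph representation of a junction: 2n+1 labeled vertices, 2n edges.

Each helix contributes a proximal vertex (facing the junction loop), a distal
vertex, and one helix edge; a centroid vertex — the arithmetic mean of the n
proximal vertices — is joined to every proximal vertex by a connector edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

PROXIMAL = "proximal"
DISTAL = "distal"
CENTROID = "centroid"


def vertex_label(helix_id: str, role: str) -> str:
    return f"{helix_id}.{role}"


@dataclass
class TreeGraph:
    """Labeled 3D tree graph of one n-way junction."""

    helix_ids: list
    vertices: dict  # label -> np.ndarray(3,)
    bp_counts: dict  # helix id -> int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = {k: np.asarray(v, dtype=float) for k, v in self.vertices.items()}
        expected = {vertex_label(h, r) for h in self.helix_ids for r in (PROXIMAL, DISTAL)}
        expected.add(CENTROID)
        if set(self.vertices) != expected:
            missing = expected - set(self.vertices)
            extra = set(self.vertices) - expected
            raise ValueError(f"vertex labels mismatch (missing={missing}, extra={extra})")

    @property
    def degree(self) -> int:
        return len(self.helix_ids)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> list:
        """The 2n edges: n helix edges (proximal->distal) + n connectors."""
        out = []
        for h in self.helix_ids:
            out.append(
                {
                    "type": "helix",
                    "helix": h,
                    "from": vertex_label(h, PROXIMAL),
                    "to": vertex_label(h, DISTAL),
                    "bp_count": self.bp_counts.get(h),
                }
            )
        for h in self.helix_ids:
            out.append(
                {"type": "connector", "from": CENTROID, "to": vertex_label(h, PROXIMAL)}
            )
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    # -- geometry helpers ---------------------------------------------------

    def vertex(self, label: str) -> np.ndarray:
        return self.vertices[label]

    def proximal(self, helix_id: str) -> np.ndarray:
        return self.vertices[vertex_label(helix_id, PROXIMAL)]

    def distal(self, helix_id: str) -> np.ndarray:
        return self.vertices[vertex_label(helix_id, DISTAL)]

    def helix_vector(self, helix_id: str) -> np.ndarray:
        """Edge vector of a helix, oriented proximal -> distal."""
        return self.distal(helix_id) - self.proximal(helix_id)

    @property
    def label_order(self) -> list:
        order = []
        for h in self.helix_ids:
            order.extend([vertex_label(h, PROXIMAL), vertex_label(h, DISTAL)])
        order.append(CENTROID)
        return order

    def coordinates(self, labels=None) -> np.ndarray:
        labels = labels if labels is not None else self.label_order
        return np.array([self.vertices[l] for l in labels])

    def proximal_mean(self) -> np.ndarray:
        return np.mean([self.proximal(h) for h in self.helix_ids], axis=0)

    def recenter_centroid(self) -> None:
        self.vertices[CENTROID] = self.proximal_mean()

    # -- I/O ----------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "helix_ids": list(self.helix_ids),
            "bp_counts": dict(self.bp_counts),
            "vertices": {k: [float(x) for x in v] for k, v in sorted(self.vertices.items())},
            "edges": self.edges,
            "meta": self.meta,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "TreeGraph":
        return cls(
            helix_ids=list(d["helix_ids"]),
            vertices={k: np.asarray(v, float) for k, v in d["vertices"].items()},
            bp_counts={k: int(v) for k, v in d.get("bp_counts", {}).items()},
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeGraph":
        return cls.from_dict(json.loads(text))

    def to_pseudo_pdb(self) -> str:
        """One pseudo-atom per vertex plus CONECT records per edge."""
        labels = self.label_order
        serial = {l: k + 1 for k, l in enumerate(labels)}
        lines = []
        for l in labels:
            x, y, z = self.vertices[l]
            name = "CEN" if l == CENTROID else ("P" if l.endswith(PROXIMAL) else "D")
            resname = "VRT"
            lines.append(
                f"HETATM{serial[l]:>5} {name:<4}{resname:>4} A{serial[l]:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        for e in self.edges:
            lines.append(f"CONECT{serial[e['from']]:>5}{serial[e['to']]:>5}")
        lines.append("END")
        return "\n".join(lines) + "\n"
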