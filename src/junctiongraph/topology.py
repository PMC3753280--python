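"""Junction topology labels: coaxial-stack sets and family types."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Family labels per junction degree (ASCII; unicode aliases normalized below).
FAMILIES = {
    3: ("none", "A", "B", "C"),
    4: ("none", "H", "cH", "cL", "cK", "pi", "cW", "psi", "cX", "X"),
}

_FAMILY_ALIASES = {"π": "pi", "Π": "pi", "Ψ": "psi", "ψ": "psi", "PI": "pi", "PSI": "psi"}

#: Admissible coaxial-stack configurations per degree, as canonical labels.
STACK_LABELS = {
    3: ("none", "H1H2", "H1H3", "H2H3"),
    4: (
        "none",
        "H1H2",
        "H1H3",
        "H1H4",
        "H2H3",
        "H2H4",
        "H3H4",
        "H1H2+H3H4",
        "H1H3+H2H4",
        "H1H4+H2H3",
    ),
}


def normalize_family(family: str) -> str:
    return _FAMILY_ALIASES.get(family, family)


def stacks_to_label(stacks) -> str:
    """Canonical label for a set of unordered helix-id pairs."""
    if not stacks:
        return "none"
    parts = sorted("".join(sorted(pair, key=lambda h: int(h[1:]))) for pair in stacks)
    return "+".join(parts)


def label_to_stacks(label: str) -> frozenset:
    if label in ("", "none", "-"):
        return frozenset()
    stacks = set()
    for part in label.split("+"):
        ids = part.replace("H", " H").split()
        if len(ids) != 2:
            raise ValueError(f"malformed stack label {label!r}")
        stacks.add(frozenset(ids))
    return frozenset(stacks)


@dataclass(frozen=True)
class JunctionTopology:
    """Predicted or annotated coaxial stacks plus a family label."""

    stacks: frozenset  # frozenset of frozenset({"Hi","Hj"})
    family: str

    def __post_init__(self):
        object.__setattr__(self, "stacks", frozenset(frozenset(s) for s in self.stacks))
        object.__setattr__(self, "family", normalize_family(self.family))
        ids = [h for s in self.stacks for h in s]
        if len(ids) != len(set(ids)):
            raise ValueError("coaxial stacks must be disjoint helix pairs")
        if any(len(s) != 2 for s in self.stacks):
            raise ValueError("each stack is an unordered pair of helix ids")

    @property
    def stack_label(self) -> str:
        return stacks_to_label(self.stacks)

    @classmethod
    def from_labels(cls, stack_label: str, family: str) -> "JunctionTopology":
        return cls(label_to_stacks(stack_label), family)

    def validate_for_degree(self, degree: int) -> None:
        if degree == 3 and len(self.stacks) > 1:
            raise ValueError("a 3-way junction admits at most one coaxial stack")
        if degree == 4 and len(self.stacks) > 2:
            raise ValueError("a 4-way junction admits at most two coaxial stacks")
        if degree in FAMILIES and self.family not in FAMILIES[degree]:
            raise ValueError(f"unknown family {self.family!r} for degree {degree}")
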