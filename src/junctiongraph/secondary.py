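"""Secondary-structure parsing and decomposition into helices and junctions.

Coordinates are 0-based internally; CT text is 1-based and converted at the
boundary. Only canonical pairs (AU, GC, GU and their reverses) are admitted
into a :class:`SecondaryStructure`.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

_OPEN_TO_CLOSE = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSE_TO_OPEN = {v: k for k, v in _OPEN_TO_CLOSE.items()}


class ParseError(ValueError):
    """Raised when an input secondary-structure text is malformed."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence plus a set of canonical base pairs (i < j, 0-based)."""

    sequence: str
    pairs: frozenset

    def __post_init__(self):
        n = len(self.sequence)
        seen = {}
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ParseError(f"pair ({i},{j}) out of range for length {n}")
            for k in (i, j):
                if k in seen:
                    raise ParseError(f"index {k} participates in more than one pair")
                seen[k] = True
            combo = self.sequence[i] + self.sequence[j]
            if combo not in CANONICAL_PAIRS:
                raise ParseError(f"non-canonical pair {combo} at ({i},{j})")

    @property
    def partner(self) -> dict:
        """Symmetric index -> partner map."""
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_sequence(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def parse_dotbracket(text: str, on_noncanonical: str = "raise") -> SecondaryStructure:
    """Parse two-line dot-bracket text (optional ``>`` header line).

    ``on_noncanonical`` is ``"raise"`` (default) or ``"drop"`` — drop silently
    removes pairs whose letters are not AU/GC/GU combinations.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith(">")]
    if not lines:
        return SecondaryStructure("", frozenset())
    if len(lines) < 2:
        raise ParseError("need a sequence line and a bracket line")
    seq, db = _normalize_sequence(lines[0]), lines[1]
    if len(seq) != len(db):
        raise ParseError(f"sequence length {len(seq)} != bracket length {len(db)}")
    stacks: dict = {o: [] for o in _OPEN_TO_CLOSE}
    pairs = set()
    for i, c in enumerate(db):
        if c in _OPEN_TO_CLOSE:
            stacks[c].append(i)
        elif c in _CLOSE_TO_OPEN:
            st = stacks[_CLOSE_TO_OPEN[c]]
            if not st:
                raise ParseError(f"unbalanced '{c}' at position {i}")
            pairs.add((st.pop(), i))
        elif c not in ".-:,_~":
            raise ParseError(f"unexpected character {c!r} at position {i}")
    for o, st in stacks.items():
        if st:
            raise ParseError(f"unbalanced '{o}' at position {st[-1]}")
    if on_noncanonical == "drop":
        pairs = {(i, j) for i, j in pairs if seq[i] + seq[j] in CANONICAL_PAIRS}
    elif on_noncanonical != "raise":
        raise ValueError("on_noncanonical must be 'raise' or 'drop'")
    return SecondaryStructure(seq, frozenset(pairs))


def parse_ct(text: str, on_noncanonical: str = "raise") -> SecondaryStructure:
    """Parse a single CT-format record (1-based; pair column 0 = unpaired)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return SecondaryStructure("", frozenset())
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("CT header must start with the residue count") from None
    if len(lines) - 1 < n:
        raise ParseError(f"CT record declares {n} residues, found {len(lines) - 1}")
    seq = []
    pairmap = {}
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        if len(cols) < 6:
            raise ParseError(f"CT line has {len(cols)} columns, expected 6: {ln!r}")
        idx, base, pair_col = int(cols[0]), cols[1], int(cols[4])
        seq.append(base)
        pairmap[idx] = pair_col
    pairs = set()
    for i, j in pairmap.items():
        if j == 0:
            continue
        if pairmap.get(j) != i:
            raise ParseError(f"inconsistent reciprocal pairing: {i}->{j} but {j}->{pairmap.get(j)}")
        if i < j:
            pairs.add((i - 1, j - 1))
    sequence = _normalize_sequence("".join(seq))
    if on_noncanonical == "drop":
        pairs = {(i, j) for i, j in pairs if sequence[i] + sequence[j] in CANONICAL_PAIRS}
    return SecondaryStructure(sequence, frozenset(pairs))


def to_ct(ss: SecondaryStructure, title: str = "") -> str:
    """Serialize to CT text (1-based)."""
    partner = ss.partner
    n = len(ss)
    out = [f"{n} {title}".rstrip()]
    for i in range(n):
        j = partner.get(i, -1) + 1
        out.append(f"{i + 1} {ss.sequence[i]} {i} {i + 2 if i + 1 < n else 0} {j} {i + 1}")
    return "\n".join(out) + "\n"


def to_dotbracket(ss: SecondaryStructure) -> str:
    """Serialize to two-line dot-bracket; crossing pairs spill into extra bracket families."""
    families = list(_OPEN_TO_CLOSE.items())
    assigned: list = [set() for _ in families]
    db = ["."] * len(ss)
    for i, j in sorted(ss.pairs):
        for fam, taken in enumerate(assigned):
            if not any(a < i < b < j or i < a < j < b for a, b in taken):
                taken.add((i, j))
                db[i], db[j] = families[fam][0], families[fam][1]
                break
        else:
            raise ParseError("structure needs more than four bracket families")
    return ss.sequence + "\n" + "".join(db) + "\n"


# ---------------------------------------------------------------------------
# pseudoknot removal
# ---------------------------------------------------------------------------

def remove_pseudoknots(ss: SecondaryStructure) -> SecondaryStructure:
    """Return the maximum-cardinality nested (non-crossing) subset of pairs.

    Interval dynamic programming over pair openings; ties are broken by
    keeping the pair whose opening index is smallest. Nested input is a
    fixed point.
    """
    if not ss.pairs:
        return ss
    partner = ss.partner
    n = len(ss)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * n + 100))
    memo: dict = {}

    def best(i: int, j: int) -> int:
        while i <= j and not (i in partner and i < partner[i] <= j):
            i += 1
        if i > j:
            return 0
        key = (i, j)
        if key in memo:
            return memo[key]
        k = partner[i]
        take = 1 + best(i + 1, k - 1) + best(k + 1, j)
        skip = best(i + 1, j)
        memo[key] = max(take, skip)
        return memo[key]

    kept = set()

    def collect(i: int, j: int) -> None:
        while i <= j:
            if not (i in partner and i < partner[i] <= j):
                i += 1
                continue
            k = partner[i]
            take = 1 + best(i + 1, k - 1) + best(k + 1, j)
            if take >= best(i + 1, j):
                kept.add((i, k))
                collect(i + 1, k - 1)
                i = k + 1
            else:
                i += 1

    best(0, n - 1)
    collect(0, n - 1)
    return SecondaryStructure(ss.sequence, frozenset(kept))


def has_crossing(pairs: Iterable) -> bool:
    ps = sorted(pairs)
    for a in range(len(ps)):
        i, j = ps[a]
        for k, l in ps[a + 1 :]:
            if i < k < j < l:
                return True
    return False


# ---------------------------------------------------------------------------
# helices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Helix:
    """A maximal run of >= 2 consecutively stacked pairs, ordered outer->inner."""

    pairs: tuple

    @property
    def bp_count(self) -> int:
        return len(self.pairs)

    @property
    def outer(self) -> tuple:
        return self.pairs[0]

    @property
    def inner(self) -> tuple:
        return self.pairs[-1]

    @property
    def strand5(self) -> range:
        return range(self.outer[0], self.inner[0] + 1)

    @property
    def strand3(self) -> range:
        return range(self.inner[1], self.outer[1] + 1)


def _stacked_runs(pairs: Iterable) -> Iterator[list]:
    run: list = []
    for i, j in sorted(pairs):
        if run and (i, j) == (run[-1][0] + 1, run[-1][1] - 1):
            run.append((i, j))
        else:
            if run:
                yield run
            run = [(i, j)]
    if run:
        yield run


def find_helices(ss: SecondaryStructure) -> list:
    """Maximal stacked runs with bp_count >= 2; isolated pairs are not helices."""
    return [Helix(tuple(run)) for run in _stacked_runs(ss.pairs) if len(run) >= 2]


def isolated_pairs(ss: SecondaryStructure) -> list:
    """Single pairs not part of any helix (dissolved into loops downstream)."""
    return [run[0] for run in _stacked_runs(ss.pairs) if len(run) == 1]


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopSegment:
    """Unpaired stretch between consecutive junction helices, [start, end)."""

    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class JunctionHelix:
    """A helix in its junction role: label, orientation, closing-pair letters."""

    id: str
    helix: Helix
    proximal_end: str  # "inner" (closing helix) or "outer" (branch helix)
    closing_pair: str

    @property
    def bp_count(self) -> int:
        return self.helix.bp_count

    @property
    def pairs_proximal_first(self) -> tuple:
        ps = self.helix.pairs
        return tuple(reversed(ps)) if self.proximal_end == "inner" else ps

    @property
    def proximal_pair(self) -> tuple:
        return self.pairs_proximal_first[0]

    @property
    def distal_pair(self) -> tuple:
        return self.pairs_proximal_first[-1]


@dataclass(frozen=True)
class Junction:
    """An n-way loop: ordered helices H1..Hn and loop segments L1..Ln.

    Loop i sits between helix i and helix (i+1) mod n. H1 is the closing
    helix when the junction has one (``closing`` False for exterior loops).
    """

    helices: tuple
    loops: tuple
    closing: bool

    @property
    def degree(self) -> int:
        return len(self.helices)

    @property
    def helix_ids(self) -> list:
        return [h.id for h in self.helices]

    def helix_by_id(self, hid: str) -> JunctionHelix:
        for h in self.helices:
            if h.id == hid:
                return h
        raise KeyError(hid)

    @property
    def loop_lengths(self) -> tuple:
        return tuple(l.length for l in self.loops)


def _loop(ss: SecondaryStructure, start: int, end: int) -> LoopSegment:
    return LoopSegment(start, end, ss.sequence[start:end])


def find_junctions(ss: SecondaryStructure) -> list:
    """Return every loop bounded by >= 3 helices as a Junction.

    Requires nested input (run :func:`remove_pseudoknots` first on knotted
    structures). Isolated single pairs are dissolved into loop regions.
    """
    if has_crossing(ss.pairs):
        raise ValueError("structure has crossing pairs; remove pseudoknots first")
    helices = find_helices(ss)
    order = sorted(range(len(helices)), key=lambda k: helices[k].outer[0])
    parent = {k: None for k in order}
    stack: list = []
    for k in order:
        o5, o3 = helices[k].outer
        while stack and helices[stack[-1]].outer[1] < o5:
            stack.pop()
        parent[k] = stack[-1] if stack else None
        stack.append(k)
    children: dict = {k: [] for k in order}
    roots = []
    for k in order:
        if parent[k] is None:
            roots.append(k)
        else:
            children[parent[k]].append(k)

    def _jh(label: str, helix: Helix, proximal_end: str) -> JunctionHelix:
        pi, pj = (helix.inner if proximal_end == "inner" else helix.outer)
        return JunctionHelix(label, helix, proximal_end, ss.sequence[pi] + ss.sequence[pj])

    junctions = []
    for k in order:
        kids = children[k]
        if len(kids) < 2:
            continue
        h = helices[k]
        jhs = [_jh("H1", h, "inner")]
        loops = []
        cursor = h.inner[0] + 1
        for m, c in enumerate(kids, start=2):
            ch = helices[c]
            loops.append(_loop(ss, cursor, ch.outer[0]))
            jhs.append(_jh(f"H{m}", ch, "outer"))
            cursor = ch.outer[1] + 1
        loops.append(_loop(ss, cursor, h.inner[1]))
        junctions.append(Junction(tuple(jhs), tuple(loops), True))
    if len(roots) >= 3:
        jhs = [_jh(f"H{m}", helices[r], "outer") for m, r in enumerate(roots, start=1)]
        loops = []
        for a, b in zip(roots, roots[1:]):
            loops.append(_loop(ss, helices[a].outer[1] + 1, helices[b].outer[0]))
        end = helices[roots[-1]].outer[1] + 1
        loops.append(LoopSegment(end, end, ""))  # exterior wrap: tails ignored
        junctions.append(Junction(tuple(jhs), tuple(loops), False))
    junctions.sort(key=lambda j: j.helices[0].helix.outer[0])
    return junctions


def junction_report(ss: SecondaryStructure) -> dict:
    """JSON-ready report of the junction decomposition of a structure."""
    nested = remove_pseudoknots(ss)
    report = {
        "length": len(ss),
        "n_pairs": len(ss.pairs),
        "n_pairs_nested": len(nested.pairs),
        "n_helices": len(find_helices(nested)),
        "junctions": [],
    }
    for j in find_junctions(nested):
        report["junctions"].append(
            {
                "degree": j.degree,
                "closing": j.closing,
                "helices": [
                    {
                        "id": h.id,
                        "bp_count": h.bp_count,
                        "closing_pair": h.closing_pair,
                        "outer_pair": list(h.helix.outer),
                        "inner_pair": list(h.helix.inner),
                    }
                    for h in j.helices
                ],
                "loops": [
                    {"length": l.length, "sequence": l.sequence} for l in j.loops
                ],
            }
        )
    return report
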