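"""Random-forest prediction of coaxial stacking and junction family.

Two forests are trained per junction degree: a stack predictor over loop
length / sequence-content features, and a family predictor that additionally
sees the (predicted) stack configuration as a one-hot block. Evaluation is
by leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .secondary import Junction
from .topology import FAMILIES, STACK_LABELS, JunctionTopology, normalize_family

BASE_ORDER = "ACGU"
CLOSING_PAIR_ORDER = ("AU", "UA", "GC", "CG", "GU", "UG")


class UnsupportedDegreeError(ValueError):
    pass


class DegenerateTrainingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _feature_vector(loop_lengths, loop_seqs, bp_counts, closing_pairs) -> np.ndarray:
    n = len(loop_lengths)
    feats = [float(x) for x in loop_lengths]
    for i in range(n):
        for j in range(i + 1, n):
            tot = loop_lengths[i] + loop_lengths[j]
            feats.append((loop_lengths[i] - loop_lengths[j]) / tot if tot else 0.0)
    for seq in loop_seqs:
        if seq:
            feats.extend(seq.count(b) / len(seq) for b in BASE_ORDER)
        else:
            feats.extend([0.0] * 4)
    for seq in loop_seqs:
        feats.append((seq.count("A") + seq.count("G")) / len(seq) if seq else 0.0)
    for cp in closing_pairs:
        feats.extend(1.0 if cp == ref else 0.0 for ref in CLOSING_PAIR_ORDER)
    feats.extend(float(b) for b in bp_counts)
    feats.append(float(sum(loop_lengths)))
    return np.asarray(feats, dtype=float)


def feature_names(degree: int) -> list:
    names = [f"loop_len_L{i + 1}" for i in range(degree)]
    names += [
        f"loop_ratio_L{i + 1}_L{j + 1}"
        for i in range(degree)
        for j in range(i + 1, degree)
    ]
    names += [f"frac_{b}_L{i + 1}" for i in range(degree) for b in BASE_ORDER]
    names += [f"purine_frac_L{i + 1}" for i in range(degree)]
    names += [f"closing_{cp}_H{i + 1}" for i in range(degree) for cp in CLOSING_PAIR_ORDER]
    names += [f"bp_count_H{i + 1}" for i in range(degree)]
    names.append("total_loop_nt")
    return names


@dataclass(frozen=True)
class JunctionRecord:
    """One labeled junction: raw attributes plus stack/family labels."""

    source_id: str
    degree: int
    loop_lengths: tuple
    loop_seqs: tuple
    bp_counts: tuple
    closing_pairs: tuple
    stack_label: str = "none"
    family_label: str = "none"

    def features(self) -> np.ndarray:
        return _feature_vector(
            self.loop_lengths, self.loop_seqs, self.bp_counts, self.closing_pairs
        )


def extract_features(junction: Junction) -> np.ndarray:
    """Deterministic feature vector of a 3- or 4-way junction."""
    if junction.degree not in (3, 4):
        raise UnsupportedDegreeError(f"degree {junction.degree} not supported")
    return record_from_junction(junction).features()


def record_from_junction(
    junction: Junction, topology: JunctionTopology | None = None, source_id: str = ""
) -> JunctionRecord:
    if junction.degree not in (3, 4):
        raise UnsupportedDegreeError(f"degree {junction.degree} not supported")
    return JunctionRecord(
        source_id=source_id,
        degree=junction.degree,
        loop_lengths=junction.loop_lengths,
        loop_seqs=tuple(l.sequence for l in junction.loops),
        bp_counts=tuple(h.bp_count for h in junction.helices),
        closing_pairs=tuple(h.closing_pair for h in junction.helices),
        stack_label=topology.stack_label if topology else "none",
        family_label=topology.family if topology else "none",
    )


# ---------------------------------------------------------------------------
# dataset I/O (tab-separated)
# ---------------------------------------------------------------------------

_DATASET_HEADER = (
    "source_id\tdegree\tloop_lengths\tloop_seqs\tbp_counts\tclosing_pairs\tstack\tfamily"
)


def write_dataset(records) -> str:
    lines = [_DATASET_HEADER]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.source_id,
                    str(r.degree),
                    ",".join(str(x) for x in r.loop_lengths),
                    ",".join(s if s else "-" for s in r.loop_seqs),
                    ",".join(str(x) for x in r.bp_counts),
                    ",".join(r.closing_pairs),
                    r.stack_label,
                    r.family_label,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_dataset(text: str) -> list:
    records = []
    seen_ids = set()
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("source_id") or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 8:
            raise ValueError(f"dataset line needs 8 tab-separated columns: {ln!r}")
        sid = cols[0]
        if sid in seen_ids:
            raise ValueError(f"duplicate source id {sid!r}")
        seen_ids.add(sid)
        records.append(
            JunctionRecord(
                source_id=sid,
                degree=int(cols[1]),
                loop_lengths=tuple(int(x) for x in cols[2].split(",")),
                loop_seqs=tuple("" if s == "-" else s for s in cols[3].split(",")),
                bp_counts=tuple(int(x) for x in cols[4].split(",")),
                closing_pairs=tuple(cols[5].split(",")),
                stack_label=cols[6],
                family_label=normalize_family(cols[7]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class _ConstantModel:
    """Fallback when a training fold contains a single class."""

    def __init__(self, label):
        self.label = label

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.label] * len(X))


def _fit_forest(X, y, seed, n_estimators):
    from sklearn.ensemble import RandomForestClassifier

    if len(set(y)) < 2:
        return _ConstantModel(y[0])
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _stack_onehot(labels, degree) -> np.ndarray:
    classes = STACK_LABELS[degree]
    out = np.zeros((len(labels), len(classes)))
    for k, lab in enumerate(labels):
        out[k, classes.index(lab)] = 1.0
    return out


@dataclass
class JunctionClassifier:
    """Fitted stack + family forests for one junction degree."""

    degree: int
    seed: int = 0
    n_estimators: int = 500
    stack_model: object = None
    family_model: object = None

    def fit(self, records) -> "JunctionClassifier":
        if any(r.degree != self.degree for r in records):
            raise UnsupportedDegreeError("training data must be degree-homogeneous")
        X = np.vstack([r.features() for r in records])
        y_stack = [r.stack_label for r in records]
        y_family = [r.family_label for r in records]
        self.stack_model = _fit_forest(X, y_stack, self.seed, self.n_estimators)
        X_fam = np.hstack([X, _stack_onehot(y_stack, self.degree)])
        self.family_model = _fit_forest(X_fam, y_family, self.seed, self.n_estimators)
        return self

    def predict_record(self, record: JunctionRecord) -> JunctionTopology:
        if record.degree != self.degree:
            raise UnsupportedDegreeError(
                f"classifier degree {self.degree} != junction degree {record.degree}"
            )
        x = record.features()[None, :]
        stack = str(self.stack_model.predict(x)[0])
        x_fam = np.hstack([x, _stack_onehot([stack], self.degree)])
        family = str(self.family_model.predict(x_fam)[0])
        return JunctionTopology.from_labels(stack, family)

    def predict(self, junction: Junction) -> JunctionTopology:
        return self.predict_record(record_from_junction(junction))


def train(records, seed: int = 0, n_estimators: int = 500) -> JunctionClassifier:
    """Fit a per-degree classifier; errors on single-class labels."""
    if not records:
        raise DegenerateTrainingError("empty training set")
    degree = records[0].degree
    for label in ("stack_label", "family_label"):
        if len({getattr(r, label) for r in records}) < 2:
            raise DegenerateTrainingError(f"single-class {label} in training data")
    return JunctionClassifier(degree=degree, seed=seed, n_estimators=n_estimators).fit(records)


def predict_topology(classifier: JunctionClassifier, junction: Junction) -> JunctionTopology:
    return classifier.predict(junction)


@dataclass
class LoocvReport:
    predictions: list  # dicts: source_id, true/predicted stack + family
    stack_correct: int
    family_correct: int
    k: int

    @property
    def stack_accuracy(self) -> float:
        return self.stack_correct / self.k

    @property
    def family_accuracy(self) -> float:
        return self.family_correct / self.k

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "stack_correct": self.stack_correct,
            "family_correct": self.family_correct,
            "stack_accuracy": self.stack_accuracy,
            "family_accuracy": self.family_accuracy,
            "predictions": self.predictions,
        }


def loocv(records, seed: int = 0, n_estimators: int = 500) -> LoocvReport:
    """Leave-one-out cross-validation: train on k-1 junctions, test the last.

    Folds whose training labels collapse to a single class fall back to a
    constant (majority) predictor instead of failing.
    """
    if len(records) < 3:
        raise ValueError("LOOCV needs at least 3 records")
    degree = records[0].degree
    predictions = []
    stack_ok = family_ok = 0
    for i, held_out in enumerate(records):
        fold = [r for k, r in enumerate(records) if k != i]
        clf = JunctionClassifier(degree=degree, seed=seed, n_estimators=n_estimators).fit(fold)
        topo = clf.predict_record(held_out)
        s_ok = topo.stack_label == held_out.stack_label
        f_ok = topo.family == normalize_family(held_out.family_label)
        stack_ok += s_ok
        family_ok += f_ok
        predictions.append(
            {
                "source_id": held_out.source_id,
                "true_stack": held_out.stack_label,
                "pred_stack": topo.stack_label,
                "true_family": held_out.family_label,
                "pred_family": topo.family,
                "stack_correct": bool(s_ok),
                "family_correct": bool(f_ok),
            }
        )
    return LoocvReport(predictions, stack_ok, family_ok, len(records))


def save_classifier(clf: JunctionClassifier, path) -> None:
    import joblib

    joblib.dump(clf, path)


def load_classifier(path) -> JunctionClassifier:
    import joblib

    return joblib.load(path)


# ---------------------------------------------------------------------------
# synthetic labeled data
# ---------------------------------------------------------------------------

_STACK_BY_ZERO_LOOP_3WAY = {0: "H1H2", 1: "H2H3", 2: "H1H3"}


def synthetic_dataset(
    n: int, degree: int = 3, noise: float = 0.0, seed: int = 0
) -> list:
    """Labeled junction records whose labels are noiseless functions of features.

    3-way: the stack is the helix pair flanking the unique zero-length loop;
    the family is encoded redundantly — family A has short H1 (b1 <= 4),
    GC closing pairs and poly-A loops, family C has long H1 (b1 >= 9),
    AU closing pairs and poly-C loops — so that separability survives
    per-split feature subsampling. 4-way: two zero-length loops select one
    of the two adjacent double-stack configurations (cH for H1H2+H3H4, cL
    for H1H4+H2H3), and the family follows the stack. With ``noise``,
    labels are flipped to a random other generated class.
    """
    if degree not in (3, 4):
        raise UnsupportedDegreeError(f"degree {degree} not supported")
    rng = np.random.default_rng(seed)
    bases = np.array(list(BASE_ORDER))
    records = []
    stack_classes: set = set()
    family_classes: set = set()
    raw = []
    for i in range(n):
        lens = [int(rng.integers(3, 8)) for _ in range(degree)]
        bps = [int(rng.integers(4, 7)) for _ in range(degree)]
        if degree == 3:
            zero = int(rng.integers(0, 3))
            lens[zero] = 0
            stack = _STACK_BY_ZERO_LOOP_3WAY[zero]
            first = rng.random() < 0.5
            bps[0] = int(rng.integers(2, 5)) if first else int(rng.integers(9, 12))
            family = "A" if first else "C"
        else:
            first = rng.random() < 0.5
            if first:
                lens[0] = lens[2] = 0
                stack, family = "H1H2+H3H4", "cH"
            else:
                lens[1] = lens[3] = 0
                stack, family = "H1H4+H2H3", "cL"
        loop_letter = "A" if first else "C"
        cps = ("GC" if first else "AU",) * degree
        seqs = tuple(loop_letter * l for l in lens)
        bps = tuple(bps)
        stack_classes.add(stack)
        family_classes.add(family)
        raw.append((tuple(lens), seqs, bps, cps, stack, family))
    for i, (lens, seqs, bps, cps, stack, family) in enumerate(raw):
        if noise > 0 and rng.random() < noise:
            stack = str(rng.choice(sorted(stack_classes - {stack})))
        if noise > 0 and rng.random() < noise:
            family = str(rng.choice(sorted(family_classes - {family})))
        records.append(
            JunctionRecord(f"syn{i:04d}", degree, lens, seqs, bps, cps, stack, family)
        )
    return records
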