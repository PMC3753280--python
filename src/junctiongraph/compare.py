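"""Graph superposition and scoring: RMSD (global) and MaxAngle (local).

Superposition translates both vertex sets to their centroids and finds the
least-squares optimal *proper* rotation by singular value decomposition
(reflections are excluded by flipping the smallest singular direction).
Vertex correspondence is by label, never by proximity. RMSD averages over
all 2n+1 vertices; MaxAngle is the maximum angle between corresponding
helix edge vectors evaluated in the RMSD-optimal frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import TreeGraph


class CorrespondenceError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonResult:
    rmsd: float
    max_angle: float
    rotation: np.ndarray  # 3x3 proper rotation applied to the predicted graph
    translation: np.ndarray
    correspondence: tuple  # vertex labels, in comparison order

    def to_dict(self) -> dict:
        return {
            "rmsd": float(self.rmsd),
            "max_angle": float(self.max_angle),
            "rotation": [[float(x) for x in row] for row in self.rotation],
            "translation": [float(x) for x in self.translation],
            "correspondence": list(self.correspondence),
        }


def kabsch(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R (3x3) minimizing ||R @ moving.T - target.T||.

    Both point sets must already be centered at the origin.
    """
    cov = moving.T @ target
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def _matched_coordinates(ref: TreeGraph, pred: TreeGraph):
    if set(ref.vertices) != set(pred.vertices):
        raise CorrespondenceError(
            f"vertex label sets differ: {sorted(set(ref.vertices) ^ set(pred.vertices))}"
        )
    labels = ref.label_order
    return labels, ref.coordinates(labels), pred.coordinates(labels)


def superpose(ref: TreeGraph, pred: TreeGraph):
    """Rotation + translation mapping ``pred`` vertices onto ``ref``."""
    _, q, p = _matched_coordinates(ref, pred)
    qc, pc = q.mean(axis=0), p.mean(axis=0)
    rot = kabsch(p - pc, q - qc)
    trans = qc - rot @ pc
    return rot, trans


def rmsd_points(moving: np.ndarray, target: np.ndarray) -> float:
    """RMSD between two matched point sets after optimal superposition."""
    moving = np.asarray(moving, float)
    target = np.asarray(target, float)
    pc, qc = moving.mean(axis=0), target.mean(axis=0)
    rot = kabsch(moving - pc, target - qc)
    moved = (moving - pc) @ rot.T
    return float(np.sqrt(np.mean(np.sum((moved - (target - qc)) ** 2, axis=1))))


def rmsd(ref: TreeGraph, pred: TreeGraph) -> float:
    """Root-mean-square vertex distance (Å) after optimal superposition."""
    _, q, p = _matched_coordinates(ref, pred)
    return rmsd_points(p, q)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two nonzero vectors."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length edge vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def max_angle(ref: TreeGraph, pred: TreeGraph) -> float:
    """Maximum angle (°) between corresponding helix edges in the RMSD frame."""
    rot, _ = superpose(ref, pred)
    angles = [
        angle_between(ref.helix_vector(h), rot @ pred.helix_vector(h))
        for h in ref.helix_ids
    ]
    return max(angles)


def compare(ref: TreeGraph, pred: TreeGraph) -> ComparisonResult:
    """Joint RMSD + MaxAngle report using a single superposition."""
    labels, q, p = _matched_coordinates(ref, pred)
    rot, trans = superpose(ref, pred)
    moved = p @ rot.T + trans
    rms = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    angles = [
        angle_between(ref.helix_vector(h), rot @ pred.helix_vector(h))
        for h in ref.helix_ids
    ]
    return ComparisonResult(rms, max(angles), rot, trans, tuple(labels))
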