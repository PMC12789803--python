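"""Rigid-body geometry kernel: torsion angles, Kabsch superposition,
all-atom RMSD, iterative mean structures and representative-by-mean
selection.

Every later stage of the pipeline (NMR ensemble reduction, sequence-
representative-structure selection, modified-vs-unmodified comparison)
delegates its numerics to this module, so the contracts here are strict:
rotations are proper (det = +1, no reflections — nucleic acid chirality
must survive superposition), RMSD is the least-squares minimum, and the
mean structure is computed by iterated superposition onto the running
mean until convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError", "UndefinedTorsionError", "CorrespondenceError",
    "CoordinateSet", "Superposition", "torsion_angle", "kabsch_superpose",
    "mean_coordinates", "representative_to_mean",
]


class GeometryError(ValueError):
    """Base class for geometry-kernel contract violations."""


class UndefinedTorsionError(GeometryError):
    """Raised when three consecutive torsion points are collinear."""


class CorrespondenceError(GeometryError):
    """Raised when two coordinate sets cannot be put in 1:1 correspondence."""


@dataclass(frozen=True)
class CoordinateSet:
    """An ordered, labelled set of 3D points (Angstrom).

    Labels are (chain_id, seq_num, atom_name) triples (any hashable works);
    they must be unique and parallel to ``coords``.
    """

    labels: tuple
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (n, 3), got {coords.shape}")
        if len(self.labels) != len(coords):
            raise GeometryError("labels and coords length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise GeometryError("duplicate labels in CoordinateSet")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, labels) -> "CoordinateSet":
        index = {lab: i for i, lab in enumerate(self.labels)}
        idx = [index[lab] for lab in labels]
        return CoordinateSet(tuple(labels), self.coords[idx])


@dataclass(frozen=True)
class Superposition:
    """Optimal proper rigid transform mapping mobile onto reference:
    x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def torsion_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, range (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, the angle is the
    clockwise rotation carrying the p2->p1 projection onto the p3->p4
    projection; a cis (eclipsed) arrangement is 0.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n == 0.0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise UndefinedTorsionError("collinear or coincident torsion points")
    angle = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2) / b2n,
                                  np.dot(n1, n2)))
    # map -180 -> +180 so the range is (-180, 180]
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def _check_correspondence(mobile: CoordinateSet, reference: CoordinateSet) -> None:
    if tuple(mobile.labels) != tuple(reference.labels):
        raise CorrespondenceError("label sequences differ between coordinate sets")


def kabsch_superpose(mobile: CoordinateSet, reference: CoordinateSet) -> Superposition:
    """Least-squares optimal proper superposition of ``mobile`` onto
    ``reference`` (Kabsch, SVD formulation with reflection correction).
    """
    _check_correspondence(mobile, reference)
    n = len(mobile)
    if n < 3:
        raise GeometryError(f"TOO_FEW_ATOMS: need >= 3 paired atoms, got {n}")
    x = mobile.coords
    y = reference.coords
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    e0 = (x0 ** 2).sum() + (y0 ** 2).sum()
    msd = max(0.0, (e0 - 2.0 * (s[0] + s[1] + d * s[2])) / n)
    rmsd = float(np.sqrt(msd))
    trans = yc - rot @ xc
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


@dataclass
class MeanResult:
    """Converged (or flagged) iterative mean of an ensemble."""

    mean: CoordinateSet
    n_iter: int
    converged: bool
    members_aligned: list = field(default_factory=list)


def mean_coordinates(members, tol: float = 1e-4, max_iter: int = 20) -> MeanResult:
    """Iterative mean structure of an ensemble sharing atom labels.

    Every member is superposed onto the current mean (initially member 1),
    the per-atom arithmetic mean of the aligned coordinates is taken, and
    the loop repeats until the mean moves less than ``tol`` (max per-atom
    displacement, Angstrom) or ``max_iter`` is reached.  Non-convergence
    returns the last iterate flagged ``converged=False``.
    """
    members = list(members)
    if not members:
        raise GeometryError("empty ensemble")
    labels = tuple(members[0].labels)
    for m in members[1:]:
        _check_correspondence(m, members[0])
    mean = members[0].coords.copy()
    n_iter = 0
    converged = False
    aligned = [m.coords.copy() for m in members]
    for n_iter in range(1, max_iter + 1):
        mean_set = CoordinateSet(labels, mean)
        aligned = []
        for m in members:
            sup = kabsch_superpose(m, mean_set)
            aligned.append(sup.apply(m.coords))
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            converged = True
            break
    return MeanResult(mean=CoordinateSet(labels, mean), n_iter=n_iter,
                      converged=converged, members_aligned=aligned)


@dataclass(frozen=True)
class RepresentativeResult:
    """Member with the lowest all-atom RMSD to the ensemble mean."""

    index: int
    rmsds: tuple
    tie: bool
    converged: bool


def representative_to_mean(members, tol: float = 1e-4,
                           max_iter: int = 20) -> RepresentativeResult:
    """Select the ensemble member closest (all-atom RMSD, after its own
    superposition) to the iterative mean structure.  Ties go to the lowest
    index."""
    members = list(members)
    if not members:
        raise GeometryError("empty ensemble")
    if len(members) == 1:
        return RepresentativeResult(index=0, rmsds=(0.0,), tie=False, converged=True)
    res = mean_coordinates(members, tol=tol, max_iter=max_iter)
    rmsds = tuple(kabsch_superpose(m, res.mean).rmsd for m in members)
    best = min(rmsds)
    idx = rmsds.index(best)  # first minimum -> lowest index on ties
    tie = sum(1 for r in rmsds if abs(r - best) < 1e-9) > 1
    return RepresentativeResult(index=idx, rmsds=rmsds, tie=tie,
                                converged=res.converged)
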