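"""Geometry metrics on coordinate sets: superposition, RMSD, distances.

Structural stability of a simulated complex is summarized by the
root-mean-square deviation of atomic positions after optimal rigid
superposition (the Kabsch least-squares alignment), and binding-site
geometry by selected atom-pair distances (for example hydroxyl oxygen to
the catalytic metal ion).  Coordinates are in angstrom throughout.

Conventions: the reference for a trajectory RMSD series is its first frame;
the fit uses backbone atoms and the measurement heavy atoms unless told
otherwise.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "AtomTable",
    "CoordinateSet",
    "Trajectory",
    "SuperpositionResult",
    "RMSDSummary",
    "select_atoms",
    "parse_selection",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "atom_pair_distances",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomTable:
    """Identity of the atoms shared by every frame of a trajectory."""

    ids: np.ndarray  # unique atom identifiers (int serials)
    names: np.ndarray  # PDB atom names, e.g. "CA"
    residue_ids: np.ndarray  # labels, e.g. "HIS204", "Cu2B"
    elements: np.ndarray  # element symbols, upper case
    groups: np.ndarray  # "protein" | "ligand" | "metal"

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("names", "residue_ids", "elements", "groups"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"atom table column {name!r} has wrong length")
        if len(np.unique(self.ids)) != n:
            raise ValidationError("atom ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class CoordinateSet:
    """One frame: an atom table plus an ``(n_atoms, 3)`` coordinate array."""

    atoms: AtomTable
    xyz: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(self.atoms), 3):
            raise ValidationError(
                f"xyz must have shape ({len(self.atoms)}, 3), got {arr.shape}"
            )
        if not np.isfinite(arr).all():
            raise ValidationError("coordinates must be finite")
        object.__setattr__(self, "xyz", arr)


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames sharing one atom table; coords ``(n_frames, n_atoms, 3)``."""

    atoms: AtomTable
    coords: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        if arr.ndim != 3 or arr.shape[1:] != (len(self.atoms), 3):
            raise ValidationError(
                f"coords must have shape (n_frames, {len(self.atoms)}, 3), got {arr.shape}"
            )
        if arr.shape[0] == 0:
            raise ValidationError("trajectory must contain at least one frame")
        if not np.isfinite(arr).all():
            raise ValidationError("coordinates must be finite")
        object.__setattr__(self, "coords", arr)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> CoordinateSet:
        return CoordinateSet(atoms=self.atoms, xyz=self.coords[i])


Selection = "str | Callable | np.ndarray | None"


def parse_selection(spec: str) -> Callable[[AtomTable], np.ndarray]:
    """Parse a textual selection: ``group[:name=CA,CB][:res=HIS204,...]``.

    ``group`` is ``protein``, ``ligand``, ``metal`` or ``all``.
    """
    parts = spec.split(":")
    group = parts[0].strip().lower()
    if group not in ("protein", "ligand", "metal", "all"):
        raise ValidationError(f"unknown selection group {group!r}")
    names: set[str] | None = None
    residues: set[str] | None = None
    for part in parts[1:]:
        key, _, value = part.partition("=")
        values = {v.strip() for v in value.split(",") if v.strip()}
        if key == "name":
            names = values
        elif key == "res":
            residues = values
        else:
            raise ValidationError(f"unknown selection filter {key!r}")

    def matcher(atoms: AtomTable) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        if group != "all":
            mask &= atoms.groups == group
        if names is not None:
            mask &= np.isin(atoms.names, sorted(names))
        if residues is not None:
            mask &= np.isin(atoms.residue_ids, sorted(residues))
        return mask

    return matcher


def select_atoms(atoms: AtomTable, selection) -> np.ndarray:
    """Resolve a selection (string, callable, mask, or None=all) to a mask."""
    if selection is None:
        return np.ones(len(atoms), dtype=bool)
    if isinstance(selection, str):
        selection = parse_selection(selection)
    if callable(selection):
        mask = np.asarray(selection(atoms), dtype=bool)
    else:
        mask = np.asarray(selection, dtype=bool)
    if mask.shape != (len(atoms),):
        raise ValidationError("selection mask has wrong length")
    return mask


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform ``x -> rotation @ x + translation`` and its fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    fitted_rmsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equally-shaped point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: CoordinateSet, reference: CoordinateSet, fit_selection=None
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Classic SVD solution: center both selections, take the SVD of the
    covariance matrix and correct the sign of the smallest singular vector
    so the rotation is proper (determinant +1, no reflection).  Requires at
    least three non-collinear atom pairs.
    """
    m_mask = select_atoms(mobile.atoms, fit_selection)
    r_mask = select_atoms(reference.atoms, fit_selection)
    x = mobile.xyz[m_mask]
    y = reference.xyz[r_mask]
    if x.shape != y.shape:
        raise ValidationError(
            f"selection sizes differ: {x.shape[0]} mobile vs {y.shape[0]} reference atoms"
        )
    if x.shape[0] < 3:
        raise ValidationError(f"superposition needs >=3 atoms, got {x.shape[0]}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # collinear (rank < 2) selections leave the rotation under-determined
    if np.linalg.matrix_rank(yc, tol=1e-8) < 2 or np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise ValidationError("degenerate (collinear) atom selection")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = y.mean(axis=0) - rotation @ x.mean(axis=0)
    fitted = rmsd(x @ rotation.T + translation, y)
    return SuperpositionResult(rotation=rotation, translation=translation, fitted_rmsd=fitted)


@dataclass(frozen=True)
class RMSDSummary:
    """Per-frame RMSD trace with its mean and sample standard deviation."""

    per_frame: np.ndarray
    mean: float
    sd: float


def rmsd_series(
    traj: Trajectory,
    reference: CoordinateSet | None = None,
    fit_selection="protein:name=N,CA,C,O",
    measure_selection="protein",
    heavy_only: bool = True,
    superpose: bool = True,
) -> RMSDSummary:
    """RMSD of every frame against a reference after optional superposition.

    Each frame is rigidly fitted on ``fit_selection`` (backbone atoms by
    default) and the RMSD measured over ``measure_selection``; hydrogens
    are excluded from the measurement unless ``heavy_only=False``.  The
    reference defaults to the first frame.  The summary reports the mean
    and sample standard deviation over frames.
    """
    if reference is None:
        reference = traj.frame(0)
    measure = select_atoms(traj.atoms, measure_selection)
    if heavy_only:
        measure &= traj.atoms.elements != "H"
    if not measure.any():
        raise ValidationError("measure selection resolves to zero atoms")
    ref_measure = select_atoms(reference.atoms, measure_selection)
    if heavy_only:
        ref_measure &= reference.atoms.elements != "H"
    if ref_measure.sum() != measure.sum():
        raise ValidationError("measure selection sizes differ between trajectory and reference")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        if superpose:
            fit = kabsch_superpose(frame, reference, fit_selection)
            moved = fit.apply(frame.xyz)
        else:
            moved = frame.xyz
        values[i] = rmsd(moved[measure], reference.xyz[ref_measure])
    sd = float(values.std(ddof=1)) if traj.n_frames > 1 else 0.0
    return RMSDSummary(per_frame=values, mean=float(values.mean()), sd=sd)


def atom_pair_distances(
    coords: CoordinateSet, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Euclidean distances for the given atom-id pairs, in input order."""
    index = {int(a): i for i, a in enumerate(coords.atoms.ids)}
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        for atom in (a, b):
            if int(atom) not in index:
                raise ValidationError(f"unknown atom id {atom!r}")
        out[k] = float(np.linalg.norm(coords.xyz[index[int(a)]] - coords.xyz[index[int(b)]]))
    return out
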