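"""Internal coordinates (stretch/bend/torsion) and their Wilson B-matrix rows.

A B-matrix row is the gradient of one internal coordinate with respect to the
3N Cartesian coordinates.  Rows are used to project normal modes onto bonds
and angles, to build constrained displacement paths for finite-difference
force constants, and to assemble analytic gradients of the synthetic
harmonic models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["InternalCoordinate", "coordinate_value", "b_row", "b_matrix"]


@dataclass(frozen=True)
class InternalCoordinate:
    """A labelled stretch (2 atoms), bend (3) or torsion (4 atoms, 0-based)."""

    kind: str                 # "stretch" | "bend" | "torsion"
    atoms: tuple[int, ...]
    label: str

    _NATOMS = {"stretch": 2, "bend": 3, "torsion": 4}

    def __post_init__(self) -> None:
        if self.kind not in self._NATOMS:
            raise ValueError(f"unknown internal-coordinate kind {self.kind!r}")
        if len(self.atoms) != self._NATOMS[self.kind]:
            raise ValueError(
                f"{self.kind} needs {self._NATOMS[self.kind]} atoms, "
                f"got {len(self.atoms)}"
            )
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"atom indices must be distinct: {self.atoms}")


def _bond_value(x: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(x[i] - x[j]))


def _angle_value(x: np.ndarray, i: int, j: int, k: int) -> float:
    u = x[i] - x[j]
    v = x[k] - x[j]
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _torsion_value(x: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def coordinate_value(coord: InternalCoordinate, coords: np.ndarray) -> float:
    """Value of the internal coordinate (Å for stretches, radians otherwise)."""
    x = np.asarray(coords, dtype=float)
    if coord.kind == "stretch":
        return _bond_value(x, *coord.atoms)
    if coord.kind == "bend":
        return _angle_value(x, *coord.atoms)
    return _torsion_value(x, *coord.atoms)


def b_row(coord: InternalCoordinate, coords: np.ndarray) -> np.ndarray:
    """Wilson B-matrix row: d(coordinate)/d(Cartesians), shape (3N,).

    Analytic for all three kinds; rows annihilate rigid translations exactly
    (the per-atom blocks sum to zero by construction).
    """
    x = np.asarray(coords, dtype=float)
    n = x.shape[0]
    row = np.zeros((n, 3))
    a = coord.atoms

    if coord.kind == "stretch":
        i, j = a
        u = x[i] - x[j]
        u /= np.linalg.norm(u)
        row[i] = u
        row[j] = -u

    elif coord.kind == "bend":
        i, j, k = a
        u = x[i] - x[j]
        v = x[k] - x[j]
        ru = np.linalg.norm(u)
        rv = np.linalg.norm(v)
        u = u / ru
        v = v / rv
        cos_t = float(np.clip(np.dot(u, v), -1.0, 1.0))
        sin_t = float(np.sqrt(max(1.0 - cos_t * cos_t, 1e-24)))
        gi = (cos_t * u - v) / (ru * sin_t)
        gk = (cos_t * v - u) / (rv * sin_t)
        row[i] = gi
        row[k] = gk
        row[j] = -(gi + gk)

    else:
        # torsion: central differences of the exact dihedral on the four
        # atoms (step 1e-6 A; the value function is smooth away from the
        # linear-angle singularity, giving ~1e-11 accuracy, ample for
        # projections, outer products and Newton Jacobians)
        h = 1e-6
        for atom in a:
            for comp in range(3):
                xp = x.copy()
                xm = x.copy()
                xp[atom, comp] += h
                xm[atom, comp] -= h
                dplus = _torsion_value(xp, *a)
                dminus = _torsion_value(xm, *a)
                diff = dplus - dminus
                if diff > np.pi:       # branch crossing at +-pi
                    diff -= 2.0 * np.pi
                elif diff < -np.pi:
                    diff += 2.0 * np.pi
                row[atom, comp] = diff / (2.0 * h)

    return row.reshape(-1)


def b_matrix(coords_list: Iterable[InternalCoordinate],
             coords: np.ndarray) -> np.ndarray:
    """Stack of B rows, shape (n_coords, 3N)."""
    rows = [b_row(c, coords) for c in coords_list]
    if not rows:
        raise ValueError("empty internal-coordinate set")
    return np.vstack(rows)


def unique_labels(coords_list: Sequence[InternalCoordinate]) -> None:
    """Raise if labels collide within a coordinate set."""
    seen: set[str] = set()
    for c in coords_list:
        if c.label in seen:
            raise ValueError(f"duplicate internal-coordinate label {c.label!r}")
        seen.add(c.label)
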