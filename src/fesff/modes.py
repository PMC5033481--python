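"""Vibrational normal modes: computation, decomposition, assignment, scaling.

The engine diagonalizes the mass-weighted Cartesian Hessian
M^(-1/2)·H·M^(-1/2), optionally after Eckart projection of the six rigid
translation/rotation directions.  Wavenumbers are signed (negative encodes
imaginary).  Modes are projected onto internal coordinates through Wilson
B-matrix rows, which is how bond/angle character is quantified and how
calculated spectra are matched to observed band tables.

Reduced-mass conventions
------------------------
Two conventions coexist in the literature and they differ by the square of
the internal-coordinate projection:

* ``NormalModeSet.reduced_masses`` stores μ = (Σ_k c_k²)⁻¹ with
  c = M^(-1/2)·v and v the unit mass-weighted eigenvector — the convention
  of mainstream frequency-analysis output.  For a homonuclear diatomic this
  gives the atomic mass m, *not* m/2.
* :func:`projected_reduced_mass` gives μ_q = 1/(B_q·c)², the effective mass
  of the mode *with respect to a named internal coordinate*; for a diatomic
  stretch it equals the textbook pair reduced mass m₁m₂/(m₁+m₂) and it is
  the convention under which k = μω² returns the spring constant of the
  coordinate.  Force-constant extraction uses this one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bundle import QMBundle
from .internals import InternalCoordinate, b_row, b_matrix, unique_labels
from .units import wavenumber_from_eigenvalue

__all__ = [
    "NormalModeSet",
    "ModeAssignment",
    "compute_modes",
    "decompose_mode",
    "assign_modes",
    "apply_scale",
    "fit_scale_factor",
    "spectrum_report",
    "projected_reduced_mass",
]

TR_WAVENUMBER_FLOOR = 1e-3  # cm^-1; below this a mode counts as rigid-body


@dataclass
class NormalModeSet:
    """Eigenmodes of a mass-weighted Hessian, sorted by ascending wavenumber.

    ``cart_displacements[i]`` is the (3N,) un-mass-weighted displacement of
    mode ``i`` (M^(-1/2)·v, v the unit mass-weighted eigenvector).
    """

    frequencies: np.ndarray          # (3N,) cm^-1, negative = imaginary
    cart_displacements: np.ndarray   # (3N, 3N)
    reduced_masses: np.ndarray       # (3N,) amu
    masses: np.ndarray               # (N,) amu
    scale_factor: float = 1.0
    tr_projected: bool = False

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def mass_weighted_eigenvector(self, index: int) -> np.ndarray:
        v = self.cart_displacements[index] * np.sqrt(np.repeat(self.masses, 3))
        return v / np.linalg.norm(v)


def _eckart_projector(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Projector onto the orthogonal complement of mass-weighted rigid
    translations and rotations about the center of mass."""
    n = len(masses)
    sm = np.sqrt(masses)
    com = np.average(coords, axis=0, weights=masses)
    x = coords - com
    vecs = []
    for a in range(3):
        t = np.zeros((n, 3))
        t[:, a] = sm
        vecs.append(t.reshape(-1))
    for a in range(3):
        axis = np.zeros(3)
        axis[a] = 1.0
        r = np.cross(np.broadcast_to(axis, (n, 3)), x) * sm[:, None]
        vecs.append(r.reshape(-1))
    q, r = np.linalg.qr(np.column_stack(vecs))
    keep = np.abs(np.diag(r)) > 1e-10  # linear molecules drop one rotation
    q = q[:, keep]
    return np.eye(3 * n) - q @ q.T


def compute_modes(bundle: QMBundle, project_tr: bool = False) -> NormalModeSet:
    """Diagonalize the bundle's mass-weighted Hessian.

    Wavenumbers follow sign(λ)·(1/2πc)√|λ|; imaginary modes come out
    negative.  With ``project_tr`` the six rigid-body directions are removed
    (Eckart projection) before diagonalizing, guaranteeing exact zeros for
    translations/rotations.
    """
    h = bundle.require_hessian()
    masses = bundle.masses
    if np.any(masses <= 0):
        raise ValueError("non-positive atomic mass")
    inv_sqrt = 1.0 / np.sqrt(np.repeat(masses, 3))
    mw = h * np.outer(inv_sqrt, inv_sqrt)
    mw = 0.5 * (mw + mw.T)
    if project_tr:
        p = _eckart_projector(bundle.coords, masses)
        mw = p @ mw @ p
        mw = 0.5 * (mw + mw.T)
    lam, vecs = np.linalg.eigh(mw)
    freqs = np.array([wavenumber_from_eigenvalue(l) for l in lam])
    order = np.argsort(freqs, kind="stable")
    freqs = freqs[order]
    vecs = vecs[:, order]
    cart = vecs * inv_sqrt[:, None]          # columns: M^(-1/2) v
    red = 1.0 / np.sum(cart**2, axis=0)
    return NormalModeSet(
        frequencies=freqs,
        cart_displacements=cart.T.copy(),
        reduced_masses=red,
        masses=masses.copy(),
        tr_projected=bool(project_tr),
    )


def projected_reduced_mass(modes: NormalModeSet, index: int,
                           coordinate: InternalCoordinate,
                           coords: np.ndarray) -> float:
    """Effective mass of mode ``index`` along a named internal coordinate:
    μ_q = 1/(B_q·c)², c the un-mass-weighted displacement of the unit
    mass-weighted eigenvector.  Diverges (raises) if the mode has no
    component along the coordinate."""
    b = b_row(coordinate, coords)
    proj = float(b @ modes.cart_displacements[index])
    if abs(proj) < 1e-10:
        raise ValueError(
            f"mode {index} has no component along {coordinate.label!r}"
        )
    return 1.0 / proj**2


def decompose_mode(modes: NormalModeSet, index: int,
                   coords_set: Sequence[InternalCoordinate],
                   coords: np.ndarray) -> dict[str, float]:
    """Normalized |B·d| projection weights of one mode over a coordinate set.

    Weights sum to 1 over the provided set; a mode orthogonal to every
    coordinate (e.g. a rigid translation) gets all-zero weights.
    """
    if not coords_set:
        raise ValueError("empty internal-coordinate set")
    unique_labels(coords_set)
    if not 0 <= index < modes.n_modes:
        raise IndexError(f"mode index {index} out of range")
    d = modes.cart_displacements[index]
    b = b_matrix(coords_set, coords)
    raw = np.abs(b @ d)
    total = raw.sum()
    if total < 1e-10:
        return {c.label: 0.0 for c in coords_set}
    return {c.label: float(r / total) for c, r in zip(coords_set, raw)}


@dataclass
class ModeAssignment:
    """Greedy coordinate→mode matching by descending overlap weight."""

    assignments: dict[str, tuple[int, float]]  # label -> (mode index, weight)
    unassigned: list[str]

    def mode_of(self, label: str) -> int:
        return self.assignments[label][0]


def assign_modes(modes: NormalModeSet,
                 coords_set: Sequence[InternalCoordinate],
                 coords: np.ndarray,
                 threshold: float = 0.1) -> ModeAssignment:
    """Match each internal coordinate to its best unclaimed mode.

    Candidate (coordinate, mode) pairs are ranked by overlap weight; each
    coordinate claims its best still-free mode, ties broken toward the
    lower-frequency mode.  Pairs below ``threshold`` stay unassigned.
    Rigid-body (near-zero) modes never participate.
    """
    if not 0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    unique_labels(coords_set)
    weights = {}
    for i in range(modes.n_modes):
        if abs(modes.frequencies[i]) <= TR_WAVENUMBER_FLOOR:
            continue
        w = decompose_mode(modes, i, coords_set, coords)
        for lab, val in w.items():
            weights[(lab, i)] = val
    # globally greedy: best remaining (coordinate, mode) pair first;
    # ties broken toward the lower-frequency mode
    order = sorted(
        weights.items(),
        key=lambda kv: (-kv[1], modes.frequencies[kv[0][1]], kv[0][0]),
    )
    taken_modes: set[int] = set()
    assigned: dict[str, tuple[int, float]] = {}
    for (lab, i), w in order:
        if w < threshold:
            break
        if lab in assigned or i in taken_modes:
            continue
        assigned[lab] = (i, w)
        taken_modes.add(i)
    unassigned = [c.label for c in coords_set if c.label not in assigned]
    return ModeAssignment(assignments=assigned, unassigned=unassigned)


def apply_scale(modes: NormalModeSet, factor: float) -> NormalModeSet:
    """Multiply all frequencies by a scale factor (displacements untouched)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return replace(
        modes,
        frequencies=modes.frequencies * factor,
        cart_displacements=modes.cart_displacements.copy(),
        reduced_masses=modes.reduced_masses.copy(),
        masses=modes.masses.copy(),
        scale_factor=modes.scale_factor * factor,
    )


def fit_scale_factor(pairs: Sequence[tuple[float, float]]) -> float:
    """Least-squares-through-origin factor mapping calculated to observed:
    f = Σ obs·calc / Σ calc²."""
    if not pairs:
        raise ValueError("need at least one (calculated, observed) pair")
    calc = np.array([p[0] for p in pairs], dtype=float)
    obs = np.array([p[1] for p in pairs], dtype=float)
    if np.any(calc == 0):
        raise ValueError("calculated wavenumbers must be nonzero")
    return float(np.dot(obs, calc) / np.dot(calc, calc))


def spectrum_report(modes: NormalModeSet,
                    assignment: ModeAssignment,
                    observed: pd.DataFrame) -> pd.DataFrame:
    """Compare scaled calculated frequencies with an observed band table.

    ``observed`` needs columns ``label`` and ``wavenumber``; rows whose label
    is assigned to no mode are flagged, not dropped.  The result carries a
    ``mad`` attribute (mean absolute deviation over matched rows) and is
    sorted by label so row order of the input is immaterial.
    """
    if not {"label", "wavenumber"}.issubset(observed.columns):
        raise ValueError("observed table needs 'label' and 'wavenumber' columns")
    rows = []
    for _, rec in observed.sort_values("label").iterrows():
        lab = rec["label"]
        obs = float(rec["wavenumber"])
        if lab in assignment.assignments:
            i, w = assignment.assignments[lab]
            calc = float(modes.frequencies[i])
            rows.append({"label": lab, "observed": obs, "calculated": calc,
                         "deviation": calc - obs, "matched": True})
        else:
            rows.append({"label": lab, "observed": obs,
                         "calculated": np.nan, "deviation": np.nan,
                         "matched": False})
    report = pd.DataFrame(rows).reset_index(drop=True)
    matched = report[report["matched"]]
    report.attrs["mad"] = (
        float(matched["deviation"].abs().mean()) if len(matched) else np.nan
    )
    return report
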