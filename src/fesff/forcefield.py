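"""Harmonic force constants by two routes, torsion fitting, parameter sets.

Route 1 (*mode*): an assigned normal mode gives k = μ_q·ω² with μ_q the
mode's reduced mass projected onto the target internal coordinate.  Exact
when the mode is pure; biased by mode mixing otherwise.

Route 2 (*finite difference*): displace the coordinate on a symmetric
stencil and differentiate the energy numerically.  Displaced geometries are
built by constrained solution — the target internal coordinate moves, every
other member of a non-redundant internal set is held at its equilibrium
value — mirroring scan protocols where all atoms not defining the probed
coordinate are relaxed.  A "rigid" path (move only the end atoms along the
bond axis / in the angle plane) is also available; it does not isolate the
coordinate whenever other terms share its atoms.

The two routes are cross-checked with a configurable tolerance (default
20%, the level at which the routes were historically found to agree on
[2Fe-2S] stretches).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .internals import InternalCoordinate, b_matrix, coordinate_value
from .modes import (
    ModeAssignment,
    NormalModeSet,
    TR_WAVENUMBER_FLOOR,
    projected_reduced_mass,
)
from .synthetic import TorsionScan
from .units import convert_force_constant, eigenvalue_from_wavenumber

__all__ = [
    "ForceConstant",
    "TorsionParams",
    "ForceFieldParamSet",
    "mode_force_constant",
    "finite_difference_fc",
    "displaced_geometry",
    "consistency_check",
    "fit_cosine_series",
    "build_param_set",
]

DEFAULT_FD_TOLERANCE = 0.20
DEFAULT_STEP = {"stretch": 0.01, "bend": math.radians(0.5),
                "torsion": math.radians(0.5)}

_STENCILS = {
    5: ([-2, -1, 0, 1, 2], [-1.0, 16.0, -30.0, 16.0, -1.0], 12.0),
    7: ([-3, -2, -1, 0, 1, 2, 3],
        [2.0, -27.0, 270.0, -490.0, 270.0, -27.0, 2.0], 180.0),
}


@dataclass(frozen=True)
class ForceConstant:
    """A typed stretch (K) or bend (H) constant with unit bookkeeping."""

    label: str
    kind: str                       # "K-stretch" | "H-bend"
    value: float                    # kcal/mol/A^2 (K) or kcal/mol/rad^2 (H)
    method: str                     # "mode" | "finite_difference" | "manual"
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("K-stretch", "H-bend"):
            raise ValueError(f"unknown force-constant kind {self.kind!r}")
        if self.value < 0:
            raise ValueError(f"negative force constant for {self.label}")

    @property
    def value_mdyne(self) -> Optional[float]:
        """mdyne/Å equivalent; stretches only (bends are per rad²)."""
        if self.kind != "K-stretch":
            return None
        return convert_force_constant(self.value, "kcal_per_mol_A2",
                                      "mdyne_per_A")


@dataclass
class TorsionParams:
    """Cosine-series torsion: terms (n, Vₙ, γ in degrees), Amber convention."""

    label: str
    terms: list[tuple[int, float, float]]
    offset: float = 0.0
    residual_rms: float = 0.0
    idivf: int = 1

    def __post_init__(self) -> None:
        for n, _, _ in self.terms:
            if int(n) != n or n < 1:
                raise ValueError("torsion periodicity must be integer >= 1")
        if self.residual_rms < 0:
            raise ValueError("residual must be non-negative")


@dataclass
class ForceFieldParamSet:
    """Typed stretch/bend/torsion records, the frcmod payload."""

    stretches: list[ForceConstant] = field(default_factory=list)
    bends: list[ForceConstant] = field(default_factory=list)
    torsions: list[TorsionParams] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.label for r in self.stretches + self.bends] + [
            t.label for t in self.torsions]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate parameter labels in set")

    def by_label(self, label: str):
        for r in self.stretches + self.bends + self.torsions:
            if r.label == label:
                return r
        raise KeyError(label)

    def to_json(self, path: str | Path) -> None:
        d = {
            "stretches": [asdict(r) for r in self.stretches],
            "bends": [asdict(r) for r in self.bends],
            "torsions": [asdict(t) for t in self.torsions],
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(d, sort_keys=True, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ForceFieldParamSet":
        d = json.loads(Path(path).read_text())
        return cls(
            stretches=[ForceConstant(**r) for r in d["stretches"]],
            bends=[ForceConstant(**r) for r in d["bends"]],
            torsions=[TorsionParams(
                label=t["label"],
                terms=[tuple(x) for x in t["terms"]],
                offset=t["offset"], residual_rms=t["residual_rms"],
                idivf=t.get("idivf", 1)) for t in d["torsions"]],
            metadata=d.get("metadata", {}),
        )


# ------------------------------------------------------------------ route 1

def mode_force_constant(modes: NormalModeSet, index: int,
                        coordinate: Optional[InternalCoordinate] = None,
                        coords: Optional[np.ndarray] = None) -> ForceConstant:
    """Per-mode effective constant k = μ·ω² for the mode at ``index``.

    With ``coordinate`` (and the geometry) the projected reduced mass is
    used, so a pure stretch mode returns exactly the spring constant of that
    bond; without it the stored per-mode reduced mass is used and the value
    is convention-dependent (documented on :mod:`fesff.modes`).
    """
    nu = float(modes.frequencies[index])
    if nu <= TR_WAVENUMBER_FLOOR:
        raise ValueError(
            f"mode {index} has non-positive wavenumber {nu:.3f} cm^-1; "
            "force constant undefined"
        )
    lam = eigenvalue_from_wavenumber(nu)   # omega^2 in kcal/mol/A^2/amu
    if coordinate is not None:
        if coords is None:
            raise ValueError("coords required with a coordinate")
        mu = projected_reduced_mass(modes, index, coordinate, coords)
        label = coordinate.label
        kind = "K-stretch" if coordinate.kind == "stretch" else "H-bend"
    else:
        mu = float(modes.reduced_masses[index])
        label = f"mode[{index}]"
        kind = "K-stretch"
    return ForceConstant(label=label, kind=kind, value=mu * lam,
                         method="mode",
                         note=f"from mode {index} at {nu:.2f} cm^-1")


# ------------------------------------------------------------------ route 2

def _rigid_displacement(coords: np.ndarray, coordinate: InternalCoordinate,
                        delta: float) -> np.ndarray:
    """Move only the coordinate's end atoms: symmetric along the bond axis
    for stretches, in the angle plane for bends, about the central bond for
    torsions."""
    x = coords.copy()
    if coordinate.kind == "stretch":
        i, j = coordinate.atoms
        u = x[i] - x[j]
        u /= np.linalg.norm(u)
        x[i] += 0.5 * delta * u
        x[j] -= 0.5 * delta * u
    elif coordinate.kind == "bend":
        i, j, k = coordinate.atoms
        u = x[i] - x[j]
        v = x[k] - x[j]
        axis = np.cross(u, v)
        axis /= np.linalg.norm(axis)
        x[i] = x[j] + _rotate(u, axis, 0.5 * delta)
        x[k] = x[j] + _rotate(v, axis, -0.5 * delta)
    else:
        i, j, k, l = coordinate.atoms
        axis = x[k] - x[j]
        axis /= np.linalg.norm(axis)
        x[l] = x[k] + _rotate(x[l] - x[k], axis, delta)
    return x


def _rotate(vec: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return (vec * c + np.cross(axis, vec) * s
            + axis * np.dot(axis, vec) * (1.0 - c))


def displaced_geometry(coords: np.ndarray, coordinate: InternalCoordinate,
                       delta: float,
                       hold: Optional[Sequence[InternalCoordinate]] = None,
                       tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Geometry with the target internal displaced by ``delta``.

    Without ``hold`` this is the rigid end-atom displacement.  With ``hold``
    (the other members of a non-redundant internal-coordinate set) the
    geometry solves q_target = q₀+δ, q_hold = q₀ by Gauss-Newton on the
    Wilson B matrix, so only the probed coordinate moves.
    """
    x0 = np.asarray(coords, dtype=float)
    if not hold:
        return _rigid_displacement(x0, coordinate, delta)
    all_coords = [coordinate] + [c for c in hold if c.atoms != coordinate.atoms
                                 or c.kind != coordinate.kind]
    base = np.array([coordinate_value(c, x0) for c in all_coords])
    e_target = np.zeros(len(all_coords))
    e_target[0] = 1.0

    def residual(xx: np.ndarray, desired: np.ndarray) -> np.ndarray:
        r = np.array([coordinate_value(c, xx) for c in all_coords]) - desired
        for idx, c in enumerate(all_coords):
            if c.kind == "torsion":  # wrap periodic residuals into (-pi, pi]
                r[idx] = math.remainder(r[idx], 2.0 * math.pi)
        return r

    def solve(x: np.ndarray, desired: np.ndarray) -> np.ndarray:
        resid = residual(x, desired)
        for _ in range(max_iter):
            if np.abs(resid).max() < tol:
                return x
            b = b_matrix(all_coords, x)
            dx, *_ = np.linalg.lstsq(b, -resid, rcond=None)
            # backtracking guards against overshoot with ill-conditioned B
            norm0 = np.linalg.norm(resid)
            for scale in (1.0, 0.5, 0.25, 0.125, 0.0625):
                x_try = x + scale * dx.reshape(x.shape)
                r_try = residual(x_try, desired)
                if np.linalg.norm(r_try) < norm0:
                    x, resid = x_try, r_try
                    break
            else:
                break
        if np.abs(resid).max() < tol:
            return x
        raise RuntimeError(
            f"constrained displacement for {coordinate.label!r} did not "
            f"converge (max residual {np.abs(resid).max():.2e})"
        )

    # continuation: walk the target in sub-steps with a first-order
    # pseudo-inverse predictor (keeps every held coordinate fixed to
    # O(step^2), so each Newton solve starts inside its convergence basin)
    n_sub = max(1, math.ceil(abs(delta) / 0.005))
    x = x0
    for s in range(1, n_sub + 1):
        desired = base + (delta * s / n_sub) * e_target
        b = b_matrix(all_coords, x)
        dx, *_ = np.linalg.lstsq(b, -residual(x, desired), rcond=None)
        x = solve(x + dx.reshape(x.shape), desired)
    return x


def finite_difference_fc(energy_oracle: Callable[[np.ndarray], float],
                         model_coords: np.ndarray,
                         coordinate: InternalCoordinate,
                         step: Optional[float] = None,
                         npoints: int = 5,
                         hold: Optional[Sequence[InternalCoordinate]] = None,
                         ) -> ForceConstant:
    """Second derivative of the energy along one internal coordinate.

    Central stencil over ``npoints`` ∈ {5, 7} structures; the 5-point form
    is (−E₂+16E₁−30E₀+16E₋₁−E₋₂)/(12h²), exact for quadratic profiles.
    """
    if npoints not in _STENCILS:
        raise ValueError(f"npoints must be 5 or 7, got {npoints}")
    if step is None:
        step = DEFAULT_STEP[coordinate.kind]
    if step <= 0:
        raise ValueError("step must be positive")
    offsets, weights, denom = _STENCILS[npoints]
    energies = []
    for m in offsets:
        x = (np.asarray(model_coords, dtype=float) if m == 0
             else displaced_geometry(model_coords, coordinate, m * step, hold))
        energies.append(float(energy_oracle(x)))
    second = sum(w * e for w, e in zip(weights, energies)) / (denom * step**2)
    kind = "K-stretch" if coordinate.kind == "stretch" else "H-bend"
    return ForceConstant(
        label=coordinate.label, kind=kind, value=max(second, 0.0),
        method="finite_difference",
        note=f"{npoints}-point stencil, h={step:.4g}"
             f"{', constrained' if hold else ', rigid'}",
    )


def consistency_check(k_mode: ForceConstant, k_fd: ForceConstant,
                      tolerance: float = DEFAULT_FD_TOLERANCE
                      ) -> tuple[bool, float]:
    """Cross-check the two routes: passes iff |k_mode−k_fd|/k_fd ≤ tolerance.

    Returns (passed, ratio k_mode/k_fd); the ratio is always reported.
    """
    if k_mode.label != k_fd.label:
        raise ValueError(
            f"label mismatch: {k_mode.label!r} vs {k_fd.label!r}"
        )
    if k_fd.value == 0:
        raise ValueError("finite-difference value is zero; ratio undefined")
    ratio = k_mode.value / k_fd.value
    passed = abs(k_mode.value - k_fd.value) / abs(k_fd.value) <= tolerance
    return passed, ratio


# --------------------------------------------------------------- torsion fit

def fit_cosine_series(scan: TorsionScan, periodicities: Sequence[int],
                      fix_phases: bool = True,
                      label: str = "torsion") -> TorsionParams:
    """Least-squares cosine series through a dihedral scan.

    With ``fix_phases`` the phases are restricted to {0°, 180°} and the model
    is linear in the barriers Vₙ plus an offset; otherwise cos/sin pairs are
    fitted (still linear) and phases are free.  The scan grid must be uniform
    (enforced by :class:`TorsionScan`) and the system determined.
    """
    ns = sorted(set(int(n) for n in periodicities))
    if any(n < 1 for n in ns):
        raise ValueError("periodicities must be positive integers")
    phi = np.radians(scan.angles_deg)
    npts = len(phi)
    ncoef = 1 + len(ns) * (1 if fix_phases else 2)
    if ncoef > npts:
        raise ValueError(
            f"underdetermined fit: {ncoef} coefficients, {npts} scan points"
        )
    cols = [np.ones(npts)]
    for n in ns:
        cols.append(np.cos(n * phi))
        if not fix_phases:
            cols.append(np.sin(n * phi))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, scan.energies, rcond=None)
    resid = scan.energies - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))

    terms: list[tuple[int, float, float]] = []
    barrier_sum = 0.0
    for idx, n in enumerate(ns):
        if fix_phases:
            a = coef[1 + idx]
            v, gamma = abs(float(a)), (0.0 if a >= 0 else 180.0)
        else:
            a = coef[1 + 2 * idx]
            b = coef[2 + 2 * idx]
            v = float(np.hypot(a, b))
            gamma = math.degrees(math.atan2(b, a)) % 360.0
        if v > 1e-12:
            terms.append((n, v, gamma))
            barrier_sum += v
    offset = float(coef[0]) - barrier_sum
    return TorsionParams(label=label, terms=terms, offset=offset,
                         residual_rms=rms)


# ------------------------------------------------------------- assembly

def _base_label(label: str) -> str:
    """Strip the uniquifying '#k' suffix used for equivalent coordinates."""
    return label.split("#")[0]


def build_param_set(assignment: ModeAssignment,
                    modes: NormalModeSet,
                    coords_set: Sequence[InternalCoordinate],
                    coords: np.ndarray,
                    fd_results: Optional[Mapping[str, ForceConstant]] = None,
                    torsions: Optional[Sequence[TorsionParams]] = None,
                    metadata: Optional[dict] = None,
                    tolerance: float = DEFAULT_FD_TOLERANCE,
                    ) -> ForceFieldParamSet:
    """Assemble a typed parameter set from assigned modes.

    One record per assigned coordinate; a finite-difference value replaces
    the mode value when provided (it probes the coordinate directly), with
    the mode/finite-difference ratio logged in the record note when the two
    disagree beyond ``tolerance``.  Coordinates sharing a base label (e.g.
    the two symmetry-equivalent Fe-S(t) bonds) are averaged into one record.
    """
    by_label = {c.label: c for c in coords_set}
    fd_results = fd_results or {}
    collected: dict[str, list[ForceConstant]] = {}
    for label, (mode_idx, _w) in assignment.assignments.items():
        coordinate = by_label[label]
        if coordinate.kind == "torsion":
            continue  # torsion parameters come from scans, not modes
        if modes.frequencies[mode_idx] <= 0:
            raise ValueError(
                f"coordinate {label!r} assigned to non-positive-frequency "
                f"mode {mode_idx}"
            )
        k_mode = mode_force_constant(modes, mode_idx, coordinate, coords)
        record = k_mode
        if label in fd_results:
            k_fd = fd_results[label]
            passed, ratio = consistency_check(k_mode, k_fd, tolerance)
            note = k_fd.note + f"; mode/fd ratio {ratio:.3f}"
            if not passed:
                note += f" (beyond {tolerance:.0%} tolerance)"
            record = ForceConstant(label=k_fd.label, kind=k_fd.kind,
                                   value=k_fd.value,
                                   method="finite_difference", note=note)
        collected.setdefault(_base_label(label), []).append(record)

    stretches: list[ForceConstant] = []
    bends: list[ForceConstant] = []
    for base, records in collected.items():
        kinds = {r.kind for r in records}
        if len(kinds) > 1:
            raise ValueError(
                f"coordinates labelled {base!r} mix kinds {sorted(kinds)}"
            )
        kind = kinds.pop()
        value = float(np.mean([r.value for r in records]))
        note = records[0].note if len(records) == 1 else (
            f"mean of {len(records)} equivalent coordinates")
        method = records[0].method
        rec = ForceConstant(label=base, kind=kind, value=value,
                            method=method, note=note)
        (stretches if kind == "K-stretch" else bends).append(rec)

    return ForceFieldParamSet(
        stretches=stretches, bends=bends,
        torsions=list(torsions or []),
        metadata=dict(metadata or {}),
    )
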