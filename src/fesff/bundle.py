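"""Cluster-level quantum-chemistry payload: the QM bundle.

A :class:`QMBundle` carries everything downstream stages need from an
electronic-structure run on a metal cluster: geometry, masses, the Cartesian
Hessian, partial charges and (optionally) an ESP grid, plus total charge and
spin multiplicity as provenance metadata.  Canonical internal units are
Å, amu, kcal·mol⁻¹·Å⁻² and elementary charges; readers normalize on load.

Three serializations are supported:

* a versioned JSON schema (``qmbundle/1``) with byte-stable canonical output,
* plain XYZ for the geometry alone,
* a read-only subset of the Gaussian formatted-checkpoint (fchk) layout
  covering ``Atomic numbers``, ``Current cartesian coordinates`` and the
  lower-triangular ``Cartesian Force Constants`` block.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .units import (
    ATOMIC_NUMBERS,
    CONSTANTS,
    ELEMENT_OF_Z,
    atomic_mass,
)

__all__ = [
    "QMBundle",
    "read_bundle",
    "write_bundle",
    "read_xyz",
    "write_xyz",
    "read_fchk_subset",
    "write_fchk_subset",
]

log = logging.getLogger(__name__)

SCHEMA = "qmbundle/1"
HESSIAN_SYMMETRY_RTOL = 1e-8
CHARGE_SUM_TOL = 1e-6

_HARTREE_BOHR2_TO_KCAL_A2 = CONSTANTS.hartree_to_kcal / CONSTANTS.bohr_to_angstrom**2


@dataclass
class QMBundle:
    """Validated cluster payload in canonical units (Å, amu, kcal·mol⁻¹·Å⁻²)."""

    elements: list[str]
    coords: np.ndarray                       # (N, 3) A
    masses: Optional[np.ndarray] = None      # (N,) amu; auto-filled
    hessian: Optional[np.ndarray] = None     # (3N, 3N) kcal/mol/A^2
    charges: Optional[np.ndarray] = None     # (N,) e
    esp_points: Optional[np.ndarray] = None  # (M, 3) A
    esp_potentials: Optional[np.ndarray] = None  # (M,) e/A
    total_charge: int = 0
    spin_multiplicity: int = 1
    label: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} elements (expected ({n}, 3))"
            )
        for e in self.elements:
            atomic_mass(e)  # raises for unknown elements
        if self.masses is None:
            self.masses = np.array([atomic_mass(e) for e in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise ValueError("masses length does not match elements")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.hessian is not None:
            h = np.asarray(self.hessian, dtype=float)
            if h.shape != (3 * n, 3 * n):
                raise ValueError(
                    f"hessian shape {h.shape} does not match 3N={3 * n}"
                )
            scale = np.abs(h).max()
            if scale > 0:
                asym = np.abs(h - h.T).max() / scale
                if asym > HESSIAN_SYMMETRY_RTOL:
                    raise ValueError(
                        f"hessian asymmetric beyond tolerance "
                        f"(max|H-H^T|/max|H| = {asym:.3e})"
                    )
            self.hessian = 0.5 * (h + h.T)
        if self.charges is not None:
            q = np.asarray(self.charges, dtype=float)
            if q.shape != (n,):
                raise ValueError("charges length does not match elements")
            if abs(q.sum() - self.total_charge) > CHARGE_SUM_TOL:
                raise ValueError(
                    f"charges sum to {q.sum():.6f}, expected total charge "
                    f"{self.total_charge}"
                )
            self.charges = q
        if (self.esp_points is None) != (self.esp_potentials is None):
            raise ValueError("esp_points and esp_potentials must come together")
        if self.esp_points is not None:
            self.esp_points = np.asarray(self.esp_points, dtype=float)
            self.esp_potentials = np.asarray(self.esp_potentials, dtype=float)
            if self.esp_points.shape != (len(self.esp_potentials), 3):
                raise ValueError("ESP grid points/potentials shape mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def require_hessian(self) -> np.ndarray:
        if self.hessian is None:
            raise ValueError("bundle has no Hessian")
        return self.hessian


# ---------------------------------------------------------------- JSON bundle

def _fmt(x: float) -> float:
    if not math.isfinite(x):
        raise ValueError("non-finite value in bundle; refusing to serialize")
    return x


def _bundle_to_dict(b: QMBundle) -> dict:
    d: dict = {
        "schema": SCHEMA,
        "label": b.label,
        "elements": list(b.elements),
        "coords_A": [[_fmt(v) for v in row] for row in b.coords.tolist()],
        "masses_amu": [_fmt(v) for v in b.masses.tolist()],
        "total_charge": int(b.total_charge),
        "spin_multiplicity": int(b.spin_multiplicity),
    }
    if b.hessian is not None:
        d["hessian_unit"] = "kcal_per_mol_A2"
        d["hessian"] = [[_fmt(v) for v in row] for row in b.hessian.tolist()]
    if b.charges is not None:
        d["charges_e"] = [_fmt(v) for v in b.charges.tolist()]
    if b.esp_points is not None:
        d["esp_points_A"] = [[_fmt(v) for v in r] for r in b.esp_points.tolist()]
        d["esp_potentials"] = [_fmt(v) for v in b.esp_potentials.tolist()]
    if b.extra:
        d["extra"] = b.extra
    return d


def write_bundle(bundle: QMBundle, path: str | Path) -> None:
    """Serialize canonically: sorted keys, fixed float repr, trailing newline.

    Identical bundles produce identical bytes.
    """
    text = json.dumps(_bundle_to_dict(bundle), sort_keys=True,
                      separators=(",", ":")) + "\n"
    Path(path).write_text(text)


def read_bundle(path: str | Path) -> QMBundle:
    """Load and fully validate a JSON bundle; units normalized internally."""
    d = json.loads(Path(path).read_text())
    schema = d.get("schema")
    if schema != SCHEMA:
        raise ValueError(f"unrecognized bundle schema {schema!r} in {path}")
    hessian = None
    if "hessian" in d:
        hessian = np.asarray(d["hessian"], dtype=float)
        unit = d.get("hessian_unit", "kcal_per_mol_A2")
        if unit == "hartree_per_bohr2":
            hessian = hessian * _HARTREE_BOHR2_TO_KCAL_A2
        elif unit != "kcal_per_mol_A2":
            raise ValueError(f"unknown hessian unit tag {unit!r}")
    else:
        log.warning("bundle %s has no Hessian block", path)
    charges = np.asarray(d["charges_e"], float) if "charges_e" in d else None
    esp_p = np.asarray(d["esp_points_A"], float) if "esp_points_A" in d else None
    esp_v = np.asarray(d["esp_potentials"], float) if "esp_potentials" in d else None
    return QMBundle(
        elements=list(d["elements"]),
        coords=np.asarray(d["coords_A"], dtype=float),
        masses=np.asarray(d["masses_amu"], dtype=float),
        hessian=hessian,
        charges=charges,
        esp_points=esp_p,
        esp_potentials=esp_v,
        total_charge=int(d["total_charge"]),
        spin_multiplicity=int(d["spin_multiplicity"]),
        label=d.get("label", ""),
        extra=d.get("extra", {}),
    )


# ------------------------------------------------------------------------ XYZ

def write_xyz(bundle: QMBundle, path: str | Path, comment: str = "") -> None:
    lines = [str(bundle.n_atoms), comment or bundle.label]
    for el, (x, y, z) in zip(bundle.elements, bundle.coords):
        lines.append(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> QMBundle:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return QMBundle(elements=elements, coords=np.array(coords),
                    label=lines[1].strip())


# ---------------------------------------------------- formatted checkpoint IO

def _fchk_scalar_line(name: str, kind: str, value: int) -> str:
    return f"{name:<40s}   {kind}     {value:12d}"


def _fchk_array_header(name: str, kind: str, n: int) -> str:
    return f"{name:<40s}   {kind}   N={n:12d}"


def write_fchk_subset(bundle: QMBundle, path: str | Path,
                      title: str = "synthetic cluster") -> None:
    """Write the fchk subset the reader understands (atomic units).

    Intended for fixture generation and round-trip tests; coordinates go out
    in bohr and the Hessian, if present, in hartree/bohr² lower-triangular
    packed order, mirroring the formatted-checkpoint conventions.
    """
    n = bundle.n_atoms
    lines = [title[:72],
             "SP        synthetic                                   synthetic"]
    lines.append(_fchk_scalar_line("Number of atoms", "I", n))
    lines.append(_fchk_scalar_line("Charge", "I", bundle.total_charge))
    lines.append(_fchk_scalar_line("Multiplicity", "I", bundle.spin_multiplicity))

    z = [ATOMIC_NUMBERS[e] for e in bundle.elements]
    lines.append(_fchk_array_header("Atomic numbers", "I", n))
    for i in range(0, n, 6):
        lines.append("".join(f"{v:12d}" for v in z[i:i + 6]))

    flat = (bundle.coords / CONSTANTS.bohr_to_angstrom).reshape(-1)
    lines.append(_fchk_array_header("Current cartesian coordinates", "R", flat.size))
    for i in range(0, flat.size, 5):
        lines.append("".join(f"{v:16.8E}" for v in flat[i:i + 5]))

    if bundle.hessian is not None:
        h = bundle.hessian / _HARTREE_BOHR2_TO_KCAL_A2
        tri = h[np.tril_indices(3 * n)]
        lines.append(_fchk_array_header("Cartesian Force Constants", "R", tri.size))
        for i in range(0, tri.size, 5):
            lines.append("".join(f"{v:16.8E}" for v in tri[i:i + 5]))

    Path(path).write_text("\n".join(lines) + "\n")


def _read_fchk_block(lines: list[str], start: int, n: int,
                     kind: str) -> np.ndarray:
    per_line = 6 if kind == "I" else 5
    vals: list[float] = []
    i = start + 1
    while len(vals) < n:
        if i >= len(lines):
            raise ValueError(
                f"truncated block near line {start + 1}: expected {n} values, "
                f"got {len(vals)}"
            )
        parts = lines[i].split()
        if not parts or len(parts) > per_line:
            raise ValueError(f"malformed fchk data at line {i + 1}")
        vals.extend(float(p) for p in parts)
        i += 1
    if len(vals) != n:
        raise ValueError(f"block starting at line {start + 1} over-ran: "
                         f"{len(vals)} values for N={n}")
    return np.array(vals)


def read_fchk_subset(path: str | Path) -> QMBundle:
    """Parse the formatted-checkpoint subset into a canonical-unit bundle.

    ``Atomic numbers`` and ``Current cartesian coordinates`` are mandatory;
    the lower-triangular ``Cartesian Force Constants`` block is optional and
    expanded symmetrically when present.
    """
    lines = Path(path).read_text().splitlines()
    blocks: dict[str, tuple[int, str, int]] = {}
    scalars: dict[str, int] = {}
    for idx, ln in enumerate(lines):
        if len(ln) > 43 and ln[40:47].strip() in ("I", "R") and "N=" in ln:
            name = ln[:40].strip()
            kind = ln[40:47].strip()
            n = int(ln.split("N=")[1])
            blocks[name] = (idx, kind, n)
        elif len(ln) > 43 and ln[40:47].strip() in ("I", "R"):
            name = ln[:40].strip()
            try:
                scalars[name] = int(float(ln[47:].strip()))
            except ValueError:
                pass

    for required in ("Atomic numbers", "Current cartesian coordinates"):
        if required not in blocks:
            raise ValueError(f"fchk file {path} missing mandatory block "
                             f"{required!r}")

    idx, kind, n = blocks["Atomic numbers"]
    z = _read_fchk_block(lines, idx, n, kind).astype(int)
    try:
        elements = [ELEMENT_OF_Z[int(v)] for v in z]
    except KeyError as exc:
        raise ValueError(f"unknown atomic number {exc} in {path}") from None

    idx, kind, m = blocks["Current cartesian coordinates"]
    if m != 3 * len(elements):
        raise ValueError("coordinate block size does not match atom count")
    coords = (_read_fchk_block(lines, idx, m, kind).reshape(-1, 3)
              * CONSTANTS.bohr_to_angstrom)

    hessian = None
    if "Cartesian Force Constants" in blocks:
        idx, kind, t = blocks["Cartesian Force Constants"]
        dim = 3 * len(elements)
        expected = dim * (dim + 1) // 2
        if t != expected:
            raise ValueError(
                f"force-constant block has {t} values, expected {expected}"
            )
        tri = _read_fchk_block(lines, idx, t, kind)
        hessian = np.zeros((dim, dim))
        hessian[np.tril_indices(dim)] = tri
        hessian = hessian + hessian.T - np.diag(np.diag(hessian))
        hessian *= _HARTREE_BOHR2_TO_KCAL_A2
    else:
        log.warning("fchk file %s lacks a force-constant block", path)

    return QMBundle(
        elements=elements,
        coords=coords,
        hessian=hessian,
        total_charge=scalars.get("Charge", 0),
        spin_multiplicity=scalars.get("Multiplicity", 1),
        label=lines[0].strip() if lines else "",
    )
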