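"""Amber force-field artifacts: frcmod parameter files and prepin templates.

The fixed-column dialects written here are documented in the repository
(``docs/methods.md``) and are round-trip safe: ``parse(write(x))`` recovers
``x`` and ``write(parse(f))`` reproduces ``f`` byte for byte.  Output is
locale-independent and byte-stable for identical inputs.

Energy convention for stretches/bends is explicit: ``full`` emits the
physical second derivative k (E = ½k·Δr²), ``half`` the Amber-native K = k/2
(E = K·Δr²).  The convention in force is recorded on the title line because
parameter files in the wild are silent about it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .charges import ChargeSet
from .forcefield import ForceConstant, ForceFieldParamSet, TorsionParams

__all__ = [
    "FrcmodDocument",
    "PrepinTemplate",
    "default_typing",
    "write_frcmod",
    "parse_frcmod",
    "frcmod_to_params",
    "write_prepin",
    "parse_prepin",
]

# types that need no MASS record (standard Amber/GAFF types)
STANDARD_TYPES = {"C", "CT", "CA", "N", "NB", "NA", "O", "O2", "OH", "OW",
                  "HW", "H", "H1", "HA", "HS", "S", "SH", "X"}
SECTION_HEADERS = ("MASS", "BOND", "ANGL", "DIHE", "NONB")
CONVENTIONS = ("full", "half")


@dataclass
class FrcmodDocument:
    """In-memory frcmod: MASS/BOND/ANGL/DIHE/NONB records."""

    title: str = "frcmod"
    masses: list[tuple[str, float]] = field(default_factory=list)
    bonds: list[tuple[str, str, float, float]] = field(default_factory=list)
    angles: list[tuple[str, str, str, float, float]] = field(
        default_factory=list)
    # (t1, t2, t3, t4, idivf, pk, phase_deg, pn) with pn < 0 -> more terms
    dihedrals: list[tuple[str, str, str, str, int, float, float, float]] = \
        field(default_factory=list)
    nonbonded: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {t for t, _ in self.masses} | STANDARD_TYPES
        for rec in self.bonds:
            types = rec[:2]
            self._check_types(types, known)
        for rec in self.angles:
            self._check_types(rec[:3], known)
        for rec in self.dihedrals:
            self._check_types(rec[:4], known)

    @staticmethod
    def _check_types(types: Sequence[str], known: set[str]) -> None:
        for t in types:
            if len(t) > 2:
                raise ValueError(f"atom-type name {t!r} exceeds 2 characters")
            if t not in known:
                raise ValueError(
                    f"atom type {t!r} has no MASS record and is not a known "
                    f"standard type"
                )


def _types_field(types: Sequence[str]) -> str:
    return "-".join(f"{t:<2s}" for t in types)


def write_frcmod_document(doc: FrcmodDocument, path: str | Path) -> None:
    lines = [doc.title]
    lines.append("MASS")
    for t, m in doc.masses:
        lines.append(f"{t:<2s}  {m:10.4f}")
    lines.append("")
    lines.append("BOND")
    for t1, t2, k, req in doc.bonds:
        lines.append(f"{_types_field((t1, t2)):<5s}{k:8.2f}{req:8.3f}")
    lines.append("")
    lines.append("ANGL")
    for t1, t2, t3, k, theta in doc.angles:
        lines.append(f"{_types_field((t1, t2, t3)):<8s}{k:9.2f}{theta:10.2f}")
    lines.append("")
    lines.append("DIHE")
    for t1, t2, t3, t4, idivf, pk, phase, pn in doc.dihedrals:
        lines.append(
            f"{_types_field((t1, t2, t3, t4)):<11s}{idivf:4d}{pk:10.4f}"
            f"{phase:8.1f}{pn:6.1f}"
        )
    lines.append("")
    lines.append("NONB")
    for t, rstar, eps in doc.nonbonded:
        lines.append(f"  {t:<2s}{rstar:12.4f}{eps:12.4f}")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_frcmod(path: str | Path) -> FrcmodDocument:
    """Lossless inverse of the writer for files it wrote; tolerant of extra
    whitespace.  Malformed records and unknown section headers are rejected
    with the line number / header name."""
    raw = Path(path).read_text().splitlines()
    if not raw:
        raise ValueError(f"empty frcmod file {path}")
    doc = FrcmodDocument.__new__(FrcmodDocument)
    doc.title = raw[0]
    doc.masses, doc.bonds, doc.angles = [], [], []
    doc.dihedrals, doc.nonbonded = [], []
    section = None
    for ln_no, line in enumerate(raw[1:], start=2):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped in SECTION_HEADERS:
            section = stripped
            continue
        # a lone all-caps alphabetic token is a (mis-spelled) section header
        if stripped.isalpha() and stripped.isupper() and len(stripped) <= 8:
            raise ValueError(
                f"unknown section header {stripped!r} at line {ln_no}"
            )
        try:
            if section == "MASS":
                t, m = stripped.split()
                doc.masses.append((t, float(m)))
            elif section == "BOND":
                types, rest = stripped[:5], stripped[5:].split()
                t1, t2 = (s.strip() for s in types.split("-"))
                doc.bonds.append((t1, t2, float(rest[0]), float(rest[1])))
            elif section == "ANGL":
                types, rest = stripped[:8], stripped[8:].split()
                t1, t2, t3 = (s.strip() for s in types.split("-"))
                doc.angles.append(
                    (t1, t2, t3, float(rest[0]), float(rest[1])))
            elif section == "DIHE":
                types, rest = stripped[:11], stripped[11:].split()
                t1, t2, t3, t4 = (s.strip() for s in types.split("-"))
                doc.dihedrals.append(
                    (t1, t2, t3, t4, int(rest[0]), float(rest[1]),
                     float(rest[2]), float(rest[3])))
            elif section == "NONB":
                t, rstar, eps = stripped.split()
                doc.nonbonded.append((t, float(rstar), float(eps)))
            else:
                raise ValueError("record outside any section")
        except ValueError as exc:
            raise ValueError(
                f"malformed {section or 'header'} record at line {ln_no}: "
                f"{stripped!r} ({exc})"
            ) from None
    doc.__post_init__()
    return doc


def default_typing(model) -> dict[str, dict]:
    """Typing map for a synthetic template: coordinate label → atom types and
    equilibrium value (mean over equivalent terms).

    Type registry: FE iron, SB bridge sulfide, ST thiolate S, NT imidazole
    Nδ (on [2Fe-2S]), NH imidazole Nε (mononuclear site), OA carboxylate O,
    OW water O.  All names fit the 2-character frcmod field; override by
    supplying your own typing map to :func:`write_frcmod`.
    """
    from .internals import coordinate_value

    def fe_neighbours(a: int) -> int:
        return sum(1 for t in model.terms if t.kind == "stretch"
                   and a in t.atoms
                   and model.elements[t.atoms[0] if t.atoms[1] == a
                                      else t.atoms[1]] == "Fe")

    def oxygen_type(a: int) -> str:
        for t in model.terms:
            if t.kind == "stretch" and a in t.atoms and "OAc" in t.label:
                return "OA"
        return "OW"

    binuclear = model.label in ("fes_4cys", "rieske")
    type_of_atom = []
    for a, el in enumerate(model.elements):
        if el == "Fe":
            type_of_atom.append("FE")
        elif el == "S":
            type_of_atom.append("SB" if fe_neighbours(a) == 2 else "ST")
        elif el == "N":
            type_of_atom.append("NT" if binuclear else "NH")
        elif el == "O":
            type_of_atom.append(oxygen_type(a))
        else:
            type_of_atom.append(el[:2].upper())

    per_label: dict[str, dict] = {}
    for t in model.terms:
        types = tuple(type_of_atom[a] for a in t.atoms)
        q = coordinate_value(t.coordinate(), model.coords)
        entry = per_label.setdefault(
            t.label, {"types": types, "kind": t.kind, "values": []})
        entry["values"].append(q)
    out = {}
    for label, e in per_label.items():
        eq = float(np.mean(e["values"]))
        out[label] = {
            "types": list(e["types"]),
            "kind": e["kind"],
            "equilibrium": eq if e["kind"] == "stretch"
            else math.degrees(eq),
        }
    return out


def params_to_frcmod(params: ForceFieldParamSet,
                     typing: Mapping[str, Mapping],
                     convention: str = "full",
                     masses: Optional[Sequence[tuple[str, float]]] = None,
                     nonbonded: Optional[Sequence[tuple[str, float, float]]]
                     = None) -> FrcmodDocument:
    """Assemble a FrcmodDocument from a typed parameter set."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    scale = 1.0 if convention == "full" else 0.5
    title = (f"fesff parameters | stretch/bend convention: {convention} "
             f"(K_file = {'k' if convention == 'full' else 'k/2'})")
    doc = FrcmodDocument.__new__(FrcmodDocument)
    doc.title = title
    doc.masses = list(masses or [])
    doc.bonds, doc.angles, doc.dihedrals = [], [], []
    doc.nonbonded = list(nonbonded or [])

    def entry(label: str) -> Mapping:
        if label not in typing:
            raise KeyError(f"no typing entry for parameter label {label!r}")
        return typing[label]

    for rec in params.stretches:
        e = entry(rec.label)
        t1, t2 = e["types"]
        doc.bonds.append((t1, t2, scale * rec.value,
                          float(e["equilibrium"])))
    for rec in params.bends:
        e = entry(rec.label)
        t1, t2, t3 = e["types"]
        doc.angles.append((t1, t2, t3, scale * rec.value,
                           float(e["equilibrium"])))
    for tor in params.torsions:
        e = entry(tor.label)
        t1, t2, t3, t4 = e["types"]
        for idx, (n, v, gamma) in enumerate(tor.terms):
            pn = float(n) if idx == len(tor.terms) - 1 else -float(n)
            doc.dihedrals.append(
                (t1, t2, t3, t4, tor.idivf, v / 2.0, gamma, pn))
    doc.__post_init__()
    return doc


def write_frcmod(params: ForceFieldParamSet, typing: Mapping[str, Mapping],
                 path: str | Path, convention: str = "full",
                 masses: Optional[Sequence[tuple[str, float]]] = None,
                 nonbonded: Optional[Sequence[tuple[str, float, float]]]
                 = None) -> None:
    """Emit a fixed-column frcmod file (see :func:`params_to_frcmod`).

    DIHE barriers are written as Vₙ/2 with negative periodicity marking
    continuation terms of a multi-term torsion.
    """
    doc = params_to_frcmod(params, typing, convention, masses, nonbonded)
    write_frcmod_document(doc, path)


def frcmod_to_params(doc: FrcmodDocument,
                     convention: str = "full"
                     ) -> tuple[ForceFieldParamSet, dict]:
    """Inverse of :func:`params_to_frcmod` (for round-trip checks)."""
    scale = 1.0 if convention == "full" else 2.0
    stretches, bends, torsions = [], [], []
    typing: dict[str, dict] = {}
    for t1, t2, k, req in doc.bonds:
        label = f"K({t1}-{t2})"
        stretches.append(ForceConstant(label, "K-stretch", scale * k,
                                       method="manual"))
        typing[label] = {"types": [t1, t2], "kind": "stretch",
                        "equilibrium": req}
    for t1, t2, t3, k, theta in doc.angles:
        label = f"H({t1}-{t2}-{t3})"
        bends.append(ForceConstant(label, "H-bend", scale * k,
                                   method="manual"))
        typing[label] = {"types": [t1, t2, t3], "kind": "bend",
                        "equilibrium": theta}
    pending: list[tuple[int, float, float]] = []
    for t1, t2, t3, t4, idivf, pk, phase, pn in doc.dihedrals:
        pending.append((abs(int(pn)), 2.0 * pk, phase))
        if pn > 0:
            label = f"T({t1}-{t2}-{t3}-{t4})"
            torsions.append(TorsionParams(label=label, terms=pending,
                                          idivf=idivf))
            typing[label] = {"types": [t1, t2, t3, t4], "kind": "torsion"}
            pending = []
    if pending:
        raise ValueError("dangling torsion continuation (negative final "
                         "periodicity)")
    return (ForceFieldParamSet(stretches=stretches, bends=bends,
                               torsions=torsions), typing)


# ---------------------------------------------------------------------- prep

@dataclass
class PrepinTemplate:
    """Residue template: named atoms with types, tree classes, Cartesian
    coordinates (internally converted to a z-matrix against three leading
    dummy atoms) and optional extra bonds (e.g. water-chain links)."""

    resname: str
    atom_names: list[str]
    atom_types: list[str]
    coords: np.ndarray
    tree: Optional[list[str]] = None
    extra_bonds: list[tuple[str, str]] = field(default_factory=list)
    net_charge: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if len(self.atom_types) != n or self.coords.shape != (n, 3):
            raise ValueError("inconsistent prepin template dimensions")
        if len(set(self.atom_names)) != n:
            raise ValueError("duplicate atom names in template")
        if self.tree is None:
            self.tree = ["M"] * n
        names = set(self.atom_names)
        for a, b in self.extra_bonds:
            if a not in names or b not in names:
                raise ValueError(f"extra bond ({a}, {b}) references unknown "
                                 f"atom")


_DUMMY = (np.array([0.0, 0.0, 0.0]),
          np.array([1.449, 0.0, 0.0]),
          np.array([0.926, 1.337, 0.0]))


def _zmatrix(coords: np.ndarray) -> list[tuple[float, float, float]]:
    """Chain z-matrix (bond, angle°, dihedral°) for each atom against its
    three predecessors, padded with three dummy atoms at fixed positions
    (writer and parser share the frame, so the round trip is exact)."""
    chain = np.vstack([*_DUMMY, coords])
    out = []
    for i in range(3, len(chain)):
        p1, p2, p3 = chain[i - 1], chain[i - 2], chain[i - 3]
        r = float(np.linalg.norm(chain[i] - p1))
        u = chain[i] - p1
        v = p2 - p1
        ang = math.degrees(math.acos(
            float(np.clip(np.dot(u, v)
                          / (np.linalg.norm(u) * np.linalg.norm(v)),
                          -1.0, 1.0))))
        # dihedral chain[i]-p1-p2-p3
        n1 = np.cross(chain[i] - p1, p2 - p1)
        n2 = np.cross(p2 - p1, p3 - p2)
        m = np.cross(n1, (p2 - p1) / np.linalg.norm(p2 - p1))
        dih = math.degrees(math.atan2(float(np.dot(m, n2)),
                                      float(np.dot(n1, n2))))
        out.append((r, ang, dih))
    return out


def write_prepin(template: PrepinTemplate, charges: ChargeSet,
                 path: str | Path, auto_renormalize: bool = False,
                 tol: float = 1e-6) -> None:
    """Emit a prep-input residue template.

    Charges are matched to template atoms by name (a missing atom is an
    error naming it).  The residue total must equal the template's declared
    net charge within ``tol`` unless ``auto_renormalize`` permits a uniform
    shift.  Extra bonds (water-chain links) are appended in the LOOP
    section, one record per link.
    """
    qmap = charges.as_mapping()
    missing = [a for a in template.atom_names if a not in qmap]
    if missing:
        raise KeyError(
            f"atoms {missing} of template {template.resname} have no charge"
        )
    q = np.array([qmap[a] for a in template.atom_names])
    deficit = template.net_charge - q.sum()
    if abs(deficit) > tol:
        if not auto_renormalize:
            raise ValueError(
                f"residue {template.resname} charges sum to {q.sum():.6f}, "
                f"target {template.net_charge:.6f}; pass auto_renormalize "
                f"to shift uniformly"
            )
        q = q + deficit / len(q)

    zmat = _zmatrix(template.coords)
    lines = [
        "    0    0    2",
        "",
        f"{template.resname} residue template (fesff)",
        f"{template.resname.lower()}.res",
        f"{template.resname:<4s} INT  0",
        "CORRECT     OMIT DU   BEG",
        "  0.0000",
        "   1  DUMM  DU    M    0   0   0     0.000       0.0         0.0     "
        "  0.00000",
        "   2  DUMM  DU    M    1   0   0     1.449       0.0         0.0     "
        "  0.00000",
        "   3  DUMM  DU    M    2   1   0     1.523     111.21        0.0     "
        "  0.00000",
    ]
    for i, (name, typ, tr) in enumerate(zip(template.atom_names,
                                            template.atom_types,
                                            template.tree)):
        r, ang, dih = zmat[i]
        # canonical rounding keeps write->parse->write byte-stable:
        # dihedrals live on [0, 360) after rounding, -0.0 is normalized
        dih = round(dih % 360.0, 2) % 360.0 + 0.0
        ang = round(ang, 2) + 0.0
        qi = round(float(q[i]), 6) + 0.0
        lines.append(
            f"{i + 4:4d}  {name:<4s}{typ:<4s}{tr:<2s}{i + 3:4d}"
            f"{i + 2:4d}{i + 1:4d}{r:10.3f}{ang:10.2f}"
            f"{dih:12.2f}{qi:11.6f}"
        )
    lines.append("")
    lines.append("LOOP")
    for a, b in template.extra_bonds:
        lines.append(f"{a:>5s}{b:>5s}")
    lines.append("")
    lines.append("IMPROPER")
    lines.append("")
    lines.append("DONE")
    lines.append("STOP")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_prepin(path: str | Path) -> tuple[PrepinTemplate, ChargeSet]:
    """Re-read a prep-input file written by :func:`write_prepin`.

    Geometry is reconstructed from the z-matrix, so write→parse→write is
    byte-identical.
    """
    lines = Path(path).read_text().splitlines()
    resname = lines[4].split()[0]
    atom_lines = []
    i = 7
    while i < len(lines) and lines[i].strip():
        atom_lines.append(lines[i])
        i += 1
    names, types, tree, charges = [], [], [], []
    internals = []
    for ln in atom_lines:
        parts = ln.split()
        if parts[2] == "DU":
            continue
        names.append(parts[1])
        types.append(parts[2])
        tree.append(parts[3])
        internals.append((float(parts[7]), float(parts[8]), float(parts[9])))
        charges.append(float(parts[10]))
    # rebuild Cartesian positions from the chain z-matrix
    chain = list(_DUMMY)
    for r, ang_deg, dih_deg in internals:
        p1, p2, p3 = chain[-1], chain[-2], chain[-3]
        chain.append(_place_atom(p1, p2, p3, r, math.radians(ang_deg),
                                 math.radians(dih_deg)))
    coords = np.array(chain[3:])
    extra: list[tuple[str, str]] = []
    if "LOOP" in [l.strip() for l in lines]:
        j = [l.strip() for l in lines].index("LOOP") + 1
        while j < len(lines) and lines[j].strip():
            a, b = lines[j].split()
            extra.append((a, b))
            j += 1
    qarr = np.array(charges)
    template = PrepinTemplate(
        resname=resname, atom_names=names, atom_types=types, coords=coords,
        tree=tree, extra_bonds=extra, net_charge=float(round(qarr.sum(), 6)))
    cset = ChargeSet(labels=names, charges=qarr,
                     net_charge_target=float(round(qarr.sum(), 6)),
                     provenance="imported")
    return template, cset


def _place_atom(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                r: float, theta: float, phi: float) -> np.ndarray:
    """NeRF-style placement: distance r to p1, angle theta at p1 towards p2,
    dihedral phi against p3."""
    b1 = p1 - p2
    b2 = p2 - p3
    b1 /= np.linalg.norm(b1)
    n = np.cross(b2, b1)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        n = np.cross(np.array([0.0, 0.0, 1.0]), b1)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, b1)
    d = np.array([-r * math.cos(theta),
                  -r * math.sin(theta) * math.cos(phi),
                  r * math.sin(theta) * math.sin(phi)])
    return p1 + d[0] * b1 + d[1] * m + d[2] * n
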