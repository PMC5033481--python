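"""Ball-and-spring harmonic models of [2Fe-2S] and mononuclear Fe centers.

These synthetic clusters stand in for electronic-structure output: each
template has a known equilibrium geometry, known stretch/bend/torsion
constants, an analytic energy/gradient, and an exact Hessian, so every
downstream stage (normal modes, finite differences, parameter assembly,
file emission) can be tested against ground truth.

Four templates mirror the centers of Rieske-type dioxygenases:

``fes_4cys``
    classic ferredoxin [2Fe-2S] with four methyl-thiolate pseudo-ligands,
``rieske``
    [2Fe-2S] with two thiolates on one Fe and two methyl-imidazoles (Nδ)
    on the other,
``roc_monodentate`` / ``roc_bidentate``
    mononuclear non-heme Fe(II) with two His (Nε), a mono- or bidentate
    carboxylate, and one water.

Ligand groups are collapsed to single pseudo-atoms carrying the group's
aggregate mass at the donor-atom position, which keeps the models at 5-8
sites while preserving the low-frequency metal-ligand mode structure.

Each template's internal-coordinate term set is deliberately NON-redundant
(exactly 3N-6 coordinates, full-rank B matrix): the [2Fe-2S] ring is spanned
by its five stretches plus one ring-pucker torsion rather than the redundant
ring bends.  This makes finite-difference extraction of every generating
constant exact for the quadratic potential, which a frustrated redundant set
cannot achieve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .bundle import QMBundle
from .internals import InternalCoordinate, b_row, b_matrix, coordinate_value
from .units import atomic_mass

__all__ = [
    "HarmonicTerm",
    "HarmonicModel",
    "TorsionScan",
    "TEMPLATE_NAMES",
    "build_template",
    "assemble_hessian",
    "generate_torsion_scan",
    "template_constants",
]

GRADIENT_TOL = 1e-8

# Aggregate pseudo-atom masses (amu): the donor atom plus its collapsed group.
MASS_FE = atomic_mass("Fe")
MASS_S_BRIDGE = atomic_mass("S")
MASS_METHYL_THIOLATE = atomic_mass("S") + atomic_mass("C") + 3 * atomic_mass("H")
MASS_METHYL_IMIDAZOLE = (4 * atomic_mass("C") + 6 * atomic_mass("H")
                         + 2 * atomic_mass("N"))
MASS_WATER = atomic_mass("O") + 2 * atomic_mass("H")
MASS_ACETATE = 2 * atomic_mass("O") + 2 * atomic_mass("C") + 3 * atomic_mass("H")


@dataclass(frozen=True)
class HarmonicTerm:
    """One spring: harmonic stretch/bend or a cosine-series torsion.

    ``constant`` is kcal·mol⁻¹·Å⁻² for stretches and kcal·mol⁻¹·rad⁻² for
    bends; torsions carry a cosine series ``[(n, V_n, gamma_deg), ...]`` in
    the Amber convention V = Σ Vₙ(1 + cos(nφ - γ)).
    """

    kind: str
    atoms: tuple[int, ...]
    label: str
    constant: float = 0.0
    equilibrium: float = 0.0
    series: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        InternalCoordinate(self.kind, self.atoms, self.label)  # validates
        if self.kind in ("stretch", "bend") and self.constant < 0:
            raise ValueError(f"negative force constant for {self.label}")
        if self.kind == "torsion":
            for n, _, _ in self.series:
                if int(n) != n or n < 1:
                    raise ValueError("torsion periodicity must be integer >= 1")

    def coordinate(self, suffix: str = "") -> InternalCoordinate:
        return InternalCoordinate(self.kind, self.atoms, self.label + suffix)

    def term_energy(self, q: float) -> float:
        if self.kind == "torsion":
            return sum(v * (1.0 + math.cos(n * q - math.radians(g)))
                       for n, v, g in self.series)
        return 0.5 * self.constant * (q - self.equilibrium) ** 2

    def term_denergy(self, q: float) -> float:
        if self.kind == "torsion":
            return sum(-n * v * math.sin(n * q - math.radians(g))
                       for n, v, g in self.series)
        return self.constant * (q - self.equilibrium)

    def term_d2energy(self, q: float) -> float:
        if self.kind == "torsion":
            return sum(-n * n * v * math.cos(n * q - math.radians(g))
                       for n, v, g in self.series)
        return self.constant


@dataclass
class HarmonicModel:
    """Atoms plus harmonic terms; energy is zero with zero gradient at
    the stored equilibrium geometry."""

    elements: list[str]
    coords: np.ndarray
    masses: np.ndarray
    terms: list[HarmonicTerm]
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3) or self.masses.shape != (n,):
            raise ValueError("inconsistent model dimensions")
        for t in self.terms:
            if max(t.atoms) >= n:
                raise ValueError(f"term {t.label} references atom out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def internal_coordinates(self) -> list[InternalCoordinate]:
        """One uniquely-labelled internal coordinate per term."""
        seen: dict[str, int] = {}
        out = []
        for t in self.terms:
            k = seen.get(t.label, 0)
            seen[t.label] = k + 1
            out.append(t.coordinate(suffix="" if k == 0 else f"#{k + 1}"))
        return out

    def energy(self, coords: np.ndarray) -> float:
        """Total energy (kcal·mol⁻¹) at arbitrary Cartesian coordinates."""
        x = np.asarray(coords, dtype=float)
        if x.shape != self.coords.shape:
            raise ValueError(
                f"coords shape {x.shape} does not match model "
                f"{self.coords.shape}"
            )
        return float(sum(
            t.term_energy(coordinate_value(t.coordinate(), x))
            for t in self.terms
        ))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        """Analytic Cartesian gradient, shape (3N,)."""
        x = np.asarray(coords, dtype=float)
        if x.shape != self.coords.shape:
            raise ValueError("coords shape mismatch")
        g = np.zeros(3 * self.n_atoms)
        for t in self.terms:
            c = t.coordinate()
            g += t.term_denergy(coordinate_value(c, x)) * b_row(c, x)
        return g

    def to_bundle(self, with_hessian: bool = True,
                  charges: Optional[np.ndarray] = None,
                  total_charge: int = 0,
                  spin_multiplicity: int = 1) -> QMBundle:
        """Export as a QM bundle so the full pipeline runs on synthetic input."""
        return QMBundle(
            elements=list(self.elements),
            coords=self.coords.copy(),
            masses=self.masses.copy(),
            hessian=assemble_hessian(self) if with_hessian else None,
            charges=charges,
            total_charge=total_charge,
            spin_multiplicity=spin_multiplicity,
            label=self.label,
        )


def assemble_hessian(model: HarmonicModel) -> np.ndarray:
    """Exact Cartesian Hessian (kcal·mol⁻¹·Å⁻²) at the model's equilibrium.

    At a geometry where every term sits at its own extremum the chain-rule
    curvature term k·(q-q0)·d²q/dx² vanishes and H = Σ V''(q0)·BᵀB exactly:
    symmetric, translationally invariant, positive semi-definite.  A model
    whose stored geometry is not a stationary point is rejected.
    """
    x = model.coords
    g = model.gradient(x)
    if np.abs(g).max() > GRADIENT_TOL * max(1.0, np.abs(x).max()):
        raise ValueError(
            f"model {model.label!r} is not at a stationary point "
            f"(max|grad| = {np.abs(g).max():.3e})"
        )
    h = np.zeros((3 * model.n_atoms, 3 * model.n_atoms))
    for t in model.terms:
        c = t.coordinate()
        q = coordinate_value(c, x)
        if abs(t.term_denergy(q)) > GRADIENT_TOL:
            raise ValueError(
                f"term {t.label} is strained at the stored geometry"
            )
        b = b_row(c, x)
        h += t.term_d2energy(q) * np.outer(b, b)
    return 0.5 * (h + h.T)


# ------------------------------------------------------------- torsion scans

@dataclass
class TorsionScan:
    """Angle/energy pairs on a uniform closed grid (angles in degrees)."""

    angles_deg: np.ndarray
    energies: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles_deg.shape != self.energies.shape:
            raise ValueError("angles/energies length mismatch")
        d = np.diff(self.angles_deg)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0], atol=1e-9)):
            raise ValueError("scan angles must be strictly increasing and "
                             "uniformly spaced")
        if len(self.angles_deg) and (
                self.angles_deg[-1] - self.angles_deg[0]) >= 360.0:
            raise ValueError("scan must span less than a full turn")


def cosine_series_energy(series: Sequence[tuple[int, float, float]],
                         angle_deg: np.ndarray) -> np.ndarray:
    """Amber-convention cosine series V = Σ Vₙ(1 + cos(nφ - γ))."""
    phi = np.radians(np.asarray(angle_deg, dtype=float))
    e = np.zeros_like(phi)
    for n, v, gamma in series:
        e = e + v * (1.0 + np.cos(n * phi - math.radians(gamma)))
    return e


def generate_torsion_scan(series: Sequence[tuple[int, float, float]],
                          grid_deg: float = 30.0,
                          noise_sd: float = 0.0,
                          seed: int = 0,
                          note: str = "") -> TorsionScan:
    """Evaluate a cosine series on a uniform grid, optionally with noise.

    Mirrors a rotate-and-optimize dihedral scan through 360° at ``grid_deg``
    steps; Gaussian energy noise of ``noise_sd`` kcal·mol⁻¹ emulates
    optimizer scatter and is reproducible for a fixed seed.
    """
    if grid_deg <= 0:
        raise ValueError("grid step must be positive")
    npts = 360.0 / grid_deg
    if abs(npts - round(npts)) > 1e-9:
        raise ValueError("grid step must divide 360 degrees")
    angles = np.arange(int(round(npts))) * grid_deg
    energies = cosine_series_energy(series, angles)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        energies = energies + rng.normal(0.0, noise_sd, size=angles.size)
    return TorsionScan(angles, energies, note=note)


# ------------------------------------------------------------------ templates

TEMPLATE_NAMES = ("fes_4cys", "rieske", "roc_monodentate", "roc_bidentate")

# Default stretch/bend constants, kcal/mol/A^2 and kcal/mol/rad^2.  Stretches
# derive from mode-based estimates for the oxidized clusters; the ring-pucker
# barrier is a package default (no tabulated out-of-plane constant exists).
_FES_4CYS = {
    "K(Fe-S(b))": 209.0,
    "K(Fe-S(t))": 165.0,
    "K(Fe-Fe)": 33.0,
    "H(S(b)-Fe-S(t))": 70.0,
    "H(S(t)-Fe-S(t))": 70.0,
    "T(ring-pucker)": 5.0,          # V2 barrier, kcal/mol
}
_RIESKE = {
    "K(Fe-S(b))": 158.0,
    "K(Fe-S(t))": 163.0,
    "K(Fe-N(t))": 63.0,
    "K(Fe-Fe)": 54.0,
    "H(S(b)-Fe-S(t))": 139.0,
    "H(S(t)-Fe-S(t))": 127.0,
    "H(S(b)-Fe-N(t))": 63.0,
    "H(N(t)-Fe-N(t))": 36.0,
    "T(ring-pucker)": 5.0,
}
_ROC_MONO = {
    "K(Fe-OH2)": 63.2,
    "K(Fe-OAc)": 37.7,
    "K(Fe-N(His))_1": 30.4,
    "K(Fe-N(His))_2": 25.8,
    "H(L-Fe-L)": 29.9,
}
_ROC_BI = {
    "K(Fe-OAc)": 45.75,            # mean of the sym/antisym carboxylate modes
    "K(Fe-OH2)": 44.5,
    "K(Fe-N(His))": 39.5,          # mean of the two His stretch modes
    "H(L-Fe-L)": 29.9,
}

# Equilibrium lengths (A): [2Fe-2S] cores from crystallographic values for
# oxidized clusters; ROC lengths are typical non-heme Fe(II) coordination.
_LENGTHS = {
    "fes_4cys": {"Fe-Fe": 2.71, "Fe-S(b)": 2.22, "Fe-S(t)": 2.35},
    "rieske": {"Fe-Fe": 2.68, "Fe-S(b)": 2.20, "Fe-S(t)": 2.32,
               "Fe-N(t)": 2.05},
    "roc_monodentate": {"Fe-N(His)": 2.15, "Fe-OAc": 2.00, "Fe-OH2": 2.10},
    "roc_bidentate": {"Fe-N(His)": 2.15, "Fe-OAc": 2.15, "Fe-OH2": 2.10},
}


def template_constants(name: str) -> dict[str, float]:
    """Default generating constants for a template (copy)."""
    table = {"fes_4cys": _FES_4CYS, "rieske": _RIESKE,
             "roc_monodentate": _ROC_MONO, "roc_bidentate": _ROC_BI}
    if name not in table:
        raise KeyError(f"unknown template {name!r}; choose from "
                       f"{TEMPLATE_NAMES}")
    return dict(table[name])


def _ring_frame(d_fefe: float, d_fesb: float):
    """Planar [2Fe-2S] rhombus: Fe on x, bridge S on y."""
    xf = d_fefe / 2.0
    ys = math.sqrt(d_fesb ** 2 - xf ** 2)
    fe1 = np.array([-xf, 0.0, 0.0])
    fe2 = np.array([xf, 0.0, 0.0])
    sb1 = np.array([0.0, ys, 0.0])
    sb2 = np.array([0.0, -ys, 0.0])
    return fe1, fe2, sb1, sb2


def _terminal_pair(fe: np.ndarray, sign: float, r: float):
    """Two terminal donor sites on one Fe, tetrahedrally splayed in xz."""
    half = math.radians(54.735)  # half the tetrahedral angle
    u_up = np.array([sign * math.cos(half), 0.0, math.sin(half)])
    u_dn = np.array([sign * math.cos(half), 0.0, -math.sin(half)])
    return fe + r * u_up, fe + r * u_dn


def _bridged_core_terms(idx: Mapping[str, int], coords: np.ndarray,
                        k: Mapping[str, float]) -> list[HarmonicTerm]:
    """Non-redundant ring terms: 4 Fe-S(b) + Fe-Fe stretches + 1 pucker."""
    def stretch(label, i, j):
        c = InternalCoordinate("stretch", (i, j), label)
        return HarmonicTerm("stretch", (i, j), label, constant=k[label],
                            equilibrium=coordinate_value(c, coords))

    terms = [
        stretch("K(Fe-S(b))", idx["Fe1"], idx["Sb1"]),
        stretch("K(Fe-S(b))", idx["Fe1"], idx["Sb2"]),
        stretch("K(Fe-S(b))", idx["Fe2"], idx["Sb1"]),
        stretch("K(Fe-S(b))", idx["Fe2"], idx["Sb2"]),
        stretch("K(Fe-Fe)", idx["Fe1"], idx["Fe2"]),
    ]
    pucker_atoms = (idx["Fe1"], idx["Sb1"], idx["Fe2"], idx["Sb2"])
    phi0 = coordinate_value(
        InternalCoordinate("torsion", pucker_atoms, "T(ring-pucker)"), coords)
    gamma = math.degrees(2.0 * phi0) - 180.0  # minimum of the n=2 term at phi0
    terms.append(HarmonicTerm(
        "torsion", pucker_atoms, "T(ring-pucker)",
        series=((2, k["T(ring-pucker)"], gamma % 360.0),),
    ))
    return terms


def _ligand_terms(fe: int, sb1: int, sb2: int, l1: int, l2: int,
                  coords: np.ndarray, k_stretch: Mapping[int, float],
                  stretch_label: Mapping[int, str],
                  h_mixed: float, h_pair: float,
                  mixed_label: str, pair_label: str) -> list[HarmonicTerm]:
    """Six coordinates spanning the 6 DOF of two terminal ligands on one Fe:
    two stretches plus the bends Sb1-Fe-L1, Sb2-Fe-L1, L1-Fe-L2, Sb1-Fe-L2."""
    out = []
    for l in (l1, l2):
        lab = stretch_label[l]
        c = InternalCoordinate("stretch", (fe, l), lab)
        out.append(HarmonicTerm("stretch", (fe, l), lab,
                                constant=k_stretch[l],
                                equilibrium=coordinate_value(c, coords)))
    bends = [
        ((sb1, fe, l1), mixed_label, h_mixed),
        ((sb2, fe, l1), mixed_label, h_mixed),
        ((l1, fe, l2), pair_label, h_pair),
        ((sb1, fe, l2), mixed_label, h_mixed),
    ]
    for atoms, lab, h in bends:
        c = InternalCoordinate("bend", atoms, lab)
        out.append(HarmonicTerm("bend", atoms, lab, constant=h,
                                equilibrium=coordinate_value(c, coords)))
    return out


def _build_fes_4cys(k: Mapping[str, float]) -> HarmonicModel:
    L = _LENGTHS["fes_4cys"]
    fe1, fe2, sb1, sb2 = _ring_frame(L["Fe-Fe"], L["Fe-S(b)"])
    st1a, st1b = _terminal_pair(fe1, -1.0, L["Fe-S(t)"])
    st2a, st2b = _terminal_pair(fe2, 1.0, L["Fe-S(t)"])
    coords = np.array([fe1, fe2, sb1, sb2, st1a, st1b, st2a, st2b])
    elements = ["Fe", "Fe", "S", "S", "S", "S", "S", "S"]
    masses = np.array([MASS_FE, MASS_FE, MASS_S_BRIDGE, MASS_S_BRIDGE]
                      + [MASS_METHYL_THIOLATE] * 4)
    idx = {"Fe1": 0, "Fe2": 1, "Sb1": 2, "Sb2": 3}
    terms = _bridged_core_terms(idx, coords, k)
    for fe, la, lb in ((0, 4, 5), (1, 6, 7)):
        terms += _ligand_terms(
            fe, 2, 3, la, lb, coords,
            k_stretch={la: k["K(Fe-S(t))"], lb: k["K(Fe-S(t))"]},
            stretch_label={la: "K(Fe-S(t))", lb: "K(Fe-S(t))"},
            h_mixed=k["H(S(b)-Fe-S(t))"], h_pair=k["H(S(t)-Fe-S(t))"],
            mixed_label="H(S(b)-Fe-S(t))", pair_label="H(S(t)-Fe-S(t))")
    return HarmonicModel(elements, coords, masses, terms, label="fes_4cys")


def _build_rieske(k: Mapping[str, float]) -> HarmonicModel:
    L = _LENGTHS["rieske"]
    fe1, fe2, sb1, sb2 = _ring_frame(L["Fe-Fe"], L["Fe-S(b)"])
    st1, st2 = _terminal_pair(fe1, -1.0, L["Fe-S(t)"])   # Cys side
    nt1, nt2 = _terminal_pair(fe2, 1.0, L["Fe-N(t)"])    # His side
    coords = np.array([fe1, fe2, sb1, sb2, st1, st2, nt1, nt2])
    elements = ["Fe", "Fe", "S", "S", "S", "S", "N", "N"]
    masses = np.array([MASS_FE, MASS_FE, MASS_S_BRIDGE, MASS_S_BRIDGE,
                       MASS_METHYL_THIOLATE, MASS_METHYL_THIOLATE,
                       MASS_METHYL_IMIDAZOLE, MASS_METHYL_IMIDAZOLE])
    idx = {"Fe1": 0, "Fe2": 1, "Sb1": 2, "Sb2": 3}
    terms = _bridged_core_terms(idx, coords, k)
    terms += _ligand_terms(
        0, 2, 3, 4, 5, coords,
        k_stretch={4: k["K(Fe-S(t))"], 5: k["K(Fe-S(t))"]},
        stretch_label={4: "K(Fe-S(t))", 5: "K(Fe-S(t))"},
        h_mixed=k["H(S(b)-Fe-S(t))"], h_pair=k["H(S(t)-Fe-S(t))"],
        mixed_label="H(S(b)-Fe-S(t))", pair_label="H(S(t)-Fe-S(t))")
    terms += _ligand_terms(
        1, 2, 3, 6, 7, coords,
        k_stretch={6: k["K(Fe-N(t))"], 7: k["K(Fe-N(t))"]},
        stretch_label={6: "K(Fe-N(t))", 7: "K(Fe-N(t))"},
        h_mixed=k["H(S(b)-Fe-N(t))"], h_pair=k["H(N(t)-Fe-N(t))"],
        mixed_label="H(S(b)-Fe-N(t))", pair_label="H(N(t)-Fe-N(t))")
    return HarmonicModel(elements, coords, masses, terms, label="rieske")


def _angle_terms_at_center(center: int, pairs: Sequence[tuple[int, int]],
                           coords: np.ndarray, h: float,
                           label: str) -> list[HarmonicTerm]:
    out = []
    for i, j in pairs:
        atoms = (i, center, j)
        c = InternalCoordinate("bend", atoms, label)
        out.append(HarmonicTerm("bend", atoms, label, constant=h,
                                equilibrium=coordinate_value(c, coords)))
    return out


def _build_roc_monodentate(k: Mapping[str, float]) -> HarmonicModel:
    L = _LENGTHS["roc_monodentate"]
    t = 1.0 / math.sqrt(3.0)
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                    dtype=float) * t
    fe = np.zeros(3)
    n1 = fe + L["Fe-N(His)"] * dirs[0]
    n2 = fe + L["Fe-N(His)"] * dirs[1]
    oac = fe + L["Fe-OAc"] * dirs[2]
    ow = fe + L["Fe-OH2"] * dirs[3]
    coords = np.array([fe, n1, n2, oac, ow])
    elements = ["Fe", "N", "N", "O", "O"]
    masses = np.array([MASS_FE, MASS_METHYL_IMIDAZOLE, MASS_METHYL_IMIDAZOLE,
                       MASS_ACETATE, MASS_WATER])

    def stretch(label, j):
        c = InternalCoordinate("stretch", (0, j), label)
        return HarmonicTerm("stretch", (0, j), label, constant=k[label],
                            equilibrium=coordinate_value(c, coords))

    terms = [
        stretch("K(Fe-N(His))_1", 1),
        stretch("K(Fe-N(His))_2", 2),
        stretch("K(Fe-OAc)", 3),
        stretch("K(Fe-OH2)", 4),
    ]
    # five of the six tetrahedral angles (the sixth is dependent)
    terms += _angle_terms_at_center(
        0, [(1, 2), (1, 3), (2, 3), (1, 4), (2, 4)], coords,
        k["H(L-Fe-L)"], "H(L-Fe-L)")
    return HarmonicModel(elements, coords, masses, terms,
                         label="roc_monodentate")


def _build_roc_bidentate(k: Mapping[str, float]) -> HarmonicModel:
    L = _LENGTHS["roc_bidentate"]
    fe = np.zeros(3)

    def site(direction, r):
        u = np.asarray(direction, dtype=float)
        return r * u / np.linalg.norm(u)

    # a generically distorted (C1) five-coordinate arrangement: ideal
    # trigonal bipyramids make some angle sets linearly dependent
    o1 = site([math.cos(math.radians(31.0)), math.sin(math.radians(31.0)),
               0.08], L["Fe-OAc"])
    o2 = site([math.cos(math.radians(31.0)), -math.sin(math.radians(31.0)),
               -0.06], L["Fe-OAc"])
    n2 = site([-0.90, 0.15, 0.40], L["Fe-N(His)"])
    n1 = site([0.12, -0.30, 0.95], L["Fe-N(His)"])
    ow = site([0.45, 0.40, -0.80], L["Fe-OH2"])
    coords = np.array([fe, n1, n2, o1, o2, ow])
    elements = ["Fe", "N", "N", "O", "O", "O"]
    masses = np.array([MASS_FE, MASS_METHYL_IMIDAZOLE, MASS_METHYL_IMIDAZOLE,
                       MASS_ACETATE / 2.0, MASS_ACETATE / 2.0, MASS_WATER])

    def stretch(label, j):
        c = InternalCoordinate("stretch", (0, j), label)
        return HarmonicTerm("stretch", (0, j), label, constant=k[label],
                            equilibrium=coordinate_value(c, coords))

    terms = [
        stretch("K(Fe-N(His))", 1),
        stretch("K(Fe-N(His))", 2),
        stretch("K(Fe-OAc)", 3),
        stretch("K(Fe-OAc)", 4),
        stretch("K(Fe-OH2)", 5),
    ]
    # seven independent angles at a five-coordinate center (2*5-3)
    terms += _angle_terms_at_center(
        0, [(1, 5), (1, 3), (1, 4), (1, 2), (5, 3), (5, 2), (3, 4)],
        coords, k["H(L-Fe-L)"], "H(L-Fe-L)")
    return HarmonicModel(elements, coords, masses, terms,
                         label="roc_bidentate")


_BUILDERS: dict[str, Callable[[Mapping[str, float]], HarmonicModel]] = {
    "fes_4cys": _build_fes_4cys,
    "rieske": _build_rieske,
    "roc_monodentate": _build_roc_monodentate,
    "roc_bidentate": _build_roc_bidentate,
}


def build_template(name: str,
                   overrides: Optional[Mapping[str, float]] = None
                   ) -> HarmonicModel:
    """Build a named template, optionally overriding term constants by label.

    The resulting model is at a gradient-free equilibrium with a
    non-redundant term set (full-rank B matrix, verified).
    """
    constants = template_constants(name)
    if overrides:
        unknown = set(overrides) - set(constants)
        if unknown:
            raise KeyError(
                f"override keys {sorted(unknown)} not in template {name!r}; "
                f"valid keys: {sorted(constants)}"
            )
        constants.update(overrides)
    model = _BUILDERS[name](constants)

    b = b_matrix(model.internal_coordinates(), model.coords)
    n_internal = 3 * model.n_atoms - 6
    rank = np.linalg.matrix_rank(b, tol=1e-8)
    if len(model.terms) != n_internal or rank != n_internal:
        raise RuntimeError(
            f"template {name!r} term set is not a non-redundant spanning set "
            f"({len(model.terms)} terms, rank {rank}, need {n_internal})"
        )
    return model
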