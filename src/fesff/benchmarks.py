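"""Shipped reference tables and the paired-unit consistency checks.

Published force-constant tables for these clusters print each value in both
mdyne/Å and kcal·mol⁻¹·Å⁻².  Because both columns are independently rounded,
the strongest statement that can be checked is agreement at *printed
rounding*: |kcal_printed − f·mdyne_printed| must not exceed half a unit in
the last place of either column (the mdyne half-ulp propagated through the
conversion factor f ≈ 143.93).  Every shipped pair passes; a transcription
or conversion error of one ulp would fail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .units import convert_force_constant

__all__ = ["load_paired_force_constants", "check_paired_units",
           "load_observed_frequencies", "PairedUnitCheck"]

_DATA = Path(__file__).parent / "data"


def _decimals(text: str) -> int:
    text = text.strip()
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1])


def load_paired_force_constants() -> pd.DataFrame:
    """The shipped (mdyne/Å, kcal·mol⁻¹·Å⁻²) pairs with printed precision."""
    df = pd.read_csv(_DATA / "paired_force_constants.csv", dtype=str)
    df["mdyne"] = df["mdyne_per_A"].astype(float)
    df["kcal"] = df["kcal_per_mol_A2"].astype(float)
    df["mdyne_decimals"] = df["mdyne_per_A"].map(_decimals)
    df["kcal_decimals"] = df["kcal_per_mol_A2"].map(_decimals)
    return df[["source", "label", "mdyne", "kcal",
               "mdyne_decimals", "kcal_decimals"]]


@dataclass
class PairedUnitCheck:
    source: str
    label: str
    mdyne: float
    kcal_printed: float
    kcal_converted: float
    tolerance: float
    passed: bool


def check_paired_units() -> list[PairedUnitCheck]:
    """Verify every shipped pair at printed rounding."""
    out = []
    for _, row in load_paired_force_constants().iterrows():
        converted = convert_force_constant(row["mdyne"], "mdyne_per_A",
                                           "kcal_per_mol_A2")
        factor = convert_force_constant(1.0, "mdyne_per_A",
                                        "kcal_per_mol_A2")
        tol = (0.5 * 10.0 ** (-row["kcal_decimals"])
               + 0.5 * 10.0 ** (-row["mdyne_decimals"]) * factor)
        out.append(PairedUnitCheck(
            source=row["source"], label=row["label"], mdyne=row["mdyne"],
            kcal_printed=row["kcal"], kcal_converted=converted,
            tolerance=tol,
            passed=abs(converted - row["kcal"]) <= tol,
        ))
    return out


def load_observed_frequencies(system: str | None = None) -> pd.DataFrame:
    """Observed vs scaled-calculated band tables for the [2Fe-2S] clusters.

    Systems: fes_4cys_oxidized, fes_4cys_reduced, rieske_oxidized,
    rieske_reduced; each row carries the published scale factor so raw
    calculated wavenumbers can be recovered as calculated_scaled / scale.
    """
    df = pd.read_csv(_DATA / "observed_frequencies.csv")
    if system is not None:
        sub = df[df["system"] == system].reset_index(drop=True)
        if sub.empty:
            raise KeyError(f"unknown system {system!r}; available: "
                           f"{sorted(df['system'].unique())}")
        return sub
    return df
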