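import numpy as np
import pytest

from fesff.synthetic import HarmonicModel, HarmonicTerm, build_template
from fesff.units import MDYNE_PER_A_TO_KCAL, atomic_mass

FE2_K_MDYNE = 0.230          # generating spring constant of the Fe2 fixture
FE2_BOND_A = 2.71


def make_diatomic(k_mdyne: float = FE2_K_MDYNE,
                  elements=("Fe", "Fe"),
                  r0: float = FE2_BOND_A) -> HarmonicModel:
    """Two atoms, one stretch: the closed-form cross-check system."""
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r0]])
    masses = np.array([atomic_mass(e) for e in elements])
    term = HarmonicTerm("stretch", (0, 1), f"K({elements[0]}-{elements[1]})",
                        constant=k_mdyne * MDYNE_PER_A_TO_KCAL,
                        equilibrium=r0)
    return HarmonicModel(list(elements), coords, masses, [term],
                         label="diatomic")


@pytest.fixture
def fe2():
    return make_diatomic()


@pytest.fixture(params=["fes_4cys", "rieske", "roc_monodentate",
                        "roc_bidentate"])
def template(request):
    return build_template(request.param)


@pytest.fixture
def rieske():
    return build_template("rieske")
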