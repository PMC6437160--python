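import numpy as np
import pytest

from globinchar.spectra import BasisSet, default_wavelengths


@pytest.fixture(scope="session")
def basis() -> BasisSet:
    return BasisSet.default()


@pytest.fixture(scope="session")
def wavelengths() -> np.ndarray:
    return default_wavelengths()


def toy_heme_pdb() -> str:
    """Minimal heme fragment: Fe plus four pyrrole-like N in a square."""
    rows = [
        ("FE", "FE", 0.0, 0.0, 0.0),
        ("NA", "N", 2.0, 0.0, 0.0),
        ("NB", "N", -2.0, 0.0, 0.0),
        ("NC", "N", 0.0, 2.0, 0.0),
        ("ND", "N", 0.0, -2.0, 0.0),
    ]
    lines = []
    for i, (name, element, x, y, z) in enumerate(rows, start=1):
        lines.append(
            f"HETATM{i:5d} {name:<4s} HEM A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
        )
    return "\n".join(lines) + "\n"


@pytest.fixture()
def toy_heme() -> str:
    return toy_heme_pdb()
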