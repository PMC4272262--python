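import numpy as np
import pytest

from g4shape.hydrocalc import HydroParams
from g4shape.qmodel_builder import build_parallel_unit


@pytest.fixture(scope="session")
def water_params():
    """Default solvent: water at 20 C, quadruplex vbar/hydration/AER."""
    return HydroParams()


@pytest.fixture(scope="session")
def parallel_unit():
    """A 3-quartet all-parallel unit with 1XAV-like (1,2,1) loops."""
    return build_parallel_unit(3, (1, 2, 1))


@pytest.fixture(scope="session")
def sphere_atoms():
    """Atom centers whose AER-inflated union is a smooth sphere of radius R:
    a dense shell of centers at R - aer plus one central atom."""

    def _make(R: float, aer: float, spacing: float = 1.5) -> np.ndarray:
        r = R - aer
        n = int(np.ceil(4 * np.pi * r * r / (0.866 * spacing ** 2)))
        i = np.arange(n)
        g = np.pi * (3 - np.sqrt(5))
        z = 1 - 2 * (i + 0.5) / n
        rr = np.sqrt(1 - z * z)
        shell = np.column_stack([rr * np.cos(g * i), rr * np.sin(g * i), z]) * r
        return np.vstack([shell, [[0.0, 0.0, 0.0]]])

    return _make
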