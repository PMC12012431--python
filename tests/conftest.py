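import numpy as np
import pytest

import leadheat as lh


@pytest.fixture(scope="session")
def analytic_field() -> lh.UniformBLinearEField:
    """Default 1 uT uniform-B / linear-E analytic field at 63.87 MHz."""
    return lh.UniformBLinearEField()


@pytest.fixture(scope="session")
def king_k() -> complex:
    """Reference King wavenumber for the ASTM-gel bench setup."""
    return lh.default_king_wavenumber()


@pytest.fixture(scope="session")
def fixtures() -> list:
    return lh.table1_fixtures()


@pytest.fixture(scope="session")
def design(fixtures, analytic_field) -> lh.WireSetDesign:
    """Precomputed line-integral design for the 20 wires at 1 mm steps."""
    return lh.WireSetDesign.from_specs(fixtures, analytic_field)


class ZeroField:
    """A field source that is identically zero (for null-integral checks)."""

    def evaluate(self, points):
        pts = np.atleast_2d(points)
        return np.zeros((pts.shape[0], 3), dtype=complex)


class PhaseShiftedField:
    """Wraps a field source, multiplying every sample by a global phase."""

    def __init__(self, base, phase):
        self.base = base
        self.factor = np.exp(1j * phase)

    def evaluate(self, points):
        return self.factor * self.base.evaluate(points)


@pytest.fixture
def zero_field() -> ZeroField:
    return ZeroField()


@pytest.fixture
def phase_shifted_field_cls():
    return PhaseShiftedField
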