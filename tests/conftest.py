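import numpy as np
import pytest
from hypothesis import settings

from lignosurf.core_io import AxisKind, Spectrum

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def two_theta_axis() -> np.ndarray:
    return np.arange(10.0, 50.0 + 1e-9, 0.02)


@pytest.fixture
def flat_diffractogram(two_theta_axis) -> Spectrum:
    return Spectrum(
        AxisKind.TWO_THETA_DEG, two_theta_axis, np.full(two_theta_axis.size, 50.0)
    )


def write_csv(path, axis, intensity, delimiter=",", header=None):
    lines = [] if header is None else list(header)
    lines += [f"{x}{delimiter}{y}" for x, y in zip(axis, intensity)]
    path.write_text("\n".join(lines) + "\n")
    return path
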