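import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---- independent geometric oracles used across test modules ----

def signed_area(contour: np.ndarray) -> float:
    """Shoelace area; positive for counter-clockwise contours."""
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def volume_of_revolution(contour: np.ndarray) -> float:
    """Volume of the solid of revolution of the right half-profile.

    V = pi * integral x(z)^2 dz over the x > 0 side, by trapezoid on the
    contour points sorted along the axis.  Independent of the generator's
    closed-form volume.
    """
    right = contour[contour[:, 0] > 0]
    order = np.argsort(right[:, 1])
    x, z = right[order, 0], right[order, 1]
    return float(np.pi * np.trapezoid(x ** 2, z))


def is_simple_closed(contour: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon(contour).is_valid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
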