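import numpy as np
import pytest

from soletrace import Contour
from soletrace.simulate import SimulationConfig, simulate_otoliths


def circle_contour(n_points: int = 256, radius: float = 1.0) -> Contour:
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return Contour(np.column_stack([radius * np.cos(t), radius * np.sin(t)]))


def ellipse_contour(a: float = 2.0, b: float = 1.0, n_points: int = 256) -> Contour:
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]))


def star_contour(rng: np.random.Generator, n_points: int = 256) -> Contour:
    """Random smooth star-shaped polygon (always simple)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = 1.0 + np.zeros_like(theta)
    for k in range(2, 8):
        amp = rng.uniform(0.0, 0.25 / k)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        r += amp * np.cos(k * theta + phase)
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic dataset shared across tests."""
    cfg = SimulationConfig(
        n_per_subunit={"SW": 12, "NE": 10, "UK": 11}, n_loci=150, seed=42
    )
    return simulate_otoliths(cfg)


@pytest.fixture(scope="session")
def sole_contours(small_dataset):
    return small_dataset.contours
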