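import numpy as np
import pytest

from sinteroct import GROUPS, AnchorSet, build_model
from sinteroct.profile import ReflectivityProfile

X_MAX = 3.25


@pytest.fixture(scope="session")
def group_models():
    """Analytic models for the eight built-in study groups."""
    return {label: g.build() for label, g in GROUPS.items()}


@pytest.fixture(scope="session")
def dense_grid():
    """Dense abscissa grid over the full domain, endpoints included."""
    return np.linspace(0.0, X_MAX, 209)


def dense_samples(model, grid) -> ReflectivityProfile:
    """Noise-free samples of a model on a grid, as a smoothed profile."""
    return ReflectivityProfile(grid, np.asarray(model.evaluate(grid)), "smoothed")


def random_anchor_set(archetype: str, rng: np.random.Generator, grid) -> AnchorSet:
    """Random but geometrically valid anchors for one archetype.

    Breakpoints are snapped to the sampling grid so that an exhaustive
    breakpoint search over the grid can recover them exactly.
    """
    interior = grid[8:-8]
    if archetype == "flat":
        return AnchorSet(rho0=rng.uniform(10, 240), x_max=X_MAX)
    if archetype == "linear_ramp":
        lo, hi = sorted(rng.uniform(10, 240, size=2))
        return AnchorSet(rho0=lo, rho_max=hi, x_max=X_MAX)
    if archetype == "valley":
        rho_min = rng.uniform(10, 100)
        rho0 = rng.uniform(rho_min + 5, 200)
        rho_max = rng.uniform(rho0, 250)
        return AnchorSet(
            rho0=rho0, rho_min=rho_min, rho_max=rho_max,
            x_m=float(rng.choice(interior)), x_max=X_MAX,
        )
    if archetype == "ramp_plateau":
        return AnchorSet(
            rho0=rng.uniform(10, 120), rho_i=rng.uniform(10, 240),
            x_i=float(rng.choice(interior)), x_max=X_MAX,
        )
    if archetype == "oscillation":
        A = rng.uniform(1, 30)
        return AnchorSet(rho0=rng.uniform(A + 5, 250 - A - 5), A=A, x_max=X_MAX)
    if archetype == "hump_valley":
        inner = grid[(grid > 0.4) & (grid < X_MAX - 0.3)]
        x_i = float(rng.choice(inner))
        x_M = rng.uniform(0.1, x_i - 0.05)
        x_m = rng.uniform(x_i + 0.05, X_MAX)
        rho_min = rng.uniform(10, 90)
        rho0 = rng.uniform(rho_min + 5, 180)
        rho_max = rng.uniform(rho0 + 5, 250)
        return AnchorSet(
            rho0=rho0, rho_min=rho_min, rho_max=rho_max,
            x_M=x_M, x_i=x_i, x_m=x_m, x_max=X_MAX,
        )
    raise ValueError(archetype)


def build_random(archetype: str, rng: np.random.Generator, grid):
    """Random anchors plus the model they build (retry degenerate draws)."""
    for _ in range(20):
        anchors = random_anchor_set(archetype, rng, grid)
        try:
            return anchors, build_model(archetype, anchors)
        except ValueError:
            continue
    raise RuntimeError(f"could not draw valid anchors for {archetype}")
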