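import numpy as np
import pytest

from vesselseg.phantom import PhantomSpec, VesselTree, generate_phantom, rasterize


@pytest.fixture(scope="session")
def small_phantom():
    """A deterministic 64^3 phantom with modest vessels (image, truth, trees)."""
    spec = PhantomSpec(shape=(64, 64, 64), n_trees=2, radius_range_um=(2.0, 8.0),
                       n_steps=120, seed=42)
    image, truth, trees = generate_phantom(spec)
    return spec, image, truth, trees


def make_cylinder_tree(radius_um: float, length: int = 50, axis: int = 2,
                       center: float = 32.0, start: float = 5.0) -> VesselTree:
    """A straight axis-aligned tube as a single-polyline tree."""
    n = length + 1
    coords = [np.full(n, center), np.full(n, center), np.full(n, center)]
    coords[axis] = np.arange(start, start + n, dtype=float)
    pts = np.stack(coords, axis=1)
    return VesselTree(polylines=[(pts, np.full(n, radius_um))], parents=[None])


@pytest.fixture(scope="session")
def cylinder_masks():
    """Filled solid cylinders r in {2,3,4,6,10} um rasterized at 1 um voxels."""
    out = {}
    for r in (2, 3, 4, 6, 10):
        spec = PhantomSpec(shape=(64, 64, 64), n_trees=1, seed=0,
                           hollow_radius_um=1e9)  # force solid rendering
        tree = make_cylinder_tree(float(r))
        _, truth = rasterize(tree, spec)
        out[r] = truth.voxels
    return out
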