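import numpy as np
import pandas as pd
import pytest

from ccm3d import ClonogenicTable, StackSpec, generate_stack
from ccm3d.synthetic import lq_survival


@pytest.fixture(scope="session")
def small_stack():
    """A small but realistic two-channel acquisition with ground truth."""
    spec = StackSpec(
        field_size_um=80.0,
        pixel_size_um=0.5,
        slab_thickness_um=40.0,
        n_nuclei=12,
        min_separation_um=14.0,
        seed=7,
    )
    nuclei, collagen, truth = generate_stack(spec)
    return spec, nuclei, collagen, truth


def exact_table(alpha, beta, doses, cells=1000, pe=1.0, arm="ideal"):
    """Noise-free colony counts equal to their Poisson means under the LQ law."""
    rows = [
        dict(
            arm=arm,
            dose_gy=float(d),
            cells_seeded=cells,
            colonies=cells * pe * lq_survival(d, alpha, beta),
            dish_id=f"{arm}-{i}",
        )
        for i, d in enumerate(doses)
    ]
    return ClonogenicTable(pd.DataFrame(rows))


@pytest.fixture
def ideal_table():
    return exact_table(0.31, 0.05, (0, 1, 2, 4, 6))


def brute_force_min_distances(points):
    """O(n^2) nearest-neighbour oracle, independent of the k-d tree path."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    out = np.empty(n)
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i != j:
                best = min(best, float(np.sqrt(np.sum((points[i] - points[j]) ** 2))))
        out[i] = best
    return out
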