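import numpy as np
import pytest

from cortiquant import CellRecord, GeneratorConfig, Mosaic, StarConfig, generate_lattice

D_C = 8.0


@pytest.fixture
def hex_lattice():
    """Noiseless 3-row offset lattice, 16 cells/row, d_r = d_c·√3/2."""
    return generate_lattice(GeneratorConfig(n_rows=3, cells_per_row=16, col_spacing=D_C))


@pytest.fixture
def interior_star_config():
    """Axis fixed at 0°, margin excluding the lattice boundary cells."""
    return StarConfig(
        axis_mode="given", given_axis_angle=0.0,
        edge_policy="exclude_margin", margin=0.6 * D_C,
    )


def square_lattice(n: int, spacing: float = 1.0) -> Mosaic:
    cells = [
        CellRecord(i * n + j, j * spacing, i * spacing, "OHC", i + 1)
        for i in range(n) for j in range(n)
    ]
    return Mosaic(cells, sample_id="square", length_um=n * spacing)


def brute_force_knn(focal, candidates, k):
    """Pure-python all-pairs oracle: sort by (distance, cell_id)."""
    scored = sorted(
        (((c.x - focal.x) ** 2 + (c.y - focal.y) ** 2, c.cell_id) for c in candidates
         if c.cell_id != focal.cell_id)
    )
    return [cid for _, cid in scored[:k]]


def random_mosaic(rng: np.random.Generator, n: int) -> Mosaic:
    pts = rng.uniform(0, 50, size=(n, 2))
    cells = [CellRecord(i, float(x), float(y), "OHC", 1) for i, (x, y) in enumerate(pts)]
    return Mosaic(cells, sample_id="rand", length_um=60.0)
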