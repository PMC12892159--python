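"""Synthetic organ-of-Corti-like mosaics with controllable disorder.

The generator lays down ``n_rows`` offset rows of cells (by default three
OHC rows in near-hexagonal packing: alternate rows shifted by half the
within-row spacing, row spacing d_c·√3/2 so that every interior cell has
six equidistant neighbors), then perturbs the lattice to emulate mutant
phenotypes:

* ``missing_rate`` — each lattice site independently loses its cell;
* ``ectopic_rate`` — extra "ectopic" hair cells appear medial to row 1,
  midway toward the pillar-cell/IHC position (a partial extra row);
* ``jitter_sd`` — isotropic Gaussian positional noise per cell.

Every operation is a pure function of its inputs and an explicit integer
seed (numpy PCG64), so identical configs reproduce bit-identical mosaics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError
from .mosaic import CellRecord, Mosaic

SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic epithelium.

    Spacings are µm. ``row_spacing=None`` derives d_r = d_c·√3/2, the
    near-hexagonal default under which the noiseless lattice has six
    equidistant nearest neighbors per interior cell. The default
    ``col_spacing`` of 8 µm is a placeholder on the scale of an embryonic
    OHC lumenal surface, not a measured value; set it from data when
    available.
    """

    n_rows: int = 3
    cells_per_row: int = 20
    col_spacing: float = 8.0
    row_spacing: float | None = None
    row_offset_fraction: float = 0.5
    jitter_sd: float = 0.0
    missing_rate: float = 0.0
    ectopic_rate: float = 0.0
    seed: int = 0
    cell_type: str = "OHC"
    include_ihc: bool = False
    genotype_label: str = "control"
    region_label: str = "base"

    def __post_init__(self) -> None:
        if not math.isfinite(self.col_spacing) or self.col_spacing <= 0:
            raise ConfigurationError(f"col_spacing must be finite and > 0, got {self.col_spacing}")
        if self.row_spacing is not None and (
            not math.isfinite(self.row_spacing) or self.row_spacing <= 0
        ):
            raise ConfigurationError(f"row_spacing must be finite and > 0, got {self.row_spacing}")
        if self.n_rows < 1:
            raise ConfigurationError(f"n_rows must be >= 1, got {self.n_rows}")
        if self.cells_per_row < 2:
            raise ConfigurationError(f"cells_per_row must be >= 2, got {self.cells_per_row}")
        for name in ("missing_rate", "ectopic_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.jitter_sd < 0:
            raise ConfigurationError(f"jitter_sd must be >= 0, got {self.jitter_sd}")

    @property
    def d_c(self) -> float:
        return self.col_spacing

    @property
    def d_r(self) -> float:
        return self.row_spacing if self.row_spacing is not None else self.col_spacing * SQRT3_2


#: Named generator presets. "control" is a mildly noisy ordered epithelium;
#: "etv_tko" emulates the knockout phenotype: strong positional disorder,
#: occasional missing cells, and ectopic hair cells in the pillar region.
PRESETS: dict[str, dict] = {
    "control": dict(jitter_sd=0.05 * 8.0, missing_rate=0.01, ectopic_rate=0.0,
                    genotype_label="control"),
    "etv_tko": dict(jitter_sd=0.25 * 8.0, missing_rate=0.05, ectopic_rate=0.1,
                    genotype_label="etv_tko"),
}


def preset_config(name: str, **overrides) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a named preset plus overrides."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return GeneratorConfig(**params)


def generate_lattice(config: GeneratorConfig) -> Mosaic:
    """Generate one synthetic mosaic from a config.

    Lattice sites (row i, column j, 0-based internally) sit at
    x = j·d_c + (i mod 2)·row_offset_fraction·d_c, y = i·d_r; ``row_index``
    stored on the cells is i + 1. Sites are then removed with
    ``missing_rate``, ectopic cells inserted with ``ectopic_rate`` (one
    candidate site per column, at y = −d_r/2), and finally all cells are
    jittered with ``jitter_sd``; all three edits draw from one RNG seeded
    with ``config.seed``. The epithelium length is cells_per_row·d_c.
    """
    rng = np.random.default_rng(config.seed)
    d_c, d_r = config.d_c, config.d_r

    cells: list[CellRecord] = []
    next_id = 0
    for i in range(config.n_rows):
        x_off = (i % 2) * config.row_offset_fraction * d_c
        for j in range(config.cells_per_row):
            cells.append(
                CellRecord(next_id, j * d_c + x_off, i * d_r, config.cell_type, i + 1)
            )
            next_id += 1
    if config.include_ihc:
        for j in range(config.cells_per_row):
            cells.append(CellRecord(next_id, j * d_c, -d_r, "IHC", 1))
            next_id += 1

    # missing cells: each site dropped independently
    if config.missing_rate > 0:
        keep = rng.random(len(cells)) >= config.missing_rate
        cells = [c for c, k in zip(cells, keep) if k]

    # ectopic cells in the pillar region, medial to row 1
    if config.ectopic_rate > 0:
        take = rng.random(config.cells_per_row) < config.ectopic_rate
        for j in np.nonzero(take)[0]:
            cells.append(CellRecord(next_id, float(j) * d_c, -0.5 * d_r, "ectopic", 1))
            next_id += 1

    length = config.cells_per_row * d_c
    mosaic = Mosaic(
        cells=cells,
        sample_id=f"{config.genotype_label}_{config.region_label}_s{config.seed}",
        genotype=config.genotype_label,
        region=config.region_label,
        length_um=length,
    )
    if config.jitter_sd > 0:
        mosaic = _jitter_with_rng(mosaic, config.jitter_sd, rng)
    return mosaic


def _jitter_with_rng(mosaic: Mosaic, sd: float, rng: np.random.Generator) -> Mosaic:
    n = len(mosaic.cells)
    disp = rng.normal(0.0, sd, size=(n, 2))
    new_cells = [
        replace(c, x=c.x + float(dx), y=c.y + float(dy))
        for c, (dx, dy) in zip(mosaic.cells, disp)
    ]
    # jitter can push cells past the digitized field edge; keep L valid
    extent = max((c.x for c in new_cells), default=0.0) - min((c.x for c in new_cells), default=0.0)
    length = max(mosaic.length_um, extent)
    return Mosaic(new_cells, mosaic.sample_id, mosaic.genotype, mosaic.region, length)


def add_jitter(mosaic: Mosaic, sd: float, seed: int) -> Mosaic:
    """Displace every cell by independent N(0, sd²) noise per axis.

    sd = 0 returns the mosaic unchanged. Labels, ids and the epithelium
    length are untouched (length only grows if jitter widens the field).
    """
    if sd < 0:
        raise ConfigurationError(f"jitter sd must be >= 0, got {sd}")
    if sd == 0:
        return mosaic
    return _jitter_with_rng(mosaic, sd, np.random.default_rng(seed))


def insert_ectopic(mosaic: Mosaic, rate: float, seed: int) -> Mosaic:
    """Insert ectopic cells medial to row 1, one candidate site per column.

    Candidate sites sit below each row-1 cell of the mosaic's majority
    non-ectopic type, midway toward the pillar/IHC position (half the
    row-1→row-2 spacing); each is included independently with probability
    ``rate``. Existing cells are untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"ectopic rate must be in [0, 1], got {rate}")
    if rate == 0 or not mosaic.cells:
        return mosaic
    types = [c.cell_type for c in mosaic.cells if c.cell_type not in ("ectopic", "IHC")]
    if not types:
        return mosaic
    majority = max(set(types), key=types.count)
    row1 = mosaic.select(cell_type=majority, row_index=1)
    if not row1:
        return mosaic
    row2 = mosaic.select(cell_type=majority, row_index=2)
    if row2:
        dy = float(np.median([c.y for c in row2])) - float(np.median([c.y for c in row1]))
    else:
        dy = 0.0
    if dy == 0.0:
        dy = SQRT3_2 * _median_nn_spacing(row1)
    rng = np.random.default_rng(seed)
    take = rng.random(len(row1)) < rate
    next_id = max(c.cell_id for c in mosaic.cells) + 1
    new_cells = list(mosaic.cells)
    for c, t in zip(row1, take):
        if t:
            new_cells.append(CellRecord(next_id, c.x, c.y - 0.5 * dy, "ectopic", 1))
            next_id += 1
    return mosaic.with_cells(new_cells)


def _median_nn_spacing(cells: list[CellRecord]) -> float:
    xs = np.sort(np.array([c.x for c in cells], dtype=float))
    if len(xs) < 2:
        return 1.0
    return float(np.median(np.diff(xs)))
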