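"""Core in-memory containers for digitized cell-centroid fields.

A :class:`Mosaic` is one imaged field of the organ of Corti: a flat list of
cell centroids (µm, image-local frame, x = longitudinal basal→apical axis,
y = medial→lateral axis) plus the sample/genotype/region labels and the
length of the sensory epithelium in the field, which the density statistic
divides by.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, IntegrityError

#: Cell-type labels understood by the counting and star machinery.
CELL_TYPES = ("IHC", "OHC", "IPC", "OPC", "DC", "ectopic")


@dataclass(frozen=True)
class CellRecord:
    """One cell centroid.

    ``row_index`` is 1-based with row 1 the medial-most row of its type
    (for OHCs, the row adjacent to the pillar cells).
    """

    cell_id: int
    x: float
    y: float
    cell_type: str
    row_index: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ConfigurationError(
                f"cell {self.cell_id}: coordinates must be finite, got ({self.x}, {self.y})"
            )
        if self.row_index < 1:
            raise ConfigurationError(
                f"cell {self.cell_id}: row_index must be >= 1, got {self.row_index}"
            )


@dataclass
class Mosaic:
    """One imaged field: cells plus labels and epithelium length (µm)."""

    cells: list[CellRecord]
    sample_id: str = "sample"
    genotype: str = "control"
    region: str = "base"
    length_um: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ConfigurationError(
                f"mosaic {self.sample_id}: epithelium length must be > 0, got {self.length_um}"
            )
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise IntegrityError(f"mosaic {self.sample_id}: duplicate cell ids")
        if self.cells:
            extent = max(c.x for c in self.cells) - min(c.x for c in self.cells)
            # allow a hair of float slack when lengths were digitized separately
            if self.length_um < extent - 1e-9:
                raise ConfigurationError(
                    f"mosaic {self.sample_id}: length {self.length_um} µm shorter than "
                    f"longitudinal cell extent {extent:.3f} µm"
                )

    def __len__(self) -> int:
        return len(self.cells)

    def coords(self) -> np.ndarray:
        """(n, 2) array of cell coordinates in insertion order."""
        return np.array([(c.x, c.y) for c in self.cells], dtype=float).reshape(-1, 2)

    def ids(self) -> np.ndarray:
        return np.array([c.cell_id for c in self.cells], dtype=np.int64)

    def select(
        self,
        cell_type: str | tuple[str, ...] | None = None,
        row_index: int | None = None,
    ) -> list[CellRecord]:
        """Cells matching a type (or tuple of types) and/or a row index."""
        if isinstance(cell_type, str):
            cell_type = (cell_type,)
        out = []
        for c in self.cells:
            if cell_type is not None and c.cell_type not in cell_type:
                continue
            if row_index is not None and c.row_index != row_index:
                continue
            out.append(c)
        return out

    def longitudinal_extent(self) -> float:
        """max(x) − min(x) over cells; a default for the epithelium length."""
        if not self.cells:
            return 0.0
        xs = [c.x for c in self.cells]
        return max(xs) - min(xs)

    def with_cells(self, cells: list[CellRecord]) -> "Mosaic":
        return replace(self, cells=cells)
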