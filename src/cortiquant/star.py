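"""Six-arm nearest-neighbor angular-sector ("star") patterning statistic.

For every focal cell in a chosen row, arms are drawn to the centers of its
k = 6 closest same-type cells; the direction of each arm, measured
counter-clockwise from the longitudinal reference axis, is binned into 16
radial sectors of 22.5° numbered 1–16. Accumulated over all focal cells in
a sample this yields a sector-occupancy profile: a perfectly ordered
offset-row lattice concentrates all arms in six sectors, while disordered
mosaics spread the mass.

Conventions (stated because the field's figures leave them implicit):
sector s covers the half-open arc [(s−1)·22.5°, s·22.5°); sector 1 starts
at the reference axis and numbering runs counter-clockwise; nearest
neighbors are ordered and tie-broken by (distance, cell_id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import (
    ConfigurationError,
    DegenerateGeometryError,
    DomainError,
    InsufficientDataError,
    InsufficientNeighborsError,
)
from .mosaic import CellRecord, Mosaic


@dataclass(frozen=True)
class StarConfig:
    """Parameters of the sector-occupancy analysis.

    ``target_row`` is 2 for the OHC analysis (second-row focal cells) and
    typically 4 for PROX1+ supporting-cell mosaics. ``min_focal_cells``
    mirrors the requirement of at least 10 focal hair cells per region per
    sample. ``axis_mode='estimated'`` orients sector 1 along the principal
    axis of the target row; ``'given'`` uses ``given_axis_angle`` (degrees,
    as when the image frame is already aligned with the epithelium).
    ``candidate_types=None`` draws neighbors from the focal row's cell type,
    plus ectopic cells when ``include_ectopic`` (they are hair cells sitting
    out of place, and they are exactly what disturbs row-1/2 neighborhoods
    in the mutant).
    """

    k: int = 6
    n_sectors: int = 16
    target_row: int = 2
    min_focal_cells: int = 10
    axis_mode: str = "estimated"
    given_axis_angle: float = 0.0
    edge_policy: str = "include"
    margin: float = 0.0
    candidate_types: tuple[str, ...] | None = None
    include_ectopic: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.n_sectors < 2:
            raise ConfigurationError(f"n_sectors must be >= 2, got {self.n_sectors}")
        if self.axis_mode not in ("estimated", "given"):
            raise ConfigurationError(f"axis_mode must be 'estimated' or 'given', got {self.axis_mode!r}")
        if self.edge_policy not in ("include", "exclude_margin"):
            raise ConfigurationError(
                f"edge_policy must be 'include' or 'exclude_margin', got {self.edge_policy!r}"
            )
        if self.margin < 0:
            raise ConfigurationError(f"margin must be >= 0, got {self.margin}")

    @property
    def sector_width(self) -> float:
        return 360.0 / self.n_sectors


@dataclass(frozen=True)
class NeighborStar:
    """One focal cell with its k nearest neighbors and arm angles (degrees)."""

    focal_id: int
    neighbor_ids: tuple[int, ...]
    arm_angles: tuple[float, ...]


@dataclass
class SectorProfile:
    """Per-sample sector-occupancy counts and frequencies."""

    sample_id: str
    genotype: str
    region: str
    counts: np.ndarray
    frequencies: np.ndarray
    n_focal: int

    @property
    def n_sectors(self) -> int:
        return len(self.counts)


def estimate_axis(mosaic: Mosaic, target_row: int) -> float:
    """Orientation (degrees, mod 180, in [0, 180)) of the target row.

    The principal axis — the direction of maximal variance — of the
    target-row cell coordinates, so collinear cells return their line's
    orientation exactly.
    """
    cells = [c for c in mosaic.cells if c.row_index == target_row and c.cell_type != "ectopic"]
    if len(cells) < 2:
        raise InsufficientDataError(
            f"axis estimation needs >= 2 cells in row {target_row}, found {len(cells)}"
        )
    pts = np.array([(c.x, c.y) for c in cells], dtype=float)
    centered = pts - pts.mean(axis=0)
    _, vecs = np.linalg.eigh(centered.T @ centered)
    v = vecs[:, -1]  # eigenvector of the largest eigenvalue
    return float(math.degrees(math.atan2(v[1], v[0])) % 180.0)


def _k_nearest_order(dists: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances, tie-broken by ascending id."""
    order = np.lexsort((ids, dists))
    return order[:k]


def find_k_nearest(focal: CellRecord, candidates: list[CellRecord], k: int) -> list[int]:
    """Ids of the k candidates closest to ``focal`` (Euclidean).

    Ordering and tie-breaking by (distance, cell_id) ascending, identical
    to an exhaustive all-pairs scan. ``candidates`` must exclude the focal
    cell itself.
    """
    cand = [c for c in candidates if c.cell_id != focal.cell_id]
    if len(cand) < k:
        raise InsufficientNeighborsError(
            f"cell {focal.cell_id}: {len(cand)} candidates < k={k}"
        )
    pts = np.array([(c.x, c.y) for c in cand], dtype=float)
    ids = np.array([c.cell_id for c in cand], dtype=np.int64)
    d = np.hypot(pts[:, 0] - focal.x, pts[:, 1] - focal.y)
    return [int(ids[i]) for i in _k_nearest_order(d, ids, k)]


def arm_angles(focal: CellRecord, neighbors: list[CellRecord], axis: float) -> list[float]:
    """Arm directions in degrees CCW from the axis, each in [0, 360)."""
    out = []
    for nb in neighbors:
        dx, dy = nb.x - focal.x, nb.y - focal.y
        if dx == 0.0 and dy == 0.0:
            raise DegenerateGeometryError(
                f"cells {focal.cell_id} and {nb.cell_id} have coincident coordinates"
            )
        a = (math.degrees(math.atan2(dy, dx)) - axis) % 360.0
        out.append(a if a < 360.0 else 0.0)  # fp guard: % can round up to 360
    return out


def bin_to_sectors(angles, n_sectors: int = 16) -> np.ndarray:
    """Map angles in [0, 360) to 1-based sector indices.

    Sector s covers [(s−1)·360/n, s·360/n); an angle just under 360 maps to
    sector n_sectors.
    """
    a = np.asarray(angles, dtype=float)
    if np.any((a < 0.0) | (a >= 360.0)):
        bad = a[(a < 0.0) | (a >= 360.0)]
        raise DomainError(f"angles must lie in [0, 360); got {bad[:5]}")
    width = 360.0 / n_sectors
    sectors = np.floor(a / width).astype(np.int64) + 1
    return np.minimum(sectors, n_sectors)


def compute_stars(mosaic: Mosaic, config: StarConfig) -> tuple[list[NeighborStar], float]:
    """Build the NeighborStar for every eligible focal cell.

    Returns the stars and the axis angle used. Focal cells are the
    non-ectopic cells of ``target_row``; candidates are every cell whose
    type is in the configured candidate set (the focal cell excluded from
    its own candidates). Focal cells with fewer than k candidates are
    skipped under the default edge policy; ``exclude_margin`` additionally
    drops focal cells within ``margin`` µm of the mosaic's bounding box.
    """
    focal_cells = [
        c for c in mosaic.cells if c.row_index == config.target_row and c.cell_type != "ectopic"
    ]
    if not focal_cells:
        raise InsufficientDataError(
            f"sample {mosaic.sample_id}: no cells in target row {config.target_row}"
        )
    types = [c.cell_type for c in focal_cells]
    focal_type = max(set(types), key=types.count)
    if config.candidate_types is not None:
        cand_types = tuple(config.candidate_types)
    elif config.include_ectopic:
        cand_types = (focal_type, "ectopic")
    else:
        cand_types = (focal_type,)
    candidates = [c for c in mosaic.cells if c.cell_type in cand_types]

    if config.axis_mode == "given":
        axis = config.given_axis_angle
    else:
        axis = estimate_axis(mosaic, config.target_row)

    if config.edge_policy == "exclude_margin" and mosaic.cells:
        xy = mosaic.coords()
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        m = config.margin
        focal_cells = [
            c for c in focal_cells
            if c.x >= lo[0] + m and c.x <= hi[0] - m and c.y >= lo[1] + m and c.y <= hi[1] - m
        ]

    cand_xy = np.array([(c.x, c.y) for c in candidates], dtype=float).reshape(-1, 2)
    cand_ids = np.array([c.cell_id for c in candidates], dtype=np.int64)
    focal_xy = np.array([(c.x, c.y) for c in focal_cells], dtype=float).reshape(-1, 2)

    stars: list[NeighborStar] = []
    if len(candidates):
        dmat = cdist(focal_xy, cand_xy)
        for i, cell in enumerate(focal_cells):
            d = dmat[i].copy()
            self_mask = cand_ids == cell.cell_id
            d[self_mask] = np.inf
            if np.count_nonzero(~self_mask) < config.k:
                continue  # edge cell with too few candidates
            sel = _k_nearest_order(d, cand_ids, config.k)
            if np.any(d[sel] == 0.0):
                j = sel[d[sel] == 0.0][0]
                raise DegenerateGeometryError(
                    f"cells {cell.cell_id} and {int(cand_ids[j])} have coincident coordinates"
                )
            dx = cand_xy[sel, 0] - cell.x
            dy = cand_xy[sel, 1] - cell.y
            ang = (np.degrees(np.arctan2(dy, dx)) - axis) % 360.0
            ang[ang >= 360.0] = 0.0  # fp guard: (x % 360) can round to 360
            stars.append(
                NeighborStar(cell.cell_id, tuple(int(v) for v in cand_ids[sel]),
                             tuple(float(v) for v in ang))
            )
    if len(stars) < config.min_focal_cells:
        raise InsufficientDataError(
            f"sample {mosaic.sample_id}: {len(stars)} eligible focal cells < "
            f"min_focal_cells={config.min_focal_cells}"
        )
    return stars, axis


def compute_profile(mosaic: Mosaic, config: StarConfig) -> SectorProfile:
    """Sector-occupancy profile of one mosaic.

    Accumulates the binned arm angles of every eligible focal cell's star;
    counts sum to k·n_focal and frequencies are normalized to 1.
    """
    stars, _ = compute_stars(mosaic, config)
    counts = np.zeros(config.n_sectors, dtype=np.int64)
    for star in stars:
        sectors = bin_to_sectors(star.arm_angles, config.n_sectors)
        np.add.at(counts, sectors - 1, 1)
    total = counts.sum()
    return SectorProfile(
        sample_id=mosaic.sample_id,
        genotype=mosaic.genotype,
        region=mosaic.region,
        counts=counts,
        frequencies=counts / total,
        n_focal=len(stars),
    )


def aggregate_group(profiles: list[SectorProfile]) -> np.ndarray:
    """Unweighted mean of per-sample frequency vectors (one group's radar)."""
    if not profiles:
        raise InsufficientDataError("aggregate_group needs at least one profile")
    n = {p.n_sectors for p in profiles}
    if len(n) != 1:
        raise ConfigurationError(f"profiles disagree on n_sectors: {sorted(n)}")
    return np.mean([p.frequencies for p in profiles], axis=0)
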