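"""Cell density per 100 µm of sensory epithelium, with two-way ANOVA + Tukey.

Density is defined exactly as it is measured from a confocal surface image:
the number of cells of a chosen type divided by the length of the organ of
Corti within the image, times 100 (cells per 100 µm). Densities across a
genotype × region design are compared with a fixed-effects two-way ANOVA
(type-II sums of squares) and Tukey's HSD over the design cells, reported
for genotype contrasts within each region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import DegenerateDesignError, DomainError, InsufficientDataError
from .mosaic import CELL_TYPES, Mosaic


def count_cells(mosaic: Mosaic, cell_type: str) -> int:
    """Count cells of a type; labels may be compound like ``"OHC+ectopic"``."""
    parts = cell_type.split("+")
    for p in parts:
        if p not in CELL_TYPES:
            raise DomainError(f"unknown cell type {p!r}; known: {list(CELL_TYPES)}")
    wanted = set(parts)
    return sum(1 for c in mosaic.cells if c.cell_type in wanted)


def compute_density(n_cells: int, length_um: float) -> float:
    """(n_cells / L) × 100 — cells per 100 µm of epithelium."""
    if length_um <= 0:
        raise DomainError(f"epithelium length must be > 0, got {length_um}")
    if n_cells < 0:
        raise DomainError(f"cell count must be >= 0, got {n_cells}")
    return n_cells / length_um * 100.0


@dataclass(frozen=True)
class DensityRecord:
    sample_id: str
    genotype: str
    region: str
    cell_type: str
    n_cells: int
    length_um: float
    density: float


def density_record(mosaic: Mosaic, cell_type: str = "OHC+ectopic") -> DensityRecord:
    """Measure one mosaic. Ectopic cells count as hair cells by default,
    since mutant fields contain them among the OHC rows."""
    n = count_cells(mosaic, cell_type)
    return DensityRecord(
        sample_id=mosaic.sample_id,
        genotype=mosaic.genotype,
        region=mosaic.region,
        cell_type=cell_type,
        n_cells=n,
        length_um=mosaic.length_um,
        density=compute_density(n, mosaic.length_um),
    )


def density_records(mosaics: list[Mosaic], cell_type: str = "OHC+ectopic") -> list[DensityRecord]:
    return [density_record(m, cell_type) for m in mosaics]


def records_frame(records: list[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class DensityComparison:
    anova: pd.DataFrame
    tukey: pd.DataFrame


def compare_density(records: list[DensityRecord] | pd.DataFrame) -> DensityComparison:
    """Two-way ANOVA (genotype, region, interaction) + Tukey HSD.

    The ANOVA is fixed-effects with type-II sums of squares (identical to
    type-I/III on balanced data). Tukey's HSD is computed over all
    genotype × region cells — so the studentized-range adjustment spans the
    whole design — and the table returned keeps the genotype contrasts
    within each region, the comparisons of interest.
    """
    df = records if isinstance(records, pd.DataFrame) else records_frame(records)
    genos = df["genotype"].unique()
    regions = df["region"].unique()
    if len(genos) < 2 or len(regions) < 2:
        raise InsufficientDataError(
            f"need >= 2 genotypes and >= 2 regions, got {len(genos)} x {len(regions)}"
        )
    sizes = df.groupby(["genotype", "region"], sort=False).size()
    if len(sizes) < len(genos) * len(regions) or (sizes < 2).any():
        raise InsufficientDataError(
            "every genotype x region cell needs >= 2 replicates; got cell sizes "
            f"{sizes.to_dict()}"
        )
    within_var = df.groupby(["genotype", "region"], sort=False)["density"].var(ddof=1)
    if np.allclose(within_var.fillna(0.0), 0.0):
        raise DegenerateDesignError("zero within-group variance in every design cell")

    model = smf.ols("density ~ C(genotype) * C(region)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(index={
        "C(genotype)": "genotype",
        "C(region)": "region",
        "C(genotype):C(region)": "genotype:region",
        "Residual": "residual",
    })

    cell = df["genotype"].astype(str) + "|" + df["region"].astype(str)
    tk = pairwise_tukeyhsd(df["density"].to_numpy(), cell.to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    g1 = tukey["group1"].str.split("|", expand=True)
    g2 = tukey["group2"].str.split("|", expand=True)
    same_region = g1[1] == g2[1]
    tukey = tukey[same_region].copy()
    tukey["region"] = g1[1][same_region]
    tukey["genotype1"] = g1[0][same_region]
    tukey["genotype2"] = g2[0][same_region]
    tukey = tukey[
        ["region", "genotype1", "genotype2", "meandiff", "p-adj", "lower", "upper", "reject"]
    ].reset_index(drop=True)
    return DensityComparison(anova=anova, tukey=tukey)
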