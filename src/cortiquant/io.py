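"""CSV/JSON formats: mosaic tables, result tables, run configuration.

The mosaic table is the digitized form of a confocal surface image: one
row per cell with columns sample_id, genotype, region, cell_type,
row_index, x_um, y_um, length_um (the epithelium length repeated for every
cell of the sample), plus an optional cell_id column. Comma-separated,
UTF-8, "." decimal separator, header required but order-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import TestOptions
from .exceptions import ConfigurationError, IntegrityError, ParseError, SchemaError
from .mosaic import CellRecord, Mosaic
from .star import SectorProfile, StarConfig
from .synthetic import GeneratorConfig, PRESETS

REQUIRED_COLUMNS = (
    "sample_id", "genotype", "region", "cell_type", "row_index", "x_um", "y_um", "length_um",
)


def read_mosaics(path: str | Path) -> list[Mosaic]:
    """Read a mosaic table into one Mosaic per sample_id (in file order).

    Malformed rows are reported with their 1-based file line numbers
    (header = line 1). Duplicate (sample_id, cell_id) pairs are an error;
    without a cell_id column, ids are assigned by row order within sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected header {list(REQUIRED_COLUMNS)}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    def _numeric(col: str, kind=float) -> np.ndarray:
        # python's float() round-trips repr exactly (pandas' fast parser does not)
        out = []
        for i, raw in enumerate(df[col]):
            line = i + 2  # +1 header, +1 zero-based
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ParseError(f"{path}: line {line}: non-numeric value in column {col!r}")
            if not np.isfinite(v):
                raise ParseError(f"{path}: line {line}: non-finite value in column {col!r}")
            if kind is int:
                if v != int(v):
                    raise ParseError(f"{path}: line {line}: column {col!r} must be an integer")
                v = int(v)
            out.append(v)
        return np.array(out, dtype=np.int64 if kind is int else float)

    x = _numeric("x_um")
    y = _numeric("y_um")
    row_index = _numeric("row_index", int)
    length = _numeric("length_um")
    if "cell_id" in df.columns:
        cell_id = _numeric("cell_id", int)
        dup = df.assign(_cid=cell_id).duplicated(subset=["sample_id", "_cid"])
        if dup.any():
            line = int(dup.idxmax()) + 2
            raise IntegrityError(f"{path}: line {line}: duplicate (sample_id, cell_id)")
    else:
        cell_id = df.groupby("sample_id", sort=False).cumcount().to_numpy()

    mosaics = []
    for sid in df["sample_id"].unique():
        mask = (df["sample_id"] == sid).to_numpy()
        rows = df[mask]
        cells = [
            CellRecord(int(ci), float(xi), float(yi), ct, int(ri))
            for ci, xi, yi, ct, ri in zip(
                cell_id[mask], x[mask], y[mask], rows["cell_type"], row_index[mask]
            )
        ]
        mosaics.append(
            Mosaic(
                cells=cells,
                sample_id=str(sid),
                genotype=str(rows["genotype"].iloc[0]),
                region=str(rows["region"].iloc[0]),
                length_um=float(length[mask][0]),
            )
        )
    return mosaics


def mosaics_frame(mosaics: list[Mosaic]) -> pd.DataFrame:
    rows = []
    for m in mosaics:
        for c in m.cells:
            rows.append(
                {"sample_id": m.sample_id, "genotype": m.genotype, "region": m.region,
                 "cell_type": c.cell_type, "row_index": c.row_index, "cell_id": c.cell_id,
                 "x_um": c.x, "y_um": c.y, "length_um": m.length_um}
            )
    return pd.DataFrame(rows)


def write_mosaics(mosaics: list[Mosaic], path: str | Path) -> None:
    mosaics_frame(mosaics).to_csv(path, index=False)


def profiles_frame(profiles: list[SectorProfile]) -> pd.DataFrame:
    """Per-sample sector table: counts and frequencies, wide format."""
    rows = []
    for p in profiles:
        row: dict = {"sample_id": p.sample_id, "genotype": p.genotype,
                     "region": p.region, "n_focal": p.n_focal}
        for s in range(p.n_sectors):
            row[f"count_{s + 1}"] = int(p.counts[s])
        for s in range(p.n_sectors):
            row[f"freq_{s + 1}"] = float(p.frequencies[s])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration

_TEST_KEYS = {f.name for f in dataclasses.fields(TestOptions)}
_STAR_KEYS = {f.name for f in dataclasses.fields(StarConfig)}
_GEN_KEYS = {f.name for f in dataclasses.fields(GeneratorConfig)}
_TOP_KEYS = {"control", "mutant", "star", "tests", "n_samples", "seed", "out_dir",
             "control_preset", "mutant_preset"}


@dataclass
class RunConfig:
    """Declarative run configuration (JSON document).

    ``control``/``mutant`` override generator fields on top of the named
    presets; unknown keys anywhere are rejected so a typo cannot silently
    change an analysis.
    """

    control_preset: str = "control"
    mutant_preset: str = "etv_tko"
    control: dict = field(default_factory=dict)
    mutant: dict = field(default_factory=dict)
    star: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)
    n_samples: int = 3
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name, keys in (("control", _GEN_KEYS), ("mutant", _GEN_KEYS),
                           ("star", _STAR_KEYS), ("tests", _TEST_KEYS)):
            unknown = set(getattr(self, name)) - keys
            if unknown:
                raise ConfigurationError(f"unknown key(s) in {name!r}: {sorted(unknown)}")
        for preset in (self.control_preset, self.mutant_preset):
            if preset not in PRESETS:
                raise ConfigurationError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")

    def generator_config(self, which: str) -> GeneratorConfig:
        preset = self.control_preset if which == "control" else self.mutant_preset
        params = dict(PRESETS[preset])
        params.update(getattr(self, which))
        return GeneratorConfig(**params)

    def star_config(self) -> StarConfig:
        star = dict(self.star)
        if "candidate_types" in star and star["candidate_types"] is not None:
            star["candidate_types"] = tuple(star["candidate_types"])
        return StarConfig(**star)

    def test_options(self) -> TestOptions:
        return TestOptions(**self.tests)

    def resolved(self) -> dict:
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")  # path choice is not part of the analysis identity
        doc["resolved_control"] = dataclasses.asdict(self.generator_config("control"))
        doc["resolved_mutant"] = dataclasses.asdict(self.generator_config("mutant"))
        doc["resolved_star"] = dataclasses.asdict(self.star_config())
        doc["resolved_tests"] = dataclasses.asdict(self.test_options())
        return doc

    def fingerprint(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: run config must be a JSON object")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"{path}: unknown key(s) {sorted(unknown)}")
    return RunConfig(**doc)


def write_resolved_config(config: RunConfig, out_dir: str | Path) -> Path:
    out = Path(out_dir) / "run_config.json"
    out.write_text(json.dumps(config.resolved(), sort_keys=True, indent=2) + "\n",
                   encoding="utf-8")
    return out
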