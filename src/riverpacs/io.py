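"""CSV schemas, run configuration and result writers.

Interchange format is plain CSV (UTF-8, header row).  Validation errors name
the offending file and column/row so a misassembled input fails loudly at
load time rather than as a silent misprediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .prediction import WFDBands
from .scenarios import DEFAULT_SCENARIOS, Scenario
from .synthetic import PREDICTOR_TAGS

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_grid_table",
    "read_reference_sites",
    "read_occurrence",
    "read_scores",
    "read_tables",
    "load_paper_tables",
    "write_geojson",
]


class SchemaError(ValueError):
    """An input table violates its documented schema."""


GRID_COLUMNS = ["x", "y", "altitude", "basin", "water_temperature", "discharge"]


def _read_indexed(path: str | Path, index_col: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if index_col not in df.columns:
        raise SchemaError(f"{path}: missing column {index_col!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate id {dup!r}")
    return df.set_index(index_col)


def read_grid_table(path: str | Path) -> pd.DataFrame:
    """Load the 500 x 500 m grid-cell table (cell_id + env predictors)."""
    df = _read_indexed(path, "cell_id", GRID_COLUMNS)
    if (df["discharge"] <= 0).any():
        bad = df.index[df["discharge"] <= 0][0]
        raise SchemaError(f"{path}: non-positive discharge at {bad!r}")
    return df


def read_reference_sites(path: str | Path) -> pd.DataFrame:
    """Load the reference-site environment table (site_id + env predictors)."""
    df = _read_indexed(path, "site_id", GRID_COLUMNS)
    if (df["discharge"] <= 0).any():
        bad = df.index[df["discharge"] <= 0][0]
        raise SchemaError(f"{path}: non-positive discharge at {bad!r}")
    return df


def read_occurrence(path: str | Path) -> pd.DataFrame:
    """Load the binary site x taxon occurrence matrix (strictly 0/1)."""
    df = _read_indexed(path, "site_id", [])
    bad = ~df.isin([0, 1]).all(axis=1)
    if bad.any():
        raise SchemaError(f"{path}: non-binary occurrence at row {df.index[bad][0]!r}")
    return df.astype(int)


def read_scores(path: str | Path) -> pd.Series:
    """Load per-taxon IBMWP scores (taxon, score)."""
    df = _read_indexed(path, "taxon", ["score"])
    return df["score"].astype(int)


def read_tables(grids, sites, occurrence, scores=None):
    """Load and validate the full input bundle; returns the four tables."""
    g = read_grid_table(grids)
    s = read_reference_sites(sites)
    o = read_occurrence(occurrence)
    sc = read_scores(scores) if scores else None
    extra = o.index.difference(s.index)
    if len(extra):
        raise SchemaError(f"occurrence has sites not in the site table: {list(extra)[:5]}")
    return g, s, o, sc


def load_paper_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The packaged published per-taxon tables (occupied grids; shifts)."""
    base = resources.files("riverpacs") / "data"
    t2 = pd.read_csv(str(base / "table2_paper.csv")).set_index("taxon")
    t3 = pd.read_csv(str(base / "table3_paper.csv")).set_index("taxon")
    return t2, t3


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with printable defaults."""

    seed: int = 0
    n_cells: int = 2000
    n_basins: int = 9
    n_taxa: int = 40
    n_sites: int = 300
    k_groups: int | None = 5  # None -> silhouette choice
    min_group_size: int = 15  # small clusters absorbed into nearest group
    n_models: int = 5
    predictors: list[str] = field(
        default_factory=lambda: ["water_temperature", "discharge", "altitude", "x", "y"]
    )
    predictor_tags: dict[str, str] = field(default_factory=lambda: dict(PREDICTOR_TAGS))
    outlier_alpha: float = 0.01
    outlier_vote_threshold: int = 3
    capture_threshold: float = 0.5
    scenarios: list[Scenario] = field(default_factory=lambda: list(DEFAULT_SCENARIOS))
    wfd_bands: WFDBands = field(default_factory=WFDBands)
    out_dir: str = "runs/out"

    def __post_init__(self) -> None:
        if not 0.0 < self.capture_threshold <= 1.0:
            raise ValueError("capture_threshold must lie in (0, 1]")
        if not self.scenarios or not self.scenarios[0].is_baseline:
            raise ValueError("scenario list must start with the baseline")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenarios" in raw:
            raw["scenarios"] = [Scenario(**s) for s in raw["scenarios"]]
        if "wfd_bands" in raw:
            raw["wfd_bands"] = WFDBands(tuple((b["label"], b["lower"]) for b in raw["wfd_bands"]))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def describe(self) -> str:
        d = asdict(self)
        d["scenarios"] = [f"{s.label}(+{s.delta_t}degC,x{s.flow_factor})" for s in self.scenarios]
        d["wfd_bands"] = [f"{l}>={b}" for l, b in self.wfd_bands.bands]
        return "\n".join(f"  {k}: {v}" for k, v in d.items())


def write_geojson(path: str | Path, grids: pd.DataFrame, values: dict[str, pd.Series]) -> None:
    """Export per-grid values as a GeoJSON point layer keyed by centroid."""
    features = []
    for cell_id, row in grids.iterrows():
        props = {"cell_id": cell_id}
        for name, series in values.items():
            v = series.get(cell_id)
            props[name] = None if pd.isna(v) else (v.item() if hasattr(v, "item") else v)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
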