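"""Readers and writers for the plain-text formats of the pipeline.

Indicator tables are TSV with ``plot_id``, ``treatment`` and one column per
indicator code; ASV tables are TSV with ASV ids as rows and sample ids as
columns, accompanied by a taxonomy TSV (``asv_id`` plus ranks
kingdom..genus); distance matrices are labeled square TSV; path-model
specs and function schemes are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .community import DistanceMatrix, OrdinationResult
from .multifunctionality import FunctionScheme
from .drivers import PathModelSpec
from .synthetic import ASVTable

__all__ = [
    "read_indicator_table",
    "write_indicator_table",
    "read_asv_table",
    "write_asv_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_ordination",
    "load_scheme",
    "save_scheme",
    "load_path_spec",
    "save_path_spec",
    "write_json",
]


def _find_bad_cells(frame: pd.DataFrame) -> list[tuple[str, str]]:
    bad = []
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        for idx in frame.index[coerced.isna()]:
            bad.append((str(idx), str(col)))
    return bad


def read_indicator_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plot x indicator TSV."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col="plot_id")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed indicator table ({exc})") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate plot ids: {dup}")
    if "treatment" not in raw.columns:
        raise ValueError(f"{path}: missing 'treatment' column")
    numeric_part = raw.drop(columns=["treatment"])
    bad = _find_bad_cells(numeric_part)
    if bad:
        raise ValueError(f"{path}: non-numeric cells at (plot, indicator): {bad[:5]}")
    out = numeric_part.astype(float)
    out.insert(0, "treatment", raw["treatment"])
    return out


def write_indicator_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="plot_id")


def read_asv_table(counts_path: str | Path, taxonomy_path: str | Path) -> ASVTable:
    """Read ASV counts (rows = ASV ids, columns = sample ids) plus taxonomy."""
    counts_path, taxonomy_path = Path(counts_path), Path(taxonomy_path)
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    bad = _find_bad_cells(raw)
    if bad:
        raise ValueError(f"{counts_path}: non-numeric cells at (asv, sample): {bad[:5]}")
    counts = raw.astype(np.int64).T  # stored ASVs x samples; in memory samples x ASVs
    negative = [
        (str(s), str(a))
        for s in counts.index
        for a in counts.columns[counts.loc[s] < 0]
    ]
    if negative:
        raise ValueError(f"{counts_path}: negative counts at (sample, asv): {negative[:5]}")
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id")
    missing = counts.columns.difference(taxonomy.index)
    if len(missing):
        raise ValueError(f"{taxonomy_path}: taxonomy missing ASV ids: {list(missing)[:10]}")
    return ASVTable(counts, taxonomy)


def write_asv_table(asv: ASVTable, counts_path: str | Path, taxonomy_path: str | Path) -> None:
    asv.counts.T.to_csv(counts_path, sep="\t", index_label="asv_id")
    asv.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="asv_id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return DistanceMatrix.from_frame(frame)


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    d.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def write_ordination(result: OrdinationResult, path: str | Path) -> None:
    """Write NMDS coordinates with the stress in a header comment line."""
    with open(path, "w") as fh:
        fh.write(f"# stress={result.stress:.6f} converged={result.converged} "
                 f"restarts={result.n_restarts_used}\n")
        result.coordinates.to_csv(fh, sep="\t", index_label="sample_id")


def load_scheme(path: str | Path) -> FunctionScheme:
    """Load a function scheme from YAML: mapping function -> list of codes."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scheme YAML must map function names to indicator lists")
    return FunctionScheme({str(k): tuple(v) for k, v in raw.items()})


def save_scheme(scheme: FunctionScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: list(v) for k, v in scheme.groups.items()}, fh, sort_keys=False)


def load_path_spec(path: str | Path) -> PathModelSpec:
    """Load a path-model DAG from YAML: ``edges: [[source, target], ...]``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "edges" not in raw:
        raise ValueError(f"{path}: path-model YAML needs an 'edges' list")
    edges = tuple((str(a), str(b)) for a, b in raw["edges"])
    return PathModelSpec(edges)


def save_path_spec(spec: PathModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"edges": [list(e) for e in spec.edges]}, fh, sort_keys=False)


def write_json(payload: Any, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict()
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_default)
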