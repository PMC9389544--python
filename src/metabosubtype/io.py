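"""Readers and writers for the delimited-table, GMT, GraphML and JSON formats
the pipeline touches, plus config loading and Table-1-style cohort summaries."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    AnalysisConfig,
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MetaboliteAbundanceMatrix,
)

log = logging.getLogger("metabosubtype")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "read_gmt",
    "write_gmt",
    "write_results",
    "summarize_cohort",
    "load_config",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(
    path: str | Path,
    kind: str = "expression",
    missing_policy: str = "reject",
) -> ExpressionMatrix | MetaboliteAbundanceMatrix:
    """Load a features x samples matrix from a TSV/CSV file.

    The first column holds feature ids, the header row sample ids.  The
    delimiter (tab or comma) is auto-detected.  ``kind='metabolome'`` enforces
    strictly positive intensities; missing cells are rejected by default or
    imputed at half the metabolite's minimum under ``missing_policy='min-impute'``.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    log.info("reading %s matrix from %s (delimiter=%r)", kind, path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature id(s) in {path.name}: {dup[:5]}")
    non_num = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_num):
        coerced = df[non_num].apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df[non_num].notna()
        if bad.any().any():
            r, c = np.argwhere(bad.values)[0]
            raise ValueError(
                f"non-numeric cell at ({bad.index[r]!r}, {bad.columns[c]!r}) in {path.name}"
            )
        df[non_num] = coerced
    if df.isna().any().any():
        if kind == "metabolome" and missing_policy == "min-impute":
            fill = df.min(axis=1) / 2.0
            df = df.apply(lambda row: row.fillna(fill[row.name]), axis=1)
            log.info("min-imputed missing metabolite intensities at half row minima")
        else:
            r, c = np.argwhere(df.isna().values)[0]
            raise ValueError(
                f"missing value at ({df.index[r]!r}, {df.columns[c]!r}); "
                "set missing_policy='min-impute' to impute"
            )
    if kind == "metabolome":
        return MetaboliteAbundanceMatrix(df)
    if kind == "expression":
        return ExpressionMatrix(df)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix: ExpressionMatrix | MetaboliteAbundanceMatrix, path: str | Path) -> None:
    """Write a matrix as TSV at full float precision (exact round-trip)."""
    matrix.values.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path: str | Path) -> ClinicalTable:
    sep = _sniff_delimiter(Path(path))
    df = pd.read_csv(path, sep=sep)
    return ClinicalTable(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _six_sig(x: Any) -> Any:
    if isinstance(x, (float, np.floating)):
        return float(f"{x:.6g}")
    return x


def write_results(obj: Any, path: str | Path, format: str = "tsv") -> None:
    """Serialise a result object with a deterministic field order.

    Supported pairs: DataFrame -> tsv, dict/Series -> json, networkx graph ->
    graphml.  Floats are rendered with 6 significant digits.
    """
    import networkx as nx

    path = Path(path)
    if format == "tsv" and isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", float_format="%.6g")
    elif format == "json" and isinstance(obj, (dict, pd.Series)):
        if isinstance(obj, pd.Series):
            obj = obj.to_dict()
        payload = json.loads(json.dumps(obj, default=_json_default))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "graphml" and isinstance(obj, nx.Graph):
        rounded = nx.Graph()
        rounded.add_nodes_from(obj.nodes(data=True))
        for u, v, data in obj.edges(data=True):
            rounded.add_edge(u, v, **{k: _six_sig(val) for k, val in data.items()})
        nx.write_graphml(rounded, path)
    else:
        raise ValueError(
            f"unsupported (object, format) pair: ({type(obj).__name__}, {format}); "
            "supported: (DataFrame, tsv), (dict|Series, json), (Graph, graphml)"
        )


def _json_default(x: Any) -> Any:
    if isinstance(x, (np.floating, float)):
        return _six_sig(float(x))
    if isinstance(x, np.integer):
        return int(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _pct(n: int, total: int) -> str:
    """Percentage rounded half-up to one decimal, rendered like '69.6'."""
    if total == 0:
        return "0.0"
    q = (Decimal(100 * n) / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return str(q)


def summarize_cohort(clinical: ClinicalTable, variables: list[str]) -> pd.DataFrame:
    """Per-level 'n (pct%)' counts for categorical variables, Table-1 style.

    Percentages use the full cohort size as denominator (missing values shown
    as an NA category), so that levels of a complete variable sum to 100%.
    """
    df = clinical.table
    total = len(df)
    rows = []
    for var in variables:
        if var not in df.columns:
            raise ValueError(f"unknown clinical variable {var!r}")
        col = df[var].astype(object).where(df[var].notna(), "NA")
        counts = col.value_counts(dropna=False)
        for level, n in counts.items():
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "n": int(n),
                    "pct": float(_pct(int(n), total)),
                    "display": f"{int(n)} ({_pct(int(n), total)}%)",
                }
            )
    return pd.DataFrame(rows, columns=["variable", "level", "n", "pct", "display"])


_CONFIG_KEYS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; None -> defaults."""
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        raw = {k: v for k, v in raw.items() if k in _CONFIG_KEYS}
    if "wmcna_powers" in raw:
        raw["wmcna_powers"] = tuple(raw["wmcna_powers"])
    return AnalysisConfig(**raw)
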