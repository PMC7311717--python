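"""Readers and writers for the pipeline's plain-text interchange formats.

Concentration tables and probe-site tables travel as CSV; networks travel
as edge-list TSV or GraphML; result reports as JSON. CSV is the single
tabular format and nM the single concentration unit. Missing concentrations
are serialized as an empty field (never 0 or an NA string); booleans as
``true``/``false``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

from .panel import (
    PANEL_CODES,
    REQUIRED_COLUMNS,
    STATES,
    TABLE_COLUMNS,
    ConcentrationTable,
    FormatError,
)

__all__ = [
    "read_concentration_table",
    "write_concentration_table",
    "read_probe_sites",
    "write_probe_sites",
    "write_network",
    "read_network",
    "write_json_report",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(raw: str, column: str, line: int) -> bool:
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise FormatError(f"line {line}: cannot parse {column}={raw!r} as boolean") from None


def read_concentration_table(path: str | Path, panel: tuple[str, ...] = PANEL_CODES) -> ConcentrationTable:
    """Parse a long-form concentration CSV.

    Header must contain ``mouse_id,state,sample_index,analyte,
    concentration_nM,below_lloq`` (``imputed`` optional). An absent
    concentration is an empty field and is legal only when below_lloq is
    true; schema violations raise :class:`FormatError`, duplicate keys and
    flag inconsistencies :class:`IntegrityError`, unknown analyte or state
    codes :class:`VocabularyError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path.name}: header lacks required column(s): {', '.join(missing)}"
            )
        has_imputed = "imputed" in header
        rows = []
        for i, row in enumerate(reader, start=2):
            conc_raw = (row["concentration_nM"] or "").strip()
            rows.append(
                {
                    "mouse_id": row["mouse_id"],
                    "state": row["state"],
                    "sample_index": int(row["sample_index"]),
                    "analyte": row["analyte"],
                    "concentration_nM": float(conc_raw) if conc_raw else math.nan,
                    "below_lloq": _parse_bool(row["below_lloq"], "below_lloq", i),
                    "imputed": _parse_bool(row["imputed"], "imputed", i) if has_imputed else False,
                }
            )
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if df.empty:
        df = df.astype(
            {"sample_index": int, "concentration_nM": float, "below_lloq": bool, "imputed": bool}
        )
    return ConcentrationTable(df, panel)


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> Path:
    """Write a concentration table; inverse of :func:`read_concentration_table`."""
    path = Path(path)
    df = table.df
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TABLE_COLUMNS)
        for row in df.itertuples(index=False):
            conc = "" if pd.isna(row.concentration_nM) else repr(float(row.concentration_nM))
            writer.writerow(
                [
                    row.mouse_id,
                    row.state,
                    int(row.sample_index),
                    row.analyte,
                    conc,
                    "true" if row.below_lloq else "false",
                    "true" if row.imputed else "false",
                ]
            )
    return path


PROBE_COLUMNS = ("mouse_id", "state", "ap_mm", "ml_mm", "dv_mm")


def read_probe_sites(path: str | Path) -> pd.DataFrame:
    """Read a probe-site CSV (AP/ML/DV in mm relative to bregma)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: header lacks required column(s): {', '.join(missing)}")
    bad = set(df["state"].unique()) - set(STATES)
    if bad:
        from .panel import VocabularyError

        raise VocabularyError(f"unknown state label(s) {sorted(bad)}")
    if df["mouse_id"].duplicated().any():
        from .panel import IntegrityError

        raise IntegrityError("duplicate mouse_id in probe-site table (one site per mouse)")
    if not np.isfinite(df[["ap_mm", "ml_mm", "dv_mm"]].to_numpy(float)).all():
        from .panel import IntegrityError

        raise IntegrityError("non-finite probe coordinate")
    return df[list(PROBE_COLUMNS)]


def write_probe_sites(sites: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sites[list(PROBE_COLUMNS)].to_csv(path, index=False)
    return path


def write_network(network: nx.Graph, path: str | Path, format: str = "edgelist") -> Path:
    """Write an (un)directed analyte network.

    ``edgelist`` produces a TSV with columns ``source, target, weight``
    plus ``directed`` for directed networks; ``graphml`` round-trips node
    and edge attributes via networkx.
    """
    path = Path(path)
    directed = network.is_directed()
    if format == "edgelist":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            header = ["source", "target", "weight"] + (["directed"] if directed else [])
            writer.writerow(header)
            for u, v, data in network.edges(data=True):
                row = [u, v, repr(float(data.get("weight", 1.0)))]
                if directed:
                    row.append("true")
                writer.writerow(row)
    elif format == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unsupported network format {format!r}; use 'edgelist' or 'graphml'")
    return path


def read_network(path: str | Path, format: str = "edgelist", directed: bool = False) -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return g
    if format != "edgelist":
        raise ValueError(f"unsupported network format {format!r}; use 'edgelist' or 'graphml'")
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:3] != ["source", "target", "weight"]:
            raise FormatError(f"{path.name}: bad edge-list header {header!r}")
        directed = directed or "directed" in header
        g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        for row in reader:
            if not row:
                continue
            g.add_edge(row[0], row[1], weight=float(row[2]))
    return g


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return path
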