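"""Tabular I/O: scans, design tables, network maps, connectivity matrices.

Everything is tab-separated text with a single header row; square matrices
carry node ids as both header and first column so files stay diff-able and
language-agnostic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConnectivityMatrix, ScanTimeseries

_FLOAT_FMT = "%.10g"


def write_scan_tsv(scan: ScanTimeseries, path: str | Path) -> None:
    df = pd.DataFrame(scan.data, columns=scan.node_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_scan_tsv(path: str | Path, meta: dict | None = None) -> ScanTimeseries:
    df = pd.read_csv(path, sep="\t")
    bad = df.columns[df.isna().any()].tolist()
    if bad:
        raise ValueError(f"{path}: missing values in columns {bad}")
    return ScanTimeseries(data=df.to_numpy(float), node_ids=list(df.columns),
                          meta=dict(meta or {}))


def read_design_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"participant", "drug", "half", "filename"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table lacks columns {sorted(missing)}")
    return df


def read_study(data_dir: str | Path) -> dict[tuple[str, str, str], ScanTimeseries]:
    """Read all scans listed in a directory's design_table.tsv."""
    data_dir = Path(data_dir)
    table = read_design_table(data_dir / "design_table.tsv")
    scans = {}
    for row in table.itertuples(index=False):
        key = (row.participant, row.drug, row.half)
        scans[key] = read_scan_tsv(
            data_dir / row.filename,
            meta={"participant": row.participant, "drug": row.drug, "half": row.half},
        )
    return scans


def write_matrix_tsv(cm: ConnectivityMatrix, path: str | Path) -> None:
    """Square matrix TSV; header comment line names the measure and units."""
    units = {"sfc_r": "pearson_r", "sfc_z": "fisher_z",
             "dfc_var": "variance", "efc_H": "nats"}[cm.measure]
    with open(path, "w") as fh:
        fh.write(f"# measure={cm.measure} units={units}\n")
        pd.DataFrame(cm.values, index=cm.node_ids, columns=cm.node_ids).to_csv(
            fh, sep="\t", float_format=_FLOAT_FMT, index_label="node_id"
        )


def read_matrix_tsv(path: str | Path, meta: dict | None = None) -> ConnectivityMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# measure="):
            raise ValueError(f"{path}: missing measure header line")
        measure = header.split()[1].split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col="node_id")
    return ConnectivityMatrix(values=df.to_numpy(float), measure=measure,
                              node_ids=list(df.columns), meta=dict(meta or {}))


def write_edge_table(
    matrices: dict[tuple[str, str, str], ConnectivityMatrix], path: str | Path
) -> None:
    """Long-format edge table: participant, drug, half, node_i, node_j,
    measure, value."""
    rows = []
    for (pid, drug, half), cm in sorted(matrices.items()):
        iu, ju = np.triu_indices(cm.n_nodes, k=1)
        nodes = np.array(cm.node_ids)
        vals = cm.upper_values()
        rows.append(pd.DataFrame({
            "participant": pid, "drug": drug, "half": half,
            "node_i": nodes[iu], "node_j": nodes[ju],
            "measure": cm.measure, "value": vals,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False,
                                              float_format=_FLOAT_FMT)


def matrix_filename(pid: str, drug: str, half: str, measure: str) -> str:
    return f"{pid}_{drug}_{half}_{measure}.tsv"


def read_measure_matrices(
    conn_dir: str | Path, design: pd.DataFrame, measure: str
) -> dict[tuple[str, str, str], ConnectivityMatrix]:
    conn_dir = Path(conn_dir)
    out = {}
    for row in design.itertuples(index=False):
        key = (row.participant, row.drug, row.half)
        path = conn_dir / matrix_filename(*key, measure)
        out[key] = read_matrix_tsv(path, meta={"participant": row.participant,
                                               "drug": row.drug, "half": row.half})
    return out
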