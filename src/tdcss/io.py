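"""Readers and writers for the plain-text formats the pipeline touches.

Traces travel as CSV (cell_id, channel, time_h, signal); count matrices as
MatrixMarket (genes x cells) with TSV sidecars for gene and cell
annotations, or as a single dense TSV; cohorts and Ct tables as TSV.  All
writers produce files the corresponding reader round-trips exactly (within
float formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .classify import StateCountMatrix
from .errors import SchemaError
from .onset import OnsetCall
from .trace import SecretionTrace

__all__ = [
    "write_traces",
    "read_traces",
    "write_counts",
    "read_counts",
    "write_cohort",
    "read_cohort",
    "read_ct_table",
    "write_onset_calls",
]

TRACE_COLUMNS = ["cell_id", "channel", "time_h", "signal"]


def write_traces(traces: list[SecretionTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "channel": tr.channel,
                "time_h": tr.times,
                "signal": tr.signal,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[SecretionTrace]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace file missing columns {missing}")
    traces = []
    for (cell_id, channel), grp in df.groupby(["cell_id", "channel"], sort=False):
        times = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise SchemaError(f"non-monotone times for cell {cell_id!r}")
        traces.append(
            SecretionTrace(
                cell_id=str(cell_id),
                times=times,
                signal=grp["signal"].to_numpy(dtype=float),
                channel=str(channel),
            )
        )
    return traces


def write_counts(matrix: StateCountMatrix, out_dir) -> None:
    """Write matrix.mtx plus genes.tsv / cells.tsv sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", scipy.sparse.csr_matrix(matrix.counts))
    pd.DataFrame(
        {"gene_id": matrix.gene_ids, "spikein": matrix.spikein_mask.astype(int)}
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    cells = pd.DataFrame({"cell_id": matrix.cell_ids, "state": matrix.state})
    if matrix.donor is not None:
        cells["donor"] = matrix.donor
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)


def read_counts(matrix_path, genes_path=None, cells_path=None) -> StateCountMatrix:
    """Read a count matrix (MTX with sidecars, or dense TSV) plus labels.

    For MTX input, ``genes_path``/``cells_path`` default to ``genes.tsv``
    and ``cells.tsv`` beside the matrix.  A dense TSV must have gene ids in
    the first column and cell ids as header; ``cells_path`` is then
    required for the state labels.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        counts = np.asarray(scipy.io.mmread(matrix_path).todense())
        genes_path = genes_path or matrix_path.parent / "genes.tsv"
        cells_path = cells_path or matrix_path.parent / "cells.tsv"
        genes = pd.read_csv(genes_path, sep="\t")
        gene_ids = genes["gene_id"].astype(str).tolist()
        spikein = (
            genes["spikein"].to_numpy(dtype=bool) if "spikein" in genes else None
        )
    else:
        dense = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts = dense.to_numpy()
        gene_ids = dense.index.astype(str).tolist()
        spikein = None
        if cells_path is None:
            raise SchemaError("dense TSV input requires a cells label file")
        cells_path = Path(cells_path)
    cells = pd.read_csv(cells_path, sep="\t")
    if "cell_id" not in cells or "state" not in cells:
        raise SchemaError("cells file must have cell_id and state columns")
    if counts.shape[0] != len(gene_ids):
        raise SchemaError(
            f"matrix has {counts.shape[0]} rows but {len(gene_ids)} gene ids"
        )
    if counts.shape[1] != len(cells):
        raise SchemaError(
            f"matrix has {counts.shape[1]} columns but {len(cells)} cell labels"
        )
    if np.any(counts < 0):
        raise SchemaError("negative counts in matrix file")
    donor = cells["donor"].to_numpy() if "donor" in cells else None
    return StateCountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        cell_ids=cells["cell_id"].astype(str).tolist(),
        state=cells["state"].to_numpy(),
        donor=donor,
        spikein_mask=spikein,
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("group", "time_h", "event") if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing columns {missing}")
    df["event"] = df["event"].astype(bool)
    return df


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample", "ct_target", "ct_ref") if c not in df.columns]
    if missing:
        raise SchemaError(f"Ct table missing columns {missing}")
    return df


def write_onset_calls(calls: list[OnsetCall], path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "cell_id": c.cell_id,
                "flag_time": c.online_flag_time,
                "a": c.fit.drift_a if c.fit else None,
                "b": c.fit.slope_b if c.fit else None,
                "t_hat": c.fit.onset_t_hat if c.fit else None,
                "sse": c.fit.sse if c.fit else None,
                "converged": c.fit.converged if c.fit else None,
                "recovery_time": c.recovery_time,
                "delta_t": c.delta_t,
                "bin": c.delta_t_bin,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
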