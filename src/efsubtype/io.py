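"""Plain-text readers and writers for pipeline artifacts.

All artifacts are small text files: cohort tables and partitions as CSV,
networks and connectome matrices as TSV, reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pls import ConnectomeSet


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_partition(node_ids, labels, path) -> None:
    pd.DataFrame({"node_id": node_ids, "community": np.asarray(labels)}).to_csv(
        path, index=False
    )


def read_partition(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_connectomes(conn: ConnectomeSet, out_dir) -> Path:
    """Write one TSV matrix per participant plus a manifest TSV.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, mat, group in zip(conn.participant_ids, conn.matrices, conn.groups):
        fname = f"{pid}_connectome.tsv"
        pd.DataFrame(mat, index=conn.node_labels, columns=conn.node_labels).to_csv(
            out_dir / fname, sep="\t"
        )
        rows.append({"participant_id": pid, "file": fname, "group_truth": group})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_connectomes(manifest_path) -> ConnectomeSet:
    """Load a connectome set from a manifest TSV written by write_connectomes."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    matrices = []
    node_labels = None
    for fname in manifest["file"]:
        frame = pd.read_csv(manifest_path.parent / fname, sep="\t", index_col=0)
        if node_labels is None:
            node_labels = [str(c) for c in frame.columns]
        matrices.append(frame.to_numpy(dtype=float))
    group_col = "group_truth" if "group_truth" in manifest else "group"
    return ConnectomeSet(
        participant_ids=list(manifest["participant_id"]),
        node_labels=node_labels,
        matrices=np.array(matrices),
        groups=manifest[group_col].to_numpy(),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
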