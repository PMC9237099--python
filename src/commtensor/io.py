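"""Readers and writers for the formats the toolkit exchanges.

Expression comes in as Matrix Market triplets with gene/barcode sidecars or
as dense gene x cell CSV/TSV; annotations and metadata as TSV; LR catalogs
and per-context edge lists as CSV; pathway gene sets as GMT.  Tensors are
serialized to HDF5 with axis-label datasets (and optionally to a long CSV).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio

from .tensor_build import (
    DEFAULT_SUBUNIT_DELIMITER,
    CommTensor,
    LRCatalog,
)


# ---------------------------------------------------------------------------
# expression input


def read_mtx_dir(path) -> pd.DataFrame:
    """Read an MTX directory (matrix.mtx, genes.tsv, barcodes.tsv).

    The matrix is stored genes x cells (the 10x convention); the returned
    DataFrame is cells x genes.
    """
    path = Path(path)
    mtx = path / "matrix.mtx"
    genes_f = path / "genes.tsv"
    barcodes_f = path / "barcodes.tsv"
    for f in (mtx, genes_f, barcodes_f):
        if not f.exists():
            raise FileNotFoundError(f"missing expression sidecar: {f}")
    mat = spio.mmread(mtx).toarray()
    genes = pd.read_csv(genes_f, sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].tolist()
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    return pd.DataFrame(mat.T, index=barcodes, columns=genes)


def read_dense_expression(path, sep: str | None = None) -> pd.DataFrame:
    """Read a dense genes x cells CSV/TSV; returns cells x genes."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.T


def read_cell_annotation(path) -> pd.Series:
    """TSV with columns (barcode, cell_type) -> barcode-indexed Series."""
    df = pd.read_csv(path, sep="\t")
    for col in ("barcode", "cell_type"):
        if col not in df.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    return df.set_index("barcode")["cell_type"]


def read_context_metadata(path) -> pd.DataFrame:
    """TSV with columns (context_id, group, ordinal_level)."""
    df = pd.read_csv(path, sep="\t")
    if "context_id" not in df.columns:
        raise ValueError("metadata table lacks column 'context_id'")
    return df.set_index("context_id")


def read_lr_catalog(
    path, delimiter: str = DEFAULT_SUBUNIT_DELIMITER
) -> LRCatalog:
    """LR catalog CSV with columns ligand, receptor[, pair_id]."""
    return LRCatalog.from_frame(pd.read_csv(path), delimiter=delimiter)


def read_edge_list(path) -> pd.DataFrame:
    """Per-context edge-list CSV: sender, receiver, ligand_complex,
    receptor_complex, score."""
    df = pd.read_csv(path)
    required = {"sender", "receiver", "ligand_complex", "receptor_complex", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gmt(path) -> dict:
    """GMT gene-set file -> {set name: set of genes}."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


# ---------------------------------------------------------------------------
# tensor serialization


def write_tensor_hdf5(tensor: CommTensor, path) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tensor.data)
        f.attrs["score_method"] = tensor.score_method
        for name, labels in tensor.axis_labels.items():
            f.create_dataset(
                name, data=np.array([str(x) for x in labels], dtype=object),
                dtype=str_dt,
            )


def read_tensor_hdf5(path) -> CommTensor:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        labels = {
            name: [x.decode() if isinstance(x, bytes) else str(x) for x in f[name][...]]
            for name in CommTensor.DIM_NAMES
        }
        method = f.attrs.get("score_method", "mean")
    return CommTensor(
        data=data,
        contexts=labels["contexts"],
        pairs=labels["pairs"],
        senders=labels["senders"],
        receivers=labels["receivers"],
        score_method=str(method),
    )


def write_tensor_long_csv(tensor: CommTensor, path) -> None:
    tensor.to_long_frame().to_csv(path, index=False)
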