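"""Build labeled 4D cell-cell communication tensors from expression data.

The central object is :class:`CommTensor`, a non-negative array of
communication scores with shape ``contexts x LR pairs x sender cell types x
receiver cell types``.  It is assembled in three steps: per-context expression
matrices are aggregated to cell-type level (:func:`aggregate_expression`),
ligand/receptor complex expression is summarised by the minimum over subunits
(:func:`complex_expression`), and a communication score couples ligand
expression in a sender with receptor expression in a receiver
(:func:`score_pair`).  Edge lists produced by external scoring tools can be
restructured into the same tensor via :func:`tensor_from_edge_lists`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGGREGATION_METHODS = ("nonzero_fraction", "mean_logcpm", "mean_raw")
SCORE_METHODS = ("mean", "product", "gmean")

#: delimiter joining complex subunits in catalog CSVs (CellChat convention)
DEFAULT_SUBUNIT_DELIMITER = "&"
#: delimiter joining ligand and receptor complexes into a pair id
PAIR_DELIMITER = "^"


def _check_unique(labels: Sequence, what: str) -> None:
    if len(set(labels)) != len(labels):
        dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} labels: {dupes}")


@dataclass
class CellTypeProfile:
    """Cell-type x gene expression summary for one context.

    Parameters
    ----------
    context_id : str
        Label of the biological context (sample, time point, ...).
    values : pandas.DataFrame
        Non-negative matrix with cell types as index and genes as columns.
    aggregation : str
        One of ``nonzero_fraction`` (fraction of cells with a non-zero
        count), ``mean_logcpm`` (mean of per-cell log(CPM+1)) or
        ``mean_raw`` (mean raw count).
    """

    context_id: str
    values: pd.DataFrame
    aggregation: str

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATION_METHODS:
            raise ValueError(
                f"unknown aggregation {self.aggregation!r}; "
                f"expected one of {AGGREGATION_METHODS}"
            )
        _check_unique(list(self.values.index), "cell-type")
        _check_unique(list(self.values.columns), "gene")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("profile contains non-finite values")
        if (arr < 0).any():
            raise ValueError("profile contains negative values")
        if self.aggregation == "nonzero_fraction" and (arr > 1).any():
            raise ValueError("nonzero_fraction values must lie in [0, 1]")

    @property
    def genes(self) -> list:
        return list(self.values.columns)

    @property
    def cell_types(self) -> list:
        return list(self.values.index)


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; either side may be a multi-subunit complex."""

    pair_id: str
    ligand_subunits: tuple
    receptor_subunits: tuple

    def __post_init__(self) -> None:
        if len(self.ligand_subunits) == 0:
            raise ValueError(f"pair {self.pair_id!r} has an empty ligand")
        if len(self.receptor_subunits) == 0:
            raise ValueError(f"pair {self.pair_id!r} has an empty receptor")

    @property
    def genes(self) -> tuple:
        return tuple(self.ligand_subunits) + tuple(self.receptor_subunits)


@dataclass
class LRCatalog:
    """Ordered list of ligand-receptor pairs."""

    pairs: list

    def __post_init__(self) -> None:
        _check_unique([p.pair_id for p in self.pairs], "pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def pair_ids(self) -> list:
        return [p.pair_id for p in self.pairs]

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, delimiter: str = DEFAULT_SUBUNIT_DELIMITER
    ) -> "LRCatalog":
        """Build a catalog from a table with ``ligand``/``receptor`` columns.

        Subunits of heteromeric complexes are ``delimiter``-joined inside a
        field.  An optional ``pair_id`` column overrides the default
        ``ligand^receptor`` identifier.
        """
        for col in ("ligand", "receptor"):
            if col not in frame.columns:
                raise ValueError(f"catalog table lacks required column {col!r}")
        pairs = []
        for _, row in frame.iterrows():
            lig = str(row["ligand"]).strip()
            rec = str(row["receptor"]).strip()
            if not lig or lig == "nan" or not rec or rec == "nan":
                raise ValueError(f"malformed pair row: {row.to_dict()}")
            pid = (
                str(row["pair_id"])
                if "pair_id" in frame.columns and not pd.isna(row["pair_id"])
                else f"{lig}{PAIR_DELIMITER}{rec}"
            )
            pairs.append(
                LRPair(
                    pair_id=pid,
                    ligand_subunits=tuple(s.strip() for s in lig.split(delimiter)),
                    receptor_subunits=tuple(s.strip() for s in rec.split(delimiter)),
                )
            )
        return cls(pairs)


@dataclass
class CommTensor:
    """Labeled non-negative 4D communication tensor.

    ``data[i, j, k, l]`` is the communication score in context ``i`` for LR
    pair ``j`` from sender cell type ``k`` to receiver cell type ``l``.
    """

    data: np.ndarray
    contexts: list
    pairs: list
    senders: list
    receivers: list
    score_method: str = "mean"

    DIM_NAMES = ("contexts", "pairs", "senders", "receivers")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected a 4-way array, got ndim={self.data.ndim}")
        labels = (self.contexts, self.pairs, self.senders, self.receivers)
        for name, lab, size in zip(self.DIM_NAMES, labels, self.data.shape):
            if len(lab) != size:
                raise ValueError(
                    f"{name}: {len(lab)} labels for axis of size {size}"
                )
            _check_unique(list(lab), name)
        if not np.isfinite(self.data).all():
            raise ValueError("tensor contains non-finite entries")
        if (self.data < 0).any():
            raise ValueError("tensor contains negative entries")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def axis_labels(self) -> dict:
        return {
            "contexts": list(self.contexts),
            "pairs": list(self.pairs),
            "senders": list(self.senders),
            "receivers": list(self.receivers),
        }

    def to_long_frame(self) -> pd.DataFrame:
        """Flatten to a long table (context, pair, sender, receiver, score)."""
        idx = pd.MultiIndex.from_product(
            [self.contexts, self.pairs, self.senders, self.receivers],
            names=["context", "pair", "sender", "receiver"],
        )
        return pd.DataFrame({"score": self.data.ravel()}, index=idx).reset_index()

    def to_hdf5(self, path) -> None:
        from .io import write_tensor_hdf5

        write_tensor_hdf5(self, path)

    @classmethod
    def from_hdf5(cls, path) -> "CommTensor":
        from .io import read_tensor_hdf5

        return read_tensor_hdf5(path)


def aggregate_expression(
    counts: pd.DataFrame,
    cell_labels: Mapping | pd.Series,
    method: str = "nonzero_fraction",
    context_id: str = "context",
    log_base: float = 2.0,
) -> CellTypeProfile:
    """Aggregate a cell x gene count matrix to the cell-type level.

    Parameters
    ----------
    counts : pandas.DataFrame
        Cells (index) x genes (columns), non-negative counts.
    cell_labels : mapping or Series
        Cell barcode -> cell-type label; every cell in ``counts`` must be
        labeled.  A categorical Series with unused categories (a declared
        cell type with zero cells) is rejected.
    method : str
        ``nonzero_fraction``: per gene, fraction of the type's cells with a
        non-zero count.  ``mean_logcpm``: per cell counts-per-million, then
        ``log(CPM + 1)`` in base ``log_base`` (default log2), averaged within
        the type.  ``mean_raw``: mean raw count within the type.
    """
    if method not in AGGREGATION_METHODS:
        raise ValueError(f"unknown aggregation method {method!r}")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    labels = pd.Series(cell_labels)
    missing = counts.index.difference(labels.index)
    if len(missing) > 0:
        raise ValueError(f"unlabeled cell(s): {list(missing[:5])}")
    labels = labels.loc[counts.index]
    if labels.isna().any():
        bad = counts.index[labels.isna()]
        raise ValueError(f"unlabeled cell(s): {list(bad[:5])}")
    if isinstance(labels.dtype, pd.CategoricalDtype):
        unused = set(labels.cat.categories) - set(labels.unique())
        if unused:
            raise ValueError(
                f"cell type(s) with zero cells: {sorted(unused)}"
            )

    if method == "nonzero_fraction":
        values = (counts > 0).groupby(labels.to_numpy()).mean()
    elif method == "mean_logcpm":
        totals = counts.sum(axis=1)
        cpm = counts.div(totals.where(totals > 0, 1.0), axis=0) * 1e6
        logged = np.log(cpm + 1.0) / np.log(log_base)
        values = logged.groupby(labels.to_numpy()).mean()
    else:  # mean_raw
        values = counts.groupby(labels.to_numpy()).mean()

    values = values.sort_index()
    values.index.name = "cell_type"
    values.columns.name = "gene"
    return CellTypeProfile(
        context_id=context_id, values=values.astype(float), aggregation=method
    )


def complex_expression(profile: CellTypeProfile, subunits: Iterable) -> pd.Series:
    """Expression of a (possibly multimeric) protein per cell type.

    For complexes the minimum expression over all subunits is used, so a
    missing subunit silences the whole complex.
    """
    subunits = list(subunits)
    missing = [g for g in subunits if g not in profile.values.columns]
    if missing:
        raise KeyError(
            f"subunit gene(s) {missing} absent from context "
            f"{profile.context_id!r}"
        )
    return profile.values[subunits].min(axis=1)


def score_pair(
    ligand_vals: np.ndarray | pd.Series,
    receptor_vals: np.ndarray | pd.Series,
    method: str = "mean",
) -> np.ndarray:
    """Sender x receiver communication-score matrix for one LR pair.

    ``mean``: (L_k + R_l)/2; ``product``: L_k * R_l; ``gmean``:
    sqrt(L_k * R_l).
    """
    if method not in SCORE_METHODS:
        raise ValueError(f"unknown score method {method!r}")
    lig = np.asarray(ligand_vals, dtype=float)
    rec = np.asarray(receptor_vals, dtype=float)
    if (lig < 0).any() or (rec < 0).any():
        raise ValueError("expression values must be non-negative")
    if method == "mean":
        return (lig[:, None] + rec[None, :]) / 2.0
    if method == "product":
        return lig[:, None] * rec[None, :]
    return np.sqrt(lig[:, None] * rec[None, :])


def filter_catalog(
    catalog: LRCatalog, profiles: Sequence[CellTypeProfile]
) -> LRCatalog:
    """Keep pairs whose every subunit gene is measured in every context."""
    if len(profiles) == 0:
        raise ValueError("at least one profile is required")
    gene_sets = [set(p.values.columns) for p in profiles]
    kept = [
        p
        for p in catalog
        if all(all(g in gs for g in p.genes) for gs in gene_sets)
    ]
    return LRCatalog(kept)


def shared_cell_types(profiles: Sequence[CellTypeProfile]) -> list:
    """Sorted intersection of cell types present in every context."""
    types = set(profiles[0].values.index)
    for p in profiles[1:]:
        types &= set(p.values.index)
    return sorted(types)


def build_tensor(
    profiles: Sequence[CellTypeProfile],
    catalog: LRCatalog,
    method: str = "mean",
) -> CommTensor:
    """Assemble the 4D communication tensor from per-context profiles.

    The sender/receiver axes are restricted to the cell types present in
    every context (missing-type entries would otherwise be undefined) and
    ordered lexicographically.  ``catalog`` should already be restricted to
    genes measured everywhere (see :func:`filter_catalog`).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 contexts to build a tensor")
    if len(catalog) == 0:
        raise ValueError("catalog is empty after filtering")
    cell_types = shared_cell_types(profiles)
    if not cell_types:
        raise ValueError("no cell type is shared across all contexts")
    contexts = [p.context_id for p in profiles]
    _check_unique(contexts, "context")

    n_c, n_p, n_t = len(profiles), len(catalog), len(cell_types)
    data = np.empty((n_c, n_p, n_t, n_t), dtype=float)
    for i, prof in enumerate(profiles):
        sub = prof.values.loc[cell_types]
        for j, pair in enumerate(catalog):
            lig = sub[list(pair.ligand_subunits)].min(axis=1).to_numpy()
            rec = sub[list(pair.receptor_subunits)].min(axis=1).to_numpy()
            data[i, j] = score_pair(lig, rec, method=method)
    return CommTensor(
        data=data,
        contexts=contexts,
        pairs=catalog.pair_ids,
        senders=cell_types,
        receivers=cell_types,
        score_method=method,
    )


def tensor_from_edge_lists(
    edge_lists: Mapping[str, pd.DataFrame],
    shift_negative: bool = False,
) -> CommTensor:
    """Restructure per-context communication edge lists into a tensor.

    Each table must carry columns ``sender``, ``receiver``,
    ``ligand_complex``, ``receptor_complex`` and ``score``; the pair label is
    ``ligand_complex^receptor_complex``.  The pair axis is the intersection
    of pairs scored in *every* context, the cell axes the intersection of
    cell types; triples missing within the kept axes get score 0.

    Scores must be non-negative.  With ``shift_negative=True`` a single
    global shift by the most negative score is applied instead (with a
    logged warning), since the decomposition requires a non-negative tensor.
    """
    if len(edge_lists) < 2:
        raise ValueError("need edge lists for at least 2 contexts")
    required = {"sender", "receiver", "ligand_complex", "receptor_complex", "score"}
    frames = {}
    for ctx, df in edge_lists.items():
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"context {ctx!r}: missing columns {sorted(missing)}")
        df = df.copy()
        df["pair"] = (
            df["ligand_complex"].astype(str)
            + PAIR_DELIMITER
            + df["receptor_complex"].astype(str)
        )
        dup = df.duplicated(subset=["sender", "receiver", "pair"], keep=False)
        if dup.any():
            conflicting = (
                df[dup].groupby(["sender", "receiver", "pair"])["score"].nunique()
            )
            if (conflicting > 1).any():
                bad = conflicting[conflicting > 1].index[0]
                raise ValueError(
                    f"context {ctx!r}: conflicting duplicate scores for {bad}"
                )
            df = df.drop_duplicates(subset=["sender", "receiver", "pair"])
        frames[ctx] = df

    global_min = min(float(df["score"].min()) for df in frames.values())
    if global_min < 0:
        if not shift_negative:
            raise ValueError(
                f"negative communication scores (min {global_min:g}); "
                "pass shift_negative=True to shift all scores to >= 0"
            )
        logger.warning(
            "shifting all communication scores by %g so the minimum is 0",
            -global_min,
        )
        warnings.warn(
            f"negative scores shifted globally by {-global_min:g}",
            UserWarning,
            stacklevel=2,
        )
        for df in frames.values():
            df["score"] = df["score"] - global_min

    contexts = list(frames)
    pair_sets = [set(df["pair"]) for df in frames.values()]
    pairs = sorted(set.intersection(*pair_sets))
    if not pairs:
        raise ValueError("no LR pair is scored in every context")
    cell_sets = [
        set(df["sender"]) | set(df["receiver"]) for df in frames.values()
    ]
    cells = sorted(set.intersection(*cell_sets))
    if not cells:
        raise ValueError("no cell type is shared across all contexts")

    pair_idx = {p: j for j, p in enumerate(pairs)}
    cell_idx = {c: k for k, c in enumerate(cells)}
    data = np.zeros((len(contexts), len(pairs), len(cells), len(cells)))
    for i, ctx in enumerate(contexts):
        df = frames[ctx]
        keep = (
            df["pair"].isin(pair_idx)
            & df["sender"].isin(cell_idx)
            & df["receiver"].isin(cell_idx)
        )
        sub = df[keep]
        data[
            i,
            sub["pair"].map(pair_idx).to_numpy(),
            sub["sender"].map(cell_idx).to_numpy(),
            sub["receiver"].map(cell_idx).to_numpy(),
        ] = sub["score"].to_numpy(dtype=float)
    return CommTensor(
        data=data,
        contexts=contexts,
        pairs=pairs,
        senders=cells,
        receivers=cells,
        score_method="external",
    )
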