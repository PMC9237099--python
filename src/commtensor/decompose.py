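"""Non-negative CP (CANDECOMP/PARAFAC) decomposition of communication tensors.

The tensor chi (contexts x pairs x senders x receivers) is approximated by a
sum of R rank-one terms

    chi ~= sum_r  c^r (x) p^r (x) s^r (x) t^r ,    all loadings >= 0,

fitted by alternating least squares: each factor matrix is updated in turn
with the others held fixed, using hierarchical (column-wise) non-negative
updates, until the squared-Frobenius objective stops improving.  Model
quality is summarised by the normalized reconstruction error

    ||chi - chi_hat||_F^2 / ||chi||_F^2  in [0, 1],

the analogue of the fraction of unexplained variance in PCA.  The public
surface follows the statsmodels convention: :class:`CPTensorModel` is built
from a :class:`~commtensor.tensor_build.CommTensor`, ``fit`` returns a
:class:`CPResults` carrying the loadings, and rank selection / downstream
analyses hang off those two objects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import reduce
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tensor_build import CommTensor

_EPS = np.finfo(float).eps

DIM_NAMES = ("contexts", "pairs", "senders", "receivers")


# ---------------------------------------------------------------------------
# numerical core


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(mats: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise Khatri-Rao product of matrices sharing a column count."""
    r = mats[0].shape[1]
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, r)
    return out


def _mttkrp(x: np.ndarray, factors: list, mode: int) -> np.ndarray:
    others = [factors[m] for m in range(len(factors)) if m != mode]
    return _unfold(x, mode) @ _khatri_rao(others)


def _init_factors(shape, rank, rng) -> list:
    # |N(0,1)| keeps the non-negativity constraint from the start; a signed
    # SVD-style init would violate it.
    return [np.abs(rng.standard_normal((dim, rank))) for dim in shape]


def _hals_update(a: np.ndarray, m: np.ndarray, gram: np.ndarray) -> None:
    """In-place non-negative column-wise least-squares update of factor a."""
    r = a.shape[1]
    for j in range(r):
        denom = gram[j, j]
        if denom < _EPS:
            denom = _EPS
        col = a[:, j] + (m[:, j] - a @ gram[:, j]) / denom
        np.maximum(col, 0.0, out=col)
        if col.max() <= 0.0:
            col[:] = _EPS  # revive a dead component; keeps the update defined
        a[:, j] = col


def _als_single(
    x: np.ndarray,
    rank: int,
    rng,
    tol: float,
    max_iter: int,
) -> tuple:
    factors = _init_factors(x.shape, rank, rng)
    norm_x2 = float((x**2).sum())
    grams = [f.T @ f for f in factors]
    last = None
    err = 1.0
    n_modes = x.ndim
    for it in range(1, max_iter + 1):
        for mode in range(n_modes):
            m = _mttkrp(x, factors, mode)
            gram = reduce(
                np.multiply, (grams[k] for k in range(n_modes) if k != mode)
            )
            _hals_update(factors[mode], m, gram)
            grams[mode] = factors[mode].T @ factors[mode]
        # residual from the last-updated mode:
        #   ||x - xhat||^2 = ||x||^2 - 2<M, A> + <G_full, A^T A>
        inner = float((m * factors[n_modes - 1]).sum())
        rec2 = float((gram * grams[n_modes - 1]).sum())
        res2 = max(norm_x2 - 2.0 * inner + rec2, 0.0)
        err = res2 / norm_x2
        # relative change criterion; the absolute floor terminates the
        # exactly-representable case where the relative change stays noisy
        if err < 1e-14 or (
            last is not None and abs(last - err) < tol * max(err, 1e-12)
        ):
            last = err
            break
        last = err
    return factors, err, it


def nncp_als(
    tensor: CommTensor | np.ndarray,
    rank: int,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
    n_restarts: int = 3,
) -> "CPResults":
    """Fit a rank-``rank`` non-negative CP model by alternating least squares.

    ``n_restarts`` independent seeded non-negative random initialisations are
    run and the fit with the lowest normalized error is kept; the result is
    deterministic given ``(seed, tol, max_iter, n_restarts)``.
    """
    model = tensor if isinstance(tensor, CommTensor) else None
    x = tensor.data if model is not None else np.asarray(tensor, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("tensor contains non-finite entries")
    if (x < 0).any():
        raise ValueError("tensor contains negative entries")
    if not (x > 0).any():
        raise ValueError("cannot decompose an all-zero tensor")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), restart]))
        factors, err, n_iter = _als_single(x, rank, rng, tol, max_iter)
        if best is None or err < best[1]:
            best = (factors, err, n_iter)
    factors, err, n_iter = best

    # stable reporting order: strongest context signal first
    order = np.argsort(-np.linalg.norm(factors[0], axis=0), kind="stable")
    factors = [f[:, order] for f in factors]

    labels = (
        model.axis_labels
        if model is not None
        else {name: list(range(n)) for name, n in zip(DIM_NAMES, x.shape)}
    )
    cols = [f"factor_{r + 1}" for r in range(rank)]
    frames = {
        name: pd.DataFrame(f, index=labels[name], columns=cols)
        for name, f in zip(DIM_NAMES, factors)
    }
    return CPResults(
        tensor=model,
        rank=rank,
        factors=frames,
        norm_error=err,
        seed=int(seed),
        n_iter_run=n_iter,
        settings={
            "tol": tol,
            "max_iter": max_iter,
            "n_restarts": n_restarts,
        },
    )


def reconstruct(results: "CPResults") -> np.ndarray:
    """Dense reconstruction sum_r c_i^r p_j^r s_k^r t_l^r."""
    c, p, s, t = (results.factors[d].to_numpy() for d in DIM_NAMES)
    return np.einsum("ir,jr,kr,lr->ijkl", c, p, s, t)


def normalized_error(
    tensor: CommTensor | np.ndarray, results: "CPResults"
) -> float:
    """Normalized reconstruction error: residual over total squared norm."""
    x = tensor.data if isinstance(tensor, CommTensor) else np.asarray(tensor)
    rec = reconstruct(results)
    if x.shape != rec.shape:
        raise ValueError(f"shape mismatch: tensor {x.shape} vs model {rec.shape}")
    denom = float((x**2).sum())
    if denom == 0.0:
        raise ValueError("normalized error undefined for an all-zero tensor")
    return float(((x - rec) ** 2).sum()) / denom


def normalize_loadings(results: "CPResults") -> "CPResults":
    """Scale every factor column to unit Euclidean length (for reporting)."""
    frames = {}
    for name, df in results.factors.items():
        norms = np.linalg.norm(df.to_numpy(), axis=0)
        if (norms == 0).any():
            bad = [c for c, nz in zip(df.columns, norms == 0) if nz]
            raise ValueError(f"degenerate all-zero factor column(s) {bad} in {name}")
        frames[name] = df / norms
    return CPResults(
        tensor=results.tensor,
        rank=results.rank,
        factors=frames,
        norm_error=results.norm_error,
        seed=results.seed,
        n_iter_run=results.n_iter_run,
        settings=dict(results.settings),
        is_normalized=True,
    )


@dataclass
class RankScan:
    """Error curve over candidate ranks and the elbow-selected rank."""

    ranks: list
    errors: list
    selected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": self.ranks, "error": self.errors})


def _elbow(ranks: np.ndarray, errors: np.ndarray) -> int:
    """Knee of the error curve: point of maximal distance below the chord
    joining the first and last points, after min-max scaling both axes."""
    r = (ranks - ranks[0]) / max(ranks[-1] - ranks[0], 1)
    e_span = errors[0] - errors[-1]
    if e_span <= 0:
        return int(ranks[0])
    e = (errors - errors[-1]) / e_span
    chord = 1.0 - r  # scaled line from (0, 1) to (1, 0)
    gap = chord - e
    return int(ranks[int(np.argmax(gap))])


def select_rank(
    tensor: CommTensor | np.ndarray,
    ranks: Sequence[int] = range(1, 11),
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
    n_restarts: int = 3,
) -> RankScan:
    """Fit every candidate rank and pick the elbow of the error curve."""
    ranks = list(ranks)
    if len(ranks) < 3:
        raise ValueError("need at least 3 candidate ranks to locate an elbow")
    if sorted(ranks) != ranks or len(set(ranks)) != len(ranks):
        raise ValueError("ranks must be strictly increasing")
    errors = [
        nncp_als(
            tensor, r, seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts
        ).norm_error
        for r in ranks
    ]
    sel = _elbow(np.asarray(ranks, dtype=float), np.asarray(errors, dtype=float))
    return RankScan(ranks=ranks, errors=errors, selected=sel)


# ---------------------------------------------------------------------------
# model / results objects


class CPTensorModel:
    """Non-negative CP model of a communication tensor.

    Examples
    --------
    >>> model = CPTensorModel(tensor)
    >>> scan = model.select_rank(range(1, 11), seed=0)
    >>> res = model.fit(rank=scan.selected, seed=0).normalized()
    >>> print(res.summary())
    """

    def __init__(self, tensor: CommTensor):
        if not isinstance(tensor, CommTensor):
            raise TypeError("CPTensorModel expects a CommTensor")
        self.tensor = tensor

    def fit(
        self,
        rank: int,
        seed: int = 0,
        tol: float = 1e-7,
        max_iter: int = 500,
        n_restarts: int = 3,
    ) -> "CPResults":
        return nncp_als(
            self.tensor,
            rank,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
            n_restarts=n_restarts,
        )

    def select_rank(
        self,
        ranks: Sequence[int] = range(1, 11),
        seed: int = 0,
        tol: float = 1e-7,
        max_iter: int = 500,
        n_restarts: int = 3,
    ) -> RankScan:
        return select_rank(
            self.tensor,
            ranks,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
            n_restarts=n_restarts,
        )


@dataclass
class CPResults:
    """Fitted non-negative CP decomposition.

    ``factors`` maps each tensor dimension (contexts, pairs, senders,
    receivers) to a labeled loading matrix (elements x factor_1..factor_R).
    """

    rank: int
    factors: dict
    norm_error: float
    seed: int
    n_iter_run: int
    tensor: CommTensor | None = None
    settings: dict = field(default_factory=dict)
    is_normalized: bool = False

    def __post_init__(self) -> None:
        for name in DIM_NAMES:
            if name not in self.factors:
                raise ValueError(f"missing factor matrix for dimension {name!r}")
            if (self.factors[name].to_numpy() < 0).any():
                raise ValueError(f"negative loadings in dimension {name!r}")
            if self.factors[name].shape[1] != self.rank:
                raise ValueError(
                    f"{name}: {self.factors[name].shape[1]} columns != rank {self.rank}"
                )

    # -- core quantities ----------------------------------------------------

    def reconstruct(self) -> np.ndarray:
        return reconstruct(self)

    def normalized_error(self, tensor: CommTensor | None = None) -> float:
        target = tensor if tensor is not None else self.tensor
        if target is None:
            raise ValueError("no tensor attached; pass one explicitly")
        return normalized_error(target, self)

    def normalized(self) -> "CPResults":
        """Copy with unit-Euclidean-length factor columns (for reporting)."""
        return normalize_loadings(self)

    @property
    def factor_names(self) -> list:
        return list(self.factors["contexts"].columns)

    # -- downstream conveniences (thin wrappers over commtensor.downstream) --

    def factor_network(self, factor):
        from .downstream import factor_network

        return factor_network(self, factor)

    def corrindex(self, other, mode: str = "stacked"):
        from .downstream import corrindex

        return corrindex(self, other, mode=mode)

    def ordinal_correlation(self, levels):
        from .downstream import ordinal_correlation

        return {
            f: ordinal_correlation(self.factors["contexts"][f], levels)
            for f in self.factor_names
        }

    def compare_groups(self, groups):
        from .downstream import compare_groups

        return compare_groups(self.factors["contexts"], groups)

    def cluster_samples(self, n_clusters=None, height=None):
        from .downstream import cluster_samples

        return cluster_samples(
            self.factors["contexts"], n_clusters=n_clusters, height=height
        )

    def gsea(self, lr_sets, n_perm: int = 999, weight: float = 1.0, seed: int = 0):
        from .downstream import prerank_gsea

        return prerank_gsea(
            self.factors["pairs"], lr_sets, n_perm=n_perm, weight=weight, seed=seed
        )

    # -- reporting ------------------------------------------------------------

    def summary(self, top: int = 5) -> str:
        shape = (
            "x".join(str(len(self.factors[d])) for d in DIM_NAMES)
            if self.tensor is None
            else "x".join(str(s) for s in self.tensor.shape)
        )
        lines = [
            "Non-negative CP decomposition",
            "=" * 64,
            f"tensor shape (C x P x S x T): {shape}",
            f"rank:                 {self.rank}",
            f"normalized error:     {self.norm_error:.6f}",
            f"explained fraction:   {1 - self.norm_error:.6f}",
            f"iterations (best):    {self.n_iter_run}",
            f"seed:                 {self.seed}",
            f"loadings normalized:  {self.is_normalized}",
            "",
        ]
        for f in self.factor_names:
            lines.append(f"{f}: top loadings per dimension")
            for name in DIM_NAMES:
                col = self.factors[name][f].sort_values(ascending=False)
                shown = ", ".join(
                    f"{idx}={val:.3f}" for idx, val in col.head(top).items()
                )
                lines.append(f"  {name:<10} {shown}")
            lines.append("")
        return "\n".join(lines)

    def to_dir(self, path) -> Path:
        """Write one loadings TSV per dimension plus a JSON config snapshot."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.factors.items():
            df.to_csv(out / f"loadings_{name}.tsv", sep="\t")
        snap = {
            "rank": self.rank,
            "norm_error": self.norm_error,
            "seed": self.seed,
            "n_iter_run": self.n_iter_run,
            "normalized": self.is_normalized,
            **self.settings,
        }
        (out / "decomposition.json").write_text(json.dumps(snap, indent=2))
        return out
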