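"""Downstream analyses on fitted communication-tensor decompositions.

Covers: similarity between decomposition runs (CorrIndex), factor-specific
cell-cell networks and their edge-weight Gini coefficient, correlation of
context loadings with an ordinal phenotype, pairwise group comparisons with
Bonferroni correction, hierarchical clustering of samples by their loadings,
construction of LR pathway sets from gene sets, and pre-ranked GSEA on LR
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

DIM_NAMES = ("contexts", "pairs", "senders", "receivers")

_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# decomposition similarity


def _factor_frames(obj) -> dict:
    if hasattr(obj, "factors"):
        return obj.factors
    return obj


def _corrindex_from_matrices(a: np.ndarray, b: np.ndarray, rank: int) -> float:
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    a = a / np.maximum(na, _EPS)
    b = b / np.maximum(nb, _EPS)
    c = np.abs(a.T @ b)
    return float(
        (1.0 / (2.0 * rank))
        * ((1.0 - c.max(axis=1)).sum() + (1.0 - c.max(axis=0)).sum())
    )


def corrindex(a, b, mode: str = "stacked"):
    """Permutation- and scaling-invariant distance between decompositions.

    Factor matrices of the two decompositions (which must share axis labels
    and rank) are vertically stacked, columns normalized to unit length, and
    the distance computed from the absolute cross inner-product matrix C as

        (1 / 2R) * [ sum_i (1 - max_j C_ij) + sum_j (1 - max_i C_ij) ].

    0 means identical up to factor permutation and positive column scaling;
    similarity between runs is conventionally reported as 1 - corrindex.
    With ``mode='per_dimension'`` the same statistic is additionally computed
    on each dimension's factor matrix separately, returned as a dict that
    also carries the headline ``stacked`` value.
    """
    fa, fb = _factor_frames(a), _factor_frames(b)
    ranks = {fa[d].shape[1] for d in DIM_NAMES} | {fb[d].shape[1] for d in DIM_NAMES}
    if len(ranks) != 1:
        raise ValueError("decompositions must have equal rank")
    rank = ranks.pop()
    for d in DIM_NAMES:
        if list(fa[d].index) != list(fb[d].index):
            raise ValueError(f"axis labels differ in dimension {d!r}")
    if mode not in ("stacked", "per_dimension"):
        raise ValueError(f"unknown mode {mode!r}")
    stacked = _corrindex_from_matrices(
        np.vstack([fa[d].to_numpy() for d in DIM_NAMES]),
        np.vstack([fb[d].to_numpy() for d in DIM_NAMES]),
        rank,
    )
    if mode == "stacked":
        return stacked
    out = {
        d: _corrindex_from_matrices(fa[d].to_numpy(), fb[d].to_numpy(), rank)
        for d in DIM_NAMES
    }
    out["stacked"] = stacked
    return out


# ---------------------------------------------------------------------------
# factor-specific networks


def gini(weights) -> float:
    """Gini coefficient of a non-negative weight vector.

    Mean-absolute-difference form, G = sum_ij |w_i - w_j| / (2 n^2 mean(w)):
    0 for perfectly equal weights, (n-1)/n -> 1 when a single weight carries
    all mass.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("empty weight vector")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("Gini undefined for all-zero weights")
    ws = np.sort(w)
    n = w.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * ws).sum() / (n * total) - (n + 1.0) / n)


@dataclass
class FactorNetwork:
    """Rank-1 sender x receiver communication network of one factor."""

    factor_id: str
    adjacency: pd.DataFrame
    gini: float

    def to_edge_list(self) -> pd.DataFrame:
        long = self.adjacency.stack().rename("weight").reset_index()
        long.columns = ["sender", "receiver", "weight"]
        return long


def factor_network(results, factor) -> FactorNetwork:
    """Outer product of a factor's sender and receiver loadings.

    The resulting matrix is the adjacency of the factor-specific cell-cell
    communication network; its edge-weight Gini coefficient measures how
    unevenly communication is distributed over cell pairs.
    """
    factors = _factor_frames(results)
    if isinstance(factor, int):
        factor = f"factor_{factor}"
    if factor not in factors["senders"].columns:
        raise KeyError(f"unknown factor {factor!r}")
    s = factors["senders"][factor]
    t = factors["receivers"][factor]
    adj = pd.DataFrame(
        np.outer(s.to_numpy(), t.to_numpy()), index=s.index, columns=t.index
    )
    return FactorNetwork(
        factor_id=factor, adjacency=adj, gini=gini(adj.to_numpy())
    )


# ---------------------------------------------------------------------------
# context-dimension statistics


class OrdinalCorrelation(NamedTuple):
    rho: float
    pvalue: float
    defined: bool


def ordinal_correlation(context_loadings, levels) -> OrdinalCorrelation:
    """Spearman correlation between context loadings and an ordinal phenotype.

    Ties get average ranks.  Constant loadings (or levels) make the rank
    correlation undefined; the result is then flagged instead of numeric.
    """
    x = np.asarray(context_loadings, dtype=float)
    y = np.asarray(pd.factorize(np.asarray(levels), sort=True)[0], dtype=float)
    if x.size != y.size:
        raise ValueError("loadings and levels differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 contexts")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 distinct ordinal levels")
    if np.allclose(x, x[0]):
        return OrdinalCorrelation(rho=float("nan"), pvalue=float("nan"), defined=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return OrdinalCorrelation(rho=float(rho), pvalue=float(p), defined=True)


def compare_groups(context_loadings: pd.DataFrame, groups) -> pd.DataFrame:
    """Two-sided independent t-tests of context loadings between groups.

    Every pair of groups is compared within every factor; p-values are
    Bonferroni-corrected over all performed comparisons jointly (capped
    at 1).
    """
    groups = pd.Series(groups)
    if list(groups.index) != list(context_loadings.index):
        groups = pd.Series(np.asarray(groups), index=context_loadings.index)
    counts = groups.value_counts()
    small = counts[counts < 2]
    if len(small) > 0:
        raise ValueError(f"group(s) with fewer than 2 samples: {list(small.index)}")
    names = sorted(counts.index)
    rows = []
    for factor in context_loadings.columns:
        for i, ga in enumerate(names):
            for gb in names[i + 1 :]:
                xa = context_loadings.loc[groups == ga, factor]
                xb = context_loadings.loc[groups == gb, factor]
                t, p = stats.ttest_ind(xa, xb)
                if np.isnan(t):  # zero variance in both groups, equal means
                    t, p = 0.0, 1.0
                rows.append(
                    {
                        "factor": factor,
                        "group_a": ga,
                        "group_b": gb,
                        "t": float(t),
                        "pvalue": float(p),
                    }
                )
    out = pd.DataFrame(rows)
    out["pvalue_bonferroni"] = np.minimum(out["pvalue"] * len(out), 1.0)
    return out


def cluster_samples(
    sample_loadings: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
):
    """Ward/Euclidean hierarchical clustering of samples by their loadings.

    Loadings are standardized (z-scored) per factor across samples first;
    zero-variance factor columns are dropped with a warning.  Returns
    ``(labels, linkage)`` where cluster labels are renumbered in order of
    first occurrence for determinism.
    """
    if len(sample_loadings) < 3:
        raise ValueError("need at least 3 samples to cluster")
    if (n_clusters is None) == (height is None):
        raise ValueError("specify exactly one of n_clusters or height")
    x = sample_loadings.astype(float)
    sd = x.std(axis=0, ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(
            f"dropping zero-variance factor column(s) {dead} before z-scoring",
            UserWarning,
            stacklevel=2,
        )
        x = x.drop(columns=dead)
        sd = sd.drop(index=dead)
    if x.shape[1] == 0:
        raise ValueError("no factor column with variance remains")
    z = (x - x.mean(axis=0)) / sd
    linkage = hierarchy.linkage(z.to_numpy(), method="ward", metric="euclidean")
    if n_clusters is not None:
        raw = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(linkage, t=height, criterion="distance")
    remap, labels = {}, []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return pd.Series(labels, index=sample_loadings.index, name="cluster"), linkage


# ---------------------------------------------------------------------------
# LR pathway sets and pre-ranked GSEA


@dataclass
class LRSetCollection:
    """Pathway label -> set of LR pair ids, filtered to a minimum size."""

    sets: dict
    min_size: int = 15

    def __post_init__(self) -> None:
        self.sets = {
            name: set(members)
            for name, members in self.sets.items()
            if len(set(members)) >= self.min_size
        }

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def build_lr_sets(
    gene_sets: Mapping[str, Sequence], catalog, min_size: int = 15
) -> LRSetCollection:
    """Annotate LR pairs with pathway gene sets.

    A pair belongs to a pathway set iff *every* ligand and receptor subunit
    gene is in the pathway's gene set; sets retaining fewer than ``min_size``
    pairs are dropped.
    """
    if len(gene_sets) == 0 or len(catalog) == 0:
        raise ValueError("gene sets and catalog must be non-empty")
    out = {}
    for name, genes in gene_sets.items():
        genes = set(genes)
        members = {p.pair_id for p in catalog if set(p.genes) <= genes}
        out[name] = members
    return LRSetCollection(sets=out, min_size=min_size)


def _enrichment_scores(
    weights: np.ndarray, hits: np.ndarray, weight_exp: float
) -> np.ndarray:
    """Signed KS-style enrichment score for one or many hit masks.

    ``weights`` is the ranked loading vector (descending); ``hits`` a boolean
    array (..., N).  Hit steps are |loading|^weight_exp normalized over hits;
    miss steps are uniform.  The ES is the running-sum extreme of maximal
    magnitude.
    """
    w = np.abs(weights) ** weight_exp
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum(axis=-1, keepdims=True)
    denom = np.where(denom > 0, denom, 1.0)
    n_hit = hits.sum(axis=-1, keepdims=True)
    n_miss = hits.shape[-1] - n_hit
    miss_step = np.where(n_miss > 0, 1.0 / np.maximum(n_miss, 1), 0.0)
    steps = hit_w / denom - np.where(~hits, miss_step, 0.0)
    running = np.cumsum(steps, axis=-1)
    idx = np.argmax(np.abs(running), axis=-1)
    return np.take_along_axis(running, np.expand_dims(idx, -1), axis=-1).squeeze(-1)


def prerank_gsea(
    rankings,
    lr_sets: LRSetCollection,
    n_perm: int = 999,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA of LR pairs against LR pathway sets.

    For each factor, pairs are ranked by loading (descending; ties broken by
    pair id for determinism) and a weighted Kolmogorov-Smirnov running-sum
    enrichment score is computed per set.  The null distribution comes from
    ``n_perm`` seeded permutations of the pair labels; NES divides the ES by
    the mean |null ES| of matching sign and the empirical p-value is taken
    from the matching-sign null.  p-values are Benjamini-Hochberg adjusted
    across all (factor, set) results jointly.
    """
    if isinstance(rankings, pd.Series):
        rankings = rankings.to_frame(name="factor_1")
    if rankings.empty:
        raise ValueError("empty ranking")
    universe = set(rankings.index)
    for name, members in lr_sets.items():
        extra = members - universe
        if extra:
            raise ValueError(
                f"set {name!r} contains pairs outside the ranked universe: "
                f"{sorted(extra)[:5]}"
            )
    if len(lr_sets) == 0:
        raise ValueError("no LR set passes the minimum-size filter")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    rows = []
    for factor in rankings.columns:
        series = rankings[factor].astype(float)
        order = (
            pd.DataFrame({"loading": series, "pair": series.index.astype(str)})
            .sort_values(["loading", "pair"], ascending=[False, True], kind="stable")
            .index
        )
        ranked = series.loc[order]
        w = ranked.to_numpy()
        pos = {p: i for i, p in enumerate(ranked.index)}
        n = len(ranked)
        for name, members in sorted(lr_sets.items()):
            hit = np.zeros(n, dtype=bool)
            hit[[pos[p] for p in members]] = True
            es = float(_enrichment_scores(w, hit, weight))
            # permute pair labels: equivalent to random hit sets of equal size
            m = hit.sum()
            perm_hits = np.zeros((n_perm, n), dtype=bool)
            sel = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
            np.put_along_axis(perm_hits, sel, True, axis=1)
            null = _enrichment_scores(w, perm_hits, weight)
            same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
            if same_sign.size == 0:
                nes, p = float("nan"), 1.0
            else:
                nes = es / float(np.abs(same_sign).mean())
                p = (1.0 + float((np.abs(same_sign) >= abs(es)).sum())) / (
                    1.0 + same_sign.size
                )
            rows.append(
                {
                    "factor": factor,
                    "set": name,
                    "size": int(m),
                    "es": es,
                    "nes": nes,
                    "pvalue": p,
                }
            )
    out = pd.DataFrame(rows)
    out["pvalue_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
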