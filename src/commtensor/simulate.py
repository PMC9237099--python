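"""Synthetic context-driven communication tensors with known ground truth.

The simulated system mirrors a small time-course experiment: a handful of
cell types exchange signals through a catalog of LR pairs grouped into
disjoint "pathways" (equal blocks of pairs).  A small number of
pathway-by-cell-pair combinations is selected; each is driven across
contexts by one of four canonical temporal patterns — an oscillation, a
pulse, an exponential decay and a linear decrease — while everything else
sits at a constant background score.  Optionally, zero-clipped Gaussian
noise is added.  Because the generator emits communication scores directly
(not counts), decomposition quality can be read off against the exact
embedded curves and pair sets via :func:`evaluate_recovery`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tensor_build import CommTensor

PATTERN_NAMES = ("oscillation", "pulse", "exponential_decay", "linear_decrease")


def pattern_curves(
    n_contexts: int, low: float = 0.05, high: float = 1.0
) -> dict:
    """The four canonical per-context score curves, scaled to [low, high].

    * oscillation: one and a half sine cycles over the context axis;
    * pulse: elevated plateau over the middle third of contexts;
    * exponential_decay: a * exp(-lambda t), strictly decreasing;
    * linear_decrease: affine from ``high`` down to ``low``.
    """
    if n_contexts < 4:
        raise ValueError("need at least 4 contexts to embed 4 patterns")
    if not 0 <= low < high:
        raise ValueError("require 0 <= low < high")
    t = np.arange(n_contexts, dtype=float)

    def rescale(v: np.ndarray) -> np.ndarray:
        v = (v - v.min()) / (v.max() - v.min())
        return low + (high - low) * v

    osc = rescale(np.sin(3.0 * np.pi * t / (n_contexts - 1)))
    pulse = np.full(n_contexts, 0.0)
    third = n_contexts // 3
    pulse[third : n_contexts - third] = 1.0
    pulse = rescale(pulse)
    decay = rescale(np.exp(-0.4 * t))
    linear = rescale(high - (high - low) * t / (n_contexts - 1))
    curves = {
        "oscillation": osc,
        "pulse": pulse,
        "exponential_decay": decay,
        "linear_decrease": linear,
    }
    for name, v in curves.items():
        assert (v >= 0).all(), name
    return curves


@dataclass
class Combo:
    """One embedded (pattern, pathway, sender, receiver) assignment."""

    pattern_id: str
    pathway_id: int
    sender: int
    receiver: int


@dataclass
class SimTruth:
    """Ground truth of a simulated tensor.

    ``pathways`` partitions the pair axis into ``n_pathways`` equal blocks;
    combos sharing a pathway share its LR pairs but use different
    sender/receiver cell pairs.
    """

    n_contexts: int = 12
    n_celltypes: int = 3
    n_pairs: int = 300
    n_pathways: int = 3
    base_score: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0
    combos: list = field(default_factory=list)
    curves: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pairs % self.n_pathways != 0:
            raise ValueError("n_pairs must split evenly into pathways")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.curves:
            self.curves = {
                k: v.copy()
                for k, v in pattern_curves(
                    self.n_contexts, low=self.base_score
                ).items()
            }
        for name, v in self.curves.items():
            if len(v) != self.n_contexts:
                raise ValueError(f"curve {name!r} length != n_contexts")
            if (np.asarray(v) < 0).any():
                raise ValueError(f"curve {name!r} has negative values")
        if not self.combos:
            self.combos = self._draw_combos()
        used = [(c.pathway_id, c.sender, c.receiver) for c in self.combos]
        if len(set(used)) != len(used):
            raise ValueError("combos must be unique in (pathway, sender, receiver)")
        by_pathway: dict = {}
        for c in self.combos:
            by_pathway.setdefault(c.pathway_id, []).append((c.sender, c.receiver))
        for pid, cells in by_pathway.items():
            for i, a in enumerate(cells):
                for b in cells[i + 1 :]:
                    if set(a) & set(b):
                        raise ValueError(
                            f"combos sharing pathway {pid} overlap in cell "
                            f"types {set(a) & set(b)}; same-pathway combos "
                            "must not share interacting cell types"
                        )
        for c in self.combos:
            if not (0 <= c.pathway_id < self.n_pathways):
                raise ValueError(f"pathway {c.pathway_id} out of range")
            if not (0 <= c.sender < self.n_celltypes):
                raise ValueError(f"sender {c.sender} out of range")
            if not (0 <= c.receiver < self.n_celltypes):
                raise ValueError(f"receiver {c.receiver} out of range")

    def _draw_combos(self) -> list:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        patterns = list(self.curves)
        all_cells = [
            (k, l)
            for k in range(self.n_celltypes)
            for l in range(self.n_celltypes)
        ]
        if len(all_cells) < len(patterns):
            raise ValueError("not enough cell pairs for the embedded patterns")
        # rejection-sample until combos sharing a pathway involve disjoint
        # cell types (they may overlap in LR pairs only)
        for _ in range(1000):
            chosen = rng.choice(len(all_cells), size=len(patterns), replace=False)
            pathways = list(rng.permutation(self.n_pathways))
            while len(pathways) < len(patterns):
                pathways.append(int(rng.integers(self.n_pathways)))
            ok = True
            for i in range(len(patterns)):
                for j in range(i + 1, len(patterns)):
                    if pathways[i] == pathways[j] and (
                        set(all_cells[chosen[i]]) & set(all_cells[chosen[j]])
                    ):
                        ok = False
            if ok:
                break
        if not ok:
            raise ValueError(
                "could not place combos with disjoint cell types per pathway; "
                "increase n_celltypes or n_pathways"
            )
        return [
            Combo(
                pattern_id=pat,
                pathway_id=int(pathways[i]),
                sender=int(all_cells[chosen[i]][0]),
                receiver=int(all_cells[chosen[i]][1]),
            )
            for i, pat in enumerate(patterns)
        ]

    @property
    def block_size(self) -> int:
        return self.n_pairs // self.n_pathways

    def pathway_pairs(self, pathway_id: int) -> list:
        """Pair labels belonging to a pathway block."""
        lo = pathway_id * self.block_size
        return [_pair_label(j, self.n_pairs) for j in range(lo, lo + self.block_size)]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["curves"] = {k: list(map(float, v)) for k, v in self.curves.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["curves"] = {k: np.asarray(v, dtype=float) for k, v in d["curves"].items()}
        d["combos"] = [Combo(**c) for c in d["combos"]]
        return cls(**d)


def _pair_label(j: int, n_pairs: int) -> str:
    width = len(str(n_pairs - 1))
    return f"L{j:0{width}d}^R{j:0{width}d}"


def build_simulated_tensor(truth: SimTruth) -> tuple:
    """Materialise the tensor described by ``truth``.

    Entries belonging to a combo trace that combo's pattern curve across
    contexts; everything else is the constant background score.  When
    ``truth.noise_sd > 0``, Gaussian noise with standard deviation
    ``noise_sd * peak`` (peak = maximum curve value) is added and the result
    clipped at zero.
    """
    shape = (truth.n_contexts, truth.n_pairs, truth.n_celltypes, truth.n_celltypes)
    data = np.full(shape, truth.base_score, dtype=float)
    block = truth.block_size
    for combo in truth.combos:
        curve = np.asarray(truth.curves[combo.pattern_id], dtype=float)
        lo = combo.pathway_id * block
        data[:, lo : lo + block, combo.sender, combo.receiver] = curve[
            :, None
        ]
    if truth.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2]))
        peak = max(float(np.max(v)) for v in truth.curves.values())
        data = data + rng.normal(0.0, truth.noise_sd * peak, size=shape)
        np.clip(data, 0.0, None, out=data)

    tensor = CommTensor(
        data=data,
        contexts=[f"t{i:02d}" for i in range(truth.n_contexts)],
        pairs=[_pair_label(j, truth.n_pairs) for j in range(truth.n_pairs)],
        senders=[f"cell_{chr(65 + k)}" for k in range(truth.n_celltypes)],
        receivers=[f"cell_{chr(65 + k)}" for k in range(truth.n_celltypes)],
        score_method="mean",
    )
    return tensor, truth


def evaluate_recovery(results, truth: SimTruth) -> pd.DataFrame:
    """Score a decomposition against the simulation's ground truth.

    Factors are matched one-to-one to embedded patterns greedily by maximal
    Pearson correlation between context loadings and pattern curves.  For
    each matched pattern the table reports that correlation and the Jaccard
    index between the combo's LR-pair block and the matched factor's top-n
    loaded pairs (n = block size).
    """
    patterns = [c.pattern_id for c in truth.combos]
    ctx = results.factors["contexts"]
    if results.rank < len(patterns):
        raise ValueError(
            f"rank {results.rank} < number of embedded patterns {len(patterns)}"
        )
    corr = pd.DataFrame(
        {
            pat: [
                stats.pearsonr(np.asarray(truth.curves[pat]), ctx[f])[0]
                for f in ctx.columns
            ]
            for pat in patterns
        },
        index=ctx.columns,
    )
    matches = {}
    remaining = corr.copy()
    while not remaining.empty:
        fac, pat = np.unravel_index(
            np.nanargmax(remaining.to_numpy()), remaining.shape
        )
        matches[remaining.columns[pat]] = remaining.index[fac]
        remaining = remaining.drop(
            index=remaining.index[fac], columns=remaining.columns[pat]
        )

    rows = []
    pair_loadings = results.factors["pairs"]
    for combo in truth.combos:
        factor = matches[combo.pattern_id]
        true_pairs = set(truth.pathway_pairs(combo.pathway_id))
        top = set(
            pair_loadings[factor]
            .sort_values(ascending=False)
            .head(len(true_pairs))
            .index
        )
        jac = len(true_pairs & top) / len(true_pairs | top)
        rows.append(
            {
                "pattern": combo.pattern_id,
                "factor": factor,
                "pearson_context": float(corr.loc[factor, combo.pattern_id]),
                "jaccard_pairs": float(jac),
            }
        )
    return pd.DataFrame(rows).set_index("pattern")
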