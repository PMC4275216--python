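"""Diversity indices, pairwise similarity, and accumulation curves.

Indices operate on relative-abundance vectors (a row of the community
matrix).  Shannon diversity is reported in nats (natural log); evenness
defaults to Pielou's J = H / ln S with Heip and Sheldon variants
selectable, because the literature names "Shannon's evenness" for more
than one formula; Berger-Parker is the dominance form d = max p_i.

Bray-Curtis and Jaccard are similarity indices in [0, 1]; dissimilarity
is 1 - similarity.  Bray-Curtis dissimilarity is a semimetric (it can
violate the triangle inequality), which is why rank-based NMDS rather
than a metric embedding is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiversityReport",
    "SimilarityMatrix",
    "shannon",
    "evenness",
    "berger_parker",
    "bray_curtis",
    "jaccard",
    "pairwise_matrix",
    "diversity_report",
    "diversity_table",
    "accumulation_curve",
]

_SUM_TOL = 1e-6


def _as_abundance(p, name: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    return p


def _check_normalized(p: np.ndarray) -> None:
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"abundances must sum to 1 (got {p.sum():.6g})")


def shannon(p, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i ln p_i over positive entries (nats).

    ``base`` converts to another logarithm base (e.g. 2 for bits).
    """
    p = _as_abundance(p)
    _check_normalized(p)
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum())
    if base is not None:
        h /= float(np.log(base))
    return h


def evenness(p, method: str = "pielou") -> float:
    """Evenness of an abundance vector, in [0, 1].

    pielou: H / ln S; heip: (e^H - 1)/(S - 1); sheldon: e^H / S.
    A single-species community (S = 1) is defined as perfectly even.
    """
    p = _as_abundance(p)
    _check_normalized(p)
    s = int(np.count_nonzero(p > 0))
    if s == 0:
        raise ValueError("empty community")
    if s == 1:
        return 1.0
    h = shannon(p)
    if method == "pielou":
        return h / float(np.log(s))
    if method == "heip":
        return float((np.exp(h) - 1.0) / (s - 1))
    if method == "sheldon":
        return float(np.exp(h) / s)
    raise ValueError(f"unknown evenness method {method!r}")


def berger_parker(p) -> float:
    """Berger-Parker dominance: the largest single relative abundance."""
    p = _as_abundance(p)
    _check_normalized(p)
    return float(p.max())


def bray_curtis(x, y) -> float:
    """Bray-Curtis similarity 1 - sum|x-y| / sum(x+y), in [0, 1]."""
    x = _as_abundance(x, "x")
    y = _as_abundance(y, "y")
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned on the same bins")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return 1.0 - float(np.abs(x - y).sum()) / denom


def jaccard(x, y, presence_threshold: float = 0.0) -> float:
    """Jaccard similarity |A∩B| / |A∪B| on supports {i : value > threshold}."""
    x = _as_abundance(x, "x")
    y = _as_abundance(y, "y")
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned on the same bins")
    a = x > presence_threshold
    b = y > presence_threshold
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("Jaccard undefined when both supports are empty")
    return float(np.count_nonzero(a & b)) / union


_METRICS = {"bray_curtis": bray_curtis, "jaccard": jaccard}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric samples-by-samples matrix of a named (dis)similarity."""

    values: pd.DataFrame
    metric: str
    mode: str  # "similarity" | "dissimilarity"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v.values, v.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be square and symmetric")
        if self.mode not in ("similarity", "dissimilarity"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def flipped(self) -> "SimilarityMatrix":
        """The 1 - values counterpart (similarity <-> dissimilarity)."""
        other = "dissimilarity" if self.mode == "similarity" else "similarity"
        return SimilarityMatrix(1.0 - self.values, self.metric, other)

    def as_dissimilarity(self) -> "SimilarityMatrix":
        return self if self.mode == "dissimilarity" else self.flipped()


def pairwise_matrix(
    matrix: pd.DataFrame, metric: str = "bray_curtis", mode: str = "similarity"
) -> SimilarityMatrix:
    """Apply a similarity index to every pair of community-matrix rows."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; known: {sorted(_METRICS)}")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two samples")
    fn = _METRICS[metric]
    ids = list(matrix.index)
    n = len(ids)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(matrix.iloc[i].values, matrix.iloc[j].values)
    values = pd.DataFrame(out, index=ids, columns=ids)
    sim = SimilarityMatrix(values, metric, "similarity")
    return sim if mode == "similarity" else sim.flipped()


@dataclass(frozen=True)
class DiversityReport:
    sample_id: str
    shannon_H: float
    evenness: float
    berger_parker: float
    richness_S: int


def diversity_report(
    sample_id: str, p, evenness_method: str = "pielou"
) -> DiversityReport:
    """All four indices for one abundance vector."""
    p = _as_abundance(p)
    return DiversityReport(
        sample_id=sample_id,
        shannon_H=shannon(p),
        evenness=evenness(p, evenness_method),
        berger_parker=berger_parker(p),
        richness_S=int(np.count_nonzero(p > 0)),
    )


def diversity_table(
    matrix: pd.DataFrame, evenness_method: str = "pielou"
) -> pd.DataFrame:
    """Diversity indices for every row of a community matrix."""
    rows = [
        diversity_report(str(sid), matrix.loc[sid].values, evenness_method)
        for sid in matrix.index
    ]
    return pd.DataFrame(
        [r.__dict__ for r in rows]
    ).set_index("sample_id")


def accumulation_curve(
    patterns: Sequence[tuple], n_permutations: int = 100, seed: int = 0
) -> np.ndarray:
    """Mean cumulative count of distinct dual-enzyme patterns vs. clones drawn.

    Random permutations of the clone library, averaged; the curve reaching
    a plateau indicates the library size was sufficient to exhaust the
    pattern richness.
    """
    if len(patterns) == 0:
        raise ValueError("empty pattern sequence")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(patterns)
    total = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        seen: set = set()
        for k, idx in enumerate(order):
            seen.add(patterns[idx])
            total[k] += len(seen)
    return total / n_permutations
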