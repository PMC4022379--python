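"""Benchmarking inferred networks and dynamics against a gold standard.

Directed-edge confusion counts follow the convention used for displayed
network comparisons: an inferred edge present in the gold network is a true
positive; any other inferred edge -- including one pointing the wrong way
along a true interaction -- is a false positive, and the unrecovered true
counterpart remains a false negative.  PPV (precision), recall (TPR) and
FPR are reported both raw and rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .polynomial import PolynomialModel, State

__all__ = [
    "GoldNetwork",
    "ConfusionCounts",
    "NetworkMetrics",
    "compare_networks",
    "steady_state_retrieval",
    "roc_point",
    "read_sif",
    "write_sif",
    "round2",
]

Edge = tuple[int, int]  # (source j, target i), 0-based


def round2(x: float) -> float:
    """Two-decimal rounding, half up (0.875 -> 0.88, 0.625 -> 0.63)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GoldNetwork:
    """A reference directed network: edges are ``(source, target)`` pairs
    of 0-based node indices (``j -> i``: node j regulates node i)."""

    n: int
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for j, i in self.edges:
            if not (0 <= j < self.n and 0 <= i < self.n):
                raise ValueError(f"edge ({j}, {i}) out of range for n={self.n}")

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[Edge]) -> "GoldNetwork":
        return cls(n, frozenset((int(j), int(i)) for j, i in edges))

    @classmethod
    def from_adjacency(cls, V: np.ndarray) -> "GoldNetwork":
        V = np.asarray(V)
        n = V.shape[0]
        return cls(n, frozenset((int(j), int(i)) for i in range(n) for j in range(n) if V[i, j]))

    def adjacency(self) -> np.ndarray:
        V = np.zeros((self.n, self.n), dtype=np.int8)
        for j, i in self.edges:
            V[i, j] = 1
        return V


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class NetworkMetrics:
    counts: ConfusionCounts
    ppv: float
    recall: float
    fpr: float
    ppv_rounded: float
    recall_rounded: float
    fpr_rounded: float
    undefined_ppv: bool

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
            "ppv": self.ppv,
            "recall": self.recall,
            "fpr": self.fpr,
            "ppv_rounded": self.ppv_rounded,
            "recall_rounded": self.recall_rounded,
            "fpr_rounded": self.fpr_rounded,
            "undefined_ppv": self.undefined_ppv,
        }


def _edge_set(net, n: int | None = None) -> tuple[int, frozenset[Edge]]:
    if isinstance(net, GoldNetwork):
        return net.n, net.edges
    V = np.asarray(net)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("adjacency matrix must be square")
    g = GoldNetwork.from_adjacency(V)
    return g.n, g.edges


def compare_networks(
    inferred, gold, include_self_loops: bool = False
) -> NetworkMetrics:
    """Confusion counts and PPV / recall / FPR of an inferred network.

    ``inferred`` is an adjacency matrix (``V[i, j] = 1`` iff ``j -> i``) or
    a :class:`GoldNetwork`; ``gold`` likewise.  The true-negative universe
    is all ordered node pairs (self-loops excluded unless requested) minus
    the gold edges.  PPV is defined as 0 (and flagged) when nothing was
    inferred.
    """
    n_inf, inf_edges = _edge_set(inferred)
    n_gold, gold_edges = _edge_set(gold)
    if n_inf != n_gold:
        raise ValueError(f"networks disagree on n: {n_inf} vs {n_gold}")
    n = n_gold
    if not include_self_loops:
        inf_edges = frozenset(e for e in inf_edges if e[0] != e[1])
        gold_edges = frozenset(e for e in gold_edges if e[0] != e[1])
        universe = n * (n - 1)
    else:
        universe = n * n
    tp = len(inf_edges & gold_edges)
    fp = len(inf_edges - gold_edges)
    fn = len(gold_edges - inf_edges)
    tn = universe - len(gold_edges) - fp
    counts = ConfusionCounts(tp, fp, fn, tn)
    undefined = (tp + fp) == 0
    ppv = 0.0 if undefined else tp / (tp + fp)
    recall = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    fpr = 0.0 if (fp + tn) == 0 else fp / (fp + tn)
    return NetworkMetrics(
        counts=counts,
        ppv=ppv,
        recall=recall,
        fpr=fpr,
        ppv_rounded=round2(ppv),
        recall_rounded=round2(recall),
        fpr_rounded=round2(fpr),
        undefined_ppv=undefined,
    )


def steady_state_retrieval(
    f: PolynomialModel, reference: Sequence[State]
) -> tuple[list[State], float]:
    """Which of the reference states are fixed points of ``f``.

    Returns the retrieved subset (in reference order) and the retrieval
    fraction; an empty reference counts as fully retrieved.
    """
    retrieved = [s for s in reference if f.step(s) == tuple(s)]
    frac = len(retrieved) / len(reference) if reference else 1.0
    return retrieved, frac


def roc_point(counts: ConfusionCounts) -> tuple[float, float, bool]:
    """The (FPR, TPR) point and whether it lies strictly above the ROC
    line of no discrimination (TPR > FPR)."""
    tpr = 1.0 if (counts.tp + counts.fn) == 0 else counts.tp / (counts.tp + counts.fn)
    fpr = 0.0 if (counts.fp + counts.tn) == 0 else counts.fp / (counts.fp + counts.tn)
    return fpr, tpr, tpr > fpr


# ---------------------------------------------------------------------------
# SIF I/O
# ---------------------------------------------------------------------------


def write_sif(net, path, variables: Sequence[str] | None = None) -> None:
    """Write edges as ``<source>\\tregulates\\t<target>`` lines."""
    n, edges = _edge_set(net)
    names = list(variables) if variables else [f"x{i + 1}" for i in range(n)]
    with open(str(path), "w") as fh:
        for j, i in sorted(edges):
            fh.write(f"{names[j]}\tregulates\t{names[i]}\n")


def read_sif(path, variables: Sequence[str] | None = None, n: int | None = None) -> GoldNetwork:
    """Read a SIF file.  Without an explicit variable list, ``x<k>`` names
    are mapped to indices and ``n`` defaults to the largest seen."""
    edges: list[tuple[str, str]] = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line {line!r}")
            edges.append((parts[0], parts[2]))
    if variables is not None:
        index = {v: k for k, v in enumerate(variables)}
        n = n or len(variables)
    else:
        import re

        names = sorted({v for e in edges for v in e})
        if all(re.fullmatch(r"x\d+", v) for v in names):
            index = {v: int(v[1:]) - 1 for v in names}
            n = n or (max(index.values()) + 1 if index else 0)
        else:
            index = {v: k for k, v in enumerate(names)}
            n = n or len(names)
    return GoldNetwork.from_edges(n, ((index[a], index[b]) for a, b in edges))
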