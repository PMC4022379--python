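"""Time-series containers, discretization, inconsistency breaking and I/O.

Input data are one or more binary time series over the ``n`` network
variables, each labelled wildtype or knock-out (with the silenced node's
index).  Because a deterministic Boolean model cannot send one state to two
different successors, inconsistent data (a consequence of noise or of
discretization) are *broken* at the offending states: every transition out
of an inconsistent state is removed and the affected series split into
maximal consistent fragments.

Wildtype series are pooled for the consistency check (a single model must
explain all of them); each knock-out target is pooled separately, since its
trajectories are generated by a different map (the knock-out model).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "TimeSeriesSet",
    "ContinuousTimeSeries",
    "find_inconsistencies",
    "break_inconsistencies",
    "inject_noise",
    "discretize_quantile",
    "discretize_interval",
    "read_timeseries",
    "write_timeseries",
    "read_continuous_timeseries",
]

WILDTYPE = "wildtype"
KNOCKOUT = "knockout"


@dataclass
class TimeSeries:
    """One binary time course: an ``alpha x n`` 0/1 matrix.

    ``ko_target`` is the 0-based index of the silenced node and must be
    present exactly when ``kind == "knockout"``.
    """

    points: np.ndarray
    kind: str = WILDTYPE
    ko_target: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int8)
        if self.points.ndim != 2 or self.points.shape[0] < 1:
            raise ValueError("points must be a non-empty 2-D matrix")
        if not np.isin(self.points, (0, 1)).all():
            raise ValueError("time series entries must be 0/1")
        if self.kind not in (WILDTYPE, KNOCKOUT):
            raise ValueError(f"kind must be {WILDTYPE!r} or {KNOCKOUT!r}")
        if (self.ko_target is not None) != (self.kind == KNOCKOUT):
            raise ValueError("ko_target must be given iff kind is knockout")
        if self.ko_target is not None and not 0 <= self.ko_target < self.n:
            raise ValueError("ko_target out of range")

    @property
    def n(self) -> int:
        return self.points.shape[1]

    @property
    def alpha(self) -> int:
        """Number of time points in the series."""
        return self.points.shape[0]

    @property
    def group(self) -> tuple[str, int | None]:
        """Pooling key for the consistency check."""
        return (self.kind, self.ko_target)

    def packed_rows(self) -> list[int]:
        weights = 1 << np.arange(self.n, dtype=np.int64)
        return [int(v) for v in self.points.astype(np.int64) @ weights]


@dataclass
class TimeSeriesSet:
    """An ordered collection of time series sharing ``n`` variables.

    ``xi`` is the assumed noise fraction: the proportion of entries believed
    to be flipped, which downstream scoring uses as the tolerated level of
    disagreement between a model and the data.
    """

    series: list[TimeSeries]
    xi: float = 0.0
    variables: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("a TimeSeriesSet needs at least one series")
        n = self.series[0].n
        if any(ts.n != n for ts in self.series):
            raise ValueError("all series must share the same number of variables")
        if not 0 <= self.xi < 1:
            raise ValueError("xi must lie in [0, 1)")
        if self.variables is None:
            self.variables = [f"x{i + 1}" for i in range(n)]
        elif len(self.variables) != n:
            raise ValueError("one variable name per column required")

    @property
    def n(self) -> int:
        return self.series[0].n

    @property
    def mu0(self) -> int:
        """Total number of series."""
        return len(self.series)

    @property
    def ell(self) -> int:
        """Number of wildtype series."""
        return sum(ts.kind == WILDTYPE for ts in self.series)

    @property
    def total_points(self) -> int:
        return sum(ts.alpha for ts in self.series)

    @property
    def total_length(self) -> int:
        """``m = sum(alpha_mu - 1)``: the number of prescribed transitions."""
        return sum(ts.alpha - 1 for ts in self.series)

    def copy(self) -> "TimeSeriesSet":
        return TimeSeriesSet(
            [replace(ts, points=ts.points.copy()) for ts in self.series],
            xi=self.xi,
            variables=list(self.variables),
        )


@dataclass
class ContinuousTimeSeries:
    """A real-valued time course awaiting discretization."""

    points: np.ndarray
    kind: str = WILDTYPE
    ko_target: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 1:
            raise ValueError("points must be a non-empty 2-D matrix")
        if not np.isfinite(self.points).all():
            raise ValueError("continuous entries must be finite")

    @property
    def n(self) -> int:
        return self.points.shape[1]


# ---------------------------------------------------------------------------
# Consistency
# ---------------------------------------------------------------------------


def find_inconsistencies(
    tss: TimeSeriesSet,
) -> list[tuple[tuple[str, int | None], tuple[int, ...], set[tuple[int, ...]]]]:
    """States with two or more distinct observed successors.

    Returns ``(group, state, successors)`` triples, where ``group`` is the
    pooling key (wildtype together; each knock-out target separately).
    """
    successors: dict[tuple, dict[tuple[int, ...], set[tuple[int, ...]]]] = {}
    for ts in tss.series:
        table = successors.setdefault(ts.group, {})
        rows = [tuple(int(b) for b in r) for r in ts.points]
        for a, b in zip(rows, rows[1:]):
            table.setdefault(a, set()).add(b)
    out = []
    for group in sorted(successors, key=str):
        for state, succ in successors[group].items():
            if len(succ) > 1:
                out.append((group, state, succ))
    return out


def break_inconsistencies(tss: TimeSeriesSet) -> TimeSeriesSet:
    """Remove *all* transitions out of inconsistent states and split the
    affected series into maximal consistent fragments.

    No transition is preferred over another; fragments of length 1 are
    retained (they contribute 0 transitions to the total length m).
    Idempotent: re-applying to an already consistent set changes nothing.
    """
    bad: dict[tuple, set[tuple[int, ...]]] = {}
    for group, state, _ in find_inconsistencies(tss):
        bad.setdefault(group, set()).add(state)
    if not bad:
        return tss
    fragments: list[TimeSeries] = []
    for ts in tss.series:
        bad_states = bad.get(ts.group, set())
        rows = [tuple(int(b) for b in r) for r in ts.points]
        # cut after every row whose state is inconsistent in its pool
        start = 0
        pieces: list[tuple[int, int]] = []
        for j, row in enumerate(rows):
            if j < len(rows) - 1 and row in bad_states:
                pieces.append((start, j + 1))
                start = j + 1
        pieces.append((start, len(rows)))
        many = len(pieces) > 1
        for k, (a, b) in enumerate(pieces):
            label = f"{ts.label}/frag{k + 1}" if many else ts.label
            fragments.append(
                TimeSeries(ts.points[a:b].copy(), kind=ts.kind, ko_target=ts.ko_target, label=label)
            )
    return TimeSeriesSet(fragments, xi=tss.xi, variables=list(tss.variables))


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------


def inject_noise(
    tss: TimeSeriesSet, xi: float, seed=None
) -> tuple[TimeSeriesSet, list[tuple[int, int, int]]]:
    """Flip exactly ``round(xi * total_points * n)`` distinct, uniformly
    chosen bits (round half-up).  Returns the noisy copy and the flipped
    positions as ``(series_index, row, column)`` triples.  Seeded and
    reproducible."""
    if not 0 <= xi < 1:
        raise ValueError("xi must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    noisy = tss.copy()
    n_bits = tss.total_points * tss.n
    n_flips = math.floor(xi * tss.total_points * tss.n + 0.5)
    if n_flips == 0:
        return noisy, []
    chosen = rng.choice(n_bits, size=n_flips, replace=False)
    offsets = np.cumsum([0] + [ts.alpha * ts.n for ts in tss.series])
    flips: list[tuple[int, int, int]] = []
    for pos in sorted(int(p) for p in chosen):
        s = int(np.searchsorted(offsets, pos, side="right")) - 1
        local = pos - offsets[s]
        row, col = divmod(int(local), tss.n)
        noisy.series[s].points[row, col] ^= 1
        flips.append((s, row, col))
    return noisy, flips


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def _as_list(cts) -> list[ContinuousTimeSeries]:
    return list(cts) if isinstance(cts, (list, tuple)) else [cts]


def _levels_from_thresholds(col: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    # value <= threshold_j is assigned the lower level (ties go down)
    return (col[:, None] > thresholds[None, :]).sum(axis=1)


def quantile_thresholds(columns: np.ndarray, s: int) -> np.ndarray:
    """Per-variable thresholds at the ``j/s`` quantiles (inclusive-median
    linear interpolation), computed over the pooled values of each column."""
    if s < 2:
        raise ValueError("number of levels s must be >= 2")
    qs = [j / s for j in range(1, s)]
    return np.quantile(columns, qs, axis=0).T  # shape (n, s-1)


def discretize_quantile(cts, s: int = 2):
    """Quantile discretization Q``s``: per-variable thresholds at the
    ``j/s`` quantiles of that variable's pooled values across the supplied
    series; values at or below a threshold take the lower level.

    Only ``s=2`` yields binary data usable by the inference engine; larger
    ``s`` exists for exporting multi-level data to external tools.
    Invariant under strictly monotone per-column transforms of the data.
    """
    series = _as_list(cts)
    pooled = np.vstack([c.points for c in series])
    for j in range(pooled.shape[1]):
        if np.ptp(pooled[:, j]) == 0:
            logger.warning("constant column %d discretizes to all 0", j + 1)
    thr = quantile_thresholds(pooled, s)
    out = []
    for c in series:
        levels = np.column_stack(
            [_levels_from_thresholds(c.points[:, j], thr[j]) for j in range(c.n)]
        )
        out.append(_discrete_like(c, levels, s))
    return out if isinstance(cts, (list, tuple)) else out[0]


def discretize_interval(cts, s: int = 2):
    """Interval discretization: per-variable equal-width bins on
    ``[min, max]`` of the pooled values; the maximum maps to the top level."""
    if s < 2:
        raise ValueError("number of levels s must be >= 2")
    series = _as_list(cts)
    pooled = np.vstack([c.points for c in series])
    lo, hi = pooled.min(axis=0), pooled.max(axis=0)
    span = hi - lo
    out = []
    for c in series:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(span > 0, (c.points - lo) / span * s, 0.0)
        levels = np.clip(np.floor(raw).astype(int), 0, s - 1)
        out.append(_discrete_like(c, levels, s))
    return out if isinstance(cts, (list, tuple)) else out[0]


def _discrete_like(c: ContinuousTimeSeries, levels: np.ndarray, s: int):
    if s == 2:
        return TimeSeries(levels.astype(np.int8), kind=c.kind, ko_target=c.ko_target, label=c.label)
    # multi-level output is for export only; return the raw level matrix with metadata
    return ContinuousTimeSeries(levels.astype(float), kind=c.kind, ko_target=c.ko_target, label=c.label)


# ---------------------------------------------------------------------------
# I/O: TSV blocks + JSON manifest
# ---------------------------------------------------------------------------


def _format_block(ts, variables: Sequence[str], fmt) -> str:
    ko = variables[ts.ko_target] if ts.ko_target is not None else "-"
    lines = [f"#series {ts.label or '-'} kind={ts.kind} ko={ko}"]
    lines.append("\t".join(variables))
    for row in ts.points:
        lines.append("\t".join(fmt(v) for v in row))
    return "\n".join(lines)


def write_timeseries(tss: TimeSeriesSet, path, manifest: bool = True) -> None:
    """Write the block TSV format; a JSON manifest is written beside it."""
    path = str(path)
    blocks = [_format_block(ts, tss.variables, lambda v: str(int(v))) for ts in tss.series]
    with open(path, "w") as fh:
        fh.write("\n\n".join(blocks) + "\n")
    if manifest:
        man = {
            "variables": list(tss.variables),
            "xi": tss.xi,
            "series": [
                {
                    "label": ts.label,
                    "kind": ts.kind,
                    "ko": tss.variables[ts.ko_target] if ts.ko_target is not None else None,
                }
                for ts in tss.series
            ],
        }
        with open(path + ".manifest.json", "w") as fh:
            json.dump(man, fh, indent=2)
            fh.write("\n")


def _parse_blocks(text: str):
    blocks = [b for b in text.split("\n\n") if b.strip()]
    for block in blocks:
        lines = [ln for ln in block.splitlines() if ln.strip()]
        header = lines[0]
        if not header.startswith("#series"):
            raise ValueError("each block must start with a '#series' line")
        parts = header.split()
        label = parts[1] if len(parts) > 1 and not parts[1].startswith("kind=") else "-"
        meta = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        variables = lines[1].split("\t")
        rows = [ln.split("\t") for ln in lines[2:]]
        yield label, meta, variables, rows


def read_timeseries(path, xi: float = 0.0) -> TimeSeriesSet:
    """Read the block TSV format written by :func:`write_timeseries`.

    If a manifest sits beside the file its ``xi`` takes precedence."""
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    series: list[TimeSeries] = []
    variables: list[str] | None = None
    for label, meta, block_vars, rows in _parse_blocks(text):
        if variables is None:
            variables = block_vars
        elif variables != block_vars:
            raise ValueError("all blocks must share the same variable header")
        kind = meta.get("kind", WILDTYPE)
        ko_name = meta.get("ko", "-")
        ko = variables.index(ko_name) if ko_name != "-" else None
        points = np.array([[int(v) for v in r] for r in rows], dtype=np.int8)
        series.append(
            TimeSeries(points, kind=kind, ko_target=ko, label="" if label == "-" else label)
        )
    try:
        with open(path + ".manifest.json") as fh:
            xi = json.load(fh).get("xi", xi)
    except FileNotFoundError:
        pass
    return TimeSeriesSet(series, xi=xi, variables=variables)


def read_continuous_timeseries(path) -> list[ContinuousTimeSeries]:
    with open(str(path)) as fh:
        text = fh.read()
    out = []
    for label, meta, variables, rows in _parse_blocks(text):
        kind = meta.get("kind", WILDTYPE)
        ko_name = meta.get("ko", "-")
        ko = variables.index(ko_name) if ko_name != "-" else None
        points = np.array([[float(v) for v in r] for r in rows], dtype=float)
        out.append(
            ContinuousTimeSeries(points, kind=kind, ko_target=ko, label="" if label == "-" else label)
        )
    return out


def write_continuous_timeseries(series: Iterable[ContinuousTimeSeries], path, variables=None) -> None:
    series = list(series)
    if variables is None:
        variables = [f"x{i + 1}" for i in range(series[0].n)]
    blocks = [_format_block(ts, variables, lambda v: repr(float(v))) for ts in series]
    with open(str(path), "w") as fh:
        fh.write("\n\n".join(blocks) + "\n")
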