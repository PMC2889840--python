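"""Expression matrices, probe collapsing, and stage windows.

The study design samples a TNFα-stimulated culture densely over 0–8 h:
every 15 minutes up to 4 h and every 30 minutes thereafter, giving the
canonical 25-point grid.  The grid is split into six stage windows
(0–1, 1–2, 2–3, 3–4, 4–6, 6–8 h); adjacent windows share their boundary
sample so that each window holds five points.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Stage boundaries in hours used throughout the inflammation study.
DEFAULT_STAGE_BOUNDARIES_HOURS = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


def canonical_grid_minutes() -> np.ndarray:
    """The 25-point sampling grid: 15-min steps on 0-4 h, 30-min on 4-8 h."""
    return np.concatenate([np.arange(0, 241, 15), np.arange(270, 481, 30)]).astype(
        float
    )


class FormatError(ValueError):
    """Malformed expression-matrix input."""


_TIME_RE = re.compile(
    r"(?P<num>\d+(?:\.\d+)?)\s*(?P<unit>h(?:ou)?rs?|h|m(?:in)?s?)?\s*$",
    re.IGNORECASE,
)


def parse_time_label(label: str) -> float:
    """Parse a column header into minutes.

    Bare numbers are minutes; an ``h``/``hr`` suffix means hours, ``m``/
    ``min`` means minutes.  Leading annotation (e.g. ``t=``) is tolerated.
    """
    m = _TIME_RE.search(label.strip())
    if m is None:
        raise FormatError(f"cannot parse time label {label!r}")
    value = float(m.group("num"))
    unit = (m.group("unit") or "m").lower()
    return value * 60.0 if unit.startswith("h") else value


@dataclass
class ExpressionMatrix:
    """A rows x times matrix of log2-scale expression values.

    Rows are probes or gene symbols; columns are a strictly increasing time
    grid in minutes.  Backed by a pandas DataFrame (``.frame``) whose
    columns are the grid values.
    """

    frame: pd.DataFrame  # index: row ids; columns: float minutes

    def __post_init__(self) -> None:
        times = np.asarray(self.frame.columns, dtype=float)
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate row ids")
        self.frame.columns = times

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.frame.columns, dtype=float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    def profile(self, row_id: str) -> np.ndarray:
        return self.frame.loc[row_id].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path, time_unit: str = "min") -> None:
        """Write the matrix back out in the tab-delimited format we read."""
        hdr = [
            f"{t / 60:g}h" if time_unit == "h" else f"{t:g}" for t in self.times
        ]
        out = self.frame.copy()
        out.columns = hdr
        out.to_csv(path, sep="\t", index_label="ID")


def read_expression_matrix(text: str) -> ExpressionMatrix:
    """Parse a tab-delimited matrix body: row ids + time-labelled columns.

    The first column holds row ids and the header row holds time labels
    parseable to minutes.  Columns arriving out of time order are sorted
    (with a warning); a ragged row raises :class:`FormatError` naming it.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("!")]
    if not lines:
        raise FormatError("empty expression matrix")
    header = lines[0].rstrip("\n").split("\t")
    times = [parse_time_label(lbl) for lbl in header[1:]]
    n = len(times)
    ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        if len(cells) != n + 1:
            raise FormatError(
                f"line {lineno}: expected {n + 1} columns, got {len(cells)}"
            )
        ids.append(cells[0].strip())
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric value ({exc})") from exc
    frame = pd.DataFrame(rows, index=ids, columns=times)
    order = np.argsort(times)
    if not np.array_equal(order, np.arange(n)):
        warnings.warn("time columns out of order; sorting", stacklevel=2)
        frame = frame.iloc[:, order]
    if pd.Index(frame.columns).has_duplicates:
        raise FormatError("duplicate time points in header")
    return ExpressionMatrix(frame)


def read_expression_file(path: str | Path) -> ExpressionMatrix:
    return read_expression_matrix(Path(path).read_text(encoding="utf-8"))


def collapse_probes(
    matrix: ExpressionMatrix, probe_map: dict[str, str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Collapse probe-level rows to one row per gene symbol.

    For each symbol the probe with maximal sample variance across the grid
    is kept (ties broken by lexicographically smallest probe id, so the
    result is invariant to input order).  Returns the collapsed matrix and
    the sorted list of map symbols with no probe present in the matrix.
    """
    by_symbol: dict[str, list[str]] = {}
    for probe, symbol in probe_map.items():
        if probe in matrix.frame.index:
            by_symbol.setdefault(symbol, []).append(probe)
    chosen: dict[str, str] = {}
    for symbol, probes in by_symbol.items():
        variances = matrix.frame.loc[probes].var(axis=1, ddof=1)
        best = min(probes, key=lambda p: (-variances[p], p))
        chosen[symbol] = best
    missing = sorted(set(probe_map.values()) - set(chosen))
    if missing:
        logger.info("symbols with no probe in matrix: %s", ", ".join(missing))
    symbols = sorted(chosen)
    frame = matrix.frame.loc[[chosen[s] for s in symbols]].copy()
    frame.index = symbols
    return ExpressionMatrix(frame), missing


@dataclass(frozen=True)
class StageWindow:
    """A contiguous slice of the time grid; adjacent windows share a point."""

    index: int  # 1-based stage number
    start_hours: float
    end_hours: float
    point_indices: tuple[int, ...]

    @property
    def n_points(self) -> int:
        return len(self.point_indices)

    @property
    def n_transitions(self) -> int:
        return len(self.point_indices) - 1

    def label(self) -> str:
        return f"{self.start_hours:g}~{self.end_hours:g}HR"


def build_stage_windows(
    grid_minutes: np.ndarray, boundaries_hours=DEFAULT_STAGE_BOUNDARIES_HOURS
) -> list[StageWindow]:
    """Split a time grid into stage windows at the given hour boundaries.

    Windows span consecutive boundary pairs inclusive of both endpoints, so
    adjacent windows share exactly the boundary sample.  The first window
    starts at the first grid point.  Every boundary must sit on the grid.
    """
    grid = np.asarray(grid_minutes, dtype=float)
    bounds = [float(b) for b in boundaries_hours]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("stage boundaries must be strictly increasing")
    cuts_min = [grid[0]] + [b * 60.0 for b in bounds]
    idx: list[int] = []
    for cut in cuts_min:
        hits = np.nonzero(np.isclose(grid, cut))[0]
        if len(hits) == 0:
            raise ValueError(f"stage boundary {cut / 60:g} h not on the time grid")
        idx.append(int(hits[0]))
    windows = []
    for k, (lo, hi) in enumerate(zip(idx, idx[1:]), start=1):
        if hi - lo < 1:
            raise ValueError(f"stage {k} has fewer than 2 points")
        windows.append(
            StageWindow(
                index=k,
                start_hours=grid[lo] / 60.0,
                end_hours=grid[hi] / 60.0,
                point_indices=tuple(range(lo, hi + 1)),
            )
        )
    return windows
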