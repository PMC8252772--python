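"""Reference-network matching and ICA dimension optimization.

Group FC maps are correlated (plain Pearson, unthresholded by default) with
each reference-network template over the brain mask. A component is reported
as matched to a network when

* its best correlation exceeds ``r_threshold`` (default 0.4),
* the best correlation beats the second-highest correlation *in the same
  component row* by more than ``ratio_threshold`` (default 1.3), and
* it likewise beats the second-highest correlation *in the matched network
  column*.

A ratio whose denominator is zero or negative counts as passed (the maximum
is overwhelming). Ties for the row maximum go to the lowest network index.
The column rule makes matched networks distinct across components.

The decomposition dimension is chosen by running the whole pipeline at every
dimension in a range and keeping the lowest dimension that attains the
largest number of matched components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["CorrelationMatrix", "SelectionParams", "SelectionResult",
           "OptimalDimension", "spatial_correlation_matrix", "select_components",
           "optimize_dimension"]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """n_components x m_networks Pearson correlations for one dimension."""

    values: np.ndarray
    dimension: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("correlation matrix must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("correlation matrix contains non-finite entries")
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v


@dataclass(frozen=True)
class SelectionParams:
    r_threshold: float = 0.4
    ratio_threshold: float = 1.3
    d_range: tuple[int, int] = (1, 15)

    def __post_init__(self) -> None:
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.ratio_threshold <= 1.0:
            raise ValueError("ratio_threshold must exceed 1")
        lo, hi = self.d_range
        if not (1 <= lo <= hi):
            raise ValueError("d_range must be an increasing interval from >= 1")

    @property
    def dimensions(self) -> range:
        return range(self.d_range[0], self.d_range[1] + 1)


@dataclass
class SelectionResult:
    """Matched (component, network, r_max) records for one dimension."""

    selected: list[tuple[int, int, float]]
    dimension: int

    @property
    def count(self) -> int:
        return len(self.selected)

    @property
    def matched_networks(self) -> list[int]:
        return [net for _, net, _ in self.selected]


@dataclass
class OptimalDimension:
    d_star: int
    counts_by_dimension: dict[int, int]
    selections: dict[int, SelectionResult] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)


def spatial_correlation_matrix(group_maps: np.ndarray, templates: np.ndarray,
                               mask: np.ndarray | None = None,
                               dimension: int | None = None,
                               map_threshold: float | None = None) -> CorrelationMatrix:
    """Pearson correlation of each group map with each template over a mask.

    ``group_maps`` is n x V, ``templates`` m x V (already vectorized on the
    same voxel ordering); ``mask`` is a boolean selector over the V columns
    (pass the union of template supports for the template-restricted mode).
    ``map_threshold`` zeroes map values with |z| below it before correlating
    (display-style thresholding; the default correlates raw maps).
    Zero-variance maps or templates give 0 entries (flagged via log).
    """
    G = np.asarray(group_maps, dtype=np.float64)
    if map_threshold is not None:
        G = np.where(np.abs(G) >= map_threshold, G, 0.0)
    Tpl = np.asarray(templates, dtype=np.float64)
    if G.ndim == 1:
        G = G[None, :]
    if Tpl.ndim == 1:
        Tpl = Tpl[None, :]
    if G.shape[1] != Tpl.shape[1]:
        raise ValueError("maps and templates are not on the same voxel grid")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("correlation mask is empty")
        G, Tpl = G[:, mask], Tpl[:, mask]
    G = G - G.mean(axis=1, keepdims=True)
    Tpl = Tpl - Tpl.mean(axis=1, keepdims=True)
    gn = np.linalg.norm(G, axis=1)
    tn = np.linalg.norm(Tpl, axis=1)
    bad_g, bad_t = gn <= 0, tn <= 0
    if bad_g.any() or bad_t.any():
        logger.warning("zero-variance inputs to spatial correlation: %d maps, %d templates",
                       int(bad_g.sum()), int(bad_t.sum()))
    C = (G @ Tpl.T) / np.outer(np.where(bad_g, 1.0, gn), np.where(bad_t, 1.0, tn))
    C[bad_g, :] = 0.0
    C[:, bad_t] = 0.0
    C = np.clip(C, -1.0, 1.0)
    return CorrelationMatrix(values=C, dimension=dimension if dimension is not None else C.shape[0])


def _ratio_passes(top: float, second: float, ratio_threshold: float) -> bool:
    if second <= 0.0:
        return True  # an overwhelming maximum: nothing comparable to beat
    return top / second > ratio_threshold


def select_components(C: CorrelationMatrix, params: SelectionParams | None = None
                      ) -> SelectionResult:
    """Apply the three matching rules to one correlation matrix."""
    if params is None:
        params = SelectionParams()
    V = C.values
    n, m = V.shape
    selected: list[tuple[int, int, float]] = []
    for i in range(n):
        row = V[i]
        j = int(np.argmax(row))  # lowest index wins ties
        r_max = float(row[j])
        if not r_max > params.r_threshold:
            continue
        row_rest = np.delete(row, j)
        if row_rest.size and not _ratio_passes(r_max, float(row_rest.max()),
                                               params.ratio_threshold):
            continue
        col_rest = np.delete(V[:, j], i)
        if col_rest.size and not _ratio_passes(r_max, float(col_rest.max()),
                                               params.ratio_threshold):
            continue
        selected.append((i, j, r_max))
    nets = [net for _, net, _ in selected]
    assert len(nets) == len(set(nets)), "column rule must keep matched networks distinct"
    return SelectionResult(selected=selected, dimension=C.dimension)


def optimize_dimension(run_dimension: Callable[[int], CorrelationMatrix],
                       params: SelectionParams | None = None,
                       d_range: Iterable[int] | None = None) -> OptimalDimension:
    """Sweep dimensions, select components at each, and keep the lowest
    dimension attaining the maximum matched-component count.

    ``run_dimension(d)`` must execute the pipeline (ICA, dual regression,
    group maps, correlation) at dimension ``d``. A failure at a single
    dimension is recorded, counted as 0 matches, and does not abort the sweep.
    """
    if params is None:
        params = SelectionParams()
    dims = list(d_range) if d_range is not None else list(params.dimensions)
    counts: dict[int, int] = {}
    selections: dict[int, SelectionResult] = {}
    failures: dict[int, str] = {}
    for d in dims:
        try:
            C = run_dimension(d)
            sel = select_components(C, params)
        except Exception as exc:  # robustness: one bad dimension must not kill the sweep
            logger.warning("dimension %d failed: %s", d, exc)
            failures[d] = str(exc)
            counts[d] = 0
            continue
        selections[d] = sel
        counts[d] = sel.count
    max_count = max(counts.values())
    d_star = min(d for d, c in counts.items() if c == max_count)
    return OptimalDimension(d_star=d_star, counts_by_dimension=counts,
                            selections=selections, failures=failures)
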