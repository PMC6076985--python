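"""Permutation-null construction and KS-based threshold selection.

Raw co-occurrence mapping tables contain a large fraction of chance pairings:
two heavily-annotated terms will share a gene or two simply by combinatorics.
To pick filtering thresholds (s_min, n_min) that separate signal from chance,
a null mapping table is built after relabeling gene identities by a random
bijection (destroying the cross-ontology coupling while preserving every
per-term annotation count), and for each candidate threshold pair the
binned similarity distributions of the observed and null tables are compared
with a two-sample Kolmogorov-Smirnov test.  The KS distance is taken between
the two binned (count-weighted) similarity CDFs, and the histogram bins -
not the individual mappings - act as the sampling units when converting the
distance to a p-value: per-bin frequencies within one table are strongly
dependent (the same term-degree structure populates many bins), so using the
raw mapping count as the sample size would declare microscopic distribution
differences significant.  The lowest threshold pair reaching significance,
scanning similarity thresholds outward and co-annotation counts inward, is
selected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np
from scipy import stats

from .annotations import AnnotationSet
from .mapping import MappingTable, filter_mapping

log = logging.getLogger(__name__)


def randomize_annotations(
    annot: AnnotationSet,
    seed: int,
    universe: Sequence[str] | None = None,
) -> AnnotationSet:
    """Relabel entities by a uniform random bijection; terms stay fixed.

    Per-term gene counts are preserved exactly.  ``universe`` widens the
    label pool beyond the table's own entities (it must contain them); by
    default the bijection permutes the table's entity set onto itself.
    Deterministic given the seed.
    """
    entities = sorted(annot.entities())
    if universe is None:
        pool = entities
    else:
        pool = sorted(set(universe))
        if not set(entities) <= set(pool):
            raise ValueError("universe must contain every annotated entity")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    relabel = {e: pool[perm[i]] for i, e in enumerate(pool)}
    return AnnotationSet(
        ((relabel[e], t) for e, t in annot), namespace=annot.namespace
    )


@dataclass(frozen=True)
class Histogram:
    """Counts of similarity values over half-open bins (lo, hi] covering (0, 1]."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)

    def occupied_bins(self) -> int:
        return sum(1 for c in self.counts if c > 0)


def s_histogram(
    table: MappingTable, s_min: float, n_min: int, bin_width: float
) -> Histogram:
    """Histogram of S over (0, 1] after filtering at (s_min, n_min).

    Bins are half-open (lo, hi]; a value equal to a bin edge falls in the
    bin whose upper edge it is (e.g. S = 0.1 at width 0.1 lands in (0, 0.1]).
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must lie in (0, 1]")
    nbins = int(math.ceil(1.0 / bin_width - 1e-9))
    counts = [0] * nbins
    for rec in table:
        if rec.n < n_min:
            continue
        s = rec.s
        if s < s_min:
            continue
        idx = int(math.ceil(s / bin_width - 1e-9)) - 1
        idx = min(max(idx, 0), nbins - 1)
        counts[idx] += 1
    edges = tuple(round(i * bin_width, 12) for i in range(nbins + 1))
    return Histogram(bin_edges=edges, counts=tuple(counts))


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS outcome; ``insufficient`` mirrors an untestable cell."""

    statistic: float
    p_value: float
    status: str = "ok"

    @classmethod
    def insufficient(cls) -> "KSResult":
        return cls(statistic=math.nan, p_value=math.nan, status="insufficient")


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], min_size: int = 3
) -> KSResult:
    """Two-sided two-sample KS test with an insufficient-sample status.

    Uses the exact null distribution for small samples and the asymptotic
    approximation otherwise.  Either sample shorter than ``min_size``
    (default 3) yields status ``insufficient`` instead of a statistic.
    """
    if len(a) < min_size or len(b) < min_size:
        return KSResult.insufficient()
    res = stats.ks_2samp(np.asarray(a, dtype=float), np.asarray(b, dtype=float), method="auto")
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue))


@dataclass
class ThresholdGrid:
    """KS p-value matrix over (n, S) threshold combinations with a selection.

    ``results[i][j]`` is the KS outcome at ``n_grid[i]``, ``s_grid[j]``.  The
    selection, when present, is the first (ascending n, then ascending S)
    cell with status ok and p < alpha.
    """

    s_grid: tuple[float, ...]
    n_grid: tuple[int, ...]
    results: list[list[KSResult]]
    alpha: float
    selection: tuple[float, int] | None = None  # (s_min, n_min)

    def result_at(self, n_min: int, s_min: float) -> KSResult:
        return self.results[self.n_grid.index(n_min)][self.s_grid.index(s_min)]


DEFAULT_S_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
DEFAULT_N_GRID = (1, 2, 3, 4, 5)


def binned_ks(
    hist_a: Histogram,
    hist_b: Histogram,
    s_min: float = 0.0,
    min_occupied_bins: int = 3,
) -> KSResult:
    """KS comparison of two binned similarity distributions.

    D is the supremum distance between the count-weighted cumulative
    distributions over the bins able to hold values >= s_min; the number of
    those bins serves as the sample size on both sides, and the p-value uses
    the classic asymptotic two-sample formula with the Stephens small-sample
    correction.  Either histogram occupying fewer than ``min_occupied_bins``
    bins yields status ``insufficient``.
    """
    if hist_a.bin_edges != hist_b.bin_edges:
        raise ValueError("histograms must share bin edges")
    if hist_a.occupied_bins() < min_occupied_bins or hist_b.occupied_bins() < min_occupied_bins:
        return KSResult.insufficient()
    first = _first_relevant_bin(hist_a.bin_edges, s_min)
    a = np.asarray(hist_a.counts[first:], dtype=float)
    b = np.asarray(hist_b.counts[first:], dtype=float)
    cdf_a = np.cumsum(a) / a.sum()
    cdf_b = np.cumsum(b) / b.sum()
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    nbins = len(a)
    en = math.sqrt(nbins / 2.0)
    lam = (en + 0.12 + 0.11 / en) * d
    p = float(stats.distributions.kstwobign.sf(lam))
    return KSResult(statistic=d, p_value=min(max(p, 0.0), 1.0))


def select_thresholds(
    original: MappingTable,
    null: MappingTable,
    s_grid: Sequence[float] = DEFAULT_S_GRID,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    alpha: float = 0.01,
    bin_width: float = 0.02,
    min_occupied_bins: int = 3,
) -> ThresholdGrid:
    """Scan the threshold grid and select the lowest significant pair.

    For each (s_min, n_min) cell both tables are filtered, histogrammed at
    ``bin_width``, and compared with :func:`binned_ks`.  A cell where either
    histogram occupies fewer than ``min_occupied_bins`` bins is marked
    insufficient.  The scan runs ascending S (outer) then ascending n
    (inner): the stringency of the similarity cut is raised only after every
    co-annotation-count cut at the current similarity level has failed to
    separate the distributions.  The first cell with status ok and
    p < alpha becomes the selection.
    """
    if not s_grid or not n_grid:
        raise ValueError("threshold grids must be non-empty")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    s_grid = tuple(s_grid)
    n_grid = tuple(n_grid)
    results: list[list[KSResult]] = [
        [KSResult.insufficient()] * len(s_grid) for _ in n_grid
    ]
    selection: tuple[float, int] | None = None
    for j, s_min in enumerate(s_grid):
        for i, n_min in enumerate(n_grid):
            h_orig = s_histogram(original, s_min, n_min, bin_width)
            h_null = s_histogram(null, s_min, n_min, bin_width)
            res = binned_ks(h_orig, h_null, s_min, min_occupied_bins)
            results[i][j] = res
            if selection is None and res.status == "ok" and res.p_value < alpha:
                selection = (s_min, n_min)
    if selection is None:
        log.warning("no threshold combination reached significance at alpha=%g", alpha)
    return ThresholdGrid(
        s_grid=s_grid, n_grid=n_grid, results=results, alpha=alpha, selection=selection
    )


def _first_relevant_bin(edges: tuple[float, ...], s_min: float) -> int:
    """Index of the first bin able to receive values >= s_min."""
    for i in range(len(edges) - 1):
        if edges[i + 1] >= s_min - 1e-12:
            return i
    return len(edges) - 2


def write_threshold_grid(grid: ThresholdGrid, stream: IO[str]) -> None:
    """Serialize the grid as a TSV matrix (rows = n thresholds, cols = S)."""
    stream.write(f"#alpha={grid.alpha}\n")
    if grid.selection is not None:
        stream.write(f"#selected_s_min={grid.selection[0]}\n#selected_n_min={grid.selection[1]}\n")
    header = "\t".join(f"S>={s:g}" if s > 0 else "S>0" for s in grid.s_grid)
    stream.write(f"n_min\t{header}\n")
    for n_min, row in zip(grid.n_grid, grid.results):
        cells = "\t".join(
            "NA" if r.status != "ok" else f"{r.p_value:.6g}" for r in row
        )
        stream.write(f"n>={n_min}\t{cells}\n")


def write_histogram(hist: Histogram, stream: IO[str]) -> None:
    stream.write("#bin_lo\tbin_hi\tcount\n")
    for lo, hi, c in zip(hist.bin_edges, hist.bin_edges[1:], hist.counts):
        stream.write(f"{lo:g}\t{hi:g}\t{c}\n")
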