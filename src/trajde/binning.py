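"""Pseudotime binning, bin equalization and pseudo-bulk aggregation.

Continuous pseudotime is discretized into ordinal bins using a histogram rule
(Sturges by default) scaled by a drop-factor ``k``; cells from different
branching paths never share a bin.  Counts are summed within each (path, bin)
to form pseudo-bulk profiles, raising the signal-to-noise ratio of sparse
single-cell counts, and per-bin size factors provide the GLM offset.

Two range conventions are supported when building the bin grid:

* ``range_mode="global"`` (default): the number of bins is computed from the
  total number of cells and the equal-width grid spans the global pseudotime
  range; each path's cells are assigned to this shared grid.  Paths covering
  a shorter pseudotime range therefore occupy fewer bins, which preserves the
  relative developmental length of each branch.
* ``range_mode="path"``: bin count and grid are derived per path from that
  path's cell count and pseudotime range.

Bins are left-closed, right-open intervals except the last bin of a grid,
which is closed on both ends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CellExperiment

logger = logging.getLogger(__name__)

__all__ = [
    "bin_count",
    "assign_bins",
    "PathBins",
    "BinMap",
    "make_bin_map",
    "equalize_bins",
    "drop_tails",
    "aggregate",
    "size_factors",
    "BinnedExperiment",
    "squeeze",
]

STRATEGIES = ("sturges", "rice", "doane", "freedman-diaconis", "scott", "sqrt")

MIN_DROP_FACTOR = 0.3


def bin_count(
    n_cells: int,
    strategy: str = "sturges",
    k: float = 1.0,
    values: np.ndarray | None = None,
) -> int:
    """Number of pseudotime bins for ``n_cells`` cells under a histogram rule.

    The base rule is evaluated with a ceiling, multiplied by the drop-factor
    ``k`` (``k < 1`` compresses pseudotime into fewer bins, useful for very
    sparse data) and ceiled again.  The result is floored at 2 bins (1 when
    fewer than 4 cells).  Data-dependent rules (Doane, Freedman-Diaconis,
    Scott) require the pseudotime ``values``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if k < MIN_DROP_FACTOR:
        raise ValueError(f"drop-factor k must be >= {MIN_DROP_FACTOR}, got {k}")
    strategy = strategy.lower()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown binning strategy {strategy!r}; choose from {STRATEGIES}")

    n = n_cells
    if strategy == "sturges":
        base = math.ceil(math.log2(n) + 1)
    elif strategy == "rice":
        base = math.ceil(2.0 * n ** (1.0 / 3.0))
    elif strategy == "sqrt":
        base = math.ceil(math.sqrt(n))
    else:
        if values is None:
            raise ValueError(f"strategy {strategy!r} requires pseudotime values")
        x = np.asarray(values, dtype=float)
        rng = float(np.max(x) - np.min(x)) if x.size else 0.0
        if strategy == "doane":
            if n < 3 or np.std(x) == 0:
                base = 1
            else:
                g1 = float(
                    np.mean(((x - x.mean()) / x.std()) ** 3)
                )
                sg1 = math.sqrt(6.0 * (n - 2) / ((n + 1.0) * (n + 3.0)))
                base = math.ceil(1 + math.log2(n) + math.log2(1 + abs(g1) / sg1))
        else:  # scott / freedman-diaconis: width rules
            if strategy == "scott":
                h = 3.49 * float(np.std(x)) * n ** (-1.0 / 3.0)
            else:
                q75, q25 = np.percentile(x, [75, 25])
                h = 2.0 * float(q75 - q25) * n ** (-1.0 / 3.0)
            if h <= 0 or rng <= 0:
                base = 1
            else:
                base = math.ceil(rng / h)

    b = math.ceil(base * k)
    floor = 1 if n_cells < 4 else 2
    return max(b, floor)


def _edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if hi <= lo:
        # degenerate pseudotime range: a single bin holds everything
        return np.array([lo, lo])
    return np.linspace(lo, hi, n_bins + 1)


def assign_to_edges(pseudotime: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign values to 1-based bins on an explicit equal-width grid.

    Intervals are left-closed/right-open; the last bin is closed on both ends.
    Values outside the grid raise.
    """
    t = np.asarray(pseudotime, dtype=float)
    n_bins = len(edges) - 1
    if n_bins == 1 and edges[0] == edges[-1]:
        return np.ones(t.shape, dtype=int)
    lo, hi = edges[0], edges[-1]
    if np.any(t < lo) or np.any(t > hi):
        raise ValueError("pseudotime values outside the bin grid")
    width = (hi - lo) / n_bins
    idx = np.floor((t - lo) / width).astype(int) + 1
    return np.minimum(idx, n_bins)


def assign_bins(pseudotime: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign pseudotime values to ``n_bins`` equal-width, 1-based ordinal bins
    over ``[min(t), max(t)]``.  Degenerate (zero-range) pseudotime collapses to
    a single bin."""
    t = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("pseudotime must be finite")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = float(np.min(t)), float(np.max(t))
    if hi <= lo:
        return np.ones(t.shape, dtype=int)
    return assign_to_edges(t, _edges(lo, hi, n_bins))


@dataclass
class PathBins:
    """Bin structure for one branching path.

    ``bin_of_cell`` holds the 1-based ordinal bin of each member cell
    (0 marks a cell dropped by pruning); ``intervals`` lists the (lower,
    upper) bounds of bins 1..B in order.
    """

    path: object
    cell_idx: np.ndarray          # indices into the experiment's cells
    pseudotime: np.ndarray        # pseudotime of those cells
    bin_of_cell: np.ndarray       # 1-based bin index per cell; 0 = pruned
    intervals: list               # [(lo, hi)] per bin, ordered

    @property
    def n_bins(self) -> int:
        return len(self.intervals)

    def sizes(self) -> np.ndarray:
        """Cell count per bin (bins 1..n_bins)."""
        return np.bincount(self.bin_of_cell, minlength=self.n_bins + 1)[1:]

    def copy(self) -> "PathBins":
        return PathBins(
            self.path,
            self.cell_idx.copy(),
            self.pseudotime.copy(),
            self.bin_of_cell.copy(),
            [tuple(iv) for iv in self.intervals],
        )


@dataclass
class BinMap:
    """Per-path bin intervals and memberships produced by pseudotime binning."""

    paths: dict
    strategy: str = "sturges"
    k: float = 1.0

    def path_labels(self) -> list:
        return list(self.paths)

    def total_cells(self) -> int:
        return sum(len(p.cell_idx) for p in self.paths.values())

    def n_retained(self) -> int:
        return sum(int(np.sum(p.bin_of_cell > 0)) for p in self.paths.values())

    def copy(self) -> "BinMap":
        return BinMap(
            {label: pb.copy() for label, pb in self.paths.items()},
            self.strategy,
            self.k,
        )


def make_bin_map(
    experiment: CellExperiment,
    strategy: str = "sturges",
    k: float = 1.0,
    range_mode: str = "global",
) -> BinMap:
    """Discretize pseudotime into ordinal bins, separately for each path."""
    if range_mode not in ("global", "path"):
        raise ValueError("range_mode must be 'global' or 'path'")
    t_all = experiment.pseudotime
    paths: dict = {}
    if range_mode == "global":
        n_bins = bin_count(experiment.n_cells, strategy, k, values=t_all)
        grid = _edges(float(t_all.min()), float(t_all.max()), n_bins)
    for label in experiment.paths:
        mask = experiment.path == label
        idx = np.flatnonzero(mask)
        t = t_all[idx]
        if range_mode == "path":
            n_bins_p = bin_count(len(idx), strategy, k, values=t)
            edges = _edges(float(t.min()), float(t.max()), n_bins_p)
        else:
            edges = grid
        raw = assign_to_edges(t, edges)
        # keep only bins this path occupies, re-labelled as consecutive ordinals
        occupied = np.unique(raw)
        relabel = {b: i + 1 for i, b in enumerate(occupied)}
        bin_of_cell = np.array([relabel[b] for b in raw], dtype=int)
        intervals = [(float(edges[b - 1]), float(edges[b])) for b in occupied]
        paths[label] = PathBins(label, idx, t, bin_of_cell, intervals)
    return BinMap(paths=paths, strategy=strategy, k=k)


def _split_bin(pb: PathBins, b: int, n_sub: int):
    """Partition bin ``b``'s cells by pseudotime rank into ``n_sub`` groups of
    near-equal size (differing by <= 1) and derive sub-interval edges."""
    members = np.flatnonzero(pb.bin_of_cell == b)
    order = members[np.argsort(pb.pseudotime[members], kind="stable")]
    groups = np.array_split(order, n_sub)
    groups = [g for g in groups if len(g)]
    lo, hi = pb.intervals[b - 1]
    sub_intervals = []
    for i, g in enumerate(groups):
        if i == 0:
            g_lo = lo
        else:
            prev_max = pb.pseudotime[groups[i - 1]].max()
            g_lo = 0.5 * (prev_max + pb.pseudotime[g].min())
        g_hi = hi if i == len(groups) - 1 else None  # filled by next lower edge
        sub_intervals.append([g_lo, g_hi])
    for i in range(len(sub_intervals) - 1):
        sub_intervals[i][1] = sub_intervals[i + 1][0]
    return groups, [tuple(iv) for iv in sub_intervals]


def equalize_bins(
    bin_map: BinMap,
    split_large: bool = True,
    prune_small: bool = False,
    max_iterations: int = 10,
) -> BinMap:
    """Equalize bin sizes within each path.

    The mean mu and population standard deviation sigma of the path's initial
    bin sizes establish the allowable size band [mu-sigma, mu+sigma]; bins
    larger than mu+sigma are split into ``ceil(size/(mu+sigma))`` rank-based
    sub-bins and, when ``prune_small``, bins smaller than mu-sigma are removed
    (their cells are dropped).  Splitting and pruning repeat against the
    established band until every bin conforms (a fixed point, normally reached
    in one or two passes) or ``max_iterations``.  Bin indices are re-assigned
    as consecutive ordinals.  Re-deriving the band from the new sizes each
    pass is deliberately avoided: every split lowers the band further, which
    fragments even near-uniform bins without ever conforming.
    """
    if not (split_large or prune_small):
        return bin_map
    out = bin_map.copy()
    for label, pb in out.paths.items():
        sizes0 = pb.sizes()
        if not np.any(sizes0 > 0):
            continue
        mu = float(sizes0[sizes0 > 0].mean())
        sigma = float(sizes0[sizes0 > 0].std())  # population sd
        hi_lim, lo_lim = mu + sigma, mu - sigma
        for _ in range(max_iterations):
            sizes = pb.sizes()
            changed = False
            new_assign = np.zeros_like(pb.bin_of_cell)
            new_intervals = []
            next_label = 1
            for b in range(1, pb.n_bins + 1):
                size = sizes[b - 1] if b - 1 < len(sizes) else 0
                if size == 0:
                    continue
                if split_large and size > hi_lim and size >= 2:
                    n_sub = math.ceil(size / hi_lim)
                    groups, sub_ivs = _split_bin(pb, b, n_sub)
                    if len(groups) > 1:
                        changed = True
                    for g, iv in zip(groups, sub_ivs):
                        new_assign[g] = next_label
                        new_intervals.append(iv)
                        next_label += 1
                elif prune_small and size < lo_lim:
                    changed = True
                    n_dropped = int(size)
                    logger.info(
                        "path %s: pruning bin %d (%d cells < %.2f)",
                        label, b, n_dropped, lo_lim,
                    )
                else:
                    members = np.flatnonzero(pb.bin_of_cell == b)
                    new_assign[members] = next_label
                    new_intervals.append(pb.intervals[b - 1])
                    next_label += 1
            pb.bin_of_cell = new_assign
            pb.intervals = new_intervals
            if not changed:
                break
        else:
            logger.warning(
                "path %s: equalization did not reach a fixed point in %d iterations",
                label, max_iterations,
            )
    return out


def drop_tails(bin_map: BinMap) -> BinMap:
    """Truncate every path to the bin count of the shortest path.

    Removes bins whose ordinal index exceeds the maximum index of the path
    with the fewest bins, so only comparable pseudotime segments remain.
    """
    if len(bin_map.paths) < 2:
        logger.warning("drop_tails requires >= 2 paths; returning input unchanged")
        return bin_map
    out = bin_map.copy()
    shortest = min(pb.n_bins for pb in out.paths.values())
    for label, pb in out.paths.items():
        if pb.n_bins > shortest:
            dropped = pb.bin_of_cell > shortest
            pb.bin_of_cell = np.where(dropped, 0, pb.bin_of_cell)
            pb.intervals = pb.intervals[:shortest]
            logger.info(
                "path %s: drop_tails removed %d cells beyond bin %d",
                label, int(dropped.sum()), shortest,
            )
        if not np.any(pb.bin_of_cell > 0):
            raise ValueError(f"path {label!r} has no cells left after drop_tails")
    return out


@dataclass
class BinnedExperiment:
    """Pseudo-bulk counts (genes x bins) with per-bin metadata.

    ``bin_meta`` columns: ``path``, ``t_index`` (ordinal binned pseudotime,
    the GLM time covariate), ``size`` (cell count), ``total`` (summed counts),
    ``size_factor`` and ``offset`` (log size factor).
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    bin_meta: pd.DataFrame
    bin_map: BinMap | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def write(self, directory) -> None:
        from pathlib import Path
        from scipy.io import mmwrite

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(
            str(directory / "pseudobulk.mtx"),
            sp.coo_matrix(self.counts),
            field="integer",
        )
        (directory / "genes.tsv").write_text(
            "\n".join(str(g) for g in self.gene_ids) + "\n"
        )
        self.bin_meta.to_csv(
            directory / "bin_metadata.tsv", sep="\t", index=False,
            float_format="%.17g",
        )


def aggregate(experiment: CellExperiment, bin_map: BinMap) -> BinnedExperiment:
    """Sum counts over the cells of each (path, bin) into pseudo-bulk columns.

    Cells without a bin (pruned during equalization) are excluded; the count
    of excluded cells is logged.  Total retained counts are conserved.
    """
    cols = []
    meta_rows = []
    n_cells = experiment.n_cells
    col_of_cell = np.full(n_cells, -1, dtype=int)
    n_excluded = 0
    for label in experiment.paths:
        pb = bin_map.paths[label]
        n_excluded += int(np.sum(pb.bin_of_cell == 0))
        for b in range(1, pb.n_bins + 1):
            members = pb.cell_idx[pb.bin_of_cell == b]
            if len(members) == 0:
                continue
            col_of_cell[members] = len(cols)
            cols.append((label, b, len(members)))
            meta_rows.append({"path": label, "t_index": b, "size": len(members)})
    if n_excluded:
        logger.info("aggregate: %d pruned cells excluded from pseudo-bulk", n_excluded)
    used = col_of_cell >= 0
    indicator = sp.csr_matrix(
        (
            np.ones(int(used.sum())),
            (np.flatnonzero(used), col_of_cell[used]),
        ),
        shape=(n_cells, len(cols)),
    )
    pseudobulk = np.asarray((experiment.counts @ indicator).todense()).astype(np.int64)
    meta = pd.DataFrame(meta_rows)
    meta["total"] = pseudobulk.sum(axis=0)
    binned = BinnedExperiment(
        counts=pseudobulk,
        gene_ids=experiment.gene_ids,
        bin_meta=meta,
        bin_map=bin_map,
    )
    size_factors(binned)
    return binned


def size_factors(binned: BinnedExperiment) -> pd.DataFrame:
    """Compute per-bin size factors and log-offsets in place.

    The size factor of bin b is its total count divided by the geometric mean
    of all bin totals, so the log size factors (the GLM offsets) average zero.
    """
    totals = binned.bin_meta["total"].to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError(
            "bins with zero total counts; enable prune_small to remove tiny bins"
        )
    log_t = np.log(totals)
    offsets = log_t - log_t.mean()
    binned.bin_meta["size_factor"] = np.exp(offsets)
    binned.bin_meta["offset"] = offsets
    return binned.bin_meta


def squeeze(
    experiment: CellExperiment,
    strategy: str = "sturges",
    k: float = 1.0,
    split_bin: bool = True,
    prune_bin: bool = False,
    drop_tails_flag: bool = False,
    range_mode: str = "global",
    max_iterations: int = 10,
) -> BinnedExperiment:
    """Full binning pipeline: grid construction, equalization, optional tail
    dropping, pseudo-bulk aggregation and size factors."""
    bm = make_bin_map(experiment, strategy=strategy, k=k, range_mode=range_mode)
    bm = equalize_bins(
        bm, split_large=split_bin, prune_small=prune_bin, max_iterations=max_iterations
    )
    if drop_tails_flag:
        bm = drop_tails(bm)
    return aggregate(experiment, bm)
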