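"""Ecoregion-based sampling units and balanced cross-validation blocks.

To limit the influence of spatial autocorrelation on model evaluation,
cells are never assigned to folds individually.  Each non-contiguous
patch of an ecoregion is a sampling unit; units are grouped into k
blocks so that every block's covariate means sit close to the global
means while each block still covers the full covariate range, and
cross-validation trains on k-1 blocks and tests on the held-out block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .world import CovariateTable, WorldGrid, connectivity_structure

__all__ = [
    "SamplingUnit",
    "BlockAssignment",
    "sampling_units",
    "assign_blocks",
    "blocked_folds",
]


@dataclass(frozen=True)
class SamplingUnit:
    """One contiguous patch of one ecoregion."""

    unit_id: int
    ecoregion_id: int
    cell_ids: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.cell_ids)


@dataclass
class BlockAssignment:
    """Mapping of sampling units (and their cells) to blocks 1..k."""

    unit_to_block: dict[int, int]
    cell_to_block: pd.Series  # indexed by cell_id
    units: list[SamplingUnit]
    k: int
    balance_report: pd.DataFrame

    def block_cells(self, block: int) -> np.ndarray:
        return self.cell_to_block.index[self.cell_to_block == block].to_numpy()


def sampling_units(world: WorldGrid) -> list[SamplingUnit]:
    """Split every ecoregion into its connected components.

    Uses the same adjacency as land-mass labelling.  Unit ids are stable
    for a fixed world: numbered in order of (ecoregion id, first cell id
    of the component).
    """
    structure = connectivity_structure(world.connectivity)
    eco = world.ecoregion_id
    units: list[SamplingUnit] = []
    next_id = 0
    for eco_id in np.unique(eco[eco >= 0]):
        mask = eco == eco_id
        labels, n = ndimage.label(mask, structure=structure)
        flat = labels.ravel()
        for comp in range(1, n + 1):
            cells = tuple(int(c) for c in np.flatnonzero(flat == comp))
            units.append(
                SamplingUnit(unit_id=next_id, ecoregion_id=int(eco_id), cell_ids=cells)
            )
            next_id += 1
    return units


@dataclass
class _BlockProblem:
    """Static per-unit statistics and objective weights."""

    unit_sums: np.ndarray  # (n_units, n_cov)
    unit_counts: np.ndarray  # (n_units,)
    unit_min: np.ndarray  # (n_units, n_cov)
    unit_max: np.ndarray
    global_mean: np.ndarray
    cov_lo: np.ndarray  # lower bound of the central range per covariate
    cov_hi: np.ndarray
    k: int
    target_size: float
    size_penalty: float
    max_dev_weight: float
    coverage_weight: float
    coverage_target: float


class _BlockState:
    """Mutable assignment with incremental objective bookkeeping.

    The objective combines (i) the mean-square deviation of block
    covariate means from the global means, (ii) a worst-deviation term
    (the blocking contract is on the largest departure, not the average
    one), (iii) a range-coverage shortfall term pushing every block to
    span each covariate's central range, and (iv) a block-size imbalance
    penalty.
    """

    def __init__(self, prob: _BlockProblem, placement: np.ndarray):
        self.prob = prob
        self.placement = placement
        k, p = prob.k, prob.unit_sums.shape[1]
        self.block_sums = np.zeros((k, p))
        self.block_counts = np.zeros(k)
        np.add.at(self.block_sums, placement[placement >= 0],
                  prob.unit_sums[placement >= 0])
        np.add.at(self.block_counts, placement[placement >= 0],
                  prob.unit_counts[placement >= 0])
        self.block_units = np.bincount(placement[placement >= 0], minlength=k)
        self.bmin = np.empty((k, p))
        self.bmax = np.empty((k, p))
        for b in range(k):
            self._recompute_minmax(b)

    def _recompute_minmax(self, b: int) -> None:
        members = self.placement == b
        if members.any():
            self.bmin[b] = self.prob.unit_min[members].min(axis=0)
            self.bmax[b] = self.prob.unit_max[members].max(axis=0)
        else:
            self.bmin[b] = np.inf
            self.bmax[b] = -np.inf

    def move(self, i: int, b: int) -> None:
        """Move unit i to block b (b = -1 removes it)."""
        src = self.placement[i]
        if src == b:
            return
        self.placement[i] = b
        if src >= 0:
            self.block_sums[src] -= self.prob.unit_sums[i]
            self.block_counts[src] -= self.prob.unit_counts[i]
            self.block_units[src] -= 1
            self._recompute_minmax(src)
        if b >= 0:
            self.block_sums[b] += self.prob.unit_sums[i]
            self.block_counts[b] += self.prob.unit_counts[i]
            self.block_units[b] += 1
            self.bmin[b] = np.minimum(self.bmin[b], self.prob.unit_min[i])
            self.bmax[b] = np.maximum(self.bmax[b], self.prob.unit_max[i])

    def objective(self) -> float:
        prob = self.prob
        with np.errstate(invalid="ignore"):
            means = self.block_sums / self.block_counts[:, None]
        dev = np.nan_to_num(means - prob.global_mean[None, :])
        balance = float((dev**2).mean())
        worst = float(np.abs(dev).max()) ** 2
        width = prob.cov_hi - prob.cov_lo
        span = (
            np.minimum(self.bmax, prob.cov_hi[None, :])
            - np.maximum(self.bmin, prob.cov_lo[None, :])
        ) / width[None, :]
        shortfall = np.clip(prob.coverage_target - np.clip(span, 0.0, 1.0), 0.0, None)
        coverage = float((shortfall**2).mean())
        size = (
            float(((self.block_counts - prob.target_size) ** 2).sum())
            / prob.target_size**2
        )
        return (
            balance
            + prob.max_dev_weight * worst
            + prob.coverage_weight * coverage
            + prob.size_penalty * size
        )

    def try_move(self, i: int, b: int) -> float:
        src = self.placement[i]
        self.move(i, b)
        value = self.objective()
        self.move(i, src)
        return value


def _refine(state: _BlockState, max_sweeps: int) -> None:
    """Local search: single-unit moves and pairwise swaps while improving."""
    n_units = len(state.prob.unit_counts)
    k = state.prob.k
    current = state.objective()
    for _ in range(max_sweeps):
        improved = False
        # single-unit moves (never emptying a block)
        for i in range(n_units):
            src = state.placement[i]
            if state.block_units[src] <= 1:
                continue
            best_b, best_obj = src, current
            for b in range(k):
                if b == src:
                    continue
                cand = state.try_move(i, b)
                if cand < best_obj - 1e-12:
                    best_b, best_obj = b, cand
            if best_b != src:
                state.move(i, best_b)
                current = best_obj
                improved = True
        # pairwise swaps between blocks
        for i in range(n_units):
            for j in range(i + 1, n_units):
                bi, bj = state.placement[i], state.placement[j]
                if bi == bj:
                    continue
                state.move(i, bj)
                state.move(j, bi)
                cand = state.objective()
                if cand < current - 1e-12:
                    current = cand
                    improved = True
                else:
                    state.move(j, bj)
                    state.move(i, bi)
        if not improved:
            break


def _anneal(
    state: _BlockState,
    rng: np.random.Generator,
    iters: int,
    temp0: float = 0.05,
) -> np.ndarray:
    """Seeded simulated annealing over single-unit reassignments."""
    n_units = len(state.prob.unit_counts)
    k = state.prob.k
    current = state.objective()
    best = current
    best_placement = state.placement.copy()
    for it in range(iters):
        temp = temp0 * (1.0 - it / iters)
        i = int(rng.integers(n_units))
        b = int(rng.integers(k))
        src = state.placement[i]
        if b == src or state.block_units[src] <= 1:
            continue
        state.move(i, b)
        cand = state.objective()
        accept = cand < current or rng.random() < np.exp(
            -(cand - current) / max(temp, 1e-9)
        )
        if accept:
            current = cand
            if cand < best:
                best = cand
                best_placement = state.placement.copy()
        else:
            state.move(i, src)
    return best_placement


def assign_blocks(
    units: list[SamplingUnit],
    covariates: CovariateTable,
    k: int = 10,
    seed: int = 0,
    size_penalty: float = 0.3,
    max_dev_weight: float = 30.0,
    coverage_weight: float = 100.0,
    coverage_target: float = 0.95,
    coverage_quantiles: tuple[float, float] = (0.05, 0.95),
    refine_sweeps: int = 8,
    max_size_ratio: float = 1.5,
    n_restarts: int = 2,
    anneal_iters: int = 40000,
) -> BlockAssignment:
    """Group sampling units into k blocks with balanced covariate means.

    Greedy size-ordered assignment: the k largest units seed the k
    blocks, then each remaining unit (largest first) is placed into the
    block that minimises a global objective — mean-square and worst-case
    deviation of block means from the global covariate means, a
    range-coverage shortfall term (every block should span at least
    ``coverage_target`` of each covariate's central range, bounded by
    ``coverage_quantiles``), and a ``size_penalty``-weighted block-size
    imbalance term — subject to a soft cap of ``max_size_ratio`` times
    the average block size.  Seeded simulated annealing over single-unit
    reassignments, followed by local move/swap sweeps (never emptying a
    block), then refines the assignment; the construction is repeated
    ``n_restarts`` times and the best objective wins, deterministically
    for a given seed.  Every cell of a unit shares its block, so
    train/test sets built from blocks are spatially segregated.
    """
    if len(units) < k:
        raise ValueError(f"need at least k={k} sampling units, got {len(units)}")
    X = covariates.data
    names = covariates.names

    n_units = len(units)
    unit_sums = np.zeros((n_units, len(names)))
    unit_counts = np.zeros(n_units)
    unit_min = np.full((n_units, len(names)), np.inf)
    unit_max = np.full((n_units, len(names)), -np.inf)
    for i, u in enumerate(units):
        cells = [c for c in u.cell_ids if c in X.index]
        if cells:
            sub = X.loc[cells, names]
            unit_sums[i] = sub.sum().to_numpy()
            unit_min[i] = sub.min().to_numpy()
            unit_max[i] = sub.max().to_numpy()
        unit_counts[i] = len(cells)

    lo = X[names].quantile(coverage_quantiles[0]).to_numpy()
    hi = X[names].quantile(coverage_quantiles[1]).to_numpy()
    width = hi - lo
    degenerate = width <= 0
    if degenerate.any():  # constant covariates cannot constrain coverage
        lo = np.where(degenerate, lo - 0.5, lo)
        hi = np.where(degenerate, hi + 0.5, hi)

    prob = _BlockProblem(
        unit_sums=unit_sums,
        unit_counts=unit_counts,
        unit_min=unit_min,
        unit_max=unit_max,
        global_mean=X[names].mean().to_numpy(),
        cov_lo=lo,
        cov_hi=hi,
        k=k,
        target_size=unit_counts.sum() / k,
        size_penalty=size_penalty,
        max_dev_weight=max_dev_weight,
        coverage_weight=coverage_weight,
        coverage_target=coverage_target,
    )
    order = sorted(range(n_units), key=lambda i: (-unit_counts[i], units[i].unit_id))
    cap = max_size_ratio * prob.target_size
    master = np.random.default_rng(seed)

    best_placement, best_obj = None, np.inf
    for restart in range(n_restarts):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        state = _BlockState(prob, np.full(n_units, -1, dtype=int))
        for pos, i in enumerate(order):
            if pos < k:
                candidates = [pos]  # largest k units seed the k blocks
            else:
                candidates = [
                    b
                    for b in range(k)
                    if state.block_counts[b] + unit_counts[i] <= cap
                ]
                if not candidates:
                    candidates = [int(state.block_counts.argmin())]
            scores = np.asarray([state.try_move(i, b) for b in candidates])
            if restart == 0:
                pick = int(scores.argmin())
            else:  # randomised greedy for restart diversity
                near = np.flatnonzero(scores <= scores.min() * 1.05 + 1e-12)
                pick = int(rng.choice(near))
            state.move(i, candidates[pick])

        placement = _anneal(state, rng, anneal_iters)
        state = _BlockState(prob, placement)
        _refine(state, refine_sweeps)
        o = state.objective()
        if o < best_obj - 1e-12:
            best_obj, best_placement = o, state.placement.copy()
    placement = best_placement

    unit_to_block = {units[i].unit_id: int(placement[i]) + 1 for i in range(len(units))}
    cell_rows = []
    for u in units:
        for c in u.cell_ids:
            cell_rows.append((c, unit_to_block[u.unit_id]))
    cell_to_block = (
        pd.DataFrame(cell_rows, columns=["cell_id", "block"])
        .set_index("cell_id")["block"]
        .sort_index()
    )

    report = _balance_report(cell_to_block, covariates, k)
    return BlockAssignment(
        unit_to_block=unit_to_block,
        cell_to_block=cell_to_block,
        units=units,
        k=k,
        balance_report=report,
    )


def _balance_report(
    cell_to_block: pd.Series, covariates: CovariateTable, k: int
) -> pd.DataFrame:
    X = covariates.data
    rows = []
    gm = X.mean()
    gs = X.std(ddof=0)
    for b in range(1, k + 1):
        cells = cell_to_block.index[cell_to_block == b]
        cells = cells.intersection(X.index)
        sub = X.loc[cells]
        for name in covariates.names:
            rows.append(
                {
                    "block": b,
                    "covariate": name,
                    "n_cells": len(sub),
                    "mean": sub[name].mean(),
                    "min": sub[name].min(),
                    "max": sub[name].max(),
                    "global_mean": gm[name],
                    "global_sd": gs[name],
                    "mean_dev_sd": abs(sub[name].mean() - gm[name]) / gs[name]
                    if gs[name] > 0
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def blocked_folds(assignment: BlockAssignment) -> list[tuple[np.ndarray, np.ndarray]]:
    """k (train cells, test cells) pairs: fold i tests on block i."""
    folds = []
    all_cells = assignment.cell_to_block
    for b in range(1, assignment.k + 1):
        test = all_cells.index[all_cells == b].to_numpy()
        train = all_cells.index[all_cells != b].to_numpy()
        folds.append((train, test))
    return folds
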