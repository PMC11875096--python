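"""Labelled-site table assembly: outlier filtering and splitting.

Targets are methyl cation/anion affinities in kJ/mol. Outliers are removed
iteratively by Chauvenet's criterion; train/test separation uses a binned
split (equal-width target bins, 85% of each bin to train) so the target
distribution is preserved across partitions, and cross-validation folds are
dealt round-robin within bins for the same reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment",
    "chauvenet_filter",
    "binned_split",
    "stratified_folds",
    "drop_connectivity_changes",
]

TRAIN_FRACTION = 0.85
CHAUVENET_THRESHOLD = 0.01


@dataclass
class SplitAssignment:
    """Per-record bin, partition and (for training records) fold labels."""

    bin_id: np.ndarray  # int per record
    partition: np.ndarray  # "train" | "test" per record
    fold_id: np.ndarray = field(default=None)  # int per record, -1 for test
    seed: int = 0
    train_fraction: float = TRAIN_FRACTION
    n_bins: int = 10

    @property
    def train_mask(self) -> np.ndarray:
        return self.partition == "train"

    @property
    def test_mask(self) -> np.ndarray:
        return self.partition == "test"


def chauvenet_filter(
    targets,
    threshold: float = CHAUVENET_THRESHOLD,
    classical: bool = False,
) -> tuple[list[int], list[int]]:
    """Iterative Chauvenet outlier rejection.

    At each step the two-sided Gaussian tail probability of the most extreme
    remaining value, ``p = 2 * (1 - Phi(|x - mean| / std))``, is compared to
    ``threshold`` (1% by default); if it falls below, the value is removed
    and the process repeats until the most extreme value passes.

    With ``classical=True`` the traditional sample-size-scaled variant is
    used instead: remove while ``n * p < 0.5``.

    Returns ``(kept_indices, removed_indices)``; removed indices are in
    removal order.
    """
    x = np.asarray(targets, dtype=float)
    if x.size < 3:
        raise ValueError("chauvenet_filter needs at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("targets must be finite")
    kept = list(range(x.size))
    removed: list[int] = []
    while len(kept) >= 3:
        vals = x[kept]
        mu, sd = vals.mean(), vals.std(ddof=0)
        if sd == 0.0:
            break
        dev = np.abs(vals - mu) / sd
        worst = int(np.argmax(dev))
        p = 2.0 * norm.sf(dev[worst])
        crit = len(kept) * p < 0.5 if classical else p < threshold
        if not crit:
            break
        removed.append(kept.pop(worst))
    return kept, removed


def binned_split(
    targets,
    n_bins: int = 10,
    train_fraction: float = TRAIN_FRACTION,
    seed: int = 0,
    equal_count: bool = False,
) -> SplitAssignment:
    """Assign records to train/test within equal-width target bins.

    Within each bin a seeded shuffle sends ``round(train_fraction * n_bin)``
    records (half-up, i.e. ties toward train) to the training partition, so
    the target distribution is consistent across both partitions. Bins with
    fewer than 2 records go entirely to train.

    ``equal_count=True`` switches to quantile (equal-population) bins.
    """
    y = np.asarray(targets, dtype=float)
    if y.size == 0:
        raise ValueError("cannot split an empty table")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if equal_count:
        edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
    else:
        edges = np.linspace(y.min(), y.max(), n_bins + 1)
    # interior edges only; right-closed top bin
    bin_id = np.clip(np.digitize(y, edges[1:-1]), 0, len(edges) - 2)

    rng = np.random.default_rng(seed)
    partition = np.empty(y.size, dtype=object)
    for b in np.unique(bin_id):
        idx = np.flatnonzero(bin_id == b)
        if idx.size < 2:
            partition[idx] = "train"
            logger.warning("bin %d has %d record(s); assigned to train", b, idx.size)
            continue
        perm = rng.permutation(idx)
        n_train = int(np.floor(train_fraction * idx.size + 0.5))
        partition[perm[:n_train]] = "train"
        partition[perm[n_train:]] = "test"
    return SplitAssignment(
        bin_id=bin_id,
        partition=partition.astype(str),
        seed=seed,
        train_fraction=train_fraction,
        n_bins=n_bins,
    )


def stratified_folds(
    assignment: SplitAssignment, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Deal training records into ``k`` folds, stratified by bin.

    Within each bin, training records are shuffled (seeded) and dealt
    round-robin, so every fold's bin composition deviates from the bin's
    share by at most one record. Test records get fold id -1.
    """
    n_train = int(assignment.train_mask.sum())
    if k > n_train:
        raise ValueError(f"k={k} exceeds the training-set size {n_train}")
    rng = np.random.default_rng(seed)
    fold_id = np.full(assignment.bin_id.size, -1, dtype=int)
    for b in np.unique(assignment.bin_id):
        idx = np.flatnonzero((assignment.bin_id == b) & assignment.train_mask)
        perm = rng.permutation(idx)
        fold_id[perm] = np.arange(perm.size) % k
    assignment.fold_id = fold_id
    return fold_id


def drop_connectivity_changes(records, flags) -> tuple[list, int]:
    """Remove records whose reference calculation changed atom connectivity.

    ``flags`` is a boolean per record produced upstream (by the reference
    workflow, or by the fixture generator in tests). Returns the retained
    records and the number removed.
    """
    records = list(records)
    flags = list(flags)
    if len(records) != len(flags):
        raise ValueError("records and flags must have equal length")
    kept = [r for r, f in zip(records, flags) if not f]
    n_removed = len(records) - len(kept)
    if n_removed == len(records) and records:
        logger.warning("all %d records flagged for connectivity changes", n_removed)
    return kept, n_removed
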