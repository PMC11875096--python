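"""Sorted charge-shell descriptors for atomic sites.

A site descriptor concatenates partial charges of the query atom and of its
neighbours up to three bonds away into a fixed 53-value vector:

    [query : 1 | shell 1 : 4 | shell 2 : 12 | shell 3 : 36]

Each shell-1 slot holds up to 4 children of the query; each deeper slot
holds up to 3 children of its parent (the fourth valence points back up the
tree). Missing positions pad with 0.0, so the layout is the only arity
consistent with 1 + 4 + 4*3 + 12*3 = 53.

Children are ordered by a modified Cahn-Ingold-Prelog priority:

1. descending atomic number;
2. ties broken by repeatedly expanding each candidate's subtree one bond at
   a time (bond orders disregarded, already-included atoms skipped) and
   comparing the summed atomic numbers of the new frontier; an exhausted
   frontier contributes 0;
3. remaining ties broken by partial charge, descending.

Atoms already placed in an inner shell are never revisited (ring closures
pad instead), so the expansion is an acyclic tree rooted at the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .molprep import (
    FALLBACK_BACKEND,
    ChargeVector,
    MoleculeInputError,
    MoleculeRecord,
    compute_charges,
    parse_molecule,
    prepare,
)
from .sites import AtomicSite

logger = logging.getLogger(__name__)

__all__ = [
    "N_FEATURES",
    "SHELL_SIZES",
    "DescriptorVector",
    "cip_order",
    "build_shells",
    "featurize",
    "ChargeShellFeaturizer",
]

#: slot counts per shell: query, then 4, 4*3, 12*3
SHELL_SIZES = (1, 4, 12, 36)
N_FEATURES = sum(SHELL_SIZES)  # 53

#: children kept per parent at shell 1 vs deeper shells
_ARITY = {1: 4, 2: 3, 3: 3}

RULE1 = "rule1"
RULE2 = "rule2"
RULE3 = "rule3"


@dataclass
class DescriptorVector:
    """The 53-value sorted charge-shell feature vector for one site."""

    values: np.ndarray
    site: AtomicSite | None = None
    pad_value: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"descriptor must have exactly {N_FEATURES} values, "
                f"got shape {self.values.shape}"
            )

    def __len__(self):
        return N_FEATURES


def _frontier_sums(mol: MoleculeRecord, parent: int, child: int) -> list[int]:
    """Rule-2 key: summed atomic numbers of successive expansion frontiers
    of ``child``'s subtree, walking away from ``parent``."""
    z = [a[0] for a in mol.atoms]
    included = {parent, child}
    frontier = set(mol.neighbors(child)) - included
    sums = []
    while frontier:
        sums.append(sum(z[i] for i in frontier))
        included |= frontier
        frontier = {
            n for f in frontier for n in mol.neighbors(f) if n not in included
        }
    return sums


def _pad_lex(seqs: list[list[int]]) -> list[tuple]:
    """Pad integer sequences with zeros to a common length so exhausted
    subtrees compare as lexicographically smaller."""
    width = max((len(s) for s in seqs), default=0)
    return [tuple(s + [0] * (width - len(s))) for s in seqs]


def cip_order(
    mol: MoleculeRecord,
    parent: int,
    children: list[int],
    charges: ChargeVector,
) -> tuple[list[int], list[str]]:
    """Order ``children`` of ``parent`` by modified CIP priority.

    Returns the ordered child indices and, aligned with them, the rule that
    fixed each child's position (``rule1`` when atomic number alone was
    unique, ``rule2`` when frontier sums broke the tie, ``rule3`` when
    charges did). Fully deterministic; equal-key children keep input order.
    """
    if not children:
        return [], []
    z = [a[0] for a in mol.atoms]
    groups: dict[int, list[int]] = {}
    for c in children:
        groups.setdefault(z[c], []).append(c)

    ordered: list[int] = []
    tags: list[str] = []
    for zval in sorted(groups, reverse=True):
        group = groups[zval]
        if len(group) == 1:
            ordered.append(group[0])
            tags.append(RULE1)
            continue
        seqs = _pad_lex([_frontier_sums(mol, parent, c) for c in group])
        by_seq: dict[tuple, list[int]] = {}
        for c, s in zip(group, seqs):
            by_seq.setdefault(s, []).append(c)
        for seq in sorted(by_seq, reverse=True):
            sub = by_seq[seq]
            if len(sub) == 1:
                ordered.append(sub[0])
                tags.append(RULE2)
            else:
                # stable: equal charges keep canonical input order
                sub_sorted = sorted(
                    sub, key=lambda c: -float(charges.values[c])
                )
                ordered.extend(sub_sorted)
                tags.extend([RULE3] * len(sub_sorted))
    return ordered, tags


def build_shells(
    mol: MoleculeRecord,
    query: int,
    charges: ChargeVector,
    depth: int = 3,
) -> list[list[int | None]]:
    """Expand ordered neighbour shells around ``query`` up to ``depth`` bonds.

    Returns ``[ [query], shell1, shell2, shell3 ]`` where each shell is a
    slotted list (``None`` marks a pad position). Shell *k* reserves a fixed
    number of child slots per shell *k-1* slot — including pad parents,
    whose children are all pads — so slot positions are stable.
    """
    if query >= mol.n_atoms:
        raise MoleculeInputError(
            f"query atom {query} out of range for {mol.smiles!r}"
        )
    visited = {query}
    shells: list[list[int | None]] = [[query]]
    parents: list[tuple[int | None, int | None]] = [(None, query)]
    for level in range(1, depth + 1):
        arity = _ARITY[level]
        slots: list[int | None] = []
        next_parents: list[tuple[int | None, int | None]] = []
        for parent, atom in parents:
            if atom is None:
                children: list[int | None] = [None] * arity
            else:
                cand = [n for n in mol.neighbors(atom) if n not in visited]
                ordered, _ = cip_order(mol, atom, cand, charges)
                if len(ordered) > arity:
                    logger.warning(
                        "atom %d of %s has %d unvisited neighbours; keeping "
                        "the %d highest-priority",
                        atom, mol.smiles, len(ordered), arity,
                    )
                    ordered = ordered[:arity]
                visited.update(ordered)
                children = list(ordered) + [None] * (arity - len(ordered))
            slots.extend(children)
            next_parents.extend((atom, c) for c in children)
        shells.append(slots)
        parents = next_parents
    return shells


def featurize(
    site: AtomicSite | int,
    mol: MoleculeRecord,
    charges: ChargeVector | None = None,
) -> DescriptorVector:
    """Build the 53-value sorted charge-shell descriptor for one site."""
    if charges is None:
        charges = mol.charges
    if charges is None:
        raise MoleculeInputError("charges must be computed before featurizing")
    query = site.atom_index if isinstance(site, AtomicSite) else int(site)
    shells = build_shells(mol, query, charges)
    values = np.zeros(N_FEATURES, dtype=float)
    pos = 0
    for shell in shells:
        for atom in shell:
            if atom is not None:
                values[pos] = float(charges.values[atom])
            pos += 1
    assert pos == N_FEATURES
    return DescriptorVector(
        values=values, site=site if isinstance(site, AtomicSite) else None
    )


class ChargeShellFeaturizer(BaseEstimator, TransformerMixin):
    """Transform ``(smiles, atom_index)`` pairs into 53-dim descriptors.

    Parameters
    ----------
    backend : str, default="gasteiger"
        Charge backend; ``"xtb-cm5"`` requires the semiempirical engine.
    seed : int, default 61453
        Conformer-embedding seed (only used by geometry-dependent backends).

    Stateless apart from a per-instance molecule cache; ``fit`` is a no-op
    kept for pipeline compatibility.
    """

    def __init__(self, backend: str = FALLBACK_BACKEND, seed: int = 0xF00D):
        self.backend = backend
        self.seed = seed

    def fit(self, X=None, y=None):
        self._cache_: dict[str, MoleculeRecord] = {}
        return self

    def _prepared(self, smiles: str) -> MoleculeRecord:
        if not hasattr(self, "_cache_"):
            self._cache_ = {}
        if smiles not in self._cache_:
            self._cache_[smiles] = prepare(
                smiles, backend=self.backend, seed=self.seed
            )
        return self._cache_[smiles]

    def transform(self, X) -> np.ndarray:
        """``X``: iterable of ``AtomicSite`` or ``(smiles, atom_index)``.

        Returns an ``(n, 53)`` float array.
        """
        rows = []
        for item in X:
            if isinstance(item, AtomicSite):
                smiles, idx = item.smiles, item.atom_index
            else:
                smiles, idx = item
            mol = self._prepared(smiles)
            rows.append(featurize(int(idx), mol).values)
        if not rows:
            return np.empty((0, N_FEATURES), dtype=float)
        return np.vstack(rows)


def featurize_smiles(
    smiles: str, atom_index: int, backend: str = FALLBACK_BACKEND
) -> DescriptorVector:
    """Convenience wrapper: parse, charge (fallback backend needs no
    geometry) and featurize a single site."""
    mol = parse_molecule(smiles)
    compute_charges(mol, backend=backend)
    return featurize(atom_index, mol)
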