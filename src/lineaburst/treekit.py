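"""Chronogram I/O and tree-shape primitives.

A :class:`Chronogram` is a rooted, (by default) binary, ultrametric tree
whose node ages are measured in Myr before present, with tips at age 0.
This module reads Newick and NEXUS tree files (via dendropy), derives
branching times and lineage-through-time curves, and draws seeded samples
from posterior tree sets.
"""
from __future__ import annotations

import logging
import os
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Chronogram",
    "BranchingTimes",
    "LttCurve",
    "TreeFormatError",
    "NotUltrametricError",
    "read_newick",
    "read_nexus_trees",
    "branching_times",
    "ltt",
    "sample_trees",
]


class TreeFormatError(ValueError):
    """Raised when a tree violates the chronogram contract."""


class NotUltrametricError(TreeFormatError):
    """Raised when root-to-tip path lengths disagree beyond tolerance.

    Carries a per-tip deviation report in :attr:`deviations`.
    """

    def __init__(self, message: str, deviations: dict[str, float]):
        super().__init__(message)
        self.deviations = deviations


class Chronogram:
    """Rooted binary ultrametric tree with node ages in Myr before present.

    Parameters
    ----------
    tree
        A ``dendropy.Tree`` with branch lengths. Ownership is taken; pass a
        clone if the original must stay untouched.
    tol
        Relative tolerance on the tip-age spread (relative to the crown
        age) beyond which the tree is rejected as non-ultrametric.
    resolve_polytomies
        If True, polytomies are resolved into zero-length bifurcations with
        a seeded tie-break; otherwise polytomies raise ``TreeFormatError``.
    seed
        Seed for the polytomy resolution order.

    Notes
    -----
    Node ages are computed from root-to-tip path lengths. Exported trees
    (e.g. from Bayesian dating software) carry rounding noise, so tip ages
    are normalized to exactly 0 after checking their spread against `tol`.
    """

    def __init__(self, tree: dendropy.Tree, tol: float = 1e-6,
                 resolve_polytomies: bool = False, seed: int | None = None,
                 info: dict | None = None):
        self.tree = tree
        self.tol = tol
        self.info = dict(info) if info else {}
        if any(len(nd.child_nodes()) > 2 for nd in tree.preorder_internal_node_iter()):
            if not resolve_polytomies:
                raise TreeFormatError(
                    "tree contains polytomies; pass resolve_polytomies=True "
                    "to resolve them (zero-length, seeded)")
            tree.resolve_polytomies(rng=random.Random(seed))
        self._assign_ages()

    def _assign_ages(self) -> None:
        tree = self.tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise TreeFormatError("tree has branches without lengths")
        depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            depth[nd] = depth[nd.parent_node] + nd.edge.length
        tips = [nd for nd in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise TreeFormatError("a chronogram needs at least 2 tips")
        tip_depths = np.array([depth[t] for t in tips])
        height = tip_depths.max()
        spread = height - tip_depths.min()
        if height <= 0:
            raise TreeFormatError("tree has zero height")
        if spread > self.tol * height:
            dev = {self._label(t): height - depth[t] for t in tips
                   if abs(height - depth[t]) > self.tol * height}
            raise NotUltrametricError(
                f"tip-age spread {spread:.6g} exceeds tolerance "
                f"{self.tol:.3g} x height {height:.6g}; deviating tips: "
                + ", ".join(f"{k}={v:.4g}" for k, v in sorted(dev.items())),
                deviations=dev)
        for nd in tree.preorder_node_iter():
            nd.age = 0.0 if nd.is_leaf() else height - depth[nd]
        self._tips = tips

    @staticmethod
    def _label(nd: dendropy.Node) -> str:
        if nd.taxon is not None and nd.taxon.label is not None:
            return nd.taxon.label
        return nd.label or "?"

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self._label(t) for t in self._tips]

    @property
    def crown_age(self) -> float:
        return self.tree.seed_node.age

    def internal_ages(self) -> np.ndarray:
        """Ages of internal nodes, sorted from oldest (crown) to youngest."""
        ages = [nd.age for nd in self.tree.preorder_internal_node_iter()]
        return np.sort(np.asarray(ages))[::-1]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def copy(self) -> "Chronogram":
        clone = self.tree.clone(depth=1)
        return Chronogram(clone, tol=self.tol, info=self.info)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Chronogram n_tips={self.n_tips} crown_age={self.crown_age:.4g}>"


@dataclass
class BranchingTimes:
    """Branching times of an ultrametric tree.

    ``ages`` holds t_2 >= t_3 >= ... >= t_n, where t_k is the age at which
    the reconstructed process goes from k-1 to k lineages (t_2 is the crown
    age). ``durations`` holds x_k = t_k - t_{k+1} with t_{n+1} = 0, the time
    during which exactly k lineages existed.
    """

    ages: np.ndarray
    durations: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ages = np.sort(np.asarray(self.ages, dtype=float))[::-1]
        shifted = np.append(self.ages[1:], 0.0)
        self.durations = self.ages - shifted

    @property
    def n(self) -> int:
        """Number of tips (one more than the number of internal nodes)."""
        return len(self.ages) + 1

    @property
    def crown_age(self) -> float:
        return float(self.ages[0])

    def lineage_time(self) -> float:
        """Total lineage-time S = sum_k k * x_k below the crown."""
        k = np.arange(2, self.n + 1)
        return float(np.sum(k * self.durations))

    def to_dataframe(self) -> pd.DataFrame:
        k = np.arange(2, self.n + 1)
        return pd.DataFrame({"k": k, "age": self.ages, "duration": self.durations})


@dataclass
class LttCurve:
    """Lineage-through-time step function: ages of steps and lineage counts.

    ``ages`` are branching-event ages sorted old -> young; ``counts[i]`` is
    the number of lineages from ``ages[i]`` (exclusive going rootward)
    until the next event.
    """

    ages: np.ndarray
    counts: np.ndarray

    def value_at(self, age: float) -> int:
        """Number of reconstructed lineages at a given age before present."""
        if age > self.ages[0]:
            return 1
        idx = np.searchsorted(-self.ages, -age, side="right") - 1
        return int(self.counts[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "n_lineages": self.counts})


def _tree_from_source(source: str, schema: str) -> dendropy.Tree:
    looks_like_data = ("(" in source and ";" in source)
    if looks_like_data and not os.path.exists(source):
        return dendropy.Tree.get(data=source, schema=schema,
                                 preserve_underscores=True)
    return dendropy.Tree.get(path=source, schema=schema,
                             preserve_underscores=True)


def read_newick(source: str | os.PathLike, tol: float = 1e-6,
                resolve_polytomies: bool = False,
                seed: int | None = None) -> Chronogram:
    """Read a chronogram from a Newick file path or literal Newick string."""
    tree = _tree_from_source(str(source), "newick")
    return Chronogram(tree, tol=tol, resolve_polytomies=resolve_polytomies,
                      seed=seed)


def read_nexus_trees(path: str | os.PathLike, tol: float = 1e-6,
                     resolve_polytomies: bool = False,
                     seed: int | None = None) -> list[Chronogram]:
    """Read all trees from a NEXUS trees block (translate tables honored)."""
    trees = dendropy.TreeList.get(path=str(path), schema="nexus",
                                  preserve_underscores=True)
    if len(trees) == 0:
        raise TreeFormatError(f"no trees found in {path}")
    return [Chronogram(t, tol=tol, resolve_polytomies=resolve_polytomies,
                       seed=seed) for t in trees]


def branching_times(chronogram: Chronogram) -> BranchingTimes:
    """Extract sorted branching times and inter-event durations."""
    return BranchingTimes(chronogram.internal_ages())


def ltt(chronogram: Chronogram) -> LttCurve:
    """Lineage-through-time curve with steps exactly at branching times."""
    ages = chronogram.internal_ages()
    counts = np.arange(2, len(ages) + 2)
    return LttCurve(ages=ages, counts=counts)


def sample_trees(trees: list[Chronogram], n: int = 100,
                 seed: int | None = None,
                 replace: bool = False) -> list[Chronogram]:
    """Seeded uniform sample of trees, without replacement by default."""
    if not replace and n > len(trees):
        raise ValueError(
            f"cannot sample {n} trees without replacement from {len(trees)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(trees), size=n, replace=replace)
    logger.info("sampled tree indices: %s", idx.tolist())
    return [trees[i] for i in idx]
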