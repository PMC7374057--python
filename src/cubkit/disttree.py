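"""Distances between modal codon usages and neighbor-joining trees.

The distance between two usage profiles is an amino-acid-frequency-weighted
per-family L1 difference: D = sum_aa m_aa * 0.5 * sum_{c in family} |cuf1(c)
- cuf2(c)| with m_aa the mean of the two amino-acid frequencies, so rare
amino acids contribute little.  Trees are built with Saitou-Nei neighbor
joining with deterministic tie-breaking and Phylip-style handling of negative
branch lengths (clamped to zero, deficit moved to the sibling branch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .code import GeneticCode, default_code
from .core import UsageProfile


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix has a nonzero diagonal")
        if (v < 0).any():
            raise ValueError("distance matrix has negative entries")
        self.values = v

    def entry(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def usage_distance(p1: UsageProfile, p2: UsageProfile,
                   code: GeneticCode | None = None) -> float:
    """Weighted per-family L1 distance between two usage profiles."""
    code = code or default_code()
    total = 0.0
    shared = 0
    for aa in code.amino_acids:
        fam = list(code.family(aa))
        if p1.cuf[fam].isna().any() or p2.cuf[fam].isna().any():
            continue
        shared += 1
        m_aa = 0.5 * (float(p1.aa_freq.get(aa, 0.0)) +
                      float(p2.aa_freq.get(aa, 0.0)))
        l1 = float((p1.cuf[fam] - p2.cuf[fam]).abs().sum())
        total += m_aa * 0.5 * l1
    if shared == 0:
        raise ValueError("profiles share no defined family")
    return total


def distance_matrix(profiles: Mapping[str, UsageProfile],
                    code: GeneticCode | None = None) -> DistanceMatrix:
    code = code or default_code()
    labels = tuple(profiles)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = usage_distance(profiles[labels[i]], profiles[labels[j]], code)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class UsageTree:
    root: TreeNode

    def leaf_names(self) -> tuple[str, ...]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return tuple(out)

    def newick(self) -> str:
        def quote(name: str | None) -> str:
            if not name:
                return ""
            if any(ch in name for ch in "(),:;[] \t'"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return quote(node.name)
            inner = ",".join(f"{fmt(child)}:{length:.10g}"
                             for child, length in node.children)
            return f"({inner}){quote(node.name)}"

        return fmt(self.root) + ";"

    def distance(self, a: str, b: str) -> float:
        """Path length between two leaves (for additivity checks)."""
        cum: dict[str, list[tuple[int, float]]] = {}

        def walk(node: TreeNode, dist: float,
                 trail: list[tuple[int, float]]) -> None:
            trail = trail + [(id(node), dist)]
            if node.is_leaf() and node.name in (a, b):
                cum[node.name] = trail
            for child, length in node.children:
                walk(child, dist + length, trail)

        walk(self.root, 0.0, [])
        if a not in cum or b not in cum:
            raise KeyError("leaf not found")
        ancestors_a = dict(cum[a])
        common = [dist for node_id, dist in cum[b] if node_id in ancestors_a]
        lca = common[-1]  # deepest shared ancestor on the root paths
        return cum[a][-1][1] + cum[b][-1][1] - 2.0 * lca


def nj_tree(dm: DistanceMatrix) -> UsageTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The minimal-Q pair with the lowest (i, j) index order is joined first;
    negative branch lengths are clamped to zero with the deficit moved to the
    sibling branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = (math.inf, -1, -1)
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if q < best[0] - 1e-15:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for other in active:
            if other in (i, j):
                continue
            dist = 0.5 * (d[i, other] + d[j, other] - dij)
            d[k, other] = d[other, k] = max(dist, 0.0)
        active = [x for x in active if x not in (i, j)] + [k]

    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    root = TreeNode(children=[(nodes[x], max(lx, 0.0)),
                              (nodes[y], max(ly, 0.0)),
                              (nodes[z], max(lz, 0.0))])
    return UsageTree(root=root)


def selection_ratio(natural: DistanceMatrix, simulated: DistanceMatrix,
                    from_label: str, to_label: str) -> float:
    """Ratio of a named natural distance to its simulated counterpart.

    Values above 1 indicate codon usages more divergent (positively adapted)
    in the natural data than under null evolution.
    """
    num = natural.entry(from_label, to_label)
    den = simulated.entry(from_label, to_label)
    if den == 0:
        raise ValueError("simulated distance is zero; ratio undefined")
    return num / den
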