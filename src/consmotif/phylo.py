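"""Distance-based phylogenetics: TN93 distances, neighbor-joining, bootstrap.

The TN93 model distinguishes purine transitions (A<->G), pyrimidine
transitions (C<->T) and transversions, with unequal base frequencies
estimated empirically from each sequence pair.  Trees are built with the
Saitou-Nei neighbor-joining agglomeration; branch support comes from a
nonparametric bootstrap that resamples codon columns of the alignment with
replacement and reports, for each internal bipartition of the point tree,
the percentage of replicate trees containing it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codon_align import CodonAlignment

log = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_NT = ("A", "C", "G", "T")


class SaturationWarning(UserWarning):
    pass


def tn93_distance(a: str, b: str, cap: float = 5.0) -> float:
    """Tamura-Nei (1993) distance between two equal-length gapped rows.

    Sites where either row is not a plain nucleotide are excluded pairwise.
    Base frequencies are the empirical frequencies pooled over the two rows
    at the comparable sites.  If a logarithm argument is non-positive
    (saturation), the configured `cap` (substitutions/site) is returned with
    a warning instead of aborting.
    """
    if len(a) != len(b):
        raise ValueError(f"rows differ in length ({len(a)} vs {len(b)})")
    counts = {nt: 0 for nt in _NT}
    n = 0
    p1 = p2 = q = 0  # purine transitions, pyrimidine transitions, transversions
    for x, y in zip(a, b):
        if x not in counts or y not in counts:
            continue
        n += 1
        counts[x] += 1
        counts[y] += 1
        if x == y:
            continue
        pair = {x, y}
        if pair <= _PURINES:
            p1 += 1
        elif pair <= _PYRIMIDINES:
            p2 += 1
        else:
            q += 1
    if n == 0:
        raise ValueError("no comparable (gap-free) sites between the two rows")
    if p1 == p2 == q == 0:
        return 0.0

    total = 2 * n
    fA, fC, fG, fT = (counts[nt] / total for nt in _NT)
    fR, fY = fA + fG, fC + fT
    P1, P2, Q = p1 / n, p2 / n, q / n

    k1 = 2.0 * fA * fG / fR if fR > 0 else 0.0
    k2 = 2.0 * fC * fT / fY if fY > 0 else 0.0
    k3 = 2.0 * (fR * fY - (fA * fG * fY / fR if fR > 0 else 0.0) - (fC * fT * fR / fY if fY > 0 else 0.0))

    def _term(coef: float, arg: float) -> float | None:
        if coef == 0.0:
            return 0.0
        if arg <= 0.0:
            return None
        return -coef * math.log(arg)

    w1 = 1.0 - P1 / k1 - Q / (2.0 * fR) if k1 > 0 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * fY) if k2 > 0 else 1.0
    w3 = 1.0 - Q / (2.0 * fR * fY) if fR > 0 and fY > 0 else 1.0

    terms = [_term(k1, w1), _term(k2, w2), _term(k3, w3)]
    if any(t is None for t in terms):
        log.warning("TN93 saturation (log argument <= 0); returning cap %.2f", cap)
        return cap
    d = sum(terms)  # type: ignore[arg-type]
    if d > cap:
        log.warning("TN93 distance %.3f exceeds cap; returning cap %.2f", d, cap)
        return cap
    return max(d, 0.0)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    def write_phylip(self, path: str | Path) -> None:
        """PHYLIP square (lower+upper) format, names padded to 10 chars."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.D):
                fh.write(f"{name[:10]:<10}  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def tn93_matrix(rows: Sequence[str], ids: Sequence[str], cap: float = 5.0) -> DistanceMatrix:
    """All-pairs TN93 distances over gapped nucleotide rows."""
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tn93_distance(rows[i], rows[j], cap=cap)
    return DistanceMatrix(tuple(ids), D)


# ---------------------------------------------------------------------------
# trees


@dataclass
class Node:
    """Minimal tree node: leaves carry a name, internal nodes may carry support."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


@dataclass
class PhyloTree:
    """Unrooted tree (root is an arbitrary internal trifurcation)."""

    root: Node

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]  # type: ignore[misc]

    def to_newick(self) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{_fmt_len(node.length)}"
            inner = ",".join(rec(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{_fmt_len(node.length)}"

        inner = ",".join(rec(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:g}"
        return f"({inner}){label};"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each as the side NOT containing the
        lexicographically smallest leaf (a rooting-free normal form)."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def rec(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])  # type: ignore[list-item]
            side = frozenset().union(*(rec(c) for c in node.children))
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(all_leaves - side if anchor in side else side)
            return side

        for c in self.root.children:
            rec(c)
        return out

    def internal_nodes(self) -> list[Node]:
        out = []

        def rec(node: Node) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    rec(c)

        rec(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q-matrix minimisation are broken by the lowest (i, j) index
    pair; negative branch-length estimates are clamped to zero with the
    deficit logged.  The returned tree is unrooted (trifurcating root).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError(f"neighbor joining needs at least 3 taxa, got {n}")
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    D = dm.D.astype(float).copy()
    active = list(range(n))

    def clamp(x: float, context: str) -> float:
        if x < 0:
            log.debug("negative branch length %.4g clamped to 0 (%s)", x, context)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                qij = (r - 2) * D[i, j] - R[i] - R[j]
                if best is None or qij < best[0] - 1e-12:
                    best = (qij, i, j)
        _, i, j = best  # type: ignore[misc]
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, f"join {i},{j}"), clamp(lj, f"join {i},{j}")
        nodes[i].length, nodes[j].length = li, lj
        new = Node(children=[nodes[i], nodes[j]])
        # reuse slot i for the merged node
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = new
        active.remove(j)

    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]), "final")
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]), "final")
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]), "final")
    nodes[a].length, nodes[b].length, nodes[c].length = la, lb, lc
    return PhyloTree(Node(children=[nodes[a], nodes[b], nodes[c]]))


def tree_path_lengths(tree: PhyloTree) -> dict[frozenset[str], float]:
    """Leaf-to-leaf path lengths (for checking additivity)."""
    dists: dict[frozenset[str], float] = {}

    def rec(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}  # type: ignore[dict-item]
        sub = [rec(c) for c in node.children]
        for ci, c in enumerate(node.children):
            for name in sub[ci]:
                sub[ci][name] += c.length
        for x in range(len(sub)):
            for y in range(x + 1, len(sub)):
                for nx, dx in sub[x].items():
                    for ny, dy in sub[y].items():
                        dists[frozenset((nx, ny))] = dx + dy
        merged: dict[str, float] = {}
        for s in sub:
            merged.update(s)
        return merged

    rec(tree.root)
    return dists


def bootstrap_supports(
    aln: CodonAlignment,
    n_reps: int = 500,
    seed: int | None = None,
    cap: float = 5.0,
    max_dropped_frac: float = 0.10,
) -> PhyloTree:
    """Point NJ tree with bootstrap supports on its internal bipartitions.

    Codon columns are resampled with replacement per replicate; replicates
    whose distance matrix cannot be computed are dropped (hard error if more
    than `max_dropped_frac` of them fail).  Supports are percentages in
    [0, 100] of the surviving replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = list(aln.ids)
    point = nj_tree(tn93_matrix(aln.nucleotide_rows(), ids, cap=cap))
    target_bips = point.bipartitions()
    counts = {bip: 0 for bip in target_bips}
    m = aln.n_positions
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        sub = aln.codons[:, cols]
        rows = ["".join(r) for r in sub]
        try:
            rep_tree = nj_tree(tn93_matrix(rows, ids, cap=cap))
        except ValueError as exc:
            dropped += 1
            log.warning("bootstrap replicate dropped: %s", exc)
            continue
        for bip in rep_tree.bipartitions():
            if bip in counts:
                counts[bip] += 1
    if dropped > max_dropped_frac * n_reps:
        raise RuntimeError(f"{dropped}/{n_reps} bootstrap replicates failed")
    kept = n_reps - dropped

    all_leaves = frozenset(point.leaf_names)
    anchor = min(all_leaves)

    def annotate(node: Node, side: frozenset[str]) -> None:
        if 2 <= len(side) <= len(all_leaves) - 2:
            bip = all_leaves - side if anchor in side else side
            node.support = 100.0 * counts[bip] / kept

    def rec(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])  # type: ignore[list-item]
        side = frozenset().union(*(rec(c) for c in node.children))
        annotate(node, side)
        return side

    for c in point.root.children:
        rec(c)
    return point
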