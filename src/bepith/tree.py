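"""Sample trees from multiregional presence/absence profiles.

Each variant's presence pattern over samples is a binary character. A
perfect phylogeny exists when all patterns are pairwise compatible (nested
or disjoint); the tree is then the Hasse diagram of the laminar family of
patterns. Real profiles contain conflicts, which are resolved greedily:
characters are processed in order of descending sharing count (ties by
lexicographic pattern) and a pattern is admitted as a clade only if it is
compatible with every clade admitted before it; a rejected (homoplastic)
character is charged to the minimal set of admitted clades covering it.
The trunk is the edge above the root clade and carries the founder
characters (patterns spanning all samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


@dataclass
class CladeNode:
    samples: frozenset
    children: list = field(default_factory=list)
    mutations: int = 0            # characters mapped to the edge above this node

    @property
    def is_leaf(self) -> bool:
        return len(self.children) == 0


@dataclass
class SampleTree:
    """Rooted tree over samples; the trunk (edge above the root) carries
    the founder mutations."""

    root: CladeNode
    sample_ids: list
    trunk_mutations: int = 0
    homoplasy_count: int = 0      # extra origins beyond one per character

    def clades(self) -> list[frozenset]:
        """All proper clades (every node below the root, leaves included)."""
        out = []

        def walk(node):
            for ch in node.children:
                out.append(ch.samples)
                walk(ch)

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(node):
            if node.is_leaf and len(node.samples) == 1:
                (name,) = node.samples
                return f"{name}:{node.mutations}"
            inner = ",".join(fmt(ch) for ch in node.children)
            return f"({inner}):{node.mutations}"

        root = self.root
        inner = ",".join(fmt(ch) for ch in root.children)
        return f"({inner}):{self.trunk_mutations};"


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def build_tree(presence: np.ndarray, sample_ids: list) -> SampleTree:
    """Greedy compatibility tree from a variants x samples boolean matrix.

    Deterministic: characters sorted by (descending sample count, then
    lexicographic presence pattern over the given sample order).
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.ndim != 2 or presence.shape[1] < 2:
        raise ValueError("need a variants x samples matrix with >= 2 samples")
    n_samples = presence.shape[1]
    all_set = frozenset(sample_ids)

    # tally characters by pattern
    counts: dict[tuple, int] = {}
    for row in presence:
        if not row.any():
            continue
        pat = tuple(bool(x) for x in row)
        counts[pat] = counts.get(pat, 0) + 1

    full = tuple([True] * n_samples)
    trunk = counts.pop(full, 0)

    ordered = sorted(
        counts.items(), key=lambda kv: (-sum(kv[0]), tuple(not b for b in kv[0]))
    )

    admitted: dict[frozenset, int] = {}
    homoplastic: list[tuple[frozenset, int]] = []
    for pat, cnt in ordered:
        s = frozenset(sid for sid, b in zip(sample_ids, pat) if b)
        if all(_compatible(s, t) for t in admitted):
            admitted[s] = admitted.get(s, 0) + cnt
        else:
            homoplastic.append((s, cnt))

    # every sample gets a leaf clade
    for sid in sample_ids:
        admitted.setdefault(frozenset([sid]), 0)

    # Hasse diagram of the laminar family
    nodes = {s: CladeNode(samples=s, mutations=m) for s, m in admitted.items()}
    root = CladeNode(samples=all_set, mutations=0)
    pool = {all_set: root, **nodes}
    for s in sorted(nodes, key=len):  # attach small clades to their minimal superset
        supersets = [t for t in pool if s < t]
        parent = min(supersets, key=len)
        pool[parent].children.append(nodes[s])
    # deterministic child order
    def sort_children(node):
        node.children.sort(key=lambda ch: sorted(map(str, ch.samples)))
        for ch in node.children:
            sort_children(ch)

    sort_children(root)

    # charge homoplastic characters to the minimal admitted cover
    homoplasy = 0
    for s, cnt in homoplastic:
        remaining = set(s)
        origins = 0
        for t in sorted(nodes, key=len, reverse=True):
            if t <= remaining:
                nodes[t].mutations += cnt
                remaining -= t
                origins += 1
            if not remaining:
                break
        homoplasy += cnt * max(0, origins - 1)

    return SampleTree(
        root=root,
        sample_ids=list(sample_ids),
        trunk_mutations=trunk,
        homoplasy_count=homoplasy,
    )


def branch_bipartitions(tree: SampleTree) -> list[tuple[frozenset, frozenset]]:
    """Sample bipartitions induced by every branch below the first branching
    point: for each proper clade, {its leaves} vs {the rest}. Complementary
    duplicates are merged and empty sides dropped."""
    all_set = frozenset(tree.sample_ids)
    seen = set()
    out = []
    for clade in tree.clades():
        rest = all_set - clade
        if not clade or not rest:
            continue
        key = frozenset((clade, rest))
        if key in seen:
            continue
        seen.add(key)
        out.append((clade, rest))
    return out


def _binary_topologies(leaves: tuple):
    """All rooted binary topologies over the leaf set, as clade frozensets."""
    if len(leaves) == 1:
        yield frozenset([frozenset(leaves)])
        return
    first, rest = leaves[0], leaves[1:]
    # split: subset containing `first` vs complement (avoids double counting)
    for k in range(0, len(rest)):
        for right in combinations(rest, len(rest) - k):
            left = (first,) + tuple(x for x in rest if x not in right)
            if not right or not left:
                continue
            for lt in _binary_topologies(left):
                for rt in _binary_topologies(tuple(right)):
                    yield lt | rt | {frozenset(leaves)}


def exhaustive_parsimony_trees(presence: np.ndarray, sample_ids: list):
    """Brute-force oracle: score every rooted binary topology on <= 6
    leaves by the number of character origins (a character charged to the
    minimal clade cover of its presence set) and return the minimum cost
    with the clade families achieving it. Intended for tests only."""
    presence = np.asarray(presence, dtype=bool)
    n = presence.shape[1]
    if n > 6:
        raise ValueError("oracle limited to <= 6 samples")
    samples = list(sample_ids)
    patterns = []
    for row in presence:
        s = frozenset(sid for sid, b in zip(samples, row) if b)
        if s and len(s) < n:
            patterns.append(s)

    def cost(clades):
        fam = sorted(clades, key=len, reverse=True)
        total = 0
        for pat in patterns:
            remaining = set(pat)
            origins = 0
            for t in fam:
                if t <= remaining:
                    origins += 1
                    remaining -= t
                if not remaining:
                    break
            total += origins
        return total

    best_cost, best = None, []
    for topo in _binary_topologies(tuple(samples)):
        c = cost(topo)
        if best_cost is None or c < best_cost:
            best_cost, best = c, [topo]
        elif c == best_cost:
            best.append(topo)
    return best_cost, best
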