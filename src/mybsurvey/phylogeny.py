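"""Domain-alignment phylogenetics: p-distance, neighbor joining, bootstrap
supports, and anchor-guided subfamily assignment.

Distances are proportion distances (p-distance) with pairwise deletion:
each sequence pair is compared only over columns where both are non-gap.
Trees are built with the Saitou–Nei neighbor-joining algorithm using the
Studier–Keppler Q criterion; ties are broken by the lexicographically
smallest pair of cluster labels so that results are independent of input
order.  Negative branch lengths are clamped to zero.

Subfamily labels propagate from anchor taxa (reference proteins of known
subfamily) to queries through the smallest supported clade containing both;
queries in strongly supported (100%) anchor-free clades found novel
subfamilies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .repeat_scanner import MybAssignment, RepeatProfile

GAP = "-"


class UndefinedDistance(ValueError):
    """Raised when a sequence pair shares fewer comparable sites than the
    minimum (no common sites for the sequence pair)."""


@dataclass
class DomainAlignment:
    """Induced alignment of MYB domains over repeat-slot × profile-column
    coordinates.  Proteins with fewer repeats than the slot count are
    right-aligned so 2R and 3R proteins share their last two repeat slots."""

    ids: list[str]
    rows: list[str]
    n_slots: int
    repeat_length: int

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "DomainAlignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return DomainAlignment(self.ids, rows, self.n_slots, self.repeat_length)


@dataclass
class SubfamilyCall:
    protein_id: str
    label: str
    anchor_ids: tuple[str, ...]
    clade_support: float


def induced_domain_alignment(assignments: Sequence[MybAssignment],
                             proteins: Mapping[str, object],
                             profile: RepeatProfile) -> DomainAlignment:
    """Place each protein's repeats on a repeat-slot × profile-column grid.

    Repeats are right-aligned into the slots (the C-terminal repeat goes in
    the last slot) and residues fall at the profile columns recorded during
    scanning; everything else is gap.  Proteins with no detected repeats
    are excluded.
    """
    usable = [a for a in assignments if a.repeats]
    if len(usable) < len(assignments):
        import warnings
        dropped = [a.protein_id for a in assignments if not a.repeats]
        warnings.warn(f"excluded {len(dropped)} protein(s) without repeats "
                      f"from the domain alignment: {dropped[:5]}", stacklevel=2)
    if not usable:
        raise ValueError("no proteins with detected repeats")
    n_slots = max(len(a.repeats) for a in usable)
    L = profile.length
    ids, rows = [], []
    for a in usable:
        seq = proteins[a.protein_id].sequence
        row = [GAP] * (n_slots * L)
        offset = n_slots - len(a.repeats)
        for s, rep in enumerate(a.repeats):
            base = (offset + s) * L
            for res_idx, col in rep.column_map.items():
                row[base + col] = seq[res_idx]
        ids.append(a.protein_id)
        rows.append("".join(row))
    return DomainAlignment(ids, rows, n_slots, L)


def p_distance(row_i: str, row_j: str, min_sites: int = 20
               ) -> tuple[float, int]:
    """Proportion of differing sites over pairwise-deleted columns.

    Returns (distance, comparable-site count); raises UndefinedDistance
    when fewer than ``min_sites`` columns are gap-free in both rows.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    a = np.frombuffer(row_i.encode(), dtype=np.uint8)
    b = np.frombuffer(row_j.encode(), dtype=np.uint8)
    gap = ord(GAP)
    both = (a != gap) & (b != gap)
    n_comp = int(both.sum())
    if n_comp < min_sites:
        raise UndefinedDistance(
            f"only {n_comp} comparable sites (min {min_sites})")
    diff = int((a[both] != b[both]).sum())
    return diff / n_comp, n_comp


def distance_matrix(alignment: DomainAlignment, min_sites: int = 20
                    ) -> tuple[list[str], np.ndarray]:
    """All pairwise p-distances.  Taxa involved in undefined pairs are
    iteratively removed (fewest-comparable first) until the matrix is
    complete; their ids are dropped from the returned taxon list."""
    ids, rows = list(alignment.ids), list(alignment.rows)
    n = len(ids)
    d = np.zeros((n, n))
    bad_counts = np.zeros(n, dtype=int)
    undefined = []
    for i, j in itertools.combinations(range(n), 2):
        try:
            d[i, j], _ = p_distance(rows[i], rows[j], min_sites)
            d[j, i] = d[i, j]
        except UndefinedDistance:
            undefined.append((i, j))
            bad_counts[i] += 1
            bad_counts[j] += 1
    keep = set(range(n))
    while undefined:
        worst = max(keep, key=lambda k: (bad_counts[k], ids[k]))
        keep.discard(worst)
        undefined = [(i, j) for i, j in undefined
                     if i != worst and j != worst]
    kept = sorted(keep)
    return [ids[k] for k in kept], d[np.ix_(kept, kept)]


def nj_tree(ids: Sequence[str], d: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    The pair minimising Q is joined; ties go to the lexicographically
    smallest (label_i, label_j) pair, where a cluster's label is its
    smallest member leaf.  Negative branch lengths are clamped to zero.
    Returns an unrooted binary tree (trifurcating root node).
    """
    n = len(ids)
    if n < 3:
        raise ValueError(f"need >=3 taxa, got {n}")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    nodes = [TreeNode(name=str(t)) for t in ids]
    labels = [str(t) for t in ids]
    D = d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), i, j)
            for i, j in ties if i < j
        )
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            dk = (D[i, k] + D[j, k] - dij) / 2.0
            D[i, k] = D[k, i] = dk
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = max((dij + dik - djk) / 2.0, 0.0)
    lj = max((dij + djk - dik) / 2.0, 0.0)
    lk = max((dik + djk - dij) / 2.0, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an (unrooted) tree, each encoded as the
    side not containing the lexicographically smallest leaf."""
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        if ref in side:
            side = frozenset(leaves - side)
        out.add(side)
    return out


def bootstrap_support(alignment: DomainAlignment, n_replicates: int = 100,
                      seed: int = 0, min_sites: int = 20,
                      max_retries: int = 10) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement per replicate; a replicate whose
    resampled alignment leaves some pair with too few comparable sites is
    redrawn (up to ``max_retries`` times) before being dropped.  Support is
    the percentage of replicates containing the same bipartition, attached
    to the original tree's internal nodes (``node.support``, also mirrored
    into the node name for newick output).
    """
    ids, d = distance_matrix(alignment, min_sites)
    tree = nj_tree(ids, d)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    n_used = 0
    for _ in range(n_replicates):
        rep_tree = None
        for _ in range(max_retries):
            rep = alignment.resample_columns(rng)
            rep_ids, rep_d = distance_matrix(rep, min_sites)
            if len(rep_ids) == len(ids):
                rep_tree = nj_tree(rep_ids, rep_d)
                break
        if rep_tree is None:
            continue
        n_used += 1
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        key = side if ref not in side else frozenset(leaves - side)
        support = 100.0 * counts.get(key, 0) / max(n_used, 1)
        node.support = support
        node.name = str(int(round(support)))
    return tree


def _supported_clades(tree: TreeNode) -> list[tuple[frozenset, float]]:
    """All clade sides (both orientations of every supported internal edge)
    with their supports, so that calls do not depend on the rooting."""
    leaves = frozenset(t.name for t in tree.tips())
    out = {}
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is None:
            continue
        below = frozenset(t.name for t in node.tips())
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        for side in (below, leaves - below):
            key = side
            out[key] = max(out.get(key, -1.0), support)
    return sorted(out.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))


def assign_subfamilies(tree: TreeNode, anchors: Mapping[str, str],
                       support_floor: float = 70.0,
                       new_support: float = 100.0) -> list[SubfamilyCall]:
    """Label query taxa by the subfamily of nearby anchors.

    For each query, the smallest clade with support >= ``support_floor``
    that contains it and at least one anchor provides the label when all
    its anchors agree; on conflict the next larger supported clade is
    tried.  Queries whose supported clades never reach an anchor are
    grouped by the largest fully supported (100%) anchor-free clade they
    share and labelled NEW-1, NEW-2, ... (numbered by descending clade
    size, then by smallest member id); a query with no such clade is
    labelled ``unclassified``.
    """
    leaf_names = {t.name for t in tree.tips()}
    missing = set(anchors) - leaf_names
    if missing:
        import warnings
        warnings.warn(f"{len(missing)} anchor(s) absent from the tree: "
                      f"{sorted(missing)[:5]}", stacklevel=2)
    anchors = {k: v for k, v in anchors.items() if k in leaf_names}
    queries = sorted(leaf_names - set(anchors))
    clades = _supported_clades(tree)
    anchor_set = set(anchors)

    calls: dict[str, SubfamilyCall] = {}
    new_groups: dict[frozenset, list[str]] = {}
    for q in queries:
        label, supp, aids = None, 0.0, ()
        for side, support in clades:
            if q not in side or support < support_floor:
                continue
            in_anchors = side & anchor_set
            if not in_anchors:
                continue
            labels = {anchors[a] for a in in_anchors}
            if len(labels) == 1:
                label = labels.pop()
                supp = support
                aids = tuple(sorted(in_anchors))
                break
            # conflicting anchor labels: widen to the next supported clade
        if label is not None:
            calls[q] = SubfamilyCall(q, label, aids, supp)
            continue
        # novel-subfamily route: largest 100-support anchor-free clade
        best = None
        for side, support in clades:
            if q in side and support >= new_support and not (side & anchor_set):
                if best is None or len(side) > len(best):
                    best = side
        if best is not None:
            new_groups.setdefault(best, []).append(q)
        else:
            calls[q] = SubfamilyCall(q, "unclassified", (), 0.0)

    for k, (side, members) in enumerate(
            sorted(new_groups.items(),
                   key=lambda kv: (-len(kv[0]), min(kv[1]))), start=1):
        for q in members:
            calls[q] = SubfamilyCall(q, f"NEW-{k}", (), new_support)
    return [calls[q] for q in queries]
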