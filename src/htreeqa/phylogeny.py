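"""Perfect and tristate semi-perfect phylogeny tree construction.

Trees are built from a binary matrix whose columns pairwise pass the
four-gamete test, using the classical perfect-phylogeny construction: every
column is recoded against the first sample's row (so that sample sits at the
root), constant columns are dropped, duplicate columns merge onto one
multi-labelled edge, and the remaining columns — pairwise nested or disjoint
— are attached along root-to-leaf paths in order of decreasing carrier
count. Samples whose selected-column states coincide with an internal node's
state are attached to that internal node rather than forced onto a pendant
leaf.

Rooting is a construction convenience only: all downstream logic (edge
splits, partitions) uses unrooted sample bipartitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .compatibility import CompatibleInterval
from .expansion import expand_column, four_gamete_pass_masks
from .genodata import GenotypeMatrix


@dataclass(frozen=True)
class Edge:
    """One tree edge: the node below it, its SNP-column labels, and the set
    of samples on its child side."""

    child: int
    labels: tuple[tuple[object, str], ...]  # (column id, expanded-column kind)
    side: frozenset[int]


@dataclass
class SemiPerfectTree:
    """Leaf-labelled tree with SNP-labelled edges and sample bipartitions.

    Node 0 is the construction root. ``edges[i]`` connects node
    ``edges[i].child`` (which is node ``i + 1``) to its parent; parents
    always have smaller node ids than children. Every sample is assigned to
    exactly one node (``sample_node``); internal nodes may host samples.
    """

    n_samples: int
    parent: list[int]  # parent[node]; parent[0] = -1
    edges: list[Edge]
    sample_node: list[int]
    sample_names: tuple[str, ...] | None = None
    node_samples: list[list[int]] = field(init=False)

    def __post_init__(self) -> None:
        self.node_samples = [[] for _ in range(len(self.parent))]
        for s, nd in enumerate(self.sample_node):
            self.node_samples[nd].append(s)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_label_ids(self, i: int) -> set[object]:
        return {cid for cid, _kind in self.edges[i].labels}

    def splits(self) -> set[frozenset[int]]:
        """Canonical unrooted splits: each edge's side not containing the
        smallest sample index."""
        ref = min(range(self.n_samples))
        all_samples = frozenset(range(self.n_samples))
        out = set()
        for e in self.edges:
            side = e.side if ref not in e.side else all_samples - e.side
            out.add(side)
        return out

    def partition_groups(
        self, removed_edges: Iterable[int]
    ) -> tuple[tuple[int, ...], ...]:
        """Sample groups of the components left after cutting the given
        edges. Exactly ``len(removed) + 1`` groups are returned, in
        component order; groups may be empty when a component holds no
        samples (callers filter by a minimum group size)."""
        removed = set(removed_edges)
        n_nodes = len(self.parent)
        comp = [0] * n_nodes
        next_comp = 1
        for node in range(1, n_nodes):
            if (node - 1) in removed:  # edge i has child node i + 1
                comp[node] = next_comp
                next_comp += 1
            else:
                comp[node] = comp[self.parent[node]]
        groups: list[list[int]] = [[] for _ in range(next_comp)]
        for s, nd in enumerate(self.sample_node):
            groups[comp[nd]].append(s)
        return tuple(tuple(g) for g in groups)

    def newick(self) -> str:
        """Newick rendering for inspection; samples attached to internal
        nodes appear as zero-length pendant leaves."""
        names = self.sample_names or tuple(
            f"s{i}" for i in range(self.n_samples)
        )
        children: list[list[int]] = [[] for _ in self.parent]
        for node in range(1, len(self.parent)):
            children[self.parent[node]].append(node)

        def render(node: int) -> str:
            parts = [f"{names[s]}:0.0" for s in self.node_samples[node]]
            parts += [render(ch) + ":1.0" for ch in children[node]]
            return "(" + ",".join(parts) + ")" if parts else ""

        return render(0) + ";"


def build_perfect_phylogeny(
    binary: np.ndarray,
    column_ids: Sequence[object] | None = None,
    *,
    sample_names: Sequence[str] | None = None,
) -> SemiPerfectTree:
    """Build the perfect phylogeny of a binary matrix (samples x columns).

    Requires every column pair to pass the four-gamete test (checked;
    raises ValueError otherwise). Duplicate unrooted splits merge onto one
    edge whose label set lists every contributing column; constant columns
    contribute no edge. Column ids may be bare ids or (id, kind) pairs; bare
    ids are stored with kind "s".
    """
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ValueError("binary matrix must be 2-D")
    m, k = binary.shape
    if m < 1:
        raise ValueError("need at least one sample")
    if column_ids is None:
        column_ids = list(range(k))
    labels = [
        cid if isinstance(cid, tuple) and len(cid) == 2 else (cid, "s")
        for cid in column_ids
    ]
    if len(labels) != k:
        raise ValueError("one column id per column required")

    full = (1 << m) - 1
    # recode against row 0 so the first sample carries state 0 everywhere
    # (complementing a column permutes the four gamete classes, so the
    # compatibility check below is unaffected by the recoding)
    masks: list[int] = []
    for c in range(k):
        mask = 0
        for i in np.flatnonzero(binary[:, c]):
            mask |= 1 << int(i)
        if binary[0, c]:
            mask ^= full
        masks.append(mask)

    for a in range(k):
        for b in range(a + 1, k):
            if not four_gamete_pass_masks(masks[a], masks[b], full):
                raise ValueError(
                    f"columns {labels[a]} and {labels[b]} fail the four-gamete "
                    "test; certify compatibility before building a tree"
                )

    # merge duplicate splits, drop constant columns, keep label order
    by_mask: dict[int, list[tuple[object, str]]] = {}
    order: list[int] = []
    for mask, lab in zip(masks, labels):
        if mask == 0:  # constant column: no edge
            continue
        if mask not in by_mask:
            by_mask[mask] = []
            order.append(mask)
        by_mask[mask].append(lab)

    seen_at = {mk: i for i, mk in enumerate(order)}
    uniq = sorted(order, key=lambda mk: (-bin(mk).count("1"), seen_at[mk]))

    # parent column = minimal strictly-containing column (last earlier one
    # in the size-descending order that contains it); containment chains are
    # guaranteed by pairwise compatibility after recoding
    parent_col: list[int] = []
    for idx, mask in enumerate(uniq):
        par = -1
        for idx2 in range(idx - 1, -1, -1):
            if mask & uniq[idx2] == mask:
                par = idx2
                break
        parent_col.append(par)

    parent = [-1] + [pc + 1 for pc in parent_col]
    edges = [
        Edge(
            child=idx + 1,
            labels=tuple(by_mask[mask]),
            side=frozenset(int(i) for i in range(m) if mask >> i & 1),
        )
        for idx, mask in enumerate(uniq)
    ]

    sample_node = []
    for s in range(m):
        bit = 1 << s
        node = 0
        for idx in range(len(uniq) - 1, -1, -1):  # smallest containing column
            if uniq[idx] & bit:
                node = idx + 1
                break
        sample_node.append(node)

    return SemiPerfectTree(
        n_samples=m,
        parent=parent,
        edges=edges,
        sample_node=sample_node,
        sample_names=tuple(sample_names) if sample_names is not None else None,
    )


def build_tristate_tree(
    matrix: GenotypeMatrix, interval: CompatibleInterval
) -> SemiPerfectTree:
    """Tristate semi-perfect phylogeny of a certified compatible interval.

    Equivalent to the perfect phylogeny of the selected two-of-three
    expanded columns, with edge labels mapped back to (marker index, kind).
    A SNP with all three alleles observed contributes two distinct
    non-constant splits; a SNP with two observed alleles contributes one.
    """
    sel = interval.selection
    cols: list[np.ndarray] = []
    ids: list[tuple[object, str]] = []
    for k, j in enumerate(sel.snp_indices):
        triple = expand_column(matrix.column(j))
        for kind in sel.kept_kinds(k):
            cols.append(triple.by_kind(kind))
            ids.append((j, kind))
    binary = (
        np.column_stack(cols)
        if cols
        else np.zeros((matrix.n_samples, 0), dtype=np.uint8)
    )
    return build_perfect_phylogeny(
        binary, ids, sample_names=matrix.samples
    )
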