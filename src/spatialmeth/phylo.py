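"""Sample phylogeny from methylation distances, and the anatomical spread path.

A neighbor-joining tree is built over the sample-by-sample distance
matrix (branch lengths in methylation-distance units), rooted on the
edge adjacent to the primary resection sample — the narrative being
that recurrent masses diverged from the original tumor.  Traversing
the rooted tree in preorder, visiting nearer children first, yields an
ordered hypothetical spread path; each traversal edge is annotated with
the Euclidean anatomical distance (mm) between the sites involved,
internal nodes standing at the centroid of their leaf descendants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import write_newick
from .matrices import SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class SamplePhylogeny:
    """Rooted tree whose leaves are the samples; branch lengths >= 0."""

    tree: TreeNode
    root_sample: str

    def __post_init__(self) -> None:
        leaves = {t.name for t in self.tree.tips()}
        if self.root_sample not in leaves:
            raise ValueError(f"root sample {self.root_sample!r} is not a leaf of the tree")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length in phylogeny")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def to_newick(self, path=None) -> str:
        return write_newick(self.tree, path)


def build_phylogeny(distances: pd.DataFrame, root_sample: str) -> SamplePhylogeny:
    """Neighbor-joining tree over samples, rooted at the primary sample.

    The distance matrix must be symmetric with a zero diagonal and
    non-negative entries.  Negative NJ branch lengths (a known artifact
    of the algorithm on non-additive data) are clamped to zero and
    logged.  The root is placed on the midpoint of the edge adjacent to
    ``root_sample``.
    """
    arr = distances.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-9):
        raise ValueError("distance matrix diagonal is not zero")
    ids = [str(s) for s in distances.index]
    if root_sample not in ids:
        raise ValueError(f"root sample {root_sample!r} not among samples")
    if len(ids) == 2:
        # NJ needs >= 3 taxa; a 2-sample tree is just the single edge
        d = float(arr[0, 1])
        tree = TreeNode.read([f"({ids[0]}:{d / 2},{ids[1]}:{d / 2});"])
        return SamplePhylogeny(tree=tree, root_sample=root_sample)

    unrooted = nj(DistanceMatrix(arr, ids))
    n_clamped = 0
    for node in unrooted.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", n_clamped)
    rooted = unrooted.root_by_outgroup([root_sample])
    return SamplePhylogeny(tree=rooted, root_sample=root_sample)


@dataclass
class SpreadPath:
    """Ordered traversal of the phylogeny with paired distances per edge.

    ``steps`` has one row per traversal edge: parent and child node
    names, methylation branch length, and anatomical Euclidean distance
    in mm between the nodes' (centroid) coordinates.
    """

    steps: pd.DataFrame

    def visit_order(self) -> list[str]:
        order = []
        for _, row in self.steps.iterrows():
            if not order:
                order.append(row["parent"])
            order.append(row["child"])
        return order

    def leaf_order(self) -> list[str]:
        """Samples in visit order (internal attachment nodes dropped)."""
        return [n for n in self.visit_order() if not n.startswith("node_")]

    def to_frame(self) -> pd.DataFrame:
        return self.steps.copy()


def infer_spread_path(phylogeny: SamplePhylogeny, meta: SampleMeta) -> SpreadPath:
    """Depth-first preorder walk of the phylogeny starting at the primary sample.

    The tree is traversed outward from the primary-sample leaf (its
    attachment point, a degree-2 node left by rooting on the pendant
    edge, is suppressed so branch lengths add up).  At every node the
    outgoing edges are followed in order of increasing methylation
    branch length (ties by node name), so nearer relatives are visited
    first.  Internal nodes inherit the coordinate centroid of the leaves
    beyond them; each traversal edge is annotated with the Euclidean
    anatomical distance (mm) between its endpoints.
    """
    tree = phylogeny.tree
    missing = [t.name for t in tree.tips() if t.name not in meta.sample_ids]
    if missing:
        raise ValueError(f"samples missing coordinates: {missing}")

    # undirected adjacency with degree-2 (rooting artifact) nodes suppressed
    adj: dict[int, list[tuple[object, float]]] = {}
    obj: dict[int, object] = {}
    for node in tree.traverse(include_self=True):
        obj[id(node)] = node
        adj.setdefault(id(node), [])
    for node in tree.traverse(include_self=False):
        length = float(node.length or 0.0)
        adj[id(node.parent)].append((node, length))
        adj[id(node)].append((node.parent, length))
    changed = True
    while changed:
        changed = False
        for key, neighbors in list(adj.items()):
            if not obj[key].is_tip() and len(neighbors) == 2:
                (u, lu), (v, lv) = neighbors
                adj[id(u)] = [(n, l) for n, l in adj[id(u)] if id(n) != key] + [(v, lu + lv)]
                adj[id(v)] = [(n, l) for n, l in adj[id(v)] if id(n) != key] + [(u, lu + lv)]
                del adj[key]
                changed = True
                break

    start = next(t for t in tree.tips() if t.name == phylogeny.root_sample)

    def leaves_beyond(node, come_from) -> list[str]:
        if node.is_tip():
            return [node.name]
        out: list[str] = []
        for neighbor, _ in adj[id(node)]:
            if id(neighbor) != id(come_from):
                out.extend(leaves_beyond(neighbor, node))
        return out

    def node_label(node, come_from) -> str:
        if node.is_tip():
            return node.name
        return "node_" + "_".join(sorted(leaves_beyond(node, come_from)))

    def node_coords(node, come_from) -> np.ndarray:
        tips = leaves_beyond(node, come_from)
        return np.mean([meta.coordinates(t) for t in tips], axis=0)

    rows = []

    def visit(node, come_from) -> None:
        outgoing = [(n, l) for n, l in adj[id(node)] if come_from is None or id(n) != id(come_from)]
        outgoing.sort(key=lambda item: (item[1], node_label(item[0], node)))
        here = node_coords(node, come_from) if come_from is not None or not node.is_tip() else meta.coordinates(node.name)
        for neighbor, length in outgoing:
            there = node_coords(neighbor, node)
            rows.append(
                {
                    "parent": node_label(node, come_from),
                    "child": node_label(neighbor, node),
                    "methylation_distance": float(length),
                    "anatomical_distance_mm": float(np.linalg.norm(here - there)),
                }
            )
            visit(neighbor, node)

    visit(start, None)
    return SpreadPath(steps=pd.DataFrame(rows))


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions of an (un)rooted tree, as min-side sets.

    Each internal edge splits the leaves in two; the smaller side (ties:
    lexicographically smaller) represents the bipartition, which makes
    the set comparable between rootings.
    """
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(pick)
    return splits
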