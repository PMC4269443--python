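"""BSH protein clustering: distance matrix, neighbor-joining tree, tree cut.

The Firmicute BSH proteins are clustered into a fixed number of groups
(four: two major, two minor) so that gene hits can be stratified by the
protein subfamily their source species carries.  Distance between two
proteins is one minus the identity of their optimal global alignment
(BLOSUM62, gap 11/1; gap columns count as mismatches).  The guide tree is
neighbor-joining over that matrix; clusters are obtained by removing the
k−1 longest internal branches (ties broken toward the deeper node, then by
node name) and numbering the resulting leaf groups by decreasing size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from . import _seq as sq
from ._align import nw_align
from .refdb import ProteinFamilyDB

log = logging.getLogger(__name__)


def pairwise_distance(a: str, b: str) -> float:
    """1 − global-alignment identity of two peptides."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = nw_align(
        sq.encode_aa(a), sq.encode_aa(b),
        sq.BLOSUM62, sq.PROT_GAP_OPEN, sq.PROT_GAP_EXTEND, sq.AA_COUNTABLE,
    )
    return 1.0 - res[1] / res[2]


def distance_matrix(db: ProteinFamilyDB) -> DistanceMatrix:
    """Symmetric pairwise-distance matrix over a protein database."""
    ids = [r.protein_id for r in db]
    seqs = [sq.encode_aa(r.sequence) for r in db]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = nw_align(
                seqs[i], seqs[j],
                sq.BLOSUM62, sq.PROT_GAP_OPEN, sq.PROT_GAP_EXTEND, sq.AA_COUNTABLE,
            )
            d[i, j] = d[j, i] = 1.0 - res[1] / res[2]
    return DistanceMatrix(d, ids)


def build_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining guide tree (deterministic for a fixed input order)."""
    if dm.shape[0] < 3:
        log.warning("fewer than 3 sequences: returning a trivial star tree")
        root = TreeNode(name=None)
        for leaf_id in dm.ids:
            root.append(TreeNode(name=leaf_id, length=0.0))
        return root
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nj(dm)


def _edges(tree: TreeNode) -> list[tuple[TreeNode, int, bool]]:
    """(node, depth, is_internal) for every branch (i.e., non-root node)."""
    out = []
    for node in tree.preorder(include_self=False):
        depth = 0
        p = node
        while p.parent is not None:
            depth += 1
            p = p.parent
        out.append((node, depth, not node.is_tip()))
    return out


def cut_clusters(tree: TreeNode, k: int) -> dict[str, int]:
    """Partition leaves into k clusters by removing the longest branches.

    Internal branches are removed first (longest length; ties broken toward
    the deeper node, then by subtree name for determinism); leaf branches
    are only used when fewer than k−1 internal branches exist, which makes
    ``k = leaf count`` yield singletons.  Clusters are numbered 1..k by
    decreasing size (ties toward the lexicographically smallest member).
    """
    leaves = [t.name for t in tree.tips()]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(leaves):
        raise ValueError(f"k={k} exceeds leaf count {len(leaves)}")
    edges = _edges(tree)

    def sort_key(item):
        node, depth, internal = item
        name = node.name or min((t.name for t in node.tips()), default="")
        return (-(node.length or 0.0), -depth, name)

    internal_sorted = sorted([e for e in edges if e[2]], key=sort_key)
    leaf_sorted = sorted([e for e in edges if not e[2]], key=sort_key)
    candidates = internal_sorted + leaf_sorted

    def partition(cut_nodes: set[int]) -> list[list[str]]:
        # each cut branch detaches its subtree; a leaf belongs to the
        # component of the nearest cut ancestor (or the root)
        groups: dict[int, list[str]] = {}
        for tip in tree.tips():
            anchor = id(tree)
            p = tip
            while p is not None:
                if id(p) in cut_nodes:
                    anchor = id(p)
                    break
                p = p.parent
            groups.setdefault(anchor, []).append(tip.name)
        return list(groups.values())

    # greedy: take branches in priority order, skipping any cut that fails to
    # split a group (e.g. a branch whose leaves are all behind deeper cuts)
    cut_nodes: set[int] = set()
    n_groups = 1
    for node, _, _ in candidates:
        if n_groups >= k:
            break
        trial = cut_nodes | {id(node)}
        m = len(partition(trial))
        if m > n_groups:
            cut_nodes = trial
            n_groups = m
    ordered = sorted(partition(cut_nodes), key=lambda g: (-len(g), sorted(g)[0]))
    return {name: ci + 1 for ci, grp in enumerate(ordered) for name in grp}


@dataclass
class ClusterModel:
    """Protein clustering result with the species-level map used downstream."""

    distances: DistanceMatrix
    tree: TreeNode
    protein_clusters: dict[str, int]  # protein_id -> cluster
    cluster_of: dict[str, int]  # species -> cluster
    n_clusters: int

    def to_newick(self) -> str:
        import io

        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue()


def cluster_proteins(
    db: ProteinFamilyDB, k: int = 4, *, family: str = "BSH",
    phylum: str | None = "Firmicutes",
) -> ClusterModel:
    """Cluster one family's proteins (optionally restricted to a phylum).

    The species→cluster map takes, per species, the cluster of its proteins
    (majority; ties toward the lowest cluster number).
    """
    members = ProteinFamilyDB(
        r for r in db
        if r.family == family and (phylum is None or r.source_phylum == phylum)
    )
    dm = distance_matrix(members)
    tree = build_tree(dm)
    protein_clusters = cut_clusters(tree, k)
    cluster_of: dict[str, int] = {}
    by_species: dict[str, list[int]] = {}
    for r in members:
        by_species.setdefault(r.source_species, []).append(
            protein_clusters[r.protein_id]
        )
    for sp, ks in by_species.items():
        counts = pd.Series(ks).value_counts()
        top = counts[counts == counts.max()].index.min()
        cluster_of[sp] = int(top)
    return ClusterModel(
        distances=dm, tree=tree, protein_clusters=protein_clusters,
        cluster_of=cluster_of, n_clusters=k,
    )


def species_cluster_table(model: ClusterModel, db: ProteinFamilyDB) -> pd.DataFrame:
    """Species → cluster table (with taxonomic family), for reporting."""
    rows = []
    seen = set()
    for r in db:
        if r.source_species in model.cluster_of and r.source_species not in seen:
            seen.add(r.source_species)
            rows.append(
                (r.source_species, r.source_family, model.cluster_of[r.source_species])
            )
    return pd.DataFrame(rows, columns=["species", "tax_family", "cluster"]).sort_values(
        ["cluster", "species"], ignore_index=True
    )
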