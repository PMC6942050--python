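"""Classify contigs into groups from pairwise sequence distances.

Contig classification is driven by the distal tails, where the cohort
diverges; distances are substitution distances (substitutions per aligned
site) from pairwise alignment of the chosen region, clustered by average
linkage (UPGMA).  Labels are sorted internally before clustering so that the
partition is invariant to input order; ties then break deterministically by
label order.  A neighbor-joining tree (via dendropy) is available for display,
but group assignment cuts only average-linkage trees: a k-cut is not well
defined on an unrooted NJ topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse import csgraph
from scipy.spatial.distance import squareform

from .align import global_align
from .io import Contig


def distance_matrix(cohort: list[Contig], region: str = "whole",
                    tail_bp: int = 100_000) -> pd.DataFrame:
    """Pairwise substitution distances over a region of each contig.

    ``region`` is "whole" or "terminal"; terminal mode compares the final
    ``tail_bp`` of each contig (a contig shorter than tail_bp contributes its
    full length).  Distance = substitutions / aligned columns.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two contigs")
    labels = [c.id for c in cohort]
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(cohort):
        for b in cohort[i + 1 :]:
            if region == "whole":
                aln = global_align(a, b)
            elif region == "terminal":
                # contig ends coincide, so the two suffixes correspond directly
                aln = global_align(a.sequence[-min(tail_bp, a.length):],
                                   b.sequence[-min(tail_bp, b.length):])
            else:
                raise ValueError(f"unknown region {region!r}")
            if aln.aligned_columns == 0:
                raise ValueError(f"unalignable pair ({a.id}, {b.id})")
            d = aln.substitutions / aln.aligned_columns
            D.loc[a.id, b.id] = D.loc[b.id, a.id] = d
    return D


@dataclass
class Tree:
    """A hierarchical merge structure (average linkage) or an NJ topology."""

    method: str
    labels: list[str]
    linkage: np.ndarray | None = None  # scipy linkage matrix (average linkage)
    newick: str = ""

    def to_newick(self) -> str:
        return self.newick


def _linkage_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node) -> tuple[str, float]:
        if node.is_leaf():
            return labels[node.id], 0.0
        left, lh = walk(node.left)
        right, rh = walk(node.right)
        h = node.dist / 2.0  # ultrametric height of this merge
        return f"({left}:{h - lh:.10g},{right}:{h - rh:.10g})", h

    s, _ = walk(tree)
    return s + ";"


def build_tree(D: pd.DataFrame, method: str = "average_linkage") -> Tree:
    """Deterministic tree from a distance matrix.

    Labels are sorted before clustering; Newick output carries branch lengths
    (half merge heights for average linkage).
    """
    labels = sorted(D.index)
    Dc = D.loc[labels, labels]
    if method == "average_linkage":
        Z = hierarchy.linkage(squareform(Dc.values, checks=False),
                              method="average")
        return Tree(method, labels, Z, _linkage_newick(Z, labels))
    if method == "neighbor_joining":
        import dendropy

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_pdm_csv(Dc), delimiter=","
        )
        njt = pdm.nj_tree()
        newick = njt.as_string(schema="newick").strip()
        return Tree(method, labels, None, newick)
    raise ValueError(f"unknown tree method {method!r}")


def _pdm_csv(D: pd.DataFrame):
    import io as _io

    buf = _io.StringIO()
    D.to_csv(buf)
    buf.seek(0)
    return buf


@dataclass
class GroupingResult:
    tree: Tree
    groups: dict[str, str]  # label -> group id
    k: int | None = None
    cut_height: float | None = None

    def partition(self) -> list[set]:
        out: dict[str, set] = {}
        for label, gid in self.groups.items():
            out.setdefault(gid, set()).add(label)
        return [out[g] for g in sorted(out)]


def _canonical_group_ids(labels: list[str], flat: np.ndarray) -> dict[str, str]:
    reps: dict[int, str] = {}
    for label, c in sorted(zip(labels, flat)):
        reps.setdefault(int(c), label)
    order = sorted(reps, key=lambda c: reps[c])
    rename = {c: f"g{i + 1}" for i, c in enumerate(order)}
    return {label: rename[int(c)] for label, c in zip(labels, flat)}


def assign_groups(tree: Tree, D: pd.DataFrame, k: int | None = None,
                  cut: float | None = None) -> GroupingResult:
    """Partition the cohort by cutting the average-linkage tree.

    Either ``k`` (remove the k-1 highest merges) or ``cut`` (a distance
    threshold).  A threshold cut is additionally checked against the
    single-graph partition (connected components of distance <= cut); a
    mismatch signals non-ultrametric structure and raises, directing the user
    to a k-cut.
    """
    if tree.linkage is None:
        raise ValueError("group assignment requires an average-linkage tree")
    if (k is None) == (cut is None):
        raise ValueError("pass exactly one of k or cut")
    labels = tree.labels
    if k is not None:
        flat = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
        return GroupingResult(tree, _canonical_group_ids(labels, flat), k=k)
    flat = hierarchy.fcluster(tree.linkage, t=cut, criterion="distance")
    adj = (D.loc[labels, labels].values <= cut).astype(int)
    n_comp, comp = csgraph.connected_components(adj, directed=False)
    tree_part = _canonical_group_ids(labels, flat)
    graph_part = _canonical_group_ids(labels, comp)
    if tree_part != graph_part:
        raise ValueError(
            "threshold partition disagrees with the tree cut "
            "(non-ultrametric structure); use a k-cut instead"
        )
    return GroupingResult(tree, tree_part, cut_height=cut)
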