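"""Branch-level tree representation and leaf-number statistics.

A *branch* is a maximal unbranched chain of reconstruction samples: a new
branch starts at every root sample and at every child of a branch point
(a sample with two or more children). Soma samples (type code 1) belong to
no branch; the first branch of each neurite starts at the first non-soma
sample whose parent is a soma sample or -1.

The *leaf number* L_n of a branch is the number of terminal tips distal to
it (a tip counts itself once, so tips have L_n = 1); the *relative leaf
number* L_n,rel = log2(L_max / L_n) is 0 at the branch with the maximal
leaf number (the soma end) and grows toward the tips, giving a
cell-size-independent coordinate for junction position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .swc_io import Reconstruction, SOMA_TYPE, SwcSample

logger = logging.getLogger(__name__)

__all__ = [
    "Branch",
    "BranchTree",
    "extract_branches",
    "branch_metrics",
    "compute_leaf_numbers",
    "relative_leaf_numbers",
    "build_branch_tree",
    "branch_table",
]


@dataclass
class Branch:
    """A maximal unbranched sample chain, proximal to distal."""

    branch_id: int
    parent_branch_id: int | None
    sample_ids: list[int]
    type_code: int
    mean_radius: float = math.nan
    path_length: float = math.nan


@dataclass
class BranchTree:
    """Branches of one reconstruction plus leaf-number annotations."""

    cell_id: str
    branches: dict[int, Branch]
    children: dict[int, list[int]]
    leaf_number: dict[int, int] = field(default_factory=dict)
    max_leaf_number: int | None = None
    relative_leaf_number: dict[int, float] = field(default_factory=dict)

    @property
    def tips(self) -> set[int]:
        return {bid for bid, ch in self.children.items() if not ch}

    @property
    def roots(self) -> list[int]:
        return [bid for bid, b in self.branches.items() if b.parent_branch_id is None]


def extract_branches(rec: Reconstruction) -> BranchTree:
    """Group the samples of a validated reconstruction into branches.

    Every non-soma sample lands in exactly one branch. Branch points are
    detected topologically (a sample with >= 2 children) rather than by
    gaps in the id numbering, so renumbered files behave identically to
    contiguously numbered ones.
    """
    index = rec.sample_index()
    child_map: dict[int, list[int]] = {s.sample_id: [] for s in rec.samples}
    for s in rec.samples:
        if s.parent_id != -1:
            child_map[s.parent_id].append(s.sample_id)

    def is_soma(sid: int) -> bool:
        return index[sid].type_code == SOMA_TYPE

    # branch seeds: non-soma samples whose parent is -1, a soma sample, or
    # a branch point (>= 2 children)
    seeds: list[int] = []
    for s in rec.samples:
        if is_soma(s.sample_id):
            continue
        p = s.parent_id
        if p == -1 or is_soma(p) or len(child_map[p]) >= 2:
            seeds.append(s.sample_id)

    branches: dict[int, Branch] = {}
    branch_of_sample: dict[int, int] = {}
    for bid, seed in enumerate(seeds):
        chain = [seed]
        cur = seed
        while True:
            kids = [c for c in child_map[cur] if not is_soma(c)]
            if len(kids) == 1 and len(child_map[cur]) == 1:
                cur = kids[0]
                chain.append(cur)
            else:
                break
        branches[bid] = Branch(
            branch_id=bid,
            parent_branch_id=None,
            sample_ids=chain,
            type_code=index[seed].type_code,
        )
        for sid in chain:
            branch_of_sample[sid] = bid

    children: dict[int, list[int]] = {bid: [] for bid in branches}
    for bid, br in branches.items():
        first = index[br.sample_ids[0]]
        p = first.parent_id
        if p != -1 and not is_soma(p):
            parent_bid = branch_of_sample[p]
            br.parent_branch_id = parent_bid
            children[parent_bid].append(bid)

    tree = BranchTree(cell_id=rec.cell_id, branches=branches, children=children)
    n_samples = sum(len(b.sample_ids) for b in branches.values())
    logger.debug(
        "%s: %d branches, %d tips, %d samples", rec.cell_id, len(branches), len(tree.tips), n_samples
    )
    return tree


def branch_metrics(tree: BranchTree, rec: Reconstruction) -> BranchTree:
    """Attach mean radius and path length to every branch.

    mean_radius is the arithmetic mean of the branch's sample radii (the
    per-branch radius used for all scale-factor ratios). path_length sums
    Euclidean distances between consecutive samples along the branch,
    including the connecting segment from the parent sample (the parent
    branch's last sample, or the soma sample the neurite hangs off).
    """
    index = rec.sample_index()
    for br in tree.branches.values():
        pts = [index[sid] for sid in br.sample_ids]
        br.mean_radius = sum(p.radius for p in pts) / len(pts)
        length = 0.0
        first = pts[0]
        if first.parent_id != -1:
            length += _dist(index[first.parent_id], first)
        elif len(pts) == 1:
            logger.debug("%s: single-sample root branch %d has path_length 0",
                         tree.cell_id, br.branch_id)
        for a, b in zip(pts, pts[1:]):
            length += _dist(a, b)
        br.path_length = length
    return tree


def _dist(a: SwcSample, b: SwcSample) -> float:
    return math.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)


def compute_leaf_numbers(tree: BranchTree) -> BranchTree:
    """Assign each branch the number of tips distal to it.

    Tips carry 1 (each terminal counts itself); every other branch is the
    sum over its children, so leaf number is conserved down the tree and
    the root of a tree carries that tree's tip count. The per-cell maximum
    is stored as ``max_leaf_number``.
    """
    ln: dict[int, int] = {}
    # iterative post-order over each root
    for root in tree.roots:
        stack = [(root, False)]
        while stack:
            bid, expanded = stack.pop()
            kids = tree.children[bid]
            if not kids:
                ln[bid] = 1
            elif expanded:
                ln[bid] = sum(ln[k] for k in kids)
            else:
                stack.append((bid, True))
                stack.extend((k, False) for k in kids)
    tree.leaf_number = ln
    tree.max_leaf_number = max(ln.values()) if ln else None
    return tree


def relative_leaf_numbers(tree: BranchTree) -> BranchTree:
    """Compute L_n,rel = log2(L_max / L_n) per branch.

    Zero exactly at the branch attaining the maximal leaf number; finite
    everywhere because tips have leaf number 1.
    """
    if not tree.leaf_number:
        compute_leaf_numbers(tree)
    lmax = tree.max_leaf_number
    tree.relative_leaf_number = {
        bid: math.log2(lmax / ln) for bid, ln in tree.leaf_number.items()
    }
    return tree


def build_branch_tree(rec: Reconstruction) -> BranchTree:
    """Full pipeline: branches, metrics, leaf numbers, relative leaf numbers."""
    tree = extract_branches(rec)
    branch_metrics(tree, rec)
    compute_leaf_numbers(tree)
    relative_leaf_numbers(tree)
    return tree


def branch_table(tree: BranchTree) -> pd.DataFrame:
    """Branch-level table for CSV export."""
    rows = []
    for bid in sorted(tree.branches):
        br = tree.branches[bid]
        rows.append(
            {
                "cell_id": tree.cell_id,
                "branch_id": bid,
                "parent_branch_id": br.parent_branch_id,
                "type_code": br.type_code,
                "n_samples": len(br.sample_ids),
                "mean_radius": br.mean_radius,
                "path_length": br.path_length,
                "leaf_number": tree.leaf_number.get(bid),
                "relative_leaf_number": tree.relative_leaf_number.get(bid),
            }
        )
    return pd.DataFrame(rows)
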