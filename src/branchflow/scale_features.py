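"""Per-junction asymmetric scale factors and feature-table assembly.

At each bifurcation the two daughter radii r1, r2 define scale factors
beta_i = r_i / r_parent; the features used downstream are their mean
beta_mean = (beta1 + beta2)/2 and signed half-difference
beta_diff = (beta1 - beta2)/2. Daughter 1 is the *longer* daughter, which
fixes the length half-difference gamma_diff >= 0 and gives beta_diff its
sign: positive when the longer daughter is also the wider one. Junctions
where either beta ratio reaches ~1 are imaging artifacts (radii pinned at
the pixel size) and are removed by :func:`filter_junctions`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .branch_graph import BranchTree

logger = logging.getLogger(__name__)

DEFAULT_BETA_FILTER = 0.999

__all__ = [
    "Junction",
    "DEFAULT_BETA_FILTER",
    "compute_junctions",
    "filter_junctions",
    "assemble_feature_table",
    "level_profile",
    "FEATURES_2D",
    "FEATURES_3D",
]

FEATURES_2D = ["beta_mean", "beta_diff"]
FEATURES_3D = ["beta_mean", "beta_diff", "rel_leaf_number"]


@dataclass(frozen=True)
class Junction:
    """One bifurcation with its radius/length scale factors.

    beta1/gamma1 belong to the longer daughter; gamma_diff is therefore
    >= 0 by construction, while beta_diff keeps its sign. gamma values are
    NaN when the parent path length is zero (degenerate single-sample
    root), in which case the junction is retained for the radius features.
    """

    cell_id: str
    parent_branch_id: int
    beta1: float
    beta2: float
    gamma1: float
    gamma2: float
    beta_mean: float
    beta_diff: float
    gamma_mean: float
    gamma_diff: float
    leaf_number_parent: int
    rel_leaf_number: float


def compute_junctions(tree: BranchTree, cell_id: str | None = None) -> list[Junction]:
    """Extract one :class:`Junction` per branch with exactly two children.

    Branches with three or more children (trifurcations, rare tracing
    artifacts) are skipped and counted — the mean/half-difference
    parametrization is a binary-branching construct.
    """
    if cell_id is None:
        cell_id = tree.cell_id
    junctions: list[Junction] = []
    n_skipped = 0
    for bid, kids in tree.children.items():
        if len(kids) != 2:
            if len(kids) > 2:
                n_skipped += 1
            continue
        parent = tree.branches[bid]
        d1, d2 = (tree.branches[k] for k in kids)
        # daughter 1 = longer daughter; exact tie -> wider daughter first
        if (d2.path_length, d2.mean_radius) > (d1.path_length, d1.mean_radius):
            d1, d2 = d2, d1
        beta1 = d1.mean_radius / parent.mean_radius
        beta2 = d2.mean_radius / parent.mean_radius
        if parent.path_length > 0:
            gamma1 = d1.path_length / parent.path_length
            gamma2 = d2.path_length / parent.path_length
        else:
            gamma1 = gamma2 = math.nan
            logger.debug("%s: junction at branch %d has zero parent length; "
                         "gamma undefined", cell_id, bid)
        junctions.append(
            Junction(
                cell_id=cell_id,
                parent_branch_id=bid,
                beta1=beta1,
                beta2=beta2,
                gamma1=gamma1,
                gamma2=gamma2,
                beta_mean=(beta1 + beta2) / 2.0,
                beta_diff=(beta1 - beta2) / 2.0,
                gamma_mean=(gamma1 + gamma2) / 2.0,
                gamma_diff=(gamma1 - gamma2) / 2.0,
                leaf_number_parent=tree.leaf_number[bid],
                rel_leaf_number=tree.relative_leaf_number[bid],
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d non-binary junctions", cell_id, n_skipped)
    return junctions


def filter_junctions(
    junctions: list[Junction], threshold: float = DEFAULT_BETA_FILTER
) -> list[Junction]:
    """Drop junctions where either daughter's beta reaches the threshold.

    Ratios at or above ~1 come from the imaging resolution floor — once
    every radius equals the pixel size, daughter/parent ratios collapse to
    1 regardless of true caliber. Idempotent; the removed count is logged.
    """
    if not (0.0 < threshold < math.inf):
        raise ValueError(f"filter threshold must be in (0, inf), got {threshold}")
    kept = [j for j in junctions if max(j.beta1, j.beta2) < threshold]
    removed = len(junctions) - len(kept)
    if removed:
        logger.info("beta filter at %g removed %d of %d junctions",
                    threshold, removed, len(junctions))
    return kept


def assemble_feature_table(
    junctions: list[Junction],
    class_label: str,
    features: str = "3d",
    abs_diff: bool = False,
    include_gamma: bool = False,
) -> pd.DataFrame:
    """Build the per-junction feature table for classification.

    One row per (filtered) junction. ``features="2d"`` emits
    (beta_mean, beta_diff); ``"3d"`` adds rel_leaf_number. ``abs_diff``
    replaces the signed half-difference by its magnitude. gamma columns
    are exported on request but never used as classifier features.
    """
    if features not in ("2d", "3d"):
        raise ValueError(f"features must be '2d' or '3d', got {features!r}")
    if not junctions:
        raise ValueError(f"no junctions to tabulate for class {class_label!r}")
    rows = []
    for j in junctions:
        row = {
            "cell_id": j.cell_id,
            "label": class_label,
            "beta_mean": j.beta_mean,
            "beta_diff": abs(j.beta_diff) if abs_diff else j.beta_diff,
        }
        if features == "3d":
            row["rel_leaf_number"] = j.rel_leaf_number
        if include_gamma:
            row["gamma_mean"] = j.gamma_mean
            row["gamma_diff"] = j.gamma_diff
        rows.append(row)
    return pd.DataFrame(rows)


def level_profile(table: pd.DataFrame, group_by: str = "cell") -> pd.DataFrame:
    """Average beta_mean/beta_diff at each distinct rel_leaf_number.

    Visualization aid only (feature-space scatter analogues); the
    classifiers always consume raw per-junction rows. ``group_by`` is
    ``"cell"`` (per cell_id) or ``"class"`` (per label).
    """
    if table.empty:
        raise ValueError("empty feature table")
    if "rel_leaf_number" not in table.columns:
        raise ValueError("level_profile needs the rel_leaf_number column (3d mode)")
    key = {"cell": "cell_id", "class": "label"}[group_by]
    out = (
        table.groupby([key, "rel_leaf_number"], sort=True)
        .agg(
            beta_mean=("beta_mean", "mean"),
            beta_diff=("beta_diff", "mean"),
            n_junctions=("beta_mean", "size"),
        )
        .reset_index()
    )
    return out
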