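"""End-to-end conveniences: reconstruction -> junction feature table.

Thin glue over the stage modules so that analyses, the CLI and tests can
go from an SWC reconstruction (or a whole synthetic cohort) to classifier-
ready feature tables in one call.
"""

from __future__ import annotations

import pandas as pd

from .branch_graph import build_branch_tree
from .scale_features import (
    DEFAULT_BETA_FILTER,
    assemble_feature_table,
    compute_junctions,
    filter_junctions,
)
from .swc_io import Reconstruction
from .synthetic_data import CohortSpec, generate_cohort

__all__ = ["junction_features", "cohort_feature_tables"]


def junction_features(
    rec: Reconstruction,
    label: str | None = None,
    beta_filter: float = DEFAULT_BETA_FILTER,
    features: str = "3d",
    abs_diff: bool = False,
) -> pd.DataFrame:
    """Branch, measure, junction-ize and filter one reconstruction."""
    tree = build_branch_tree(rec)
    junctions = filter_junctions(compute_junctions(tree), threshold=beta_filter)
    return assemble_feature_table(
        junctions, class_label=label if label is not None else (rec.label or ""),
        features=features, abs_diff=abs_diff,
    )


def cohort_feature_tables(
    cohort: CohortSpec,
    beta_filter: float = DEFAULT_BETA_FILTER,
    features: str = "3d",
) -> dict[str, pd.DataFrame]:
    """Generate a synthetic cohort and return per-class feature tables."""
    recs, _manifest = generate_cohort(cohort)
    per_class: dict[str, list[pd.DataFrame]] = {}
    for rec in recs:
        tab = junction_features(rec, label=rec.label, beta_filter=beta_filter,
                                features=features)
        per_class.setdefault(rec.label, []).append(tab)
    return {lab: pd.concat(tabs, ignore_index=True) for lab, tabs in per_class.items()}
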