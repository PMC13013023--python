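#!/usr/bin/env python
"""Simulate the study cohorts as SWC files.

Two labeled cohorts of complete-binary synthetic arbors:

* ``glia_like`` — the astrocyte/microglia-style comparison: both classes
  share the same level-dependent radius-scaling profile, but class B
  draws its ratios at shuffled levels, so the pooled (beta_mean,
  beta_diff) marginals are identical while the level-conditional
  structure differs.
* ``separated`` — a dendrite-style comparison with well-separated mean
  scale factors (0.55 vs 0.75), classifiable from the 2D features alone.

SWC files land under scratch/cohorts/ (regenerable at will — everything
is seeded); the manifests go to results/.
"""

from pathlib import Path

import pandas as pd

from branchflow import ArborSpec, CohortSpec, generate_cohort, write_swc
from branchflow.synthetic_data import level_localized_specs

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260924
N_CELLS = 12


def cohorts() -> dict[str, CohortSpec]:
    glia_a, glia_b = level_localized_specs(depth=6)
    sep_a = ArborSpec(depth=5, beta_mean_profile=0.55, beta_diff_profile=0.08,
                      noise_sd=0.04)
    sep_b = ArborSpec(depth=5, beta_mean_profile=0.75, beta_diff_profile=0.08,
                      noise_sd=0.04)
    return {
        "glia_like": CohortSpec({"levelA": glia_a, "levelB": glia_b},
                                n_cells_per_class=N_CELLS, seed=SEED),
        "separated": CohortSpec({"thin": sep_a, "wide": sep_b},
                                n_cells_per_class=N_CELLS, seed=SEED + 1),
    }


def main() -> None:
    manifests = []
    for name, cohort in cohorts().items():
        out = ROOT / "scratch" / "cohorts" / name
        out.mkdir(parents=True, exist_ok=True)
        recs, manifest = generate_cohort(cohort)
        for rec in recs:
            write_swc(rec, out / f"{rec.cell_id}.swc")
        manifest.insert(0, "cohort", name)
        manifests.append(manifest)
        n_samples = sum(len(r) for r in recs)
        print(f"{name}: {len(recs)} cells, {n_samples} samples -> {out}")
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    pd.concat(manifests, ignore_index=True).to_csv(res / "cohort_manifest.csv", index=False)
    print(f"manifest -> {res / 'cohort_manifest.csv'}")


if __name__ == "__main__":
    main()
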