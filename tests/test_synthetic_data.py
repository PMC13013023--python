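import numpy as np
import pytest
from scipy import stats

from branchflow.branch_graph import build_branch_tree
from branchflow.pipeline import cohort_feature_tables, junction_features
from branchflow.scale_features import compute_junctions, filter_junctions
from branchflow.swc_io import write_swc
from branchflow.synthetic_data import (
    ArborSpec,
    CohortSpec,
    generate_arbor,
    generate_cohort,
    level_localized_specs,
    quantize_radii,
)

from conftest import make_rec


class TestGenerateArbor:
    def test_noise_free_junctions_hit_profile_exactly(self):
        rec = generate_arbor(ArborSpec(depth=4, beta_mean_profile=0.7,
                                       beta_diff_profile=0.1, noise_sd=0.0, seed=0))
        js = compute_junctions(build_branch_tree(rec))
        assert len(js) == 15
        for j in js:
            assert j.beta_mean == pytest.approx(0.7, abs=1e-12)
            assert abs(j.beta_diff) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("depth", [1, 3, 5])
    def test_topology_is_complete_binary(self, depth):
        tree = build_branch_tree(generate_arbor(ArborSpec(depth=depth, seed=1)))
        assert len(tree.tips) == 2**depth
        assert len(tree.branches) == 2 ** (depth + 1) - 1
        assert tree.max_leaf_number == 2**depth

    def test_rel_leaf_number_equals_generation(self):
        # complete tree: a junction whose parent has leaf number 2^(d-g)
        # sits at relative leaf number exactly g
        tree = build_branch_tree(generate_arbor(ArborSpec(depth=4, seed=2)))
        for j in compute_junctions(tree):
            g = 4 - np.log2(j.leaf_number_parent)
            assert j.rel_leaf_number == pytest.approx(g)

    def test_same_seed_byte_identical_swc(self, tmp_path):
        spec = ArborSpec(depth=3, noise_sd=0.05, jitter_sd=0.1, seed=42)
        p1 = write_swc(generate_arbor(spec, "c"), tmp_path / "a.swc")
        p2 = write_swc(generate_arbor(spec, "c"), tmp_path / "b.swc")
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ArborSpec(depth=0).validate()
        with pytest.raises(ValueError):
            ArborSpec(samples_per_branch=1).validate()
        with pytest.raises(ValueError):
            ArborSpec(beta_mean_profile=0.95, beta_diff_profile=0.1).validate()
        with pytest.raises(ValueError):
            ArborSpec(gamma_mean=0.5, gamma_diff=0.6).validate()


class TestQuantizeRadii:
    def test_zero_pixel_is_identity(self):
        rec = generate_arbor(ArborSpec(depth=2, seed=0))
        assert quantize_radii(rec, 0.0) is rec

    def test_collapsed_radii_produce_beta_one_removed_by_filter(self):
        rec = make_rec([
            (1, 3, 0, 0, 0.0, 1.0, -1),
            (2, 3, 0, 0, 1.0, 1.0, 1),
            (3, 3, 1, 0, 2.0, 0.3, 2),
            (4, 3, 2, 0, 3.0, 0.3, 3),
            (5, 3, -1, 0, 2.0, 0.2, 2),
            (6, 3, -2, 0, 2.5, 0.2, 5),
        ])
        q = quantize_radii(rec, 0.5)
        assert {s.radius for s in q.samples if s.sample_id >= 3} == {0.5}
        js = compute_junctions(build_branch_tree(q))
        assert js[0].beta1 == 0.5  # 0.5 / 1.0: parent snapped to 1.0
        q2 = quantize_radii(make_rec([
            (1, 3, 0, 0, 0.0, 0.4, -1),
            (2, 3, 0, 0, 1.0, 0.4, 1),
            (3, 3, 1, 0, 2.0, 0.3, 2),
            (4, 3, 2, 0, 3.0, 0.3, 3),
            (5, 3, -1, 0, 2.0, 0.2, 2),
            (6, 3, -2, 0, 2.5, 0.2, 5),
        ]), 0.5)
        js2 = compute_junctions(build_branch_tree(q2))
        assert js2[0].beta1 == js2[0].beta2 == 1.0
        assert filter_junctions(js2) == []

    def test_negative_pixel_rejected(self):
        rec = generate_arbor(ArborSpec(depth=1, seed=0))
        with pytest.raises(ValueError):
            quantize_radii(rec, -0.1)


class TestGenerateCohort:
    def test_balanced_manifest_and_determinism(self):
        spec = ArborSpec(depth=2, seed=0)
        cohort = CohortSpec(class_specs={"A": spec, "B": spec},
                            n_cells_per_class=5, seed=3)
        recs, manifest = generate_cohort(cohort)
        assert len(recs) == 10
        assert manifest["label"].value_counts().to_dict() == {"A": 5, "B": 5}
        _, manifest2 = generate_cohort(cohort)
        assert manifest.equals(manifest2)

    def test_per_cell_seeds_distinct(self):
        cohort = CohortSpec(class_specs={"A": ArborSpec(depth=2)},
                            n_cells_per_class=8, seed=0)
        _, manifest = generate_cohort(cohort)
        assert manifest["seed"].nunique() == 8
        assert (manifest["seed"] < 2**31).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(class_specs={"A": ArborSpec()}, n_cells_per_class=1).validate()

    def test_identical_specs_give_indistinguishable_features(self):
        # null cohort: same generator spec, different per-cell seeds
        spec = ArborSpec(depth=6, noise_sd=0.04, seed=0)
        cohort = CohortSpec(class_specs={"A": spec, "B": spec},
                            n_cells_per_class=32, seed=12)
        tables = cohort_feature_tables(cohort)
        a, b = tables["A"], tables["B"]
        assert min(len(a), len(b)) >= 2000
        for col in ("beta_mean", "beta_diff"):
            p = stats.mannwhitneyu(a[col], b[col]).pvalue
            assert p > 0.01, f"{col} distributions separated (p={p:.4g})"


def test_level_localized_specs_match_marginals_but_not_conditionals():
    # pooled feature marginals indistinguishable; per-level means differ
    sa, sb = level_localized_specs(depth=6)
    cohort = CohortSpec(class_specs={"A": sa, "B": sb}, n_cells_per_class=16, seed=5)
    tables = cohort_feature_tables(cohort)
    a, b = tables["A"], tables["B"]
    p = stats.mannwhitneyu(a["beta_mean"], b["beta_mean"]).pvalue
    assert p > 0.01
    lo_a = a[a["rel_leaf_number"] <= 2]["beta_mean"].mean()
    lo_b = b[b["rel_leaf_number"] <= 2]["beta_mean"].mean()
    assert lo_a < lo_b - 0.02  # class A is thinner-scaled near the soma


def test_parameter_recovery_with_noise():
    spec = ArborSpec(depth=5, beta_mean_profile=0.7, beta_diff_profile=0.1,
                     noise_sd=0.02, seed=0)
    cohort = CohortSpec(class_specs={"A": spec}, n_cells_per_class=20, seed=1)
    recs, _ = generate_cohort(cohort)
    import pandas as pd
    tab = pd.concat([junction_features(r, label="A") for r in recs], ignore_index=True)
    n = len(tab)
    se = 0.02 / np.sqrt(n)
    assert abs(tab["beta_mean"].mean() - 0.7) < 3 * se
    assert abs(tab["beta_diff"].abs().mean() - 0.1) < 3 * se
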