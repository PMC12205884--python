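"""Masking protocols, the built-in imputer, and accuracy bookkeeping."""

import numpy as np
import pytest

from crossgp import genoqc, impute
from crossgp.impute import (
    accuracy_percentiles, apply_mask, blocked_mask, imputation_accuracy,
    impute_builtin, impute_marker_mode, random_mask,
)
from crossgp.simdata import SimConfig, simulate_dataset

from conftest import toy_matrix


def _coverage_matrix(cov_per_marker, n_geno=100):
    """Matrix where marker j is observed for cov_per_marker[j] genotypes."""
    calls = np.zeros((n_geno, len(cov_per_marker)))
    for j, c in enumerate(cov_per_marker):
        calls[int(round(c * n_geno)):, j] = np.nan
    return toy_matrix(calls.tolist())


class TestBlockedMask:
    def test_coverage_boundary_strictly_greater(self):
        # 71% coverage -> low-density (not masked); 70% -> high-density
        gm = _coverage_matrix([0.71, 0.70, 1.0])
        mask = blocked_mask(gm, coverage_cut=0.70, genotype_frac=0.5, seed=0)
        masked_markers = set(mask.markers)
        assert "m2" in masked_markers
        assert "m1" not in masked_markers and "m3" not in masked_markers

    def test_exact_genotype_count(self):
        # high-density markers observed for the first 120 genotypes: those
        # are the eligible pool, and 10% of them -> exactly 12 masked
        gm = _coverage_matrix([1.0] * 4 + [0.6] * 4, n_geno=200)
        mask = blocked_mask(gm, genotype_frac=0.10, seed=1)
        assert mask.params["n_genotypes_masked"] == 12

    def test_toy_hand_enumeration(self):
        # 10 genotypes x 6 markers; markers 4-6 at 60% coverage form the
        # high-density set; genotypes 0-5 observe all of them (eligible)
        calls = np.zeros((10, 6))
        calls[6:, 3:] = np.nan
        gm = toy_matrix(calls.tolist())
        mask = blocked_mask(gm, coverage_cut=0.70, genotype_frac=0.5,
                            min_hd_frac=0.5, seed=3)
        assert mask.params["n_genotypes_masked"] == 3
        assert set(mask.markers) <= {"m4", "m5", "m6"}
        for g in set(mask.genotypes):
            assert int(g[1:]) <= 6  # only eligible genotypes masked
        # every masked genotype loses all its observed high-density calls
        per_geno = {g: 0 for g in set(mask.genotypes)}
        for g in mask.genotypes:
            per_geno[g] += 1
        assert all(v == 3 for v in per_geno.values())

    def test_requires_two_density_classes(self):
        gm = _coverage_matrix([1.0, 1.0])
        with pytest.raises(ValueError, match="split"):
            blocked_mask(gm, seed=0)


class TestRandomMask:
    def test_cell_count_rounds(self):
        calls = np.zeros((100, 100))
        gm = toy_matrix(calls.tolist())
        mask = random_mask(gm, 0.01, seed=0)
        assert mask.n_cells == 100

    def test_same_seed_identical(self, merged_matrix):
        a = random_mask(merged_matrix, 0.01, seed=7)
        b = random_mask(merged_matrix, 0.01, seed=7)
        assert np.array_equal(a.rows, b.rows) and np.array_equal(a.cols, b.cols)

    def test_vanishing_fraction_rejected(self):
        gm = toy_matrix(np.zeros((5, 5)).tolist())
        with pytest.raises(ValueError, match="empty mask"):
            random_mask(gm, 1e-6, seed=0)

    def test_never_masks_missing_cells(self, merged_matrix):
        mask = random_mask(merged_matrix, 0.05, seed=1)
        assert not np.isnan(merged_matrix.calls[mask.rows, mask.cols]).any()


class TestBuiltinImputer:
    def test_identity_on_complete_matrix(self, small_dataset):
        complete = small_dataset.complete
        out = impute_builtin(complete, k_neighbours=5)
        assert np.array_equal(out.calls, complete.calls)

    def test_duplicated_genotype_restored_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.choice([0.0, 2.0], size=60)
        calls = rng.choice([0.0, 2.0], size=(8, 60))
        calls[0] = base
        calls[1] = base
        calls[1, 10] = np.nan
        gm = toy_matrix(calls.tolist())
        out = impute_builtin(gm, k_neighbours=1)
        assert out.calls[1, 10] == base[10]

    def test_beats_marker_mode_under_blocked_masking(self):
        wins = 0
        for seed in range(20):
            cfg = SimConfig(
                n_series=2, genotypes_per_series=(60, 60), n_markers=240,
                n_founders=25, seed=seed,
            )
            ds = simulate_dataset(cfg)
            filtered = [genoqc.filter_batch(b)[0] for b in ds.batches]
            merged = genoqc.merge_batches(
                filtered, genoqc.build_harmonization_plan(filtered)
            )
            mask = blocked_mask(merged, seed=seed)
            holed = apply_mask(merged, mask)
            a_knn = imputation_accuracy(merged, impute_builtin(holed), mask)
            a_mode = imputation_accuracy(merged, impute_marker_mode(holed), mask)
            if a_knn["accuracy"].mean() > a_mode["accuracy"].mean():
                wins += 1
        assert wins >= 15

    def test_blocked_not_more_accurate_than_random(self, merged_matrix):
        diffs = []
        for seed in range(5):
            bm = blocked_mask(merged_matrix, seed=seed)
            rm = random_mask(merged_matrix, 0.01, seed=seed)
            acc_b = imputation_accuracy(
                merged_matrix, impute_builtin(apply_mask(merged_matrix, bm)), bm
            )["accuracy"].mean()
            acc_r = imputation_accuracy(
                merged_matrix, impute_builtin(apply_mask(merged_matrix, rm)), rm
            )["accuracy"].mean()
            diffs.append(acc_r - acc_b)
        assert np.mean(diffs) > 0


class TestAccuracy:
    def test_perfect_imputation_scores_one(self, merged_matrix):
        mask = random_mask(merged_matrix, 0.02, seed=0)
        table = imputation_accuracy(merged_matrix, merged_matrix, mask)
        assert (table["accuracy"] == 1.0).all()
        assert table["n_masked"].sum() == mask.n_cells

    def test_toy_three_of_four_correct(self):
        gm = toy_matrix([[0.0], [0.0], [0.0], [0.0]])
        imputed = toy_matrix([[0.0], [0.0], [0.0], [2.0]])
        mask = impute.MaskSpec(
            "manual", np.arange(4), np.zeros(4, dtype=int),
            gm.genotypes, ["m1"] * 4, {},
        )
        table = imputation_accuracy(gm, imputed, mask)
        assert table["accuracy"].iloc[0] == 0.75

    def test_invariant_to_global_allele_relabeling(self, merged_matrix):
        mask = random_mask(merged_matrix, 0.02, seed=2)
        filled = impute_builtin(apply_mask(merged_matrix, mask))
        t1 = imputation_accuracy(merged_matrix, filled, mask)
        flip_orig = merged_matrix.copy()
        flip_orig.calls = 2.0 - flip_orig.calls
        flip_fill = filled.copy()
        flip_fill.calls = 2.0 - flip_fill.calls
        t2 = imputation_accuracy(flip_orig, flip_fill, mask)
        assert np.allclose(t1["accuracy"], t2["accuracy"])

    def test_unfilled_masked_cell_is_integrity_error(self, merged_matrix):
        mask = random_mask(merged_matrix, 0.01, seed=3)
        holed = apply_mask(merged_matrix, mask)
        with pytest.raises(ValueError, match="unfilled"):
            imputation_accuracy(merged_matrix, holed, mask)

    def test_percentiles_are_lower_tail_thresholds(self):
        import pandas as pd

        table = pd.DataFrame({"accuracy": np.linspace(0, 1, 101)})
        pct = accuracy_percentiles(table)
        assert pct["p95"] == pytest.approx(0.05)
        assert pct["p75"] == pytest.approx(0.25)
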