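"""eQTL mapping: filtering, pruning, scans, FDR and auxiliary statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cellqtl import eqtl
from cellqtl.eqtl import (
    FdrCurve,
    bh_fdr,
    direction_concordance,
    filter_expressed,
    lod_drop_ci,
    lod_from_correlation,
    prune_markers,
    standardize,
    stouffer_combine,
)


class TestFilterAndPrune:
    def test_expression_filter_threshold(self):
        Y = sp.csc_matrix(
            np.column_stack(
                [
                    np.repeat([1, 0], [20, 10]),  # exactly 20 cells
                    np.repeat([1, 0], [19, 11]),  # one short
                    np.zeros(30),  # silent
                ]
            )
        )
        assert filter_expressed(Y, min_cells=20).tolist() == [True, False, False]
        assert filter_expressed(Y, min_cells=1).tolist() == [True, True, False]

    def test_duplicate_marker_pruned_independent_kept(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(100), rng.random(100)
        dosage = np.column_stack([a, a, b])
        coords = pd.DataFrame({"chrom": ["c"] * 3, "pos": [10, 20, 30]})
        md = prune_markers(dosage, coords)
        assert md.n_markers == 2
        assert md.coords["pos"].tolist() == [10, 30]

    def test_pruned_markers_are_standardized(self, mapping_inputs):
        _, _, markers, _, _ = mapping_inputs
        assert np.abs(markers.values.mean(axis=0)).max() < 1e-8
        assert np.abs(markers.values.var(axis=0) - 1.0).max() < 1e-6

    def test_no_retained_pair_exceeds_r_max(self):
        rng = np.random.default_rng(1)
        base = rng.random(200)
        cols = [base + rng.normal(0, s, 200) for s in (0, 1e-9, 0.5, 0.7)]
        coords = pd.DataFrame({"chrom": ["c"] * 4, "pos": [1, 2, 3, 4]})
        md = prune_markers(np.column_stack(cols), coords)
        z = md.values
        corr = (z.T @ z) / len(z)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.9999


class TestScans:
    def test_planted_cis_effects_recovered_with_sign(
        self, planted_dataset, mapping_inputs
    ):
        Y, genes, markers, cov, _ = mapping_inputs
        cis = eqtl.cis_scan(Y, genes, markers, cov)
        truth = planted_dataset.truth.planted_cis.set_index("gene")
        hits = cis[cis["gene"].isin(truth.index)].set_index("gene")
        detected = hits[hits["lod"] > 3.0]
        assert len(detected) >= 0.75 * len(truth)
        signs = np.sign(detected["effect"]) == np.sign(
            truth.loc[detected.index, "effect"]
        )
        assert signs.all()

    def test_gene_at_marker_position_maps_to_itself(self):
        coords = pd.DataFrame({"chrom": ["c", "c"], "pos": [100, 5000]})
        assert eqtl.closest_marker(coords, "c", 5000) == 1

    def test_cis_lod_equals_trans_lod_at_closest_marker(self, mapping_inputs):
        Y, genes, markers, cov, _ = mapping_inputs
        sub_genes = genes.iloc[:5].reset_index(drop=True)
        cis = eqtl.cis_scan(Y[:, :5], sub_genes, markers, cov)
        thetas = cis.set_index("gene")["theta"]
        peaks, lodmat = eqtl.trans_scan(Y[:, :5], sub_genes, markers, cov, thetas)
        for _, row in cis.iterrows():
            assert lodmat.loc[row["gene"], row["marker"]] == pytest.approx(
                row["lod"], abs=1e-4
            )

    def test_trans_peak_ci_contains_peak(self, mapping_inputs):
        Y, genes, markers, cov, _ = mapping_inputs
        sub_genes = genes.iloc[:4].reset_index(drop=True)
        peaks, _ = eqtl.trans_scan(Y[:, :4], sub_genes, markers, cov)
        assert (
            (peaks["ci_lo_marker"] <= peaks["marker"])
            & (peaks["marker"] <= peaks["ci_hi_marker"])
        ).all()


class TestLodDropInterval:
    def test_flat_curve_spans_chromosome(self):
        assert lod_drop_ci(np.full(10, 2.0), 4) == (0, 9)

    def test_single_spike_collapses_to_peak(self):
        lods = np.zeros(9)
        lods[4] = 8.0
        assert lod_drop_ci(lods, 4) == (4, 4)

    def test_outermost_markers_within_drop(self):
        lods = np.array([0.1, 4.0, 2.9, 5.0, 4.1, 0.2])
        assert lod_drop_ci(lods, 3, drop=1.5) == (1, 4)


class TestFdr:
    def test_identical_null_and_observed_gives_fdr_one(self):
        grid = np.arange(0.1, 2.0, 0.01)
        counts = np.linspace(100, 1, len(grid))
        curve = FdrCurve(grid, counts.copy(), counts.copy())
        assert np.allclose(curve.fdr, 1.0)

    def test_curve_is_monotone_non_increasing(self):
        rng = np.random.default_rng(2)
        grid = np.arange(0.1, 3.0, 0.01)
        observed = np.maximum(np.linspace(200, 1, len(grid)), 1)
        expected = observed * np.clip(rng.normal(0.5, 0.2, len(grid)), 0, 2)
        curve = FdrCurve(grid, expected, observed)
        assert (np.diff(curve.fdr[np.isfinite(curve.fdr)]) <= 1e-12).all()

    def test_permutation_fdr_controls_planted_cis(
        self, planted_dataset, mapping_inputs
    ):
        Y, genes, markers, cov, batch = mapping_inputs
        cis = eqtl.cis_scan(Y, genes, markers, cov)
        out, curves = eqtl.permutation_fdr(
            Y, genes, markers, cov, batch, cis, mode="cis", n_perm=5, seed=3
        )
        sig = out[out["fdr"] <= 0.1]
        planted = set(planted_dataset.truth.planted_cis["gene"])
        false = sum(g not in planted for g in sig["gene"])
        assert len(sig) > 0
        assert false / max(len(sig), 1) <= 0.3
        assert np.isfinite(curves["all"].fdr).any()

    def test_same_seed_reproduces_fdr(self, mapping_inputs):
        Y, genes, markers, cov, batch = mapping_inputs
        cis = eqtl.cis_scan(Y[:, :10], genes.iloc[:10], markers, cov)
        a, _ = eqtl.permutation_fdr(
            Y[:, :10], genes.iloc[:10], markers, cov, batch, cis, n_perm=2, seed=7
        )
        b, _ = eqtl.permutation_fdr(
            Y[:, :10], genes.iloc[:10], markers, cov, batch, cis, n_perm=2, seed=7
        )
        assert np.allclose(a["fdr"], b["fdr"])

    def test_permutation_stays_within_batch(self):
        rng = np.random.default_rng(4)
        batch = np.repeat(["a", "b"], 50)
        perm = eqtl.permute_within_batch(rng, batch)
        assert (batch[perm] == batch).all()
        assert (perm != np.arange(100)).any()

    def test_bh_stepup_hand_computed(self):
        assert np.allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert bh_fdr([0.7])[0] == pytest.approx(0.7)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)


class TestAuxiliaryStatistics:
    def test_correlation_lod_values(self):
        assert lod_from_correlation(0.0, 100) == 0.0
        assert lod_from_correlation(0.5, 100) == pytest.approx(15.051, abs=1e-3)
        with pytest.raises(ValueError):
            lod_from_correlation(1.0, 100)

    def test_correlation_lod_monotone(self):
        grid = [lod_from_correlation(r2, 50) for r2 in (0.1, 0.3, 0.5, 0.9)]
        assert (np.diff(grid) > 0).all()
        assert lod_from_correlation(0.5, 200) > lod_from_correlation(0.5, 100)

    def test_stouffer_weighted_z(self):
        assert stouffer_combine([1.5]) == pytest.approx(1.5)
        assert stouffer_combine([1.96, 1.96]) == pytest.approx(2.772, abs=1e-3)
        assert stouffer_combine([2.0, -2.0]) == pytest.approx(0.0)

    def test_direction_concordance_matches_reported_regimes(self):
        # 33 same / 36 opposite: indistinguishable from chance
        rng = np.random.default_rng(5)
        a = rng.normal(size=69)
        a[a == 0] = 1.0
        b = np.abs(rng.normal(size=69)) * np.sign(a)
        b[33:] *= -1
        same, opp, p = direction_concordance(a, b)
        assert (same, opp) == (33, 36)
        assert p > 0.5
        # 88 same / 6 opposite: overwhelming concordance
        a = np.abs(rng.normal(size=94)) + 0.01
        b = a.copy()
        b[:6] *= -1
        same, opp, p = direction_concordance(a, b)
        assert (same, opp) == (88, 6)
        assert p < 1e-6
        # even split: symmetric
        a = np.ones(20)
        b = np.concatenate([np.ones(10), -np.ones(10)])
        assert direction_concordance(a, b)[2] > 0.99

    def test_compositional_shift_leaves_genetic_effect(self, mapping_inputs):
        """Doubling total UMIs only moves the intercept, not the eQTL effect."""
        from cellqtl.nbglm import fit_nb_glm

        Y, genes, markers, cov, _ = mapping_inputs
        y = np.asarray(Y[:, [0]].todense()).ravel()
        X = np.column_stack([cov[:, :2], markers.values[:, 0]])  # no batch
        fit1 = fit_nb_glm(y, X, theta=2.0)
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] + np.log(2.0)
        fit2 = fit_nb_glm(y, X2, theta=2.0)
        assert fit1.beta[-1] == pytest.approx(fit2.beta[-1], abs=1e-6)
        assert np.sign(fit1.beta[-1]) == np.sign(fit2.beta[-1])


def test_standardize_population_variance():
    x = np.array([[1.0], [2.0], [3.0]])
    z = standardize(x)
    assert z.mean() == pytest.approx(0.0)
    assert z.var() == pytest.approx(1.0)
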