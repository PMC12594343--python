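"""Normalization, TF-IDF, regulatory potential, CCA and GIM fusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from branchgas.integration import (
    MultiomeIntegrator,
    build_gim,
    cca_align,
    compute_rp_scores,
    GeneActivityMatrix,
    normalize_rna,
    tfidf_normalize,
)


class TestNormalizeRNA:
    def test_hand_computed_values(self):
        out, kept = normalize_rna(np.array([[10, 0], [3, 1]]))
        assert np.allclose(out[0], [np.log1p(10_000), 0.0])
        assert np.allclose(out[1], [np.log1p(7500.0), np.log1p(2500.0)])
        assert list(kept) == [0, 1]

    def test_proportional_cells_identical(self):
        out, _ = normalize_rna(np.array([[1, 1], [2, 2]]))
        assert np.allclose(out[0], out[1])

    def test_all_zero_cell_dropped_and_all_zero_matrix_rejected(self):
        out, kept = normalize_rna(np.array([[1, 2], [0, 0]]))
        assert out.shape == (1, 2) and list(kept) == [0]
        with pytest.raises(ValueError):
            normalize_rna(np.zeros((3, 2)))


class TestTFIDF:
    def test_uniform_matrix_uniform_output(self):
        out, _ = tfidf_normalize(np.ones((2, 2)))
        assert np.allclose(out, out[0, 0])

    def test_rare_peak_upweighted(self):
        # peak 0 in all cells, peak 1 only in cell 0, equal raw counts
        mat = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        out, _ = tfidf_normalize(mat)
        assert out[0, 1] > out[0, 0]

    def test_hand_computed_formula(self):
        mat = np.array([[1.0, 0.0], [1.0, 1.0]])
        out, _ = tfidf_normalize(mat)
        # cell 0: tf = (1, 0); idf = (2/3, 2/2)
        expected_00 = np.log1p(1.0 * (2 / 3) * 1e4)
        expected_10 = np.log1p(0.5 * (2 / 3) * 1e4)
        expected_11 = np.log1p(0.5 * 1.0 * 1e4)
        assert np.allclose(out, [[expected_00, 0.0], [expected_10, expected_11]])


def _one_gene_annotation(tss=100_000, strand="+"):
    start, end = tss, tss + 5_000
    if strand == "-":
        start, end = tss - 5_000, tss
    return pd.DataFrame({
        "gene_id": ["g1"], "chrom": ["chr1"], "strand": [strand],
        "tss": [tss], "start": [start], "end": [end],
    })


class TestRegulatoryPotential:
    def _bed(self, centers, width=200):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [c - width // 2 for c in centers],
            "end": [c + width // 2 for c in centers],
            "name": [f"p{i}" for i in range(len(centers))],
        })

    def test_peak_at_tss_full_weight(self):
        genes = _one_gene_annotation()
        out = compute_rp_scores(np.array([[4.0]]), self._bed([100_000]), genes)
        assert np.allclose(out.values, [[4.0]])

    def test_half_weight_at_decay_distance(self):
        genes = _one_gene_annotation()
        out = compute_rp_scores(np.array([[4.0]]), self._bed([90_000]), genes,
                                decay_bp=10_000)
        assert np.allclose(out.values, [[2.0]])

    def test_additive_against_brute_force(self, rng):
        genes = pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "strand": ["+", "+"], "tss": [100_000, 400_000],
            "start": [100_000, 400_000], "end": [105_000, 405_000],
        })
        centers = [100_000, 90_000, 130_000, 395_000, 600_000]
        bed = self._bed(centers)
        access = rng.uniform(0, 5, size=(3, len(centers)))
        out = compute_rp_scores(access, bed, genes, decay_bp=10_000,
                                window_bp=50_000)
        # brute force over all peak-gene pairs
        expected = np.zeros((3, 2))
        for gi, gene in genes.iterrows():
            for pi, c in enumerate(centers):
                lo, hi = bed.loc[pi, "start"], bed.loc[pi, "end"]
                overlap = hi > gene["start"] and lo < gene["end"]
                d = 0.0 if overlap else abs(c - gene["tss"])
                if d <= 50_000:
                    expected[:, gi] += access[:, pi] * 2 ** (-d / 10_000)
        assert np.allclose(out.values, expected)

    def test_gene_without_peaks_scores_zero(self):
        genes = _one_gene_annotation()
        out = compute_rp_scores(np.array([[3.0]]), self._bed([900_000]), genes)
        assert np.allclose(out.values, 0.0)


class TestCCA:
    def test_identical_matrices_first_correlation_one(self, rng):
        X = rng.standard_normal((30, 5))
        _, corrs, _, _ = cca_align(X, X.copy(), k=3)
        assert corrs[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(corrs) <= 1e-9)

    def test_matches_grid_search_oracle(self, rng):
        X = rng.standard_normal((60, 2))
        Y = X @ rng.standard_normal((2, 2)) + 0.5 * rng.standard_normal((60, 2))
        _, corrs, _, _ = cca_align(X, Y, k=1)
        # exhaustive search over unit directions
        best = 0.0
        for ta in np.linspace(0, np.pi, 721):
            a = np.array([np.cos(ta), np.sin(ta)])
            for tb in np.linspace(0, np.pi, 721):
                b = np.array([np.cos(tb), np.sin(tb)])
                r = abs(np.corrcoef(X @ a, Y @ b)[0, 1])
                best = max(best, r)
        assert corrs[0] == pytest.approx(best, abs=1e-3)

    def test_independent_matrices_low_correlation(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((500, 4))
        Y = rng.standard_normal((500, 4))
        _, corrs, _, _ = cca_align(X, Y, k=4)
        assert np.all(corrs < 0.5)

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 3)) + 0.5 * X
        _, c1, _, _ = cca_align(X, Y, k=2)
        _, c2, _, _ = cca_align(X * 7.0 + 3.0, Y * 0.2 - 1.0, k=2)
        assert np.allclose(c1, c2, atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            cca_align(X, X, k=5)


class TestBuildGIM:
    def test_zero_activity_gives_half_scaled_rna(self, rng):
        rna = rng.uniform(0, 5, (6, 3))
        act = GeneActivityMatrix(np.zeros((6, 3)), ["a", "b", "c"])
        gim = build_gim(rna, act, rna_gene_ids=["a", "b", "c"])
        scaled = (rna - rna.min(0)) / (rna.max(0) - rna.min(0))
        assert np.allclose(gim.X, 0.5 * scaled)

    def test_identical_modalities_idempotent(self, rng):
        rna = rng.uniform(0, 5, (6, 3))
        act = GeneActivityMatrix(rna.copy(), ["a", "b", "c"])
        gim = build_gim(rna, act, rna_gene_ids=["a", "b", "c"])
        scaled = (rna - rna.min(0)) / (rna.max(0) - rna.min(0))
        assert np.allclose(gim.X, scaled)

    def test_hand_computed_two_by_two(self):
        rna = np.array([[0.0, 1.0], [1.0, 0.0]])
        act = GeneActivityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]),
                                 ["g1", "g2"])
        gim = build_gim(rna, act, rna_gene_ids=["g1", "g2"])
        assert np.allclose(gim.X, 0.5)

    def test_empty_intersection_rejected(self, rng):
        act = GeneActivityMatrix(rng.uniform(0, 1, (4, 2)), ["x", "y"])
        with pytest.raises(ValueError):
            build_gim(rng.uniform(0, 1, (4, 2)), act, rna_gene_ids=["a", "b"])

    def test_cca_smoothed_mode_nonnegative(self, gim7):
        assert (gim7.X >= 0).all()


def test_integrator_end_to_end_nonnegative_and_aligned(sim7, gim7):
    assert gim7.shape == (300, 200)
    assert not np.isnan(gim7.X).any()
    assert gim7.gene_ids == sim7.gene_ids
    assert gim7.provenance["mode"] == "average"


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_gim_nonnegative_property(seed):
    rng = np.random.default_rng(seed)
    rna = rng.poisson(2.0, size=(12, 6)).astype(float)
    rna[0] += 1  # keep at least one nonzero per cell
    act = GeneActivityMatrix(rng.uniform(0, 3, (12, 6)),
                             [f"g{i}" for i in range(6)])
    gim = build_gim(rna, act, rna_gene_ids=[f"g{i}" for i in range(6)])
    assert (gim.X >= 0).all() and not np.isnan(gim.X).any()
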