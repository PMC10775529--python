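"""LD statistics, EM haplotype frequencies, D' confidence intervals and
Gabriel block detection."""

import numpy as np
import pandas as pd
import pytest

from driftscan.errors import ValidationError
from driftscan.linkage import (
    block_summary,
    dosage_r2,
    dprime_ci,
    dprime_point,
    em_haplotype_freqs,
    gabriel_blocks,
    HaplotypeBlock,
    ld_decay,
    pairwise_r2,
)
from driftscan.variant_io import MISSING

from conftest import make_matrix


class TestDosageR2:
    def test_hand_computed_value(self):
        gi = np.array([0, 0, 1, 1, 2, 2])
        gj = np.array([0, 1, 0, 1, 2, 2])
        assert dosage_r2(gi, gj) == pytest.approx(9 / 16)

    def test_copy_gives_one_and_flip_invariance(self):
        rng = np.random.default_rng(0)
        gi = rng.integers(0, 3, 40)
        gj = rng.integers(0, 3, 40)
        assert dosage_r2(gi, gi.copy()) == pytest.approx(1.0)
        assert dosage_r2(gi, 2 - gj) == pytest.approx(dosage_r2(gi, gj))

    def test_pairwise_complete_missing_handling(self):
        rng = np.random.default_rng(1)
        gi = rng.integers(0, 3, 60)
        gj = rng.integers(0, 3, 60)
        gi_m = gi.copy()
        gi_m[:10] = MISSING
        keep = np.arange(60) >= 10
        assert dosage_r2(gi_m, gj) == pytest.approx(dosage_r2(gi[keep], gj[keep]))

    def test_monomorphic_is_nan(self):
        assert np.isnan(dosage_r2(np.zeros(10, int), np.arange(10) % 3))

    def test_matrix_path_agrees_with_scalar_path(self):
        rng = np.random.default_rng(2)
        dose = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        dose[rng.random(dose.shape) < 0.1] = MISSING
        M = pairwise_r2(dose)
        for i in range(8):
            for j in range(i + 1, 8):
                expect = dosage_r2(dose[:, i], dose[:, j])
                if np.isnan(expect):
                    assert np.isnan(M[i, j])
                else:
                    assert M[i, j] == pytest.approx(expect)


class TestEmHaplotypes:
    def test_unambiguous_phase(self):
        f = em_haplotype_freqs(np.array([0, 2]), np.array([0, 2]))
        assert f == pytest.approx((0.5, 0.0, 0.0, 0.5))
        assert dprime_point(f) == pytest.approx(1.0)

    def test_simplex_constraints(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            gi = rng.integers(0, 3, 30)
            gj = rng.integers(0, 3, 30)
            f = np.array(em_haplotype_freqs(gi, gj))
            assert np.all(f >= -1e-12)
            assert f.sum() == pytest.approx(1.0)

    def test_loglik_trace_monotone(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            gi = rng.integers(0, 3, 24)
            gj = rng.integers(0, 3, 24)
            _, trace = em_haplotype_freqs(gi, gj, return_loglik_trace=True)
            assert np.all(np.diff(trace) >= -1e-9)

    def test_matches_brute_force_profile_likelihood(self):
        """EM equals direct likelihood maximisation over the one free
        parameter D (marginals are fixed at sample values by EM)."""
        from driftscan.linkage import _loglik, _pair_counts

        rng = np.random.default_rng(5)
        checked = 0
        while checked < 50:
            gi = rng.integers(0, 3, 40)
            gj = rng.integers(0, 3, 40)
            if len(set(gi)) < 2 or len(set(gj)) < 2:
                continue
            f_em = np.array(em_haplotype_freqs(gi, gj, tol=1e-12, max_iter=20_000))
            counts = _pair_counts(gi, gj)
            n = counts.sum()
            p = (2 * counts.sum(axis=1)[0] + counts.sum(axis=1)[1]) / (2 * n)
            q = (2 * counts.sum(axis=0)[0] + counts.sum(axis=0)[1]) / (2 * n)
            dmin = -min(p * (1 - q), (1 - p) * q)
            dmax = min(p * q, (1 - p) * (1 - q))
            best, best_ll = None, -np.inf
            for D in np.linspace(-dmax, -dmin, 4001):  # sign: f00 = pq + D
                f = np.array(
                    [p * q + D, p * (1 - q) - D, (1 - p) * q - D, (1 - p) * (1 - q) + D]
                )
                if (f < -1e-12).any():
                    continue
                ll = _loglik(np.clip(f, 0, 1), counts)
                if ll > best_ll:
                    best, best_ll = f, ll
            assert np.max(np.abs(f_em - best)) < 1e-3
            checked += 1


class TestDprimeCI:
    def test_complete_ld_is_strong(self):
        rng = np.random.default_rng(6)
        h = rng.integers(0, 2, size=(100, 2))
        g = h.sum(axis=1)
        d, lo, hi = dprime_ci(g, g.copy())
        assert d == pytest.approx(1.0, abs=1e-6)
        assert lo > 0.7 and hi > 0.98

    def test_independent_loci_show_recombination_evidence(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            g1 = rng.integers(0, 2, size=(100, 2)).sum(axis=1)
            g2 = rng.integers(0, 2, size=(100, 2)).sum(axis=1)
            _, lo, hi = dprime_ci(g1, g2)
            assert lo <= hi
            if hi < 0.9:
                hits += 1
        assert hits >= 80

    def test_monomorphic_rejected(self):
        with pytest.raises(ValidationError):
            dprime_ci(np.zeros(20, int), np.arange(20) % 3)


def _two_cluster_matrix(rng, gap_chrom_pos=True):
    """5+5 SNPs in two perfect-LD clusters with ~zero inter-cluster LD."""
    c1 = np.repeat([0, 1, 2], [8, 16, 8])
    c2 = np.array(c1)
    rng.shuffle(c2)  # independent assortment of cluster genotypes
    while abs(np.corrcoef(c1, c2)[0, 1]) > 0.15:
        rng.shuffle(c2)
    dose = np.stack([c1] * 5 + [c2] * 5, axis=1).astype(np.int8)
    pos = np.concatenate([1000 + np.arange(5) * 2000, 150_000 + np.arange(5) * 2000])
    return make_matrix(dose, positions=pos)


class TestGabrielBlocks:
    def test_two_clusters_give_two_blocks_split_at_gap(self):
        rng = np.random.default_rng(8)
        gm = _two_cluster_matrix(rng)
        blocks = gabriel_blocks(gm)
        assert len(blocks) == 2
        spans = sorted((b.start, b.end) for b in blocks)
        assert spans[0] == (1000, 9000)
        assert spans[1] == (150_000, 158_000)

    def test_independent_loci_rarely_form_blocks(self):
        blockless = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            dose = rng.integers(0, 2, size=(100, 2, 15)).sum(axis=1).astype(np.int8)
            gm = make_matrix(dose, positions=np.arange(1, 16) * 5000)
            if not gabriel_blocks(gm):
                blockless += 1
        assert blockless >= 9

    def test_postconditions_and_invariances(self, linked_study):
        gm = linked_study.populations["B9A"]
        blocks = gabriel_blocks(gm)
        assert blocks, "expected blocks under tight linkage and drift"
        for b in blocks:
            assert b.n_snps >= 2
            assert b.length <= 200_000
        # non-overlap within each chromosome
        by_chrom = {}
        for b in blocks:
            by_chrom.setdefault(b.chrom, []).append(b)
        for bs in by_chrom.values():
            bs.sort(key=lambda b: b.start)
            for a, b in zip(bs, bs[1:]):
                assert a.end < b.start
        # sample-order invariance
        rng = np.random.default_rng(9)
        perm = list(rng.permutation(gm.sample_ids))
        assert gabriel_blocks(gm.take_samples(perm)) == blocks

    def test_allele_relabelling_invariance(self):
        rng = np.random.default_rng(10)
        gm = _two_cluster_matrix(rng)
        flipped = gm.dosage.copy()
        flipped[:, ::2] = 2 - flipped[:, ::2]
        gm2 = make_matrix(flipped, positions=gm.snps["pos"].to_numpy())
        assert gabriel_blocks(gm2) == gabriel_blocks(gm)

    def test_single_snp_chromosome_yields_no_blocks(self):
        gm = make_matrix(np.array([[0], [1], [2], [1]], dtype=np.int8))
        assert gabriel_blocks(gm) == []


class TestLdDecay:
    def test_duplicate_snp_pair_contributes_unity(self):
        rng = np.random.default_rng(11)
        col = rng.integers(0, 3, size=32)
        dose = np.stack([col, col], axis=1).astype(np.int8)
        gm = make_matrix(dose, positions=[1000, 3500])
        pops = pd.DataFrame({"sample_id": gm.sample_ids, "population": "P"})
        out = ld_decay(gm, pops, max_dist_kb=10, bin_width_kb=5)
        first = out[(out.population == "P") & (out.bin_start_kb == 0)]
        assert first["median_r2"].iloc[0] == pytest.approx(1.0)
        assert bool(first["low_n"].iloc[0])  # a single pair is flagged

    def test_sample_permutation_leaves_medians_unchanged(self, linked_study):
        gm = linked_study.populations["A1"]
        pops = pd.DataFrame({"sample_id": gm.sample_ids, "population": "A1"})
        base = ld_decay(gm, pops, max_dist_kb=20, bin_width_kb=4)
        rng = np.random.default_rng(12)
        perm = list(rng.permutation(gm.sample_ids))
        shuffled = ld_decay(gm.take_samples(perm), pops, max_dist_kb=20, bin_width_kb=4)
        assert np.allclose(
            base["median_r2"].to_numpy(),
            shuffled["median_r2"].to_numpy(),
            equal_nan=True,
        )


class TestBlockSummary:
    def test_empty_and_simple_means(self):
        out = block_summary(
            {
                "empty": [],
                "two": [
                    HaplotypeBlock("A01", 1, 10_000, 4),
                    HaplotypeBlock("A01", 50_000, 79_999, 6),
                ],
            }
        )
        row_empty = out[out.population == "empty"].iloc[0]
        assert row_empty["n_blocks"] == 0 and np.isnan(row_empty["mean_length_kb"])
        row_two = out[out.population == "two"].iloc[0]
        assert row_two["mean_length_kb"] == pytest.approx(20.0)
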