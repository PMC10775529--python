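"""Drift null, empirical p-values, FDR and scan behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import driftscan as ds
from driftscan.drift import (
    DriftBank,
    bh_fdr,
    build_drift_bank,
    delta_h,
    empirical_pvalue,
    intersect_significant,
    scan_all_pairs,
    scan_population,
    wright_fisher_final_af,
)
from driftscan.errors import ValidationError
from driftscan.simulate import merged_matrix


class TestWrightFisher:
    def test_absorbing_states(self):
        rng = np.random.default_rng(0)
        assert wright_fisher_final_af(0.0, rng=rng) == 0.0
        assert wright_fisher_final_af(1.0, rng=rng) == 1.0

    def test_martingale_mean_and_variance(self):
        rng = np.random.default_rng(1)
        finals = wright_fisher_final_af(0.5, ne=16, transitions=8, rng=rng, size=10_000)
        se = np.sqrt(finals.var() / finals.size)
        assert abs(finals.mean() - 0.5) < 3 * se
        expected = 0.25 * (1 - (1 - 1 / 32) ** 8)
        assert abs(finals.var() - expected) / expected < 0.10

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            wright_fisher_final_af(1.5)
        with pytest.raises(ValidationError):
            wright_fisher_final_af(0.5, ne=0)
        with pytest.raises(ValidationError):
            wright_fisher_final_af(0.5, transitions=0)


class TestDriftBank:
    def test_edge_grid_points_are_absorbed(self, bank16):
        assert (bank16.sims[0] == 0).all()
        assert (bank16.sims[-1] == 1).all()
        assert len(bank16.grid) == 101

    def test_build_is_deterministic(self):
        a = build_drift_bank(n_sim=500, seed=7)
        b = build_drift_bank(n_sim=500, seed=7)
        assert np.array_equal(a.sims, b.sims)

    def test_neutral_symmetry_at_half(self, bank16):
        """Final-AF distribution from p0=0.5 is symmetric about 0.5."""
        sims = np.sort(bank16.sims[50])
        xs = np.linspace(0.01, 0.99, 99)
        # P(X <= x) should match P(X >= 1-x) = 1 - P(X < 1-x)
        F = np.searchsorted(sims, xs, side="right") / sims.size
        L = np.searchsorted(sims, 1 - xs, side="left") / sims.size
        assert np.max(np.abs(F + L - 1)) < 0.03

    def test_save_load_round_trip(self, bank16, tmp_path):
        p = tmp_path / "bank.npz"
        bank16.save(p)
        loaded = DriftBank.load(p)
        assert np.array_equal(loaded.sims, bank16.sims)
        assert (loaded.ne, loaded.transitions, loaded.seed) == (16, 8, 123)

    def test_grid_assignment_ties_toward_lower(self, bank16):
        idx = bank16.grid_index(np.array([0.005, 0.014, 0.015, 0.996]))
        assert list(idx) == [0, 1, 1, 100]


def _toy_bank():
    """Hand-constructed bank: oracle for tail counting."""
    grid = np.round(np.linspace(0, 1, 101), 10)
    rng = np.random.default_rng(99)
    sims = rng.random((101, 200)).astype(np.float32)
    sims[0] = 0
    sims[-1] = 1
    return DriftBank(grid=grid, sims=sims, ne=16, transitions=8)


class TestEmpiricalPvalue:
    def test_no_change_gives_one(self, bank16):
        assert empirical_pvalue(0.3, 0.3, bank16) == 1.0

    def test_matches_brute_force_recount(self):
        """p equals a direct tail count over the stored simulations."""
        bank = _toy_bank()
        rng = np.random.default_rng(5)
        a0 = rng.random(100)
        a1 = rng.random(100)
        p = empirical_pvalue(a0, a1, bank)
        for k in range(100):
            row = bank.sims[bank.grid_index(np.array([a0[k]]))[0]]
            if a0[k] > a1[k]:
                expect = np.sum(row <= a1[k]) / row.size
            elif a0[k] < a1[k]:
                expect = np.sum(row >= a1[k]) / row.size
            else:
                expect = 1.0
            assert p[k] == pytest.approx(expect)

    def test_literal_tails_swap_directions(self):
        bank = _toy_bank()
        p = empirical_pvalue(0.8, 0.2, bank, literal_tails=True)
        row = bank.sims[bank.grid_index(np.array([0.8]))[0]]
        assert p == pytest.approx(np.sum(row >= 0.2) / row.size)

    def test_empty_tail_gives_zero(self):
        bank = _toy_bank()
        bank.sims[80] = np.clip(bank.sims[80], 0.3, None)  # nothing below 0.3
        assert empirical_pvalue(0.8, 0.1, bank) == 0.0

    def test_deeper_tail_never_raises_p(self, bank16):
        finals = np.linspace(0.4, 0.0, 30)
        p = empirical_pvalue(np.full(30, 0.6), finals, bank16)
        assert np.all(np.diff(p) <= 0)

    def test_missing_af_propagates_nan(self, bank16):
        p = empirical_pvalue(np.array([np.nan, 0.4]), np.array([0.2, 0.2]), bank16)
        assert np.isnan(p[0]) and not np.isnan(p[1])


class TestDeltaH:
    def test_examples(self):
        assert delta_h(0.2, 0.7) == pytest.approx(0.5)
        assert delta_h(0.4, 0.4) == 0.0

    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert delta_h(a, b) == pytest.approx(-delta_h(b, a))


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.04, 0.8])
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_degenerate_inputs(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)
        assert bh_fdr([]).size == 0

    def test_q_at_least_p_and_order_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p[perm]), q[perm])


def _af_table(study):
    gm = merged_matrix(study)
    return ds.allele_frequencies(gm, study.sample_map)


class TestScan:
    def test_drift_only_data_rarely_flagged(self, bank16):
        """Null calibration at matched effective size: a handful of flags at
        most across populations (spec's <= 2 per scan guide)."""
        params = ds.SimulationParams(
            n_snps=500,
            n_plants=16,
            n_sequenced=16,
            chromosomes=(("A01", 10_000_000), ("A02", 10_000_000)),
            missing_rate=0.0,
            seed=3,
        )
        study = ds.simulate_experiment(params)
        scan = scan_all_pairs(_af_table(study), bank16)
        per_pop = scan[scan.significant].groupby("population").size()
        assert per_pop.sum() <= 2

    def test_null_pvalue_tail_is_calibrated(self, bank16):
        """P(p <= 0.05) under the null is close to 0.05: the tail that FDR
        control consumes is honest even though the global law is folded."""
        params = ds.SimulationParams(
            n_snps=1000,
            n_plants=16,
            n_sequenced=16,
            chromosomes=(("A01", 10_000_000),),
            missing_rate=0.0,
            seed=4,
        )
        study = ds.simulate_experiment(params)
        scan = scan_all_pairs(_af_table(study), bank16)
        frac = (scan.pvalue < 0.05).mean()
        assert abs(frac - 0.05) < 0.03

    def test_missing_af_records_skipped(self, bank16):
        af = pd.DataFrame(
            {
                "chrom": ["A01"] * 4,
                "pos": [1, 2, 1, 2],
                "population": ["G1", "G1", "G9", "G9"],
                "af_ref": [0.5, np.nan, 0.1, 0.4],
                "n_called": [10, 0, 10, 10],
            }
        )
        out = scan_population(af, bank16, "G1", "G9")
        assert len(out) == 1
        assert out.attrs["n_skipped"] == 1

    def test_no_overlap_rejected(self, bank16):
        af = pd.DataFrame(
            {
                "chrom": ["A01", "A02"],
                "pos": [1, 1],
                "population": ["G1", "G9"],
                "af_ref": [0.5, 0.5],
                "n_called": [10, 10],
            }
        )
        with pytest.raises(ValidationError):
            scan_population(af, bank16, "G1", "G9")

    def test_power_monotone_in_selection_strength(self, bank36):
        """Fraction of truth loci recovered does not decrease with s
        (null matched to the census size so recovery is observable)."""
        flagged = {}
        for s in (0.1, 0.3, 0.5):
            hits = 0
            for seed in range(3):
                sel = tuple((i * 20 + 3, s) for i in range(10))
                params = ds.SimulationParams(
                    n_snps=200,
                    n_plants=36,
                    n_sequenced=32,
                    recomb_fraction=0.5,
                    chromosomes=(("A01", 10_000_000), ("A02", 10_000_000)),
                    missing_rate=0.0,
                    selected_loci=sel,
                    seed=seed,
                )
                study = ds.simulate_experiment(params)
                scan = scan_all_pairs(_af_table(study), bank36)
                bb = scan[scan.population.str.startswith("bumblebee")]
                sig = set(map(tuple, bb[bb.significant][["chrom", "pos"]].to_numpy()))
                truth = set(map(tuple, study.truth[["chrom", "pos"]].to_numpy()))
                hits += len(sig & truth)
            flagged[s] = hits
        assert flagged[0.1] <= flagged[0.3] <= flagged[0.5]


class TestIntersections:
    def test_exclusive_counts(self):
        out = intersect_significant({"A": {1, 2, 3}, "B": {3, 4}})
        got = dict(zip(out["members"], out["count"]))
        assert got == {"A": 2, "B": 1, "A+B": 1}

    def test_identical_sets_concentrate_on_full_intersection(self):
        out = intersect_significant({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        got = dict(zip(out["members"], out["count"]))
        assert got["A+B+C"] == 2
        assert sum(v for k, v in got.items() if k != "A+B+C") == 0

    def test_counts_partition_the_union(self):
        rng = np.random.default_rng(8)
        sets = {
            name: set(rng.integers(0, 40, size=rng.integers(0, 25)).tolist())
            for name in "ABCD"
        }
        out = intersect_significant(sets)
        union = set().union(*sets.values())
        assert out["count"].sum() == len(union)
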