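"""Synthetic amplicons, electropherograms, clone libraries, chemistry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trflp import peaks as P
from trflp.digest import dual_pattern, find_recognition_sites
from trflp.simulate import (
    UNCUT,
    CommunitySpec,
    InfeasibleTargetError,
    NoiseSpec,
    TaxonSpec,
    make_reference_design,
    make_taxon_sequence,
    simulate_chemistry,
    simulate_clone_library,
    simulate_electropherogram,
)

targets = st.one_of(st.integers(min_value=50, max_value=550), st.just(UNCUT))


class TestMakeTaxonSequence:
    def test_target_pair_round_trip(self):
        spec = TaxonSpec("otu9", "Pestalotiopsis", 325, 148)
        seq = make_taxon_sequence(spec, seed=7)
        hha, msp = dual_pattern(seq)
        assert (hha.trf_length, msp.trf_length) == (325, 148)
        assert len(seq) == 600

    def test_uncut_enzyme_motif_absent(self):
        seq = make_taxon_sequence(TaxonSpec("u", target_hha=UNCUT, target_msp=101), seed=2)
        assert "GCGC" not in seq
        hha, msp = dual_pattern(seq)
        assert hha.uncut and msp.trf_length == 101

    def test_short_target_cut_position_verified_by_motif_scan(self):
        # HhaI target 7: motif occupies positions 4-7 after a 4-base flank
        seq = make_taxon_sequence(TaxonSpec("s", target_hha=7, target_msp=UNCUT, amplicon_length=60), seed=0)
        assert find_recognition_sites(seq, "HhaI")[0] == 4
        assert seq[4:8] == "GCGC"

    def test_no_upstream_motif_of_either_enzyme(self):
        spec = TaxonSpec("t", target_hha=300, target_msp=120)
        seq = make_taxon_sequence(spec, seed=11)
        assert find_recognition_sites(seq, "HhaI")[0] == 300 - 3
        assert find_recognition_sites(seq, "MspI")[0] == 120 - 1

    def test_deterministic_under_seed(self):
        spec = TaxonSpec("t", target_hha=200, target_msp=100)
        assert make_taxon_sequence(spec, 5) == make_taxon_sequence(spec, 5)
        assert make_taxon_sequence(spec, 5) != make_taxon_sequence(spec, 6)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(InfeasibleTargetError):
            make_taxon_sequence(TaxonSpec("t", target_hha=2, target_msp=UNCUT), 0)
        with pytest.raises(ValueError):
            TaxonSpec("t", target_hha=600, target_msp=UNCUT, amplicon_length=600)

    @settings(max_examples=40)
    @given(hha=targets, msp=targets, seed=st.integers(0, 2**20))
    def test_round_trip_property(self, hha, msp, seed):
        spec = TaxonSpec("t", target_hha=hha, target_msp=msp)
        try:
            seq = make_taxon_sequence(spec, seed)
        except InfeasibleTargetError:
            return  # overlapping planted motifs can genuinely conflict
        res_h, res_m = dual_pattern(seq)
        assert res_h.trf_length == (None if hha == UNCUT else hha)
        assert res_m.trf_length == (None if msp == UNCUT else msp)


class TestSimulateElectropherogram:
    def test_degenerate_single_taxon_exact_peak(self):
        pool = {"a": TaxonSpec("a", target_hha=200, target_msp=100)}
        comm = CommunitySpec("s", {}, {"a": 1.0})
        noise = NoiseSpec(size_jitter_sd=0.0, n_noise_peaks=0, height_cv=0.0)
        table = simulate_electropherogram(comm, pool, "HhaI", noise)
        assert len(table) == 1
        assert table.sizes[0] == 200.0
        assert table.heights[0] == noise.total_signal

    def test_abundances_conserved_through_filter_and_normalize(self, design):
        comm = design.communities[3]
        noise = NoiseSpec(size_jitter_sd=0.0, n_noise_peaks=8, height_cv=0.0, seed=1)
        table = simulate_electropherogram(comm, design.pool, "HhaI", noise)
        profile = P.normalize(P.filter_peaks(table))
        expected = {
            float(design.pool[t].target_hha): a for t, a in comm.abundances.items()
        }
        assert profile.bins == pytest.approx(expected, abs=1e-12)

    def test_noise_peaks_always_filtered(self, design):
        comm = design.communities[0]
        noise = NoiseSpec(n_noise_peaks=50, seed=3)
        table = simulate_electropherogram(comm, design.pool, "HhaI", noise)
        kept = P.filter_peaks(table)
        taxa_present = sum(1 for a in comm.abundances.values() if a > 0)
        assert len(kept) == taxa_present

    def test_seeding_contract(self, design):
        comm = design.communities[0]
        t1 = simulate_electropherogram(comm, design.pool, "HhaI", NoiseSpec(seed=1))
        t2 = simulate_electropherogram(comm, design.pool, "HhaI", NoiseSpec(seed=1))
        t3 = simulate_electropherogram(comm, design.pool, "HhaI", NoiseSpec(seed=2))
        assert np.array_equal(t1.sizes, t2.sizes) and np.array_equal(t1.heights, t2.heights)
        assert not np.array_equal(t1.sizes, t3.sizes)

    def test_unknown_enzyme_and_missing_taxon(self, design):
        comm = CommunitySpec("s", {}, {"ghost": 1.0})
        with pytest.raises(KeyError, match="ghost"):
            simulate_electropherogram(comm, design.pool, "HhaI")
        with pytest.raises(KeyError):
            simulate_electropherogram(design.communities[0], design.pool, "EcoRI")

    def test_uncut_taxon_falls_outside_window(self):
        pool = {"m": TaxonSpec("m", target_hha=UNCUT, target_msp=100)}
        comm = CommunitySpec("s", {}, {"m": 1.0})
        noise = NoiseSpec(size_jitter_sd=0.0, n_noise_peaks=0, height_cv=0.0)
        table = simulate_electropherogram(comm, pool, "HhaI", noise)
        assert table.sizes[0] == 600.0  # full-length product, outside 50-550
        assert len(P.filter_peaks(table)) == 0


class TestSimulateCloneLibrary:
    def test_pure_community_all_identical(self, design):
        pool = {"a": TaxonSpec("a", target_hha=200, target_msp=100)}
        comm = CommunitySpec("s", {}, {"a": 1.0})
        lib = simulate_clone_library(comm, pool, 10, seed=0)
        assert lib == [(200, 100)] * 10

    def test_even_split_within_binomial_bounds(self):
        pool = {
            "a": TaxonSpec("a", target_hha=200, target_msp=100),
            "b": TaxonSpec("b", target_hha=300, target_msp=150),
        }
        comm = CommunitySpec("s", {}, {"a": 0.5, "b": 0.5})
        lib = simulate_clone_library(comm, pool, 226, seed=4)
        count_a = sum(1 for p in lib if p == (200, 100))
        # 99% binomial interval around 113: 113 +/- 2.576*sqrt(226/4)
        half = 2.576 * np.sqrt(226 * 0.25)
        assert 113 - half <= count_a <= 113 + half

    def test_invalid_inputs_rejected(self, design):
        with pytest.raises(ValueError):
            simulate_clone_library(design.communities[0], design.pool, 0)
        comm = CommunitySpec("s", {}, {"ghost": 1.0})
        with pytest.raises(KeyError, match="ghost"):
            simulate_clone_library(comm, design.pool, 5)

    def test_deterministic(self, design):
        comm = design.communities[1]
        assert simulate_clone_library(comm, design.pool, 50, 9) == simulate_clone_library(
            comm, design.pool, 50, 9
        )


class TestSimulateChemistry:
    def test_zero_sd_replicates_equal_group_mean(self):
        groups = {"g": {"galangin": (10.0, 0.0)}}
        table = simulate_chemistry(groups, {"s1": "g", "s2": "g"}, 3, seed=0)
        assert (table["mean"] == 10.0).all()
        assert (table["sd"] == 0.0).all()
        assert (table["n"] == 3).all()

    def test_single_group_single_analyte_grouping(self):
        from trflp.chemistry import chem_groups

        groups = {"g": {"galangin": (10.0, 0.3)}}
        design = {f"s{i}": "g" for i in range(4)}
        table = simulate_chemistry(groups, design, 3, seed=1)
        assert len(chem_groups(table, "galangin").group_order) == 1

    def test_unknown_group_and_bad_n(self):
        groups = {"g": {"x": (1.0, 0.1)}}
        with pytest.raises(KeyError):
            simulate_chemistry(groups, {"s": "h"}, 3, 0)
        with pytest.raises(ValueError):
            simulate_chemistry(groups, {"s": "g"}, 1, 0)

    def test_deterministic(self):
        groups = {"g": {"x": (1.0, 0.1)}}
        t1 = simulate_chemistry(groups, {"s": "g"}, 3, 5)
        t2 = simulate_chemistry(groups, {"s": "g"}, 3, 5)
        assert t1.equals(t2)


class TestReferenceDesign:
    def test_twelve_samples_four_groups(self, design):
        assert len(design.communities) == 12
        assert set(design.sample_groups.values()) == {"High", "Sub-high", "Intermediate", "Low"}
        for comm in design.communities:
            assert sum(comm.abundances.values()) == pytest.approx(1.0, abs=1e-9)

    def test_bit_reproducible(self):
        d1 = make_reference_design(3)
        d2 = make_reference_design(3)
        for c1, c2 in zip(d1.communities, d2.communities):
            assert c1.abundances == c2.abundances

    def test_noise_spec_invariants(self):
        with pytest.raises(ValueError):
            NoiseSpec(size_jitter_sd=0.5)
        with pytest.raises(ValueError):
            NoiseSpec(n_noise_peaks=-1)
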