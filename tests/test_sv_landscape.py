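"""SV filtering rules, spectra, window tilings, hotspot detection and
SV-gene annotation."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_sv

from panlandscape import io
from panlandscape.errors import ConfigError, CoordinateError
from panlandscape.records import GeneRecord
from panlandscape.sv_landscape import (
    annotate_sv_gene,
    detect_hotspots,
    filter_svs,
    hotspot_significance,
    make_windows,
    simulate_matched_null,
    sv_spectrum,
    window_breakpoint_counts,
)

CHROM = {"chr01": 10_000_000}


def twelve_record_toy_set():
    """Hand-constructed records covering every filter-rule boundary.

    Expected survivors: keep_min_len, keep_max_len, keep_depth_boundary,
    keep_plain.
    """
    gaps = [("chr01", 2_000_000, 2_010_000)]
    svs = [
        make_sv("rm_len_49", svlen=49),                          # rule 1 low
        make_sv("keep_min_len", svlen=50),                       # boundary keep
        make_sv("keep_max_len", svlen=1_000_000, pos=3_000_000), # boundary keep
        make_sv("rm_len_1mb_plus1", svlen=1_000_001, pos=3_000_000),  # rule 1 high
        make_sv("rm_depth_29", depth=29),                        # rule 5
        make_sv("keep_depth_boundary", depth=30),                # boundary keep
        make_sv("rm_all_ref", genotypes={"a1": 0, "a2": 0}),     # rule 3
        make_sv("rm_imprecise", precise=False),                  # rule 4
        make_sv("rm_in_gap", pos=2_005_000),                     # rule 2
        make_sv("rm_multi", svlen=30, depth=10, precise=False),  # rules 1+4+5
        make_sv("keep_plain", pos=5_000_000),
        make_sv("rm_missing_depth", depth=None),                 # rule 5 (missing)
    ]
    expected_kept = {"keep_min_len", "keep_max_len", "keep_depth_boundary", "keep_plain"}
    return svs, gaps, expected_kept


class TestFilterSVs:
    def test_toy_set_matches_manual_enumeration(self):
        svs, gaps, expected = twelve_record_toy_set()
        with pytest.warns(UserWarning, match="missing read depth"):
            kept, counts = filter_svs(svs, gaps)
        assert {sv.sv_id for sv in kept} == expected
        assert counts["length_out_of_range"] == 3
        assert counts["in_reference_gap"] == 1
        assert counts["absent_genotype"] == 1
        assert counts["imprecise"] == 2
        assert counts["low_depth"] == 3
        assert counts["low_depth_missing"] == 1

    def test_toy_set_survives_vcf_round_trip(self, tmp_path):
        svs, gaps, expected = twelve_record_toy_set()
        path = tmp_path / "toy.vcf"
        io.write_sv_vcf(svs, ["a1", "a2"], CHROM, path)
        with pytest.warns(UserWarning):
            kept, _ = filter_svs(io.read_sv_vcf(path), gaps)
        assert {sv.sv_id for sv in kept} == expected

    def test_filtering_is_idempotent_and_partitions_input(self):
        svs, gaps, _ = twelve_record_toy_set()
        with pytest.warns(UserWarning):
            kept, counts = filter_svs(svs, gaps)
        kept2, counts2 = filter_svs(kept, gaps)
        assert kept2 == kept
        assert all(v == 0 for v in counts2.values())
        n_rejected = len(svs) - len(kept)
        assert n_rejected == len({s.sv_id for s in svs} - {s.sv_id for s in kept})


class TestSpectrum:
    def test_all_short(self):
        svs = [make_sv(f"s{i}", svlen=200, pos=1000 * (i + 1)) for i in range(5)]
        assert sv_spectrum(svs)["frac_lt_1kb"] == 1.0

    def test_rare_and_universal_mafs(self):
        genos_rare = {f"a{i}": int(i == 0) for i in range(100)}
        genos_all = {f"a{i}": 1 for i in range(100)}
        svs = [make_sv("rare", genotypes=genos_rare), make_sv("fixed", genotypes=genos_all)]
        spec = sv_spectrum(svs)
        # rare SV: MAF 0.01 (< 0.05); fixed SV: MAF 0
        assert spec["frac_maf_lt_005"] == 1.0
        assert spec["frac_shared_ge2"] == 0.5

    def test_all_missing_excluded(self):
        svs = [make_sv("m", genotypes={"a1": None, "a2": None}), make_sv("ok")]
        spec = sv_spectrum(svs)
        assert spec["n_excluded_missing"] == 1


class TestWindows:
    def test_500kb_chromosome_tiling(self):
        w = make_windows({"c": 500_000})
        assert list(map(tuple, w[["start", "end"]].to_numpy())) == [
            (0, 200_000), (100_000, 300_000), (200_000, 400_000), (300_000, 500_000)]

    def test_trailing_partial_window(self):
        w = make_windows({"c": 520_000})
        assert tuple(w.iloc[-1][["start", "end"]]) == (400_000, 520_000)

    def test_short_chromosome_single_window(self):
        w = make_windows({"c": 150_000})
        assert len(w) == 1 and tuple(w.iloc[0][["start", "end"]]) == (0, 150_000)

    def test_breakpoint_in_two_overlapping_windows(self):
        sv = make_sv("d", pos=150_000, svlen=100)  # both ends in [0,200k) & [100k,300k)
        w = window_breakpoint_counts([sv], {"chr01": 500_000})
        assert w["count"].tolist() == [2, 2, 0, 0]

    def test_del_contributes_two_breakpoints_ins_one(self):
        # DEL start sits in window [0,200k) only; its end (349,999) falls in
        # the two overlapping windows [200k,400k) and [300k,500k)
        del_sv = make_sv("d", pos=50_000, svlen=300_000)
        ins_sv = make_sv("i", pos=50_000, svtype="INS", svlen=300_000)
        w_del = window_breakpoint_counts([del_sv], {"chr01": 500_000})
        w_ins = window_breakpoint_counts([ins_sv], {"chr01": 500_000})
        assert w_del["count"].tolist() == [1, 0, 1, 1]
        assert w_ins["count"].tolist() == [1, 0, 0, 0]

    def test_empty_sv_list_zero_counts(self):
        w = window_breakpoint_counts([], CHROM)
        assert (w["count"] == 0).all()

    def test_breakpoint_mass_conserved_on_half_steps(self):
        rng = np.random.default_rng(3)
        svs = [make_sv(f"s{i}", pos=int(p), svlen=200)
               for i, p in enumerate(rng.integers(1, 9_000_000, 200))]
        w = window_breakpoint_counts(svs, CHROM)
        # non-overlapping half-step tiling: even-indexed 100 kb halves
        half = window_breakpoint_counts(svs, CHROM, window=100_000, step=100_000)
        total_breakpoints = sum(len(sv.breakpoints) for sv in svs)
        assert half["count"].sum() == total_breakpoints

    def test_sv_beyond_chromosome_end_rejected(self):
        sv = make_sv("far", pos=11_000_000)
        with pytest.raises(CoordinateError, match="far"):
            window_breakpoint_counts([sv], CHROM)


class TestHotspots:
    def test_unique_counts_flag_exactly_top_decile(self):
        windows = pd.DataFrame({
            "chrom": ["c"] * 100,
            "start": np.arange(100) * 200_000,
            "end": np.arange(1, 101) * 200_000,
            "count": np.arange(100) + 1,
        })
        regions = detect_hotspots(windows)
        assert sum(r.n_windows_merged for r in regions) == 10

    def test_adjacent_windows_merge(self):
        counts = np.ones(20)
        counts[[0, 1]] = [50, 40]  # overlapping windows [0,200k) and [100k,300k)
        windows = pd.DataFrame({
            "chrom": ["c"] * 20,
            "start": np.arange(20) * 100_000,
            "end": np.arange(20) * 100_000 + 200_000,
            "count": counts,
        })
        regions = detect_hotspots(windows)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 300_000)
        assert regions[0].peak_count == 50

    def test_all_zero_counts_empty(self):
        windows = pd.DataFrame({
            "chrom": ["c"] * 10, "start": np.arange(10), "end": np.arange(10) + 1,
            "count": np.zeros(10, dtype=int)})
        with pytest.warns(UserWarning, match="zero"):
            assert detect_hotspots(windows) == []


class TestMatchedNull:
    def test_replicates_bit_identical_for_seed(self):
        svs = [make_sv(f"s{i}", pos=1000 * (i + 1), svlen=100 + i) for i in range(50)]
        _, a = simulate_matched_null(svs, CHROM, n_sim=1, seed=42)
        _, b = simulate_matched_null(svs, CHROM, n_sim=1, seed=42)
        assert (a == b).all()

    def test_length_multiset_preserved(self):
        # counts conserve total breakpoint mass per replicate
        svs = [make_sv(f"s{i}", pos=1000 * (i + 1), svlen=100,
                       svtype="DEL" if i % 2 else "INS") for i in range(60)]
        windows, counts = simulate_matched_null(
            svs, CHROM, n_sim=5, seed=1, window=100_000, step=100_000)
        total = sum(len(sv.breakpoints) for sv in svs)
        assert (counts.sum(axis=1) == total).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigError):
            simulate_matched_null([], CHROM)


class TestHotspotSignificance:
    def _windows(self, counts):
        n = len(counts)
        return pd.DataFrame({"chrom": ["c"] * n, "start": np.arange(n) * 100,
                             "end": np.arange(n) * 100 + 200, "count": counts})

    def test_identical_samples_p_near_one(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20, 100)
        p = hotspot_significance(self._windows(counts), counts[None, :])
        assert p > 0.9

    def test_complete_separation_tiny_p(self):
        rng = np.random.default_rng(0)
        null = rng.poisson(20, (3, 100))
        observed = self._windows(null[0] + 10)
        assert hotspot_significance(observed, null) < 1e-6

    def test_single_window_refused(self):
        with pytest.raises(ConfigError, match="single window"):
            hotspot_significance(self._windows([5]), np.array([[4]]))

    def test_mismatched_tiling_refused(self):
        obs = self._windows([1, 2, 3])
        other = obs.copy()
        other["start"] += 50
        with pytest.raises(ConfigError, match="tiling"):
            hotspot_significance(obs, np.zeros((1, 3)), other)


class TestAnnotateSVGene:
    GENE = GeneRecord("gene1", "acc", "chr01", 200, 4_000, "+", "OG1", False)

    @pytest.mark.parametrize(
        "pos, end, svlen, expected",
        [
            (100, 5_000, 4_901, "contains-gene"),   # covers both gene ends
            (3_900, 4_200, 301, "overlaps-gene"),   # partial intersection
            (4_500, 4_600, 101, "within-flank"),    # 500 bp from gene end
            (9_000, 9_100, 101, "intergenic"),
        ],
    )
    def test_categories(self, pos, end, svlen, expected):
        sv = make_sv("s", pos=pos, svlen=svlen)
        sv_df, gene_df = annotate_sv_gene([sv], [self.GENE])
        assert sv_df.loc[0, "category"] == expected
        assert gene_df.loc[0, "flanked_by_sv"] == (expected != "intergenic")

    def test_negative_flank_rejected(self):
        with pytest.raises(ConfigError):
            annotate_sv_gene([], [self.GENE], flank=-1)
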