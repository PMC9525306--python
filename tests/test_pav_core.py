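"""PAV matrix construction, core/dispensable calls, rarefaction, divergence,
taxon levels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from helpers import pairwise_divergence_oracle, rarefaction_oracle
from hypothesis import given, settings
from hypothesis import strategies as st

from panlandscape import pav_core
from panlandscape.errors import ConfigError
from panlandscape.pav_core import (
    PAVMatrix,
    assign_taxon_levels,
    build_pav_matrix,
    classify_core_dispensable,
    exhaustive_rarefaction,
    pairwise_pav_divergence,
    rarefaction_curves,
)
from panlandscape.synthetic_data import PangenomeSimConfig, simulate_pangenome


class TestBuildPAVMatrix:
    def test_direct_transcription(self):
        table = pd.DataFrame(
            {"accA": ["gA1", "gA2", "gA3"], "accB": ["gB1", "", "gB3"]},
            index=pd.Index(["og1", "og2", "og3"], name="Orthogroup"),
        )
        pav = build_pav_matrix(table)
        assert pav.df.to_numpy().sum() == 5
        assert not pav.df.loc["og2", "accB"]

    def test_all_absent_row_dropped(self):
        table = pd.DataFrame(
            {"accA": ["g1", ""], "accB": ["g2", ""]},
            index=pd.Index(["og1", "og2"], name="Orthogroup"),
        )
        pav = build_pav_matrix(table)
        assert list(pav.df.index) == ["og1"]
        assert pav.n_dropped_rows == 1

    def test_matches_generator_truth_matrix(self):
        sim = simulate_pangenome(PangenomeSimConfig(seed=21))
        pav = build_pav_matrix(sim.orthogroup_table, subpop_of=sim.subpop_of)
        realized = sim.presence[sim.presence.any(axis=1)]
        pd.testing.assert_frame_equal(pav.df, realized, check_names=False)

    def test_unknown_accession_rejected(self):
        table = pd.DataFrame({"accA": ["g"]}, index=pd.Index(["og1"]))
        with pytest.raises(ConfigError):
            build_pav_matrix(table, accessions=["accA", "accZ"])

    def test_tsv_round_trip(self, tmp_path):
        sim = simulate_pangenome(PangenomeSimConfig(seed=2))
        from panlandscape.io import read_orthogroup_tsv, write_orthogroup_tsv

        path = tmp_path / "og.tsv"
        write_orthogroup_tsv(sim.orthogroup_table, path)
        back = read_orthogroup_tsv(path)
        pd.testing.assert_frame_equal(
            back, sim.orthogroup_table, check_names=False
        )


class TestCoreDispensable:
    @staticmethod
    def _single_og_pav(n_present: int, n_total: int) -> PAVMatrix:
        row = [True] * n_present + [False] * (n_total - n_present)
        df = pd.DataFrame([row], index=["og"], columns=[f"a{i}" for i in range(n_total)])
        return PAVMatrix(df)

    def test_boundary_239_of_251_is_core(self):
        labels = classify_core_dispensable(self._single_og_pav(239, 251))
        assert labels["og"] == "core"

    def test_boundary_238_of_251_is_dispensable(self):
        labels = classify_core_dispensable(self._single_og_pav(238, 251))
        assert labels["og"] == "dispensable"

    def test_present_everywhere_core_at_any_threshold(self):
        pav = self._single_og_pav(17, 17)
        for threshold in (0.5, 0.95, 1.0):
            assert classify_core_dispensable(pav, threshold)["og"] == "core"

    def test_partition_sums_to_total_at_every_threshold(self):
        sim = simulate_pangenome(PangenomeSimConfig(seed=13))
        pav = build_pav_matrix(sim.orthogroup_table)
        for threshold in (0.05, 0.5, 0.9, 0.95, 1.0):
            labels = classify_core_dispensable(pav, threshold)
            n_core = (labels == "core").sum()
            n_disp = (labels == "dispensable").sum()
            assert n_core + n_disp == len(pav.df)

    def test_empty_matrix_empty_result(self):
        pav = PAVMatrix(pd.DataFrame(columns=["a"], dtype=bool))
        assert classify_core_dispensable(pav).empty


class TestRarefaction:
    def test_sampled_matches_exhaustive_enumeration(self, toy_pav):
        sets = [
            {og for og in toy_pav.df.index if toy_pav.df.loc[og, acc]}
            for acc in toy_pav.df.columns
        ]
        pan_mean, _, core_mean, _ = rarefaction_oracle(sets)
        pan, core = rarefaction_curves(toy_pav, n_orders=600, seed=3)
        # 600 samples of 6 equiprobable orderings: tight agreement expected
        assert np.allclose(pan.mean_count, pan_mean, atol=0.15)
        assert np.allclose(core.mean_count, core_mean, atol=0.15)
        ex_pan, ex_core = exhaustive_rarefaction(toy_pav)
        assert np.allclose(ex_pan["mean_count"], pan_mean)
        assert np.allclose(ex_core["mean_count"], core_mean)

    def test_monotonicity_within_every_ordering(self, toy_pav):
        matrix = toy_pav.df.to_numpy()
        for order in itertools.permutations(range(3)):
            pan, core = pav_core.accumulation_counts(matrix, order)
            assert (np.diff(pan) >= 0).all()
            assert (np.diff(core) <= 0).all()

    def test_step_boundaries(self, toy_pav):
        matrix = toy_pav.df.to_numpy()
        total = matrix.shape[0]
        for order in itertools.permutations(range(3)):
            pan, core = pav_core.accumulation_counts(matrix, order)
            first = matrix[:, order[0]].sum()
            assert pan[0] == core[0] == first  # single-accession identity
            assert pan[-1] == total  # full union

    def test_nonprivate_mode_restricts_on_full_panel(self):
        df = pd.DataFrame(
            [[1, 0, 0], [1, 1, 0], [1, 1, 1]],
            index=["private", "shared2", "shared3"],
            columns=["a", "b", "c"],
            dtype=bool,
        )
        pav = PAVMatrix(df)
        pan, _ = rarefaction_curves(pav, n_orders=10, seed=0, gene_set_mode="nonprivate")
        assert pan.mean_count[-1] == 2  # the private orthogroup never counts

    def test_invalid_order_count(self, toy_pav):
        with pytest.raises(ConfigError):
            rarefaction_curves(toy_pav, n_orders=0)


class TestPairwiseDivergence:
    def test_hand_enumerated_example(self):
        # A={g1,g2,g3}, B={g2,g3,g4}: symmetric difference 2, union 4
        df = pd.DataFrame(
            {"A": [1, 1, 1, 0], "B": [0, 1, 1, 1]},
            index=["g1", "g2", "g3", "g4"], dtype=bool)
        res = pairwise_pav_divergence(PAVMatrix(df), ["A", "B"])
        assert res.pairs.loc[0, "differing"] == 2
        assert res.pairs.loc[0, "union"] == 4
        assert res.mean_ratio == 0.5

    def test_identical_and_disjoint_extremes(self):
        df = pd.DataFrame(
            {"A": [1, 1, 0, 0], "B": [1, 1, 0, 0], "C": [0, 0, 1, 1]},
            index=list("wxyz"), dtype=bool)
        pav = PAVMatrix(df)
        assert pairwise_pav_divergence(pav, ["A", "B"]).mean_ratio == 0.0
        assert pairwise_pav_divergence(pav, ["A"], ["C"]).mean_ratio == 1.0

    def test_matches_brute_force_on_toy_matrix(self):
        rng = np.random.default_rng(5)
        m = rng.random((5, 5)) < 0.6
        m[:, 0] |= ~m[:, 0].any()  # ensure no empty accession columns
        df = pd.DataFrame(m, index=[f"og{i}" for i in range(5)],
                          columns=[f"a{i}" for i in range(5)])
        df = df[df.any(axis=1)]
        pav = PAVMatrix(df)
        res = pairwise_pav_divergence(pav, list(df.columns))
        for _, row in res.pairs.iterrows():
            i = list(df.columns).index(row["accession_a"])
            j = list(df.columns).index(row["accession_b"])
            diff, ratio = pairwise_divergence_oracle(df.to_numpy(), i, j)
            assert row["differing"] == diff
            assert row["ratio"] == pytest.approx(ratio)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((8, 4)) < 0.5
        m[0, :] = True  # keep every accession non-empty and rows non-empty
        df = pd.DataFrame(m, index=[f"og{i}" for i in range(8)],
                          columns=list("abcd"))
        pav = PAVMatrix(df[df.any(axis=1)])
        ab = pairwise_pav_divergence(pav, ["a"], ["b"]).mean_ratio
        ba = pairwise_pav_divergence(pav, ["b"], ["a"]).mean_ratio
        assert ab == ba
        assert 0.0 <= ab <= 1.0

    def test_empty_group_rejected(self, toy_pav):
        with pytest.raises(ConfigError):
            pairwise_pav_divergence(toy_pav, [])


class TestTaxonLevels:
    @staticmethod
    def _pav(rows: dict[str, list[int]]) -> PAVMatrix:
        accs = ["or1", "ob1", "og1", "osi1", "osj1"]
        subpops = dict(zip(accs, ["Or", "Ob", "Og", "Osi", "Osj"]))
        df = pd.DataFrame.from_dict(rows, orient="index", columns=accs).astype(bool)
        return PAVMatrix(df, subpops)

    def test_level_assignments(self):
        pav = self._pav(
            {
                "both_wild": [1, 1, 0, 0, 0],       # Or & Ob -> I
                "or_and_osj": [1, 0, 0, 0, 1],      # Or & Os, not Ob -> II
                "og_and_ob": [0, 1, 1, 0, 0],       # Og & Ob, not Or -> III
                "osi_osj": [0, 0, 0, 1, 1],         # both cultivated Asian -> IV
                "osi_og_only": [0, 0, 1, 1, 0],     # admixture-like -> undetermined
            }
        )
        levels = assign_taxon_levels(pav)
        assert levels["both_wild"] == "I"
        assert levels["or_and_osj"] == "II"
        assert levels["og_and_ob"] == "III"
        assert levels["osi_osj"] == "IV"
        assert levels["osi_og_only"] == "undetermined"

    def test_exactly_one_level_per_orthogroup(self):
        sim = simulate_pangenome(PangenomeSimConfig(seed=17))
        pav = build_pav_matrix(sim.orthogroup_table, subpop_of=sim.subpop_of)
        levels = assign_taxon_levels(pav)
        assert set(levels.index) == set(pav.df.index)
        assert levels.isin(["I", "II", "III", "IV", "undetermined"]).all()

    def test_missing_subpopulation_rejected(self):
        df = pd.DataFrame({"a": [True]}, index=["og"])
        with pytest.raises(ConfigError, match="Or"):
            assign_taxon_levels(PAVMatrix(df, {"a": "Osi"}))


def test_core_fraction_recovered_on_synthetic_panel():
    """At 50 accessions the estimated core orthogroup count recovers the
    configured count within 2% (all-absent dispensable rows are, by
    definition, not part of the observable pan-genome)."""
    cfg = PangenomeSimConfig(
        n_accessions_per_subpop={"Osi": 20, "Osj": 10, "Or": 10, "Og": 5, "Ob": 5},
        seed=29,
    )
    sim = simulate_pangenome(cfg)
    pav = build_pav_matrix(sim.orthogroup_table, subpop_of=sim.subpop_of)
    n_core = (classify_core_dispensable(pav) == "core").sum()
    assert abs(n_core - cfg.n_core_orthogroups) / cfg.n_core_orthogroups <= 0.02
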