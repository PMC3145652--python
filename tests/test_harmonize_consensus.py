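"""Probe-to-gene mapping, master list, consensus rules and peak filters."""

import numpy as np
import pandas as pd
import pytest

from barrex import harmonize_consensus as hc
from barrex import synthetic_cohorts as sc
from barrex.expression_io import ABSENT, load_fixture_tables


def stats_frame(records):
    """Minimal per-probe stats table (columns as compute_gene_stats emits)."""
    cols = ["entrez", "status", "p", "q", "mean_S", "mean_BE", "mean_EAC",
            "fold_S_BE", "fold_BE_EAC"]
    df = pd.DataFrame(records, columns=cols)
    df.index = [f"p{i}" for i in range(len(df))]
    return df


class TestMapProbesToEntrez:
    def test_unmapped_and_multimapped_dropped(self):
        stats = stats_frame([
            (1, "ok", 0.01, 0.02, 1, 2, 3, 2.0, 1.5),
            (2, "ok", 0.01, 0.02, 1, 2, 3, 2.0, 1.5),
            (pd.NA, "unmapped", 0.01, 0.02, 1, 2, 3, 2.0, 1.5),
            (pd.NA, "multimapped", 0.01, 0.02, 1, 2, 3, 2.0, 1.5),
            (3, "ok", 0.01, 0.02, 1, 2, 3, 2.0, 1.5),
        ])
        out = hc.map_probes_to_entrez(stats)
        assert list(out.index) == [1, 2, 3]

    def test_min_p_collapse_keeps_strongest_probe(self):
        stats = stats_frame([
            (7, "ok", 0.001, 0.002, 1, 5, 3, 5.0, -1.7),
            (7, "ok", 0.2, 0.3, 1, 1.1, 3, 1.1, 2.7),
        ])
        out = hc.map_probes_to_entrez(stats)
        assert out.loc[7, "p"] == 0.001
        assert out.loc[7, "fold_S_BE"] == 5.0
        assert out.loc[7, "n_probes"] == 2

    def test_zero_mappable_probes_yields_empty_table(self):
        stats = stats_frame([(pd.NA, "unmapped", 0.01, 0.02, 1, 2, 3, 2.0, 1.5)])
        out = hc.map_probes_to_entrez(stats)
        assert out.empty


def gene_table(genes, q=0.001, fold_sbe=2.0, fold_bea=1.0):
    df = pd.DataFrame({
        "p": q / 2, "q": q, "mean_S": 1.0, "mean_BE": 2.0, "mean_EAC": 2.0,
        "fold_S_BE": fold_sbe, "fold_BE_EAC": fold_bea, "n_probes": 1,
    }, index=pd.Index(genes, name="entrez"))
    return df


class TestMasterList:
    def test_presence_rule(self):
        tables = {
            "A": gene_table([1, 2, 3]),
            "B": gene_table([1, 2]),
            "C": gene_table([1, 3]),
            "D": gene_table([1, 3]),
        }
        table = hc.build_master_list(tables)
        df = table.df
        assert bool(df.loc[1, "master"])      # 4 of 4
        assert bool(df.loc[3, "master"])      # 3 of 4
        assert not bool(df.loc[2, "master"])  # only 2 cohorts

    def test_fewer_than_three_cohorts_rejected(self):
        with pytest.raises(ValueError, match="3 cohorts"):
            hc.build_master_list({"A": gene_table([1]), "B": gene_table([1])})

    def test_master_count_matches_brute_force_on_truth(self):
        cfg = sc.SimulationConfig(n_cohorts=4, group_sizes=(5, 5, 5),
                                  master_gene_count=400, platform_overlap=0.6,
                                  multimap_rate=0.05, unmapped_rate=0.05,
                                  seed=17)
        cohorts, truth = sc.generate_cohorts(cfg)
        table = hc.run_consensus_pipeline(cohorts)
        expected = {g for g, c in truth.mapped_presence.items() if len(c) >= 3}
        assert set(table.df.index[table.df["master"]]) == expected


class TestSignificanceConsensus:
    @pytest.mark.parametrize("present, passing, expected", [
        (4, 3, True),    # "at least 3 of the four"
        (3, 2, False),   # 2/3 < 75%
        (4, 4, True),
        (3, 3, True),
    ])
    def test_seventy_five_percent_rule(self, present, passing, expected):
        cohorts = ["A", "B", "C", "D"][:4]
        tables = {}
        for i, c in enumerate(cohorts):
            if i < present:
                q = 0.001 if i < passing else 0.5
                tables[c] = gene_table([1], q=q)
            else:
                tables[c] = gene_table([99])
        table = hc.build_master_list(tables, hc.FilterParams(min_cohorts_present=3))
        table = hc.significance_consensus(table, {c: 0.01 for c in cohorts})
        row = table.df.loc[1]
        assert (row["pass_num"], row["pass_den"]) == (passing, present)
        assert bool(row["significant_consensus"]) is expected


def fixture_row_folds(symbol, rows, comparison):
    row = next(r for r in rows if r.symbol == symbol and r.comparison == comparison)
    return row


class TestDirectionalCounting:
    params = hc.FilterParams()

    @pytest.mark.parametrize("folds, direction, expect_count", [
        ((1.5, 1.3, 2.0, -1.1), "up", 3),
        ((1.5, 1.3, np.nan, np.nan), "up", 2),
        ((-1.3, -1.3, -1.3, -1.3), "down", 4),
    ])
    def test_counts(self, folds, direction, expect_count):
        up, down = hc._directional_counts(np.asarray(folds, float),
                                          self.params.directional_fold,
                                          self.params)
        assert (up if direction == "up" else down) == expect_count


@pytest.fixture(scope="module")
def rows():
    return load_fixture_tables()


class TestPeakFilterOnFixtures:
    def test_nt5e_all_four_cohorts_qualify(self, rows):
        row = fixture_row_folds("NT5E", rows, "S_BE")
        params = hc.FilterParams(comparison_mode="inclusive_ge")
        n = hc.count_qualifying_folds(row.folds.values(), "up", 3.0, params)
        assert n == 4  # the rounded 3.0 qualifies under the inclusive mode

    def test_ckmt1a_three_cohorts_qualify(self, rows):
        row = fixture_row_folds("CKMT1A", rows, "BE_EAC")
        params = hc.FilterParams(comparison_mode="inclusive_ge")
        n = hc.count_qualifying_folds(row.folds.values(), "down", 2.0, params)
        assert n == 3

    def test_two_qualifying_cohorts_are_not_enough(self):
        params = hc.FilterParams(comparison_mode="inclusive_ge")
        n = hc.count_qualifying_folds([2.5, 2.5, ABSENT, ABSENT], "up", 2.0, params)
        assert n == 2
        assert n < params.min_cohorts_fold

    def test_strict_mode_excludes_boundary_folds(self, rows):
        row = fixture_row_folds("CKMT1A", rows, "BE_EAC")
        strict = hc.FilterParams(comparison_mode="strict_gt")
        n = hc.count_qualifying_folds(row.folds.values(), "down", 2.0, strict)
        assert n == 2  # -2.0 no longer qualifies

    def test_threshold_monotonicity_on_fixture_tables(self, rows):
        """Raising a fold threshold can only shrink a peak list."""
        last = None
        for threshold in (1.5, 2.0, 2.5, 3.0, 4.0):
            params = hc.FilterParams(comparison_mode="inclusive_ge",
                                     peak_fold_S_BE=threshold)
            flagged = hc.peak_filter_fixture(rows, "S_BE", params)
            if last is not None:
                assert flagged <= last
            last = flagged

    def test_dual_list_overlap_matches_reported_genes(self, rows):
        s_be = [r for r in rows if r.comparison == "S_BE"]
        be_eac = [r for r in rows if r.comparison == "BE_EAC"]
        overlap = hc.dual_list_overlap((s_be, be_eac))
        symbols = {next(r.symbol for r in rows if r.entrez == g)
                   for g in overlap.index}
        assert symbols == {"ANXA10", "CA2", "TFF1", "MUC6", "LIPF", "KRT20",
                           "HYAL1", "ADH1C", "MYO1A", "SULT1C2"}
        assert overlap["reversal"].all()  # up in S->BE, down again in BE->EAC

    def test_disjoint_lists_give_empty_overlap(self, rows):
        s_be = [r for r in rows if r.symbol == "AQP3"]
        be_eac = [r for r in rows if r.symbol == "CKMT1A"]
        assert hc.dual_list_overlap((s_be, be_eac)).empty


class TestPipelineInvariants:
    def test_flag_implications_checked_after_run(self):
        cohorts, _ = sc.generate_cohorts(sc.SimulationConfig(
            n_cohorts=3, group_sizes=(6, 6, 6), master_gene_count=150,
            platform_overlap=0.9, seed=29))
        table = hc.run_consensus_pipeline(cohorts)
        table.check_invariants()  # raises on violation
        df = table.df
        assert (df.loc[df["significant_consensus"], "master"]).all()
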