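"""Weighted methylation levels, distributions, windows, paired tests."""

import numpy as np
import pandas as pd
import pytest

from methgrass import simulate, stats
from methgrass.io import RegionSet
from conftest import make_table, toy_annotation


class TestWeightedLevel:
    def test_pooled_arithmetic(self):
        t = make_table([("c", 10, "+", 5, 5, "CG"), ("c", 20, "+", 0, 10, "CG")])
        assert stats.weighted_level(t, "CG").level == pytest.approx(5 / 20)

    def test_fully_methylated(self):
        t = make_table([("c", 10, "+", 8, 0, "CG"), ("c", 20, "+", 3, 0, "CG")])
        assert stats.weighted_level(t, "CG").level == 1.0

    def test_no_qualifying_sites_is_missing_not_zero(self):
        t = make_table([("c", 10, "+", 1, 1, "CHH")])
        lvl = stats.weighted_level(t, "CG")
        assert lvl.missing and np.isnan(lvl.level)

    def test_weighted_not_mean_of_site_levels(self):
        # one deep unmethylated site + many shallow fully methylated sites:
        # the two definitions disagree and the weighted one must win
        rows = [("c", 10, "+", 0, 100, "CG")] + \
               [("c", 10 + i, "+", 1, 0, "CG") for i in range(1, 11)]
        t = make_table(rows)
        lvl = stats.weighted_level(t, "CG")
        assert lvl.level == pytest.approx(10 / 110)
        site_mean = np.mean([0.0] + [1.0] * 10)
        assert abs(lvl.level - site_mean) > 0.5

    def test_additive_over_disjoint_regions(self):
        rng = np.random.default_rng(0)
        rows = [("c", int(p), "+", int(m), int(u), "CG")
                for p, m, u in zip(rng.choice(5000, 300, replace=False) + 1,
                                   rng.integers(0, 10, 300),
                                   rng.integers(0, 10, 300))]
        t = make_table(rows)
        left = RegionSet(pd.DataFrame([("c", 0, 2500)],
                                      columns=["chrom", "start", "end"]))
        right = RegionSet(pd.DataFrame([("c", 2500, 6000)],
                                       columns=["chrom", "start", "end"]))
        both = RegionSet(pd.DataFrame([("c", 0, 2500), ("c", 2500, 6000)],
                                      columns=["chrom", "start", "end"]))
        a = stats.weighted_level(t, "CG", regions=left)
        b = stats.weighted_level(t, "CG", regions=right)
        ab = stats.weighted_level(t, "CG", regions=both)
        assert ab.total_meth_reads == a.total_meth_reads + b.total_meth_reads
        assert ab.total_reads == a.total_reads + b.total_reads

    def test_synthetic_genome_recovers_generating_mean(self):
        cfg = simulate.SimulationConfig(seed=11, n_chroms=1,
                                        chrom_length=220_000, n_genes=55,
                                        n_tes=77, n_dmrs=0)
        genome = simulate.simulate_genome(cfg)
        ann = simulate.simulate_annotation(cfg, genome)
        ta, tb, _ = simulate.simulate_methylome_pair(cfg, genome, ann)
        assert stats.weighted_level(ta, "CG").level == pytest.approx(0.38, abs=0.01)
        assert stats.weighted_level(tb, "CG").level == pytest.approx(0.36, abs=0.01)


class TestLevelDistribution:
    def test_hand_binning(self):
        t = make_table([("c", 10, "+", 0, 10, "CG"), ("c", 20, "+", 1, 9, "CG"),
                        ("c", 30, "+", 5, 5, "CG"), ("c", 40, "+", 9, 1, "CG")])
        d = stats.level_distribution(t, "CG", min_depth=5)
        assert d.proportions == (0.5, 0.25, 0.25)

    def test_boundary_exactly_at_edge_is_middle(self):
        t = make_table([("c", 10 + i, "+", 2, 8, "CG") for i in range(5)])
        d = stats.level_distribution(t, "CG", min_depth=5)
        assert d.proportions == (0.0, 1.0, 0.0)  # 0.2 is not "< 0.2"

    def test_proportions_sum_to_one(self, small_study):
        d = stats.level_distribution(small_study.table_a, "CG")
        assert sum(d.proportions) == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_errors(self):
        t = make_table([("c", 10, "+", 1, 0, "CHH")])
        with pytest.raises(ValueError, match="no sites"):
            stats.level_distribution(t, "CG", min_depth=5)

    def test_recovers_generating_mixture_shape(self, default_study):
        d = stats.level_distribution(default_study.table_a, "CG")
        assert d.proportions[0] == pytest.approx(0.40, abs=0.02)
        assert d.proportions[2] == pytest.approx(0.48, abs=0.02)


class TestFeatureLevels:
    def test_te_instance_level(self):
        ann = toy_annotation()
        t = make_table([("ChrT", 20001, "+", 10, 0, "CG"),
                        ("ChrT", 20050, "+", 0, 10, "CG")])
        fl = stats.feature_levels(t, ann, "TE", context="CG")
        te1 = fl.levels.set_index("instance_id").loc["te_1"]
        assert te1["level"] == 0.5
        assert fl.n_omitted == 4  # the other four TEs had no sites

    def test_unknown_feature_lists_valid_names(self):
        with pytest.raises(ValueError, match="promoter"):
            stats.feature_levels(make_table([]), toy_annotation(), "enhancer")

    def test_te_more_methylated_than_cds(self, small_study):
        te = stats.feature_levels(small_study.table_a, small_study.annotation,
                                  "TE", context="CG")
        cds = stats.feature_levels(small_study.table_a, small_study.annotation,
                                   "CDS", context="CG")
        assert te.levels["level"].median() > cds.levels["level"].median()


class TestWindowTrack:
    def test_tiling_arithmetic(self):
        t = make_table([("c", 10, "+", 1, 1, "CG")])
        track = stats.window_track(t, "CG", {"c": 250}, 100)
        spans = list(zip(track.df["start"], track.df["end"]))
        assert spans == [(0, 100), (100, 200), (200, 250)]

    def test_uniform_half_methylation(self):
        rows = [("c", p, "+", 5, 5, "CG") for p in range(1, 200, 7)]
        track = stats.window_track(make_table(rows), "CG", {"c": 250}, 100)
        scores = track.df["score"].to_numpy()
        assert np.allclose(scores[:2], 0.5)
        assert np.isnan(scores[2])  # window without sites is missing

    def test_planted_block_stands_out(self):
        rng = np.random.default_rng(1)
        rows = []
        for p in range(1, 1000, 5):
            level = 0.9 if 400 <= p < 600 else 0.1
            m = rng.binomial(20, level)
            rows.append(("c", p, "+", int(m), int(20 - m), "CG"))
        track = stats.window_track(make_table(rows), "CG", {"c": 1000}, 100)
        s = track.df["score"].to_numpy()
        assert s[4:6].min() > s[[0, 1, 2, 3, 6, 7, 8, 9]].max()


class TestSubgenomePairs:
    def _levels(self, values):
        return pd.DataFrame({"CG": values},
                            index=[f"g{i}" for i in range(len(values))])

    def test_identical_pairs_report_no_difference(self):
        levels = self._levels([0.1, 0.5, 0.9, 0.3])
        pairs = pd.DataFrame({"a": ["g0", "g1"], "b": ["g0", "g1"]})
        res = stats.subgenome_pair_comparison(pairs, levels)["CG"]
        assert res.mean_diff == 0.0
        assert res.note == "no difference"

    def test_unresolvable_gene_id(self):
        levels = self._levels([0.1])
        pairs = pd.DataFrame({"a": ["g0"], "b": ["missing"]})
        with pytest.raises(KeyError):
            stats.subgenome_pair_comparison(pairs, levels)

    def test_insufficient_pairs(self):
        levels = self._levels([0.1, np.nan])
        pairs = pd.DataFrame({"a": ["g0"], "b": ["g1"]})
        with pytest.raises(ValueError, match="insufficient"):
            stats.subgenome_pair_comparison(pairs, levels)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(0.5, 0.2, 300)
            b = rng.normal(0.5, 0.2, 300)
            levels = pd.DataFrame({"CG": np.concatenate([a, b])},
                                  index=[f"g{i}" for i in range(600)])
            pairs = pd.DataFrame({"a": [f"g{i}" for i in range(300)],
                                  "b": [f"g{i}" for i in range(300, 600)]})
            res = stats.subgenome_pair_comparison(pairs, levels)["CG"]
            rejections += res.p_value < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.04)

    def test_power_against_planted_shift(self):
        rng = np.random.default_rng(3)
        detected = 0
        reps = 30
        for _ in range(reps):
            a = rng.normal(0.4, 0.2, 1000)
            b = a + rng.normal(0.1, 0.2, 1000)  # +0.1 shift, sd 0.2
            levels = pd.DataFrame({"CG": np.concatenate([a, b])},
                                  index=[f"g{i}" for i in range(2000)])
            pairs = pd.DataFrame({"a": [f"g{i}" for i in range(1000)],
                                  "b": [f"g{i}" for i in range(1000, 2000)]})
            res = stats.subgenome_pair_comparison(pairs, levels)["CG"]
            detected += res.p_value < 0.05
        assert detected / reps > 0.9


def test_context_ordering_on_default_data(default_study):
    levels = {ctx: stats.weighted_level(default_study.table_a, ctx).level
              for ctx in ("CG", "CHG", "CHH")}
    assert levels["CG"] > levels["CHG"] > levels["CHH"]
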