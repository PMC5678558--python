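"""Fisher tests, BH adjustment, DMC clustering, DMR filtering, merging."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from methgrass import dmr, simulate
from conftest import make_table


def fisher_oracle_exact(am, au, bm, bu):
    """Two-sided Fisher p by exhaustive enumeration in exact rational
    arithmetic (independent of the package's hypergeometric route)."""
    n1, n2 = am + au, bm + bu
    K = am + bm
    N = n1 + n2
    denom = comb(N, K)
    obs = Fraction(comb(n1, am) * comb(n2, bm), denom)
    total = Fraction(0)
    for k in range(max(0, K - n2), min(n1, K) + 1):
        p = Fraction(comb(n1, k) * comb(n2, K - k), denom)
        if p <= obs:
            total += p
    return float(min(total, Fraction(1)))


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert dmr.test_dmc(5, 5, 5, 5) == 1.0

    def test_moderate_table_matches_enumeration(self):
        expected = fisher_oracle_exact(8, 2, 2, 8)
        assert dmr.test_dmc(8, 2, 2, 8) == pytest.approx(expected, abs=1e-12)

    def test_extreme_table_closed_form(self):
        # [[20,0],[0,20]]: only the two corner tables are as extreme
        assert dmr.test_dmc(20, 0, 0, 20) == pytest.approx(2 / comb(40, 20),
                                                           rel=1e-10)

    def test_zero_depth_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            dmr.test_dmc(0, 0, 3, 4)

    def test_exhaustive_small_margins_vs_exact_oracle(self):
        # every 2x2 table with both row sums <= 12, exact rational oracle
        tables = [(a, n1 - a, b, n2 - b)
                  for n1 in range(1, 13) for n2 in range(1, 13)
                  for a in range(n1 + 1) for b in range(n2 + 1)]
        am, au, bm, bu = map(np.array, zip(*tables))
        got = dmr.fisher_exact_vector(am, au, bm, bu)
        exact = np.array([fisher_oracle_exact(*t) for t in tables])
        assert np.max(np.abs(got - exact)) < 1e-10

    def test_random_tables_vs_scipy(self):
        rng = np.random.default_rng(8)
        tables = rng.integers(0, 40, size=(300, 4))
        tables[:, 1] += 1  # avoid zero margins
        tables[:, 3] += 1
        got = dmr.fisher_exact_vector(*tables.T)
        ref = np.array([scipy_fisher([[a, b], [c, d]]).pvalue
                        for a, b, c, d in tables])
        assert np.max(np.abs(got - ref)) < 1e-9


class TestBH:
    def test_single_p_unchanged(self):
        assert dmr.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # m=4: q_i = min over j>=i of p_j * m / j, here all collapse to 0.04
        q = dmr.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_hand_step_up_mixed(self):
        p = np.array([0.005, 0.009, 0.05, 0.5])
        # ranks 1..4: 0.005*4/1=0.02, 0.009*4/2=0.018 -> monotone floor 0.018
        # for both; 0.05*4/3=0.0667; 0.5
        q = dmr.bh_adjust(p)
        assert np.allclose(q, [0.018, 0.018, 0.2 / 3, 0.5])

    def test_empty_vector(self):
        assert dmr.bh_adjust(np.array([])).size == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    def test_bounds_and_order_preservation(self, ps):
        p = np.array(ps)
        q = dmr.bh_adjust(p)
        assert q.min() >= p.min() - 1e-12
        assert q.max() <= 1 + 1e-12
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


def dmc_frame(positions, chrom="c", context="CG", direction="hyper"):
    return pd.DataFrame({
        "chrom": chrom, "pos": positions, "strand": "+", "context": context,
        "direction": direction, "level_a": 0.1, "level_b": 0.9})


class TestClustering:
    def test_gap_rule_splits_and_joins(self):
        clusters = dmr.cluster_dmcs(dmc_frame([100, 150, 400]))
        spans = [(c.first_pos, c.last_pos, c.n_dmcs)
                 for c in clusters.itertuples()]
        assert spans == [(100, 150, 2), (400, 400, 1)]

    def test_gap_exactly_max_gap_splits(self):
        clusters = dmr.cluster_dmcs(dmc_frame([100, 200]))
        assert len(clusters) == 2  # distance 100 is NOT < 100

    def test_directions_never_mix(self):
        d = pd.concat([dmc_frame([100, 150], direction="hyper"),
                       dmc_frame([160, 190], direction="hypo")])
        clusters = dmr.cluster_dmcs(d)
        assert len(clusters) == 2
        assert set(clusters["direction"]) == {"hyper", "hypo"}

    def test_matches_brute_force_single_linkage(self):
        rng = np.random.default_rng(5)
        positions = np.unique(rng.integers(1, 60_000, size=1000))
        clusters = dmr.cluster_dmcs(dmc_frame(positions), max_gap=100)
        # oracle: linear scan chaining consecutive gaps < 100
        expected = []
        run = [positions[0]]
        for p in positions[1:]:
            if p - run[-1] < 100:
                run.append(p)
            else:
                expected.append((run[0], run[-1], len(run)))
                run = [p]
        expected.append((run[0], run[-1], len(run)))
        got = [(c.first_pos, c.last_pos, c.n_dmcs) for c in clusters.itertuples()]
        assert got == expected


def tables_for_region(level_a, level_b, positions, depth=20, chrom="c",
                      context="CG"):
    rows_a, rows_b = [], []
    for p in positions:
        rows_a.append((chrom, p, "+", int(round(level_a * depth)),
                       depth - int(round(level_a * depth)), context))
        rows_b.append((chrom, p, "+", int(round(level_b * depth)),
                       depth - int(round(level_b * depth)), context))
    return make_table(rows_a, "A"), make_table(rows_b, "B")


class TestDmrFiltering:
    def make_cluster(self, positions, context="CG", direction="hyper"):
        return pd.DataFrame([{
            "chrom": "c", "first_pos": positions[0], "last_pos": positions[-1],
            "context": context, "direction": direction,
            "n_dmcs": len(positions), "span_bp": positions[-1] - positions[0] + 1,
        }])

    def test_too_few_dmcs_discarded(self):
        ta, tb = tables_for_region(0.1, 0.9, [100, 180, 260])
        out = dmr.call_dmrs(self.make_cluster([100, 180, 260]), ta, tb)
        assert len(out) == 0

    def test_short_span_discarded(self):
        pos = [100, 110, 120, 139]  # 5 DMC-like sites spanning 40 bp
        ta, tb = tables_for_region(0.1, 0.9, pos)
        clusters = self.make_cluster(pos)
        clusters["n_dmcs"] = 5
        assert len(dmr.call_dmrs(clusters, ta, tb)) == 0

    def test_boundary_span_49_rejected_50_kept(self):
        for span, expected in ((49, 0), (50, 1)):
            pos = [100, 110, 120, 100 + span - 1]
            ta, tb = tables_for_region(0.0, 0.9, pos)
            assert len(dmr.call_dmrs(self.make_cluster(pos), ta, tb)) == expected

    def test_diff_exactly_at_threshold_rejected(self):
        pos = [100, 140, 170, 200]
        ta, tb = tables_for_region(0.5, 0.9, pos)  # diff exactly 0.4
        assert len(dmr.call_dmrs(self.make_cluster(pos), ta, tb)) == 0

    def test_hand_arithmetic_region(self):
        pos = [100, 140, 170, 200]
        ta, tb = tables_for_region(0.9, 0.45, pos)
        out = dmr.call_dmrs(self.make_cluster(pos, direction="hypo"), ta, tb)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["diff"] == pytest.approx(-0.45)
        assert row["direction"] == "hypo"
        assert (row["start"], row["end"]) == (99, 200)

    def test_region_level_uses_all_context_sites(self):
        # non-DMC site inside the span dilutes the region difference
        pos = [100, 140, 170, 200]
        ta, tb = tables_for_region(0.0, 0.9, pos)
        extra_a = make_table(list(ta.df.itertuples(index=False, name=None)) +
                             [("c", 150, "+", 18, 2, "CG")], "A")
        extra_b = make_table(list(tb.df.itertuples(index=False, name=None)) +
                             [("c", 150, "+", 18, 2, "CG")], "B")
        out_plain = dmr.call_dmrs(self.make_cluster(pos), ta, tb)
        out_diluted = dmr.call_dmrs(self.make_cluster(pos), extra_a, extra_b)
        assert abs(out_diluted.iloc[0]["diff"]) < abs(out_plain.iloc[0]["diff"])


class TestMergeContexts:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                           "direction"])

    def test_overlapping_contexts_union(self):
        d = self.frame([("c", 100, 200, "CG", "hyper"),
                        ("c", 150, 250, "CHG", "hyper")])
        merged = dmr.merge_contexts(d)
        assert [(iv.start, iv.end) for iv in merged["hyper"]] == [(100, 250)]

    def test_directions_kept_separate(self):
        d = self.frame([("c", 100, 200, "CG", "hyper"),
                        ("c", 150, 250, "CHG", "hypo")])
        merged = dmr.merge_contexts(d)
        assert len(merged["hyper"]) == 1 and len(merged["hypo"]) == 1

    def test_known_overlap_graph(self):
        # hand-drawn union: hyper {[0,30),[25,50)}+{[60,70)} -> 2;
        # book-ended [70,80) joins [60,70); hypo 3 disjoint -> 3
        d = self.frame([
            ("c", 0, 30, "CG", "hyper"), ("c", 25, 50, "CHG", "hyper"),
            ("c", 60, 70, "CG", "hyper"), ("c", 70, 80, "CHH", "hyper"),
            ("c", 0, 10, "CG", "hypo"), ("c", 20, 30, "CHG", "hypo"),
            ("c", 40, 50, "CHH", "hypo"),
        ])
        merged = dmr.merge_contexts(d)
        assert len(merged["hyper"]) == 2
        assert len(merged["hypo"]) == 3


class TestCallDmcs:
    def test_joint_depth_gate(self):
        ta = make_table([("c", 10, "+", 4, 0, "CG"), ("c", 20, "+", 5, 5, "CG")])
        tb = make_table([("c", 10, "+", 0, 9, "CG"), ("c", 20, "+", 5, 5, "CG")])
        _, tested = dmr.call_dmcs(ta, tb, return_tested=True)
        assert tested["pos"].tolist() == [20]  # depth 4 site not tested

    def test_planted_sites_recovered_with_direction(self):
        rng = np.random.default_rng(12)
        n_null, n_sig = 10_000, 100
        pos = np.arange(1, n_null + n_sig + 1) * 10
        null_p = rng.uniform(0.3, 0.7, n_null)
        rows_a, rows_b = [], []
        for i, p in enumerate(pos):
            if i < n_null:
                la = lb = null_p[i]
            else:
                la, lb = 0.1, 0.9
            da, db = 30, 30
            ma, mb = rng.binomial(da, la), rng.binomial(db, lb)
            rows_a.append(("c", int(p), "+", int(ma), int(da - ma), "CG"))
            rows_b.append(("c", int(p), "+", int(mb), int(db - mb), "CG"))
        dmcs = dmr.call_dmcs(make_table(rows_a), make_table(rows_b))
        sig = dmcs[dmcs["pos"] > n_null * 10]
        assert len(sig) >= 90
        assert (sig["direction"] == "hyper").all()

    def test_genotype_swap_flips_directions(self):
        cfg = simulate.SimulationConfig(seed=21, n_chroms=1,
                                        chrom_length=120_000, n_genes=30,
                                        n_tes=40, n_dmrs=8,
                                        depth_meth_bias=0.0)
        genome = simulate.simulate_genome(cfg)
        ann = simulate.simulate_annotation(cfg, genome)
        ta, tb, _ = simulate.simulate_methylome_pair(cfg, genome, ann)
        fwd = dmr.dmr_pipeline(ta, tb)
        rev = dmr.dmr_pipeline(tb, ta)
        pd.testing.assert_series_equal(fwd.dmcs["p_value"], rev.dmcs["p_value"])
        pd.testing.assert_series_equal(fwd.dmcs["q_value"], rev.dmcs["q_value"])
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert (fwd.dmcs["direction"].map(flip) == rev.dmcs["direction"]).all()
        assert np.allclose(fwd.dmrs["diff"].to_numpy(),
                           -rev.dmrs["diff"].to_numpy())
        assert (fwd.dmrs["start"].to_numpy() == rev.dmrs["start"].to_numpy()).all()


def test_pipeline_funnel_is_monotone(recovery_run):
    funnel = recovery_run["result"].funnel
    for row in funnel.itertuples(index=False):
        assert (row.sites_tested >= row.sites_p_lt_alpha >= row.dmcs)
        assert row.clusters_kept >= row.dmrs
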