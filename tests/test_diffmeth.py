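import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrbs_methkit.diffmeth import (DiffConfig, fisher_site, reconstruct_table,
                                   run_comparison, summarize_comparison, ttest_site)
from rrbs_methkit.methcall import finalize_calls


def fisher_oracle(x1: int, n1: int, x2: int, n2: int) -> Fraction:
    """Exact-rational two-sided Fisher p by full hypergeometric enumeration."""
    k = x1 + x2
    total = n1 + n2
    denom = math.comb(total, k)
    probs = {a: Fraction(math.comb(n1, a) * math.comb(n2, k - a), denom)
             for a in range(max(0, k - n2), min(k, n1) + 1)}
    p_obs = probs[x1]
    return sum(p for p in probs.values() if p <= p_obs)


def _calls(rows):
    cols = ["contig", "pos", "strand", "context", "count_C", "count_T"]
    return finalize_calls(pd.DataFrame(rows, columns=cols))


class TestFisherSite:
    # printed per-site report values: (x1, n1, x2, n2, exact, rounded)
    @pytest.mark.parametrize("x1,n1,x2,n2,exact,rounded", [
        (5, 5, 0, 5, 2 / 252, 0.01),    # 5/5 vs 0/5, |diff| 1.00
        (5, 5, 1, 5, 12 / 252, 0.05),   # 5/5 vs 1/5, |diff| 0.80
        (4, 5, 0, 5, 12 / 252, 0.05),   # the other 0.80 table, same p
        (6, 6, 1, 5, 7 / 462, 0.02),    # 6/6 vs 1/5, |diff| 0.80
    ])
    def test_published_tables(self, x1, n1, x2, n2, exact, rounded):
        p = fisher_site(x1, n1, x2, n2)
        assert p == pytest.approx(exact, abs=1e-12)
        assert round(p, 2) == rounded

    @given(st.integers(1, 10), st.integers(1, 10),
           st.data())
    @settings(max_examples=300)
    def test_matches_enumeration_oracle(self, n1, n2, data):
        x1 = data.draw(st.integers(0, n1))
        x2 = data.draw(st.integers(0, n2))
        assert fisher_site(x1, n1, x2, n2) == pytest.approx(
            float(fisher_oracle(x1, n1, x2, n2)), abs=1e-12)

    @given(st.integers(1, 30), st.integers(1, 30), st.data())
    @settings(max_examples=100)
    def test_group_swap_invariance(self, n1, n2, data):
        x1 = data.draw(st.integers(0, n1))
        x2 = data.draw(st.integers(0, n2))
        assert fisher_site(x1, n1, x2, n2) == pytest.approx(
            fisher_site(x2, n2, x1, n1), abs=1e-12)

    def test_large_counts_stable(self):
        p = fisher_site(900, 1000, 100, 1000)
        assert np.isfinite(p) and 0.0 <= p < 1e-100  # deep tail, no overflow/NaN
        assert fisher_site(500, 1000, 500, 1000) == pytest.approx(1.0, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_site(1, 0, 0, 5)
        with pytest.raises(ValueError):
            fisher_site(6, 5, 0, 5)


class TestTTestSite:
    def test_degenerate_identical(self):
        p, _, degenerate = ttest_site([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert p == 1.0 and degenerate

    def test_separation(self):
        eps = 1e-6
        p, _, _ = ttest_site([0.0, eps, 0.0], [1.0, 1.0 - eps, 1.0])
        assert p < 1e-6

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            ttest_site([0.5], [0.4, 0.6])

    def test_null_type_one_error(self):
        rng = np.random.default_rng(29)
        n_sim, hits = 4000, 0
        for _ in range(n_sim):
            a = rng.normal(0.5, 0.1, 3)
            b = rng.normal(0.5, 0.1, 3)
            p, _, _ = ttest_site(a, b)
            hits += p < 0.05
        rate = hits / n_sim
        mc_se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 0.01 + 2 * mc_se


class TestRunComparison:
    def test_coverage_filter_per_group(self):
        a = _calls([("c", 1, "+", "CpG", 4, 0), ("c", 5, "+", "CpG", 5, 0)])
        b = _calls([("c", 1, "+", "CpG", 0, 5), ("c", 5, "+", "CpG", 0, 5)])
        table = run_comparison(a, b, DiffConfig(min_coverage=5))
        assert list(table["start"]) == [5]  # site 1 has coverage 4 in group 1

    def test_identical_groups_null(self):
        rows = [("c", i, "+", "CpG", 6, 6) for i in range(0, 50, 2)]
        a, b = _calls(rows), _calls(rows)
        table = run_comparison(a, b)
        assert (table["difference"] == 0).all()
        assert np.allclose(table["p_value"], 1.0)
        assert not table["significant"].any()

    def test_swap_antisymmetry(self):
        a = _calls([("c", 1, "+", "CpG", 8, 2)])
        b = _calls([("c", 1, "+", "CpG", 1, 9)])
        t1 = run_comparison(a, b)
        t2 = run_comparison(b, a)
        assert t1["difference"].iloc[0] == pytest.approx(-t2["difference"].iloc[0])
        assert t1["p_value"].iloc[0] == pytest.approx(t2["p_value"].iloc[0])

    def test_direction_labels(self):
        a = _calls([("c", 1, "+", "CpG", 0, 10)])
        b = _calls([("c", 1, "+", "CpG", 10, 0)])
        table = run_comparison(a, b)
        assert table["direction"].iloc[0] == "hyper"  # higher in group 2

    def test_empty_overlap_warns(self):
        a = _calls([("c", 1, "+", "CpG", 6, 0)])
        b = _calls([("c", 99, "+", "CpG", 6, 0)])
        with pytest.warns(UserWarning):
            table = run_comparison(a, b)
        assert table.empty

    def test_ttest_mode_with_fallback(self):
        reps_a = [_calls([("c", 1, "+", "CpG", 5, 1), ("c", 7, "+", "CpG", 6, 0)]),
                  _calls([("c", 1, "+", "CpG", 4, 2)])]
        reps_b = [_calls([("c", 1, "+", "CpG", 1, 5), ("c", 7, "+", "CpG", 0, 6)]),
                  _calls([("c", 1, "+", "CpG", 2, 4)])]
        from rrbs_methkit.methcall import pool_calls
        table = run_comparison(pool_calls(reps_a), pool_calls(reps_b),
                               DiffConfig(test="ttest"),
                               replicates1=reps_a, replicates2=reps_b)
        by_site = table.set_index("start")["test_used"]
        assert by_site.loc[1] == "ttest"
        assert by_site.loc[7] == "fisher(fallback)"  # one replicate only

    def test_sim_recall_with_strong_effect(self, sim_clean, sim_clean_db):
        """dm_effect 1.0 planted sites are recovered at P < 0.05."""
        from rrbs_methkit.align import AlignConfig, Aligner
        from rrbs_methkit.methcall import pileup, pool_calls
        aligner = Aligner(sim_clean_db, AlignConfig())
        pooled = {}
        for group in ("LMFA", "HMFA"):
            tabs = []
            for rep in (1, 2):
                kept = []
                for rec in sim_clean.reads[(group, rep)]:
                    hit, _ = aligner.align_read(rec.read_id, rec.seq)
                    if hit is not None:
                        kept.append((rec.seq, hit))
                tabs.append(pileup(kept, sim_clean_db, sim_clean.genome))
            pooled[group] = pool_calls(tabs)
        table = run_comparison(pooled["LMFA"], pooled["HMFA"], DiffConfig())
        truth = sim_clean.truth_sites
        dm = truth[truth.is_dm]
        merged = table.merge(dm, left_on=["contig", "start", "strand"],
                             right_on=["contig", "pos", "strand"])
        well_covered = merged[(merged.n1 >= 10) & (merged.n2 >= 10)]
        assert len(well_covered) >= 30
        assert (well_covered["p_value"] < 0.05).mean() >= 0.95
        summary = summarize_comparison(table)
        assert summary[summary.context == "all"]["tested"].iloc[0] == len(table)


class TestReconstructTable:
    def test_boundary_unique(self):
        cands, unique = reconstruct_table(5, 5, 1.0)
        assert unique and cands == [(5, 0)]

    def test_six_five_080_unique(self):
        cands, unique = reconstruct_table(6, 5, 0.80)
        assert unique and cands == [(6, 1)]

    def test_five_five_080_two_candidates(self):
        cands, unique = reconstruct_table(5, 5, 0.80)
        assert not unique
        assert sorted(cands) == [(4, 0), (5, 1)]

    def test_candidates_all_match_difference(self):
        for n1, n2, d in [(7, 10, 1.0), (8, 5, 0.75), (12, 12, 1.0), (9, 10, 0.79)]:
            cands, _ = reconstruct_table(n1, n2, d)
            assert cands
            for x1, x2 in cands:
                assert round(abs(x1 / n1 - x2 / n2), 2) == round(d, 2)
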