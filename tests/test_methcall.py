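import numpy as np
import pandas as pd
import pytest

from rrbs_methkit.align import AlignConfig, Aligner, AlignmentHit
from rrbs_methkit.digest import DigestConfig, Fragment, build_reference
from rrbs_methkit.io import validate_bedgraph
from rrbs_methkit.methcall import (classify_context, export_tracks, finalize_calls,
                                   pileup, pool_calls, read_calls)


class TestClassifyContext:
    @pytest.mark.parametrize("seq,expected", [
        ("CGA", "CpG"), ("CTG", "CHG"), ("CTT", "CHH"),
        ("CAG", "CHG"), ("CCG", "CHG"), ("CCC", "CHH"), ("CAT", "CHH"),
    ])
    def test_plus_strand(self, seq, expected):
        assert classify_context(seq, 0, "+") == expected

    def test_minus_strand(self):
        # bottom-strand C at the G of top-strand "CG": context reads leftward
        assert classify_context("ACGA", 2, "-") == "CpG"
        # top "CAG": bottom C at pos 2, next bases complement of A,C -> T,G => CHG
        assert classify_context("CAG", 2, "-") == "CHG"
        assert classify_context("TTG", 2, "-") == "CHH"

    def test_near_edge_skipped(self):
        assert classify_context("AAC", 2, "+") is None
        assert classify_context("GAA", 0, "-") is None

    def test_n_in_window_skipped(self):
        assert classify_context("CNA", 0, "+") is None

    def test_wrong_base_raises(self):
        with pytest.raises(ValueError):
            classify_context("AAA", 0, "+")

    def test_partition(self, sim_clean):
        assert set(sim_clean.truth_sites["context"]) <= {"CpG", "CHG", "CHH"}


def _tiny_setup():
    # fragment covering the whole 12-bp contig; C at pos 2 (CpG: CG at 2-3)
    genome = {"c": "ATCGATTAGGAT"}
    frag = Fragment("c", 0, 12, "MspI", "TaqI")
    db = build_reference([frag], genome, DigestConfig(size_min=1, size_max=350))
    entry = next(e for e in db.entries if e.strand == "top")
    return genome, db, entry


class TestPileup:
    def test_level_formula(self):
        genome, db, entry = _tiny_setup()
        hit = AlignmentHit(entry.entry_id, 0, "top", 0, 0)
        reads = [("ATCGATTAGGAT", hit)] * 3 + [("ATTGATTAGGAT", hit)]  # 3 C, 1 T
        calls = pileup(reads, db, genome)
        row = calls[(calls.pos == 2) & (calls.strand == "+")].iloc[0]
        assert (row.count_C, row.count_T) == (3, 1)
        assert row.level == pytest.approx(0.75)
        assert row.context == "CpG"

    def test_non_ct_base_excluded(self):
        genome, db, entry = _tiny_setup()
        hit = AlignmentHit(entry.entry_id, 0, "top", 0, 0)
        calls = pileup([("ATGGATTAGGAT", hit)], db, genome)  # G at the C site
        assert len(calls[(calls.pos == 2) & (calls.strand == "+")]) == 0

    def test_conservation(self, sim_clean, sim_clean_db):
        """Total coverage equals the number of kept read-base observations
        at reference cytosines reporting C or T."""
        aligner = Aligner(sim_clean_db, AlignConfig())
        reads = [(r.read_id, r.seq) for r in sim_clean.reads[("LMFA", 1)][:500]]
        kept = []
        expected_obs = 0
        for rid, seq in reads:
            hit, _ = aligner.align_read(rid, seq)
            if hit is None:
                continue
            kept.append((seq, hit))
            entry = sim_clean_db.by_id(hit.entry_id)
            for i, b in enumerate(seq):
                if entry.raw_seq[hit.offset + i] == "C" and b in "CT":
                    ctx_ok = classify_context(
                        sim_clean.genome[entry.contig],
                        entry.genome_coord(hit.offset + i),
                        "+" if entry.strand == "top" else "-") is not None
                    if ctx_ok:
                        expected_obs += 1
        calls = pileup(kept, sim_clean_db, sim_clean.genome)
        assert calls["coverage"].sum() == expected_obs

    def test_order_invariance(self, sim_clean, sim_clean_db):
        aligner = Aligner(sim_clean_db, AlignConfig())
        kept = []
        for rec in sim_clean.reads[("HMFA", 1)][:200]:
            hit, _ = aligner.align_read(rec.read_id, rec.seq)
            if hit is not None:
                kept.append((rec.seq, hit))
        a = pileup(kept, sim_clean_db, sim_clean.genome)
        b = pileup(kept[::-1], sim_clean_db, sim_clean.genome)
        pd.testing.assert_frame_equal(a, b)

    def test_binomial_recovery(self, sim_clean, sim_clean_db):
        """Noiseless simulation: pooled estimates within 3 binomial SE of
        the true probability for nearly all adequately covered sites."""
        aligner = Aligner(sim_clean_db, AlignConfig())
        tables = []
        for rep in (1, 2):
            kept = []
            for rec in sim_clean.reads[("LMFA", rep)]:
                hit, _ = aligner.align_read(rec.read_id, rec.seq)
                if hit is not None:
                    kept.append((rec.seq, hit))
            tables.append(pileup(kept, sim_clean_db, sim_clean.genome))
        calls = pool_calls(tables)
        truth = sim_clean.truth_sites.set_index(["contig", "pos", "strand"])["p_LMFA"]
        merged = calls[calls["coverage"] >= 10]
        ok = total = 0
        for r in merged.itertuples():
            p = truth.loc[(r.contig, r.pos, r.strand)]
            se = np.sqrt(p * (1 - p) / r.coverage)
            total += 1
            ok += abs(r.level - p) <= 3 * se + 1e-12
        assert total > 200
        assert ok / total >= 0.97


class TestPooling:
    def test_pool_sums_counts(self):
        cols = ["contig", "pos", "strand", "context", "count_C", "count_T"]
        a = finalize_calls(pd.DataFrame([("c", 1, "+", "CpG", 3, 1)], columns=cols))
        b = finalize_calls(pd.DataFrame([("c", 1, "+", "CpG", 2, 2),
                                         ("c", 5, "-", "CHH", 0, 4)], columns=cols))
        pooled = pool_calls([a, b])
        row = pooled[pooled.pos == 1].iloc[0]
        assert (row.count_C, row.count_T, row.level) == (5, 3, 0.625)
        assert len(pooled) == 2


class TestExport:
    def test_single_call_bedgraph(self, tmp_path):
        cols = ["contig", "pos", "strand", "context", "count_C", "count_T"]
        calls = finalize_calls(pd.DataFrame([("c", 7, "+", "CpG", 4, 0)], columns=cols))
        bg, tsv = export_tracks(calls, tmp_path / "x")
        lines = [l for l in bg.read_text().splitlines() if not l.startswith("track")]
        assert lines == ["c\t7\t8\t1"]
        assert validate_bedgraph(bg) == 1

    def test_empty_call_set(self, tmp_path):
        empty = finalize_calls(pd.DataFrame(
            columns=["contig", "pos", "strand", "context", "count_C", "count_T"]))
        bg, tsv = export_tracks(empty, tmp_path / "e")
        assert validate_bedgraph(bg) == 0
        assert read_calls(tsv).empty

    def test_tsv_roundtrip(self, sim_clean, sim_clean_db, tmp_path):
        aligner = Aligner(sim_clean_db, AlignConfig())
        kept = []
        for rec in sim_clean.reads[("LMFA", 1)][:300]:
            hit, _ = aligner.align_read(rec.read_id, rec.seq)
            if hit is not None:
                kept.append((rec.seq, hit))
        calls = pileup(kept, sim_clean_db, sim_clean.genome)
        _, tsv = export_tracks(calls, tmp_path / "c")
        back = read_calls(tsv)
        pd.testing.assert_frame_equal(
            calls.reset_index(drop=True), back.reset_index(drop=True))

    def test_bedgraph_sorted_valid(self, sim_clean, sim_clean_db, tmp_path):
        aligner = Aligner(sim_clean_db, AlignConfig())
        kept = []
        for rec in sim_clean.reads[("HMFA", 2)][:300]:
            hit, _ = aligner.align_read(rec.read_id, rec.seq)
            if hit is not None:
                kept.append((rec.seq, hit))
        calls = pileup(kept, sim_clean_db, sim_clean.genome)
        bg, _ = export_tracks(calls, tmp_path / "v")
        assert validate_bedgraph(bg) == calls.drop_duplicates(["contig", "pos"]).shape[0]
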