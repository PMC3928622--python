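import numpy as np
import pytest

from rrbs_methkit.align import AlignConfig, AlignmentHit, Aligner
from rrbs_methkit.digest import DigestConfig, build_reference, digest, size_select
from rrbs_methkit.simdata import SimConfig, simulate

# 24-bp toy: MspI sites at 3 and 17 (cuts 4, 18), TaqI site at 10 (cut 11)
TOY_SEQ = "AAACCGGTTTTCGATTTCCGGAAA"


@pytest.fixture(scope="session")
def toy_genome():
    return {"toy": TOY_SEQ}


@pytest.fixture(scope="session")
def toy_db(toy_genome):
    cfg = DigestConfig(size_min=1, size_max=350)
    frags = size_select(digest(toy_genome, cfg), cfg)
    return build_reference(frags, toy_genome, cfg)


@pytest.fixture(scope="session")
def sim_clean():
    """Small noiseless simulation: perfect conversion, no sequencing error."""
    cfg = SimConfig(genome_length=20_000, seed=11, replicates_per_group=2,
                    coverage_target=8, conversion_efficiency=1.0,
                    sequencing_error_rate=0.0, dm_fraction=0.2, dm_effect=1.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_clean_db(sim_clean):
    dcfg = sim_clean.config.digest_config()
    frags = size_select(digest(sim_clean.genome, dcfg), dcfg)
    return build_reference(frags, sim_clean.genome, dcfg)


def oracle_align(raw_seq: str, db, cfg: AlignConfig):
    """Independent full-scan reference aligner for cross-checking.

    Scans every offset of every entry in converted space, recounts
    bisulfite-aware mismatches on the raw sequences, and applies the
    uniqueness margin. Returns (kept hit or None, candidate list).
    """
    conv = raw_seq.upper().replace("C", "T")
    L = len(conv)
    hits = []
    for entry in db.entries:
        ref_conv = entry.conv_seq
        for off in range(len(ref_conv) - L + 1):
            mm = 0
            for a, b in zip(conv, ref_conv[off:off + L]):
                if a != b or a == "N":
                    mm += 1
                    if mm > cfg.max_mismatches:
                        break
            if mm > cfg.max_mismatches:
                continue
            bs = 0
            for r, g in zip(raw_seq.upper(), entry.raw_seq[off:off + L]):
                if (r == g and r != "N") or (r == "T" and g == "C"):
                    continue
                bs += 1
            hits.append(AlignmentHit(entry.entry_id, off, entry.strand, mm, bs))
    if not hits:
        return None, hits
    ranked = sorted(hits, key=lambda h: (h.bs_mismatches, h.entry_id, h.offset))
    if len(ranked) == 1:
        return ranked[0], hits
    if ranked[1].bs_mismatches - ranked[0].bs_mismatches >= cfg.uniqueness_margin:
        return ranked[0], hits
    return None, hits
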