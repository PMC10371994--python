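"""Local alignment, pileup accumulation, SAM interchange.

The affine-gap Smith-Waterman is checked for score equality against
Biopython's PairwiseAligner (an independent implementation of the same
optimisation problem) over random sequence pairs.
"""

import random

import numpy as np
import pytest

from amplitype.align import (Alignment, Rejection, Scoring, align_read,
                             pileup, read_sam, smith_waterman, write_sam)


def _biopython_local(scoring=Scoring()):
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    return a


class TestSmithWaterman:
    @pytest.mark.parametrize("max_len, n_pairs, seed", [(12, 1000, 0),
                                                        (50, 60, 1)])
    def test_score_matches_independent_aligner(self, max_len, n_pairs, seed):
        rng = random.Random(seed)
        oracle = _biopython_local()
        for _ in range(n_pairs):
            s1 = "".join(rng.choice("ACGT")
                         for _ in range(rng.randint(1, max_len)))
            s2 = "".join(rng.choice("ACGT")
                         for _ in range(rng.randint(1, max_len)))
            assert smith_waterman(s1, s2)[0] == oracle.score(s1, s2)

    def test_empty_inputs_score_zero(self):
        assert smith_waterman("", "ACGT") == (0, [])
        assert smith_waterman("ACGT", "") == (0, [])

    def test_columns_monotone_and_consistent(self):
        rng = random.Random(7)
        for _ in range(50):
            s1 = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
            s2 = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
            score, cols = smith_waterman(s1, s2)
            reads = [r for r, t in cols if r is not None]
            refs = [t for r, t in cols if t is not None]
            assert reads == sorted(reads) and len(set(reads)) == len(reads)
            assert refs == sorted(refs) and len(set(refs)) == len(refs)
            # recompute the score from the columns
            total, prev_gap = 0, False
            for r, t in cols:
                if r is not None and t is not None:
                    total += 1 if s1[r] == s2[t] else -1
                    prev_gap = False
                else:
                    total += -1 if prev_gap else -2
                    prev_gap = True
            assert total == score


class TestAlignRead:
    @pytest.mark.parametrize("method", ["auto", "exact"])
    def test_exact_substring_full_identity(self, refs, method):
        ref = refs["HBB_1"]
        read = ref[100:300]
        res = align_read(read, refs, method=method, read_id="r1")
        assert isinstance(res, Alignment)
        assert res.amplicon_id == "HBB_1"
        assert res.score == 200
        assert res.identity == 1.0
        assert res.n_mismatch == 0
        assert res.ref_start == 100

    @pytest.mark.parametrize("method", ["auto", "exact"])
    def test_single_substitution_scored(self, refs, method):
        ref = refs["ACKR1_1"]
        read = list(ref[50:250])
        read[100] = {"A": "C"}.get(read[100], "A")
        read = "".join(read)
        res = align_read(read, refs, method=method)
        assert isinstance(res, Alignment)
        assert res.amplicon_id == "ACKR1_1"
        assert res.n_mismatch == 1
        assert res.score == 199 * 1 + 1 * (-1)  # (len-1) matches, 1 mismatch

    def test_methods_agree_on_substitution_reads(self, refs):
        rng = np.random.default_rng(3)
        ref = refs["G6PD_2"]
        for _ in range(20):
            start = int(rng.integers(0, len(ref) - 150))
            read = list(ref[start:start + 150])
            for p in rng.choice(np.arange(5, 145), size=3, replace=False):
                read[p] = "ACGT"[(("ACGT".index(read[p])) + 1) % 4]
            read = "".join(read)
            auto = align_read(read, refs, method="auto")
            exact = align_read(read, refs, method="exact")
            assert isinstance(auto, Alignment) and isinstance(exact, Alignment)
            assert auto.score == exact.score
            assert auto.amplicon_id == exact.amplicon_id

    def test_random_read_rejected(self, refs):
        rng = random.Random(99)
        read = "".join(rng.choice("ACGT") for _ in range(100))
        res = align_read(read, refs)
        assert isinstance(res, Rejection)

    def test_empty_read_rejected(self, refs):
        res = align_read("", refs)
        assert res == Rejection("", "empty_read")

    def test_short_span_rejected(self, refs):
        res = align_read(refs["HBB_1"][10:40], refs)
        assert isinstance(res, Rejection)
        assert res.reason == "short_span"

    def test_empty_refs_signal(self):
        with pytest.raises(ValueError):
            align_read("ACGT", {})


class TestPileup:
    def _mk_aln(self, amp_id, ref, read, start, read_id="r"):
        n = len(read)
        offs = np.arange(n, dtype=np.int32)
        mism = sum(a != b for a, b in zip(read, ref[start:start + n]))
        return Alignment(read_id, amp_id, read, offs, offs + start,
                         score=n - 2 * mism, n_mismatch=mism, n_columns=n)

    def test_counts_ref_and_alt(self, panel, refs):
        site = panel.site_by_rsid("rs334")
        amp = panel.amplicon("HBB_1")
        off = amp.local_offset(site.pos)
        ref = refs["HBB_1"]
        alt_read = ref[:off] + site.alt_allele + ref[off + 1:]
        alns = (
            [self._mk_aln("HBB_1", ref, ref, 0, f"ref{i}") for i in range(6)]
            + [self._mk_aln("HBB_1", ref, alt_read, 0, f"alt{i}")
               for i in range(4)]
        )
        cols = pileup(alns, panel)
        col = next(c for c in cols
                   if c.amplicon_id == "HBB_1" and c.local_offset == off)
        assert col.counts[site.ref_allele] == 6
        assert col.counts[site.alt_allele] == 4
        assert col.depth == 10

    def test_nonspanning_read_contributes_nothing(self, panel, refs):
        amp = panel.amplicon("HBB_1")
        site = panel.site_by_rsid("rs334")
        off = amp.local_offset(site.pos)
        ref = refs["HBB_1"]
        aln = self._mk_aln("HBB_1", ref, ref[:60], 0)  # ends before the site
        col = next(c for c in pileup([aln], panel)
                   if c.amplicon_id == "HBB_1" and c.local_offset == off)
        assert col.depth == 0

    def test_depth_bounded_by_read_count(self, panel, refs):
        ref = refs["DANTU_1"]
        alns = [self._mk_aln("DANTU_1", ref, ref, 0, f"r{i}")
                for i in range(7)]
        for col in pileup(alns, panel):
            if col.amplicon_id == "DANTU_1":
                assert col.depth == 7  # error-free full-length reads
            else:
                assert col.depth == 0

    def test_het_pileup_contains_exactly_two_bases(self, panel, refs,
                                                   small_pool, scheme):
        """Error-free heterozygote: site columns carry ref and alt only."""
        from amplitype.demux import demultiplex

        res = demultiplex(
            ((r.read_id, r.sequence, r.quality)
             for r in small_pool["reads"]),
            scheme,
            small_pool["sheet"],
        )
        truth = {t.sample_id: t for t in small_pool["truth"]}
        sites = {s.key: s for s in panel.sites}
        checked = 0
        for sample, reads in res.assigned.items():
            alns = [align_read(seq, refs, read_id=rid)
                    for rid, seq, _q in reads]
            alns = [a for a in alns if isinstance(a, Alignment)]
            cols = {(c.amplicon_id, c.local_offset): c
                    for c in pileup(alns, panel)}
            for amp in panel.amplicons:
                for s in amp.sites:
                    gt = set(truth[sample].genotypes[s.key])
                    col = cols[(amp.amplicon_id, amp.local_offset(s.pos))]
                    observed = {b for b, n in col.counts.items() if n > 0}
                    assert observed == gt
                    if len(gt) == 2:
                        checked += 1
        assert checked > 0  # at least one het exercised


class TestSamInterchange:
    def test_round_trip_pileup_identical(self, panel, refs, tmp_path):
        rng = np.random.default_rng(5)
        alns = []
        for i, (amp_id, ref) in enumerate(refs.items()):
            read = list(ref)
            p = int(rng.integers(20, len(read) - 20))
            read[p] = "ACGT"[("ACGT".index(read[p]) + 2) % 4]
            res = align_read("".join(read), refs, read_id=f"r{i}")
            assert isinstance(res, Alignment)
            alns.append(res)
        sam = tmp_path / "aln.sam"
        write_sam(alns, refs, sam)
        back, skipped = read_sam(sam, panel, refs)
        assert skipped["unmapped"] == 0
        direct = pileup(alns, panel)
        via_sam = pileup(back, panel)
        assert [(c.amplicon_id, c.local_offset, c.counts) for c in direct] \
            == [(c.amplicon_id, c.local_offset, c.counts) for c in via_sam]

    def test_unmapped_and_secondary_skipped(self, panel, refs, tmp_path):
        import pysam

        sam = tmp_path / "mixed.sam"
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "HBB_1", "LN": len(refs["HBB_1"])}]}
        with pysam.AlignmentFile(str(sam), "w", header=header) as out:
            a = pysam.AlignedSegment(out.header)
            a.query_name = "mapped"
            a.query_sequence = refs["HBB_1"][:100]
            a.reference_id = 0
            a.reference_start = 0
            a.cigarstring = "100M"
            out.write(a)
            u = pysam.AlignedSegment(out.header)
            u.query_name = "unmapped"
            u.query_sequence = "ACGT" * 10
            u.is_unmapped = True
            out.write(u)
            s = pysam.AlignedSegment(out.header)
            s.query_name = "secondary"
            s.query_sequence = refs["HBB_1"][:50]
            s.reference_id = 0
            s.reference_start = 10
            s.cigarstring = "50M"
            s.is_secondary = True
            out.write(s)
        alns, skipped = read_sam(sam, panel, refs)
        assert len(alns) == 1
        assert skipped["unmapped"] == 1
        assert skipped["secondary"] == 1

    def test_genomic_coordinates_translated(self, panel, refs, tmp_path):
        """A SAM mapped to genomic chromosome coordinates yields the same
        site offsets as the amplicon-local path."""
        import pysam

        amp = panel.amplicon("HBB_1")
        site = panel.site_by_rsid("rs334")
        ref = refs["HBB_1"]
        sam = tmp_path / "genomic.sam"
        header = {"HD": {"VN": "1.6"},
                  "SQ": [{"SN": "11", "LN": 135_000_000}]}
        with pysam.AlignmentFile(str(sam), "w", header=header) as out:
            a = pysam.AlignedSegment(out.header)
            a.query_name = "g1"
            a.query_sequence = ref  # full amplicon, genomic placement
            a.reference_id = 0
            a.reference_start = amp.start - 1  # SAM 0-based
            a.cigarstring = f"{len(ref)}M"
            out.write(a)
        alns, _ = read_sam(sam, panel, refs)
        assert len(alns) == 1
        assert alns[0].amplicon_id == "HBB_1"
        col = next(c for c in pileup(alns, panel)
                   if c.amplicon_id == "HBB_1"
                   and c.local_offset == amp.local_offset(site.pos))
        assert col.counts[site.ref_allele] == 1
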