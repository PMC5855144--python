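"""Locus assignment, spacer stripping and flank-anchored allele measurement."""

import numpy as np
import pytest

from ssrgeno import ReadRecord, SpanCallParams, assign_locus, call_read, measure_allele, strip_spacer, tally_reads
from ssrgeno.panel import reverse_complement
from ssrgeno.repeat_caller import AlleleTally, ReadCall, UNASSIGNED, _find_anchor, read_tallies, write_tallies


def read_with_tract(locus, allele_len, flank5_bases=8, flank3_bases=8):
    """Synthetic read: trimmed 5' context + resized tract + trimmed 3' context."""
    m = len(locus.motif)
    tract = (locus.motif * (allele_len // m + 1))[:allele_len]
    left = locus.amplicon_seq[: locus.repeat_start - 1]
    right = locus.amplicon_seq[locus.repeat_end :]
    seq = left[len(left) - flank5_bases :] + tract + right[:flank3_bases]
    return ReadRecord("t", seq, (37,) * len(seq))


def full_read(locus, allele_len=None, prefix=""):
    if allele_len is None:
        seq = locus.amplicon_seq
    else:
        m = len(locus.motif)
        tract = (locus.motif * (allele_len // m + 1))[:allele_len]
        seq = (
            locus.amplicon_seq[: locus.repeat_start - 1]
            + tract
            + locus.amplicon_seq[locus.repeat_end :]
        )
    seq = prefix + seq
    return ReadRecord("t", seq, (37,) * len(seq))


class TestStripSpacer:
    def test_spacer_before_primer_is_stripped(self, panel):
        params = SpanCallParams(spacer_set=("AAA", "TTT"))
        read = full_read(panel["ProC10"], prefix="AAA")
        out, spacer = strip_spacer(read, panel, params)
        assert spacer == "AAA"
        assert out.seq == panel["ProC10"].amplicon_seq
        assert len(out.quals) == len(out.seq)

    def test_read_without_spacer_unchanged(self, panel):
        params = SpanCallParams(spacer_set=("AAA", "TTT"))
        read = full_read(panel["ProC10"])
        out, spacer = strip_spacer(read, panel, params)
        assert spacer is None and out is read

    def test_spacer_without_primer_context_kept(self, panel):
        params = SpanCallParams(spacer_set=("AAA", "TTT"))
        read = ReadRecord("t", "AAA" + "CGCGCGCGCGCGCGCGCGCGCGCG", (37,) * 27)
        out, spacer = strip_spacer(read, panel, params)
        assert spacer is None and out.seq.startswith("AAA")


class TestAssignLocus:
    def test_every_locus_assigned_forward(self, panel):
        for loc in panel:
            assert assign_locus(full_read(loc), panel) == (loc.name, "forward")

    def test_reverse_complement_assigned_reverse(self, panel):
        loc = panel["ProC22"]
        rc = ReadRecord("t", reverse_complement(loc.amplicon_seq), (37,) * len(loc.amplicon_seq))
        assert assign_locus(rc, panel) == ("ProC22", "reverse")

    def test_tolerates_primer_mismatches(self, panel):
        loc = panel["ProC10"]
        seq = "GC" + loc.amplicon_seq[2:]  # two substitutions in the primer
        assert assign_locus(ReadRecord("t", seq, (37,) * len(seq)), panel) == ("ProC10", "forward")
        seq3 = "GCA" + loc.amplicon_seq[3:]
        assert assign_locus(ReadRecord("t", seq3, (37,) * len(seq3)), panel)[0] == UNASSIGNED

    def test_random_reads_overwhelmingly_unassigned(self, panel):
        rng = np.random.default_rng(123)
        bases = np.array(list("ACGT"))
        hits = 0
        for _ in range(10_000):
            seq = "".join(rng.choice(bases, size=150))
            if assign_locus(ReadRecord("t", seq, (37,) * 150), panel)[0] != UNASSIGNED:
                hits += 1
        # P(<=2 mismatches to a 19-21-mer at a fixed offset) is ~1e-9
        assert hits == 0


class TestMeasureAllele:
    def test_att_times_four_is_allele_12(self, panel):
        call = measure_allele(read_with_tract(panel["ProC10"], 12), panel["ProC10"])
        assert call.status == "spanning"
        assert call.allele_len == 12
        assert call.purity == 1.0

    @pytest.mark.parametrize("flank3_bases,expect", [(8, "spanning"), (7, "non_spanning"), (0, "non_spanning")])
    def test_requires_eight_bases_of_3prime_flank(self, panel, flank3_bases, expect):
        call = measure_allele(read_with_tract(panel["ProC10"], 12, flank3_bases=flank3_bases), panel["ProC10"])
        assert call.status == expect

    @pytest.mark.parametrize("flank5_bases,expect", [(8, "spanning"), (7, "non_spanning")])
    def test_requires_eight_bases_of_5prime_flank(self, panel, flank5_bases, expect):
        call = measure_allele(read_with_tract(panel["ProC10"], 12, flank5_bases=flank5_bases), panel["ProC10"])
        assert call.status == expect

    def test_single_tract_substitution_purity(self, panel):
        loc = panel["ProC10"]
        read = read_with_tract(loc, 12)
        tract_start = 8
        mutated = read.seq[: tract_start + 10] + "G" + read.seq[tract_start + 11 :]
        assert mutated != read.seq
        call = measure_allele(ReadRecord("t", mutated, read.quals), loc)
        assert call.status == "spanning"
        assert call.allele_len == 12
        assert call.purity == pytest.approx(11 / 12)

    def test_garbage_tract_is_impure(self, panel):
        loc = panel["ProC10"]
        seq = loc.flank5 + "GCGCGCGCGCGC" + loc.flank3
        call = measure_allele(ReadRecord("t", seq, (37,) * len(seq)), loc)
        assert call.status == "impure"
        assert call.allele_len is None

    def test_exhaustive_error_free_recovery(self, panel):
        """Every locus x allele length (4..15 motif copies) measures exactly."""
        for loc in panel:
            m = len(loc.motif)
            for copies in range(4, 16):
                call = measure_allele(full_read(loc, copies * m), loc)
                assert (call.status, call.allele_len) == ("spanning", copies * m), (
                    loc.name,
                    copies,
                )

    def test_reverse_complement_invariance(self, panel):
        for loc in panel:
            fwd = full_read(loc, 10 * len(loc.motif))
            rev = ReadRecord("t", reverse_complement(fwd.seq), fwd.quals[::-1])
            call_f = call_read(fwd, panel)
            call_r = call_read(rev, panel)
            assert call_f.status == call_r.status == "spanning"
            assert call_f.allele_len == call_r.allele_len
            assert (call_f.orientation, call_r.orientation) == ("forward", "reverse")


def oracle_anchor_measure(seq, a5, a3, max_mm):
    """Brute force: leftmost acceptable 5' placement, then leftmost
    acceptable 3' placement strictly after it."""

    def mm(i, anchor):
        return sum(x != y for x, y in zip(seq[i : i + len(anchor)], anchor))

    p5 = next(
        (i for i in range(len(seq) - len(a5) + 1) if mm(i, a5) <= max_mm), None
    )
    if p5 is None:
        return None
    start = p5 + len(a5)
    p3 = next(
        (j for j in range(start, len(seq) - len(a3) + 1) if mm(j, a3) <= max_mm),
        None,
    )
    if p3 is None:
        return None
    return p3 - start


class TestAnchorOracle:
    def test_agreement_on_random_reads(self, panel):
        """Production anchor search equals the try-everything oracle."""
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        loc = panel["ProC10"]
        a5, a3 = loc.flank5, loc.flank3
        params = SpanCallParams(purity_min=0.0)  # isolate anchor placement
        for trial in range(400):
            n = int(rng.integers(20, 90))
            seq = "".join(rng.choice(bases, size=n))
            if trial % 2:
                # plant anchors around a noisy middle to exercise hits
                mid = "".join(rng.choice(bases, size=int(rng.integers(1, 20))))
                seq = seq[:5] + a5 + mid + a3 + seq[5:]
            expected = oracle_anchor_measure(seq, a5, a3, params.max_anchor_mismatch)
            got = measure_allele(ReadRecord("t", seq, (37,) * len(seq)), loc, params)
            if expected is None or expected < 1:
                assert got.status == "non_spanning"
            else:
                assert got.allele_len == expected

    def test_find_anchor_prefers_leftmost(self):
        # approximate hit left of an exact hit wins (leftmost-acceptable rule)
        seq = "CCCCATTGCCCCCATTGGCCC"
        assert _find_anchor(seq, "ATTGG", 0, 1) == 4


class TestTally:
    def make_calls(self, spec):
        calls = []
        for locus, status, allele in spec:
            calls.append(ReadCall("r", locus, "forward", status, allele_len=allele))
        return calls

    def test_counts_and_totals(self):
        calls = self.make_calls(
            [("L1", "spanning", 12)] * 8 + [("L1", "spanning", 15)] * 2
        )
        tallies = tally_reads(calls, "ind1")
        assert len(tallies) == 1
        t = tallies[0]
        assert t.counts == {12: 8, 15: 2}
        assert t.total_reads == 10
        assert t.n_alleles_detected == 2

    def test_non_spanning_excluded(self):
        calls = self.make_calls(
            [("L1", "spanning", 12)] * 5 + [("L1", "non_spanning", None)] * 7
        )
        (t,) = tally_reads(calls, "ind1")
        assert t.total_reads == 5

    def test_conservation_across_loci(self):
        calls = self.make_calls(
            [("L1", "spanning", 12)] * 3
            + [("L2", "spanning", 16)] * 4
            + [("L1", "impure", None)] * 2
        )
        tallies = tally_reads(calls, "ind1")
        assert sum(t.total_reads for t in tallies) == 7

    def test_tsv_round_trip(self, tmp_path):
        tallies = [
            AlleleTally("ind1", "L1", {12: 8, 15: 2}),
            AlleleTally("ind2", "L2", {20: 30}),
        ]
        path = tmp_path / "t.tsv"
        write_tallies(tallies, path)
        back = read_tallies(path)
        assert [(t.individual, t.locus, t.counts) for t in back] == [
            (t.individual, t.locus, t.counts) for t in tallies
        ]
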