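import numpy as np
import pytest

from tandemhmm.read_localization import (
    LocalizedRead,
    RejectedRead,
    align_flanks,
    chain_candidates,
    find_tandem_tracts,
    localize_read,
)
from tandemhmm.repeat_spec import ErrorProfile, reverse_complement
from tandemhmm.simulator import SimConfig, mutate_sequence, simulate_participant_random


class TestTractFinding:
    def test_clean_tract_recovered_exactly(self, locus, rng):
        flank_a = "".join(rng.choice(list("TGA"), size=60))
        flank_b = "".join(rng.choice(list("TCA"), size=60))
        read = flank_a + "CAG" * 30 + flank_b
        tracts = find_tandem_tracts(read, locus.spec)
        assert tracts[0].start == 60
        assert tracts[0].end == 60 + 90

    def test_no_occurrences_yields_empty(self, locus):
        assert find_tandem_tracts("T" * 80, locus.spec) == []

    def test_noisy_tract_boundaries_near_truth(self, locus):
        # at a 15% error rate boundary windows are often disrupted, so the
        # detector recovers most — not all — boundaries tightly; the rest
        # are eroded edges that the decoder's pad/tail mechanism absorbs
        # (count accuracy is asserted end-to-end in the pipeline tests)
        rng = np.random.default_rng(0)
        profile = ErrorProfile()
        tight = coarse = 0
        n = 20
        for _ in range(n):
            tract, _ = mutate_sequence("CAG" * 20, profile, rng)
            flank_a = "".join(rng.choice(list("TTGAC"), size=50))
            flank_b = "".join(rng.choice(list("TTGAC"), size=50))
            read = flank_a + tract + flank_b
            tracts = find_tandem_tracts(read, locus.spec)
            if not tracts:
                continue
            best = chain_candidates(tracts, 3)
            err = max(abs(best.start - 50), abs(best.end - (50 + len(tract))))
            tight += err <= 6
            coarse += err <= 30
        assert tight >= 0.6 * n
        assert coarse >= 0.9 * n

    def test_empty_read_rejected(self, locus):
        with pytest.raises(ValueError):
            find_tandem_tracts("", locus.spec)


class TestFlankAnchoring:
    def test_verbatim_flanks(self, locus):
        spec = locus.spec
        up = locus.sequence[spec.start - 201 : spec.start - 1]
        down = locus.sequence[spec.end : spec.end + 200]
        anchors = align_flanks(up, down, locus.sequence)
        assert anchors.up_identity == 1.0
        assert anchors.down_identity == 1.0
        assert anchors.up_end == spec.start - 1
        assert anchors.down_start == spec.end
        assert anchors.ordered

    def test_substituted_flanks_keep_position(self, locus, rng):
        spec = locus.spec
        up = list(locus.sequence[spec.start - 201 : spec.start - 1])
        for i in rng.choice(len(up), size=20, replace=False):  # 10% substitutions
            up[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[up[i]]
        anchors = align_flanks("".join(up), locus.sequence[spec.end : spec.end + 200],
                               locus.sequence)
        assert anchors.up_identity == pytest.approx(0.9, abs=0.03)
        assert abs(anchors.up_end - (spec.start - 1)) <= 3

    def test_swapped_flanks_flagged(self, locus):
        spec = locus.spec
        up = locus.sequence[spec.start - 201 : spec.start - 1]
        down = locus.sequence[spec.end : spec.end + 200]
        anchors = align_flanks(down, up, locus.sequence)
        assert not anchors.ordered

    def test_window_shorter_than_flank(self, locus):
        with pytest.raises(ValueError):
            align_flanks("A" * 50, "C" * 50, "ACGT" * 5)


class TestLocalizeRead:
    def test_error_free_reads_recover_truth_exactly(self, locus, errorfree_profile):
        config = SimConfig(locus=locus, coverage=20, profile=errorfree_profile)
        part = simulate_participant_random(config, np.random.default_rng(3), "p0")
        for read in part.reads:
            loc = localize_read(read.read_id, read.sequence, locus)
            assert isinstance(loc, LocalizedRead)
            assert loc.anchored
            assert (loc.tract_start, loc.tract_end) == (read.tract_start, read.tract_end)

    def test_short_upstream_flank_rejected(self, locus):
        read = locus.sequence[locus.spec.start - 11 : locus.spec.end + 700]
        result = localize_read("r", read, locus)
        assert isinstance(result, RejectedRead)
        assert result.reason == "short_flank"

    def test_reverse_strand_read_is_flipped(self, locus):
        fwd = locus.sequence[locus.spec.start - 301 : locus.spec.end + 300]
        rev = reverse_complement(fwd)
        loc_f = localize_read("f", fwd, locus)
        loc_r = localize_read("r", rev, locus)
        assert isinstance(loc_r, LocalizedRead)
        assert loc_r.strand == "-"
        assert loc_r.sequence == fwd
        assert (loc_r.tract_start, loc_r.tract_end) == (loc_f.tract_start, loc_f.tract_end)

    def test_unrelated_read_rejected(self, locus, rng):
        junk = "".join(rng.choice(list("ACGT"), size=400))
        result = localize_read("r", junk, locus)
        assert isinstance(result, RejectedRead)
        # random sequence may contain a chance repeat-like window, in which
        # case rejection happens at the flank-identity stage instead
        assert result.reason in {"no_tract", "unaligned", "low_identity"}

    def test_accept_reject_partition(self, locus, rng):
        config = SimConfig(locus=locus, coverage=30)
        part = simulate_participant_random(config, np.random.default_rng(7), "p0")
        outcomes = [localize_read(r.read_id, r.sequence, locus) for r in part.reads]
        accepted = [o for o in outcomes if isinstance(o, LocalizedRead)]
        rejected = [o for o in outcomes if isinstance(o, RejectedRead)]
        assert len(accepted) + len(rejected) == len(part.reads)
        assert all(r.reason in {"no_tract", "short_flank", "low_identity", "unaligned"}
                   for r in rejected)

    def test_prepared_segment_layout(self, locus):
        read = locus.sequence[locus.spec.start - 101 : locus.spec.end + 100]
        loc = localize_read("r", read, locus)
        prepared = loc.prepared
        assert prepared.count("NNN") >= 2
        inner = prepared.split("NNN")[1]
        assert "CAG" * locus.reference_units in inner
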