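"""Array detection, anchor module recovery, tracrRNA localisation."""

import numpy as np
import pytest

from castkit.crisprdet import (AnchorParams, ArrayParams, detect_arrays,
                               find_anchor, locate_tracr, orient_array)
from castkit.orfcat import Orf
from castkit.seqio import GenomeRecord, Interval, TssRecord, reverse_complement
from castkit.synth import CastParams, generate_cast_genome


def _guarded_array_genome(rng, n_repeats=4, repeat_len=37, spacer_len=35,
                          flank=400, mutate_unit=None, n_subs=0):
    """Random background + planted array whose unit-flank columns are kept
    below the detector's column threshold (well-defined boundaries)."""
    repeat = "".join(rng.choice(list("ACGT"), repeat_len))
    chars = list(rng.choice(list("ACGT"), flank))
    starts = []
    for i in range(n_repeats):
        starts.append(len(chars))
        unit = list(repeat)
        if mutate_unit == i:
            # substitutions clustered in the 5' half (repeats are most
            # conserved in their 3' segments); a seed k-mer must survive
            for pos in range(5, 5 + 5 * n_subs, 5):
                unit[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[unit[pos]]
        chars.extend(unit)
        if i < n_repeats - 1:
            chars.extend(rng.choice(list("ACGT"), spacer_len))
    chars.extend(rng.choice(list("ACGT"), flank))
    # boundary guard: no flanking column may reach 75% agreement
    allowed_top = int(np.ceil(0.75 * n_repeats)) - 1
    for offset in (-1, repeat_len):
        cols = [s + offset for s in starts]
        while max([chars[c] for c in cols].count(b) for b in "ACGT") > allowed_top:
            chars[cols[int(rng.integers(len(cols)))]] = "ACGT"[int(rng.integers(4))]
    return GenomeRecord("g", "".join(chars)), repeat, starts


class TestDetectArrays:
    def test_four_identical_repeats(self):
        rng = np.random.default_rng(0)
        genome, repeat, starts = _guarded_array_genome(rng)
        arrays = detect_arrays(genome)
        assert len(arrays) == 1
        a = arrays[0]
        assert len(a.repeats) == 4
        assert a.consensus_repeat == repeat
        assert [r.start for r in a.repeats] == starts
        assert (a.loc.start, a.loc.end) == (starts[0], starts[-1] + 37)
        assert len(a.spacers) == 3 and all(len(s) == 35 for s in a.spacers)

    def test_one_unit_with_three_substitutions_still_detected(self):
        rng = np.random.default_rng(1)
        genome, repeat, starts = _guarded_array_genome(rng, mutate_unit=1, n_subs=3)
        arrays = detect_arrays(genome)
        assert len(arrays) == 1
        assert len(arrays[0].repeats) == 4  # identity 34/37 >= 0.8 keeps the unit
        assert arrays[0].consensus_repeat == repeat

    def test_two_repeats_below_minimum(self):
        rng = np.random.default_rng(2)
        genome, _, _ = _guarded_array_genome(rng, n_repeats=2)
        assert detect_arrays(genome) == []

    def test_no_array_in_plain_random_sequence(self):
        rng = np.random.default_rng(3)
        genome = GenomeRecord("g", "".join(rng.choice(list("ACGT"), 20000)))
        assert detect_arrays(genome) == []


class TestOrientArray:
    def test_le_context_left_gives_minus(self, default_genome):
        genome, truth = default_genome
        (array,) = detect_arrays(genome)
        assert orient_array(array, genome, {"le": truth.meta["le"]}) == "-"

    def test_uniform_repeats_without_context_unknown(self):
        rng = np.random.default_rng(4)
        genome, _, _ = _guarded_array_genome(rng)
        (array,) = detect_arrays(genome)
        assert orient_array(array, genome, None) == "unknown"

    def test_reversing_genome_flips_orientation(self, default_genome):
        genome, truth = default_genome
        flipped = GenomeRecord(genome.id, reverse_complement(genome.seq))
        (array,) = detect_arrays(flipped)
        le_flipped = len(genome.seq) - truth.meta["le"]
        assert orient_array(array, flipped, {"le": le_flipped}) == "+"


class TestFindAnchor:
    def test_exact_recovery_on_generated_genome(self, default_genome):
        genome, truth = default_genome
        (array,) = detect_arrays(genome)
        anchor = find_anchor(genome, array, truth.meta["le"])
        t = truth.meta["anchor"]
        assert anchor is not None
        assert (anchor.r_star.start, anchor.r_star.end) == (t["r_star"].start, t["r_star"].end)
        assert (anchor.anchor_spacer.start, anchor.anchor_spacer.end) == \
            (t["anchor_spacer"].start, t["anchor_spacer"].end)
        assert (anchor.protospacer.start, anchor.protospacer.end) == \
            (t["protospacer"].start, t["protospacer"].end)
        assert anchor.pam == t["pam"]
        assert anchor.pam_to_le_distance == t["pam_to_le"]
        assert anchor.mismatches == 0 and anchor.warnings == ()

    def test_one_protospacer_mismatch_tolerated(self, default_genome):
        genome, truth = default_genome
        t = truth.meta["anchor"]
        seq = list(genome.seq)
        mid = (t["protospacer"].start + t["protospacer"].end) // 2
        seq[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[mid]]
        mutated = GenomeRecord(genome.id, "".join(seq))
        (array,) = detect_arrays(mutated)
        anchor = find_anchor(mutated, array, truth.meta["le"])
        assert anchor is not None and anchor.mismatches == 1
        assert (anchor.protospacer.start, anchor.protospacer.end) == \
            (t["protospacer"].start, t["protospacer"].end)

    def test_pam_violation_rejects_module(self, default_genome):
        genome, truth = default_genome
        t = truth.meta["anchor"]
        seq = list(genome.seq)
        pam_start = t["protospacer"].end  # plus-strand slice holding revcomp(PAM)
        seq[pam_start : pam_start + 3] = reverse_complement("CT" + t["pam"][2])
        mutated = GenomeRecord(genome.id, "".join(seq))
        (array,) = detect_arrays(mutated)
        assert find_anchor(mutated, array, truth.meta["le"]) is None

    def test_translation_invariance(self, default_genome):
        genome, truth = default_genome
        shift = 500
        rng = np.random.default_rng(99)
        shifted = GenomeRecord(genome.id,
                               "".join(rng.choice(list("ACGT"), shift)) + genome.seq)
        (array,) = detect_arrays(shifted)
        anchor = find_anchor(shifted, array, truth.meta["le"] + shift)
        t = truth.meta["anchor"]
        assert anchor is not None
        assert anchor.r_star.start == t["r_star"].start + shift
        assert anchor.pam_to_le_distance == t["pam_to_le"]


def _cas12k_orf(truth) -> Orf:
    iv = truth.meta["cas12k"]["corrected"]
    return Orf(iv, "ATG", "M" * (len(iv) // 3 - 1), len(iv) // 3 - 1)


class TestLocateTracr:
    def test_generated_tss_gives_distance_35(self, default_genome):
        genome, truth = default_genome
        (array,) = detect_arrays(genome)
        tracr = locate_tracr(genome, _cas12k_orf(truth), truth.tss_table, array)
        assert tracr.distance_from_cas12k_stop == 35
        assert not tracr.predicted
        assert tracr.tss.label == "tracrRNA"
        # the locus spans from the array edge to the TSS
        assert tracr.loc.start == array.loc.end

    def test_no_tss_table_falls_back_to_prediction(self, default_genome):
        genome, truth = default_genome
        (array,) = detect_arrays(genome)
        tracr = locate_tracr(genome, _cas12k_orf(truth), [], array)
        assert tracr.predicted and tracr.tss is None
        assert tracr.loc == Interval(genome.id, array.loc.end,
                                     truth.meta["cas12k"]["corrected"].start, "-")

    def test_tss_outside_window_ignored(self, default_genome):
        genome, truth = default_genome
        (array,) = detect_arrays(genome)
        far = TssRecord(genome.id, truth.meta["cas12k"]["corrected"].start - 150, "-")
        tracr = locate_tracr(genome, _cas12k_orf(truth), [far], array)
        assert tracr.predicted


class TestRecallInvariants:
    """Array + anchor recovery is exact over many seeded genomes, with no
    false positives on large random backgrounds."""

    @pytest.mark.parametrize("seed", range(50))
    def test_exact_recovery_50kb_background(self, seed):
        genome, truth = generate_cast_genome(
            CastParams(seed=1000 + seed, background_len=50000))
        arrays = detect_arrays(genome)
        assert len(arrays) == 1  # the planted array and nothing else
        a = arrays[0]
        t = truth.meta["array"]
        assert (a.loc.start, a.loc.end) == (t["loc"].start, t["loc"].end)
        assert [r.start for r in a.repeats] == t["repeat_starts"]
        assert a.consensus_repeat == t["consensus"]
        anchor = find_anchor(genome, a, truth.meta["le"])
        assert anchor is not None
        assert anchor.pam == truth.meta["anchor"]["pam"]
        assert anchor.pam_to_le_distance == truth.meta["anchor"]["pam_to_le"]
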