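"""Regulator classification, end detection, system assembly and reporting."""

import json

import numpy as np
import pytest

from castkit.caster import (AnnotateConfig, Ends, annotate, assemble_system,
                            classify_regulator, detect_ends, find_trna, report,
                            report_json)
from castkit.crisprdet import detect_arrays
from castkit.orfcat import Orf, find_orfs
from castkit.refdata import TRNA_TOKEN, load_reference_sets
from castkit.seqio import GenomeRecord, Interval
from castkit.synth import CastParams, generate_cast_genome


def _orf(contig: str, start: int, end: int, strand: str, protein: str) -> Orf:
    assert len(protein) == (end - start) // 3 - 1
    return Orf(Interval(contig, start, end, strand), "ATG", protein, len(protein))


def _fake_cas12k() -> Orf:
    return _orf("c", 1000, 2920, "-", "M" * 639)


class TestClassifyRegulator:
    def test_cvkr_candidate(self):
        refs = load_reference_sets()
        protein = refs["CvkR"][0][1][:150]
        cand = _orf("c", 3002, 3002 + 453, "+", protein)
        call = classify_regulator([cand], _fake_cas12k())
        assert call is not None
        assert call.family == "CvkR"
        assert call.length_ok
        assert call.distance_to_cas12k == 82

    def test_arc_candidate(self):
        refs = load_reference_sets()
        protein = refs["Arc_1"][0][1][:60]
        cand = _orf("c", 3002, 3002 + 183, "+", protein)
        call = classify_regulator([cand], _fake_cas12k())
        assert call is not None and call.family == "Arc_1" and call.length_ok

    def test_same_strand_candidate_excluded(self):
        refs = load_reference_sets()
        protein = refs["CvkR"][0][1][:150]
        cand = _orf("c", 3002, 3002 + 453, "-", protein)  # same strand as cas12k
        assert classify_regulator([cand], _fake_cas12k()) is None

    def test_distant_candidate_excluded(self):
        refs = load_reference_sets()
        protein = refs["CvkR"][0][1][:150]
        cand = _orf("c", 9020, 9020 + 453, "+", protein)  # > 3 kb away
        assert classify_regulator([cand], _fake_cas12k()) is None

    def test_unrelated_protein_not_called(self):
        rng = np.random.default_rng(0)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150))
        cand = _orf("c", 3002, 3002 + 453, "+", protein)
        assert classify_regulator([cand], _fake_cas12k()) is None


class TestDetectEnds:
    def test_exact_tir_recovery(self, default_genome):
        genome, truth = default_genome
        (array,) = detect_arrays(genome)
        tnsB = _orf(genome.id, truth.meta["tnsb"].start, truth.meta["tnsb"].end, "-",
                    "M" * ((len(truth.meta["tnsb"])) // 3 - 1))
        ends = detect_ends(genome, None, None, tnsB, array)
        assert ends.confidence == "high"
        assert (ends.le, ends.re) == (truth.meta["le"], truth.meta["re"])
        assert ends.tir_len == truth.meta["params"]["tir_len"]

    def test_deleted_tir_falls_back_to_flanks(self, default_genome):
        genome, truth = default_genome
        m = truth.meta
        rng = np.random.default_rng(5)
        seq = list(genome.seq)
        tir_len = m["params"]["tir_len"]
        seq[m["le"] : m["le"] + tir_len] = rng.choice(list("ACGT"), tir_len)
        broken = GenomeRecord(genome.id, "".join(seq))
        (array,) = detect_arrays(broken)
        tnsB = _orf(genome.id, m["tnsb"].start, m["tnsb"].end, "-",
                    "M" * (len(m["tnsb"]) // 3 - 1))
        ends = detect_ends(broken, None, None, tnsB, array)
        assert ends.confidence == "low"
        assert ends.re == m["tnsb"].end

    def test_no_evidence_raises(self, default_genome):
        genome, _ = default_genome
        with pytest.raises(ValueError, match="evidence"):
            detect_ends(genome, None, None, None, None)


class TestFindTrna:
    def test_planted_token_located(self, default_genome):
        genome, truth = default_genome
        iv = find_trna(genome)
        assert iv is not None
        assert (iv.start, iv.end) == (truth.meta["trna"].start, truth.meta["trna"].end)

    def test_absent_token(self):
        rng = np.random.default_rng(1)
        genome = GenomeRecord("g", "".join(rng.choice(list("ACGT"), 2000)))
        assert find_trna(genome) is None


class TestAssemble:
    def test_full_generated_locus_has_no_flags(self, default_genome):
        genome, truth = default_genome
        (system,) = annotate(genome, truth.tss_table)
        assert system.flags == []
        assert system.regulator_type == "CvkR"

    def test_swapped_transposases_flagged(self, default_genome):
        genome, truth = default_genome
        (system,) = annotate(genome, truth.tss_table)
        parts = {"cas12k": system.cas12k, "tnsB": system.tnsC, "tnsC": system.tnsB,
                 "tniQ": system.tniQ, "ends": Ends(system.le, system.re, "high"),
                 "array": system.array, "tracr": system.tracr}
        flagged = assemble_system(genome, parts)
        assert any("order violated" in f for f in flagged.flags)

    def test_missing_regulator_is_not_a_flag(self):
        genome, truth = generate_cast_genome(
            CastParams(seed=11, regulator_family="none", background_len=2000))
        (system,) = annotate(genome, truth.tss_table)
        assert system.regulator_type == "none"
        assert not any("regulator" in f for f in system.flags)

    def test_system_requires_cas12k(self):
        with pytest.raises(ValueError, match="cas12k"):
            assemble_system(GenomeRecord("g", "ACGT" * 100), {})

    def test_annotate_plain_genome_has_no_system(self):
        rng = np.random.default_rng(2)
        genome = GenomeRecord("g", "".join(rng.choice(list("ACGT"), 8000)))
        with pytest.raises(ValueError, match="cas12k"):
            annotate(genome, [])


class TestReport:
    def test_empty_report_valid(self):
        doc = report([])
        assert doc["systems"] == [] and doc["schema_version"] == 1

    def test_round_trip_idempotent(self, default_genome):
        genome, truth = default_genome
        systems = annotate(genome, truth.tss_table)
        blob = report_json(systems)
        assert json.dumps(json.loads(blob), sort_keys=True, indent=2) == blob

    def test_distances_consistent_with_coordinates(self, default_genome):
        genome, truth = default_genome
        (system,) = annotate(genome, truth.tss_table)
        doc = report([system])["systems"][0]
        # regulator distance equals the divergent gap between corrected starts
        assert doc["regulator"]["distance_to_cas12k"] == \
            doc["regulator"]["orf"]["loc"]["start"] - doc["cas12k"]["loc"]["end"]
        # PAM-LE distance recomputable from protospacer end and LE
        pam_end = doc["anchor"]["protospacer"]["end"] + 3
        assert doc["anchor"]["pam_to_le_distance"] == doc["le"] - pam_end

    def test_reverse_complement_symmetry_of_regulator_distance(self, default_genome):
        from castkit.seqio import reverse_complement
        genome, truth = default_genome
        flipped = GenomeRecord(genome.id, reverse_complement(genome.seq))
        n = len(genome.seq)
        tss_flipped = [type(t)(t.contig, n - t.pos + 1, "+-"[t.strand == "+"], t.label)
                       for t in truth.tss_table]
        (system,) = annotate(flipped, tss_flipped)
        (orig,) = annotate(genome, truth.tss_table)
        assert system.regulator.distance_to_cas12k == orig.regulator.distance_to_cas12k
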