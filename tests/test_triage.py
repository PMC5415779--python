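import numpy as np
import pytest

from mitodip.readqc import ReadPair
from mitodip.refgenome import ReferenceGenome, build_nuclear_only
from mitodip.simulate import SimulationConfig, evaluate_triage
from mitodip.triage import (
    Alignment,
    AlignParams,
    align_reads,
    alignments_from_sam,
    pass1_select,
    pass2_filter,
    pass3_confirm,
    revcomp,
    run_triage,
)


def _pair(rid, seq1, seq2=None):
    seq2 = seq2 or revcomp(seq1)
    q = (35,) * len(seq1)
    return ReadPair(rid, seq1, q, seq2, (35,) * len(seq2), None)


class TestToyAligner:
    def test_verbatim_read_maps_uniquely_at_correct_position(self, toy_reference):
        seq = toy_reference.records["chrM"][299:349]  # unique 50-mer at pos 300
        aln = align_reads([_pair("r1", seq)], toy_reference)
        a = aln[("r1", 1)]
        assert a.mapped and a.unique and a.target == "chrM" and a.pos == 300

    def test_mate2_maps_on_reverse_strand(self, toy_reference):
        seq = toy_reference.records["chrM"][299:349]
        aln = align_reads([_pair("r1", seq)], toy_reference)
        a2 = aln[("r1", 2)]
        assert a2.mapped and a2.target == "chrM" and a2.pos == 300

    def test_shared_block_read_is_non_unique(self, toy_reference):
        # the 60 bp block at chrM:101 is duplicated at chr1:201
        seq = toy_reference.records["chrM"][100:150]
        a = align_reads([_pair("tie", seq)], toy_reference)[("tie", 1)]
        assert a.mapped and not a.unique and a.mapq == 0

    def test_random_reads_do_not_map(self, toy_reference):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        pairs = [_pair(f"rnd{i}", "".join(rng.choice(bases, 50))) for i in range(200)]
        aln = align_reads(pairs, toy_reference)
        mapped = sum(a.mapped for a in aln.values())
        assert mapped == 0

    def test_mismatches_within_budget_still_map(self, toy_reference):
        seq = list(toy_reference.records["chrM"][299:349])
        seq[10] = {"A": "C"}.get(seq[10], "A")
        seq[40] = {"A": "C"}.get(seq[40], "A")
        a = align_reads([_pair("mm", "".join(seq))], toy_reference)[("mm", 1)]
        assert a.mapped and a.unique and a.pos == 300

    def test_seed_longer_than_read_is_an_error(self, toy_reference):
        with pytest.raises(ValueError, match="seed_k"):
            align_reads([_pair("s", "ACGTACGT")], toy_reference)

    def test_deterministic(self, toy_reference):
        seq = toy_reference.records["chrM"][50:100]
        a = align_reads([_pair("d", seq)], toy_reference)
        b = align_reads([_pair("d", seq)], toy_reference)
        assert a == b


def _aln(rid, mate, target, pos=10, unique=True, mapped=True, mapq=37):
    if not mapped:
        return Alignment(rid, mate, None, 0, 0, False, False, 0)
    return Alignment(rid, mate, target, pos, mapq, unique, mapped, 50)


class TestPassLogic:
    def test_pass1_keeps_only_unique_mito_pairs(self):
        alns = {}
        for rid, tgt, uniq in [("a", "chrM", True), ("b", "chr1", True), ("c", "chrM", False)]:
            alns[(rid, 1)] = _aln(rid, 1, tgt, unique=uniq, mapq=37 if uniq else 0)
            alns[(rid, 2)] = _aln(rid, 2, tgt, unique=uniq, mapq=37 if uniq else 0)
        assert pass1_select(alns, "chrM") == {"a"}

    def test_pass1_both_mates_required_by_default(self):
        alns = {
            ("a", 1): _aln("a", 1, "chrM"),
            ("a", 2): _aln("a", 2, "chr1"),
        }
        assert pass1_select(alns, "chrM") == set()
        assert pass1_select(alns, "chrM", pair_mode="any") == {"a"}

    def test_pass2_keeps_nuclear_unmapped(self):
        alns = {
            ("a", 1): _aln("a", 1, None, mapped=False),
            ("a", 2): _aln("a", 2, None, mapped=False),
            ("b", 1): _aln("b", 1, "chr1"),
            ("b", 2): _aln("b", 2, None, mapped=False),
        }
        assert pass2_filter({"a", "b"}, alns) == {"a"}

    def test_pass2_missing_id_is_an_error(self):
        with pytest.raises(KeyError):
            pass2_filter({"ghost"}, {})

    def test_pass2_empty_input(self):
        assert pass2_filter(set(), {}) == set()

    def test_pass3_records_fragment_outer_span(self):
        alns = {
            ("a", 1): _aln("a", 1, "chrM", pos=101),
            ("a", 2): _aln("a", 2, "chrM", pos=301),
        }
        retained = pass3_confirm({"a"}, alns, "chrM")
        assert retained.fragments["a"] == ("chrM", 101, 250)

    def test_pass3_drops_newly_non_unique(self):
        alns = {
            ("a", 1): _aln("a", 1, "chrM", unique=False, mapq=0),
            ("a", 2): _aln("a", 2, "chrM"),
        }
        assert len(pass3_confirm({"a"}, alns, "chrM")) == 0


class TestRunTriage:
    def test_zero_reads(self, toy_reference):
        retained, report = run_triage([], toy_reference, build_nuclear_only(toy_reference))
        assert len(retained) == 0
        assert (report.n_input, report.n_pass3_confirmed) == (0, 0)

    def test_counts_monotone_non_increasing(self, toy_reference):
        rng = np.random.default_rng(3)
        mito = toy_reference.records["chrM"]
        pairs = []
        for i in range(30):
            s = int(rng.integers(0, len(mito) - 120))
            frag = mito[s : s + 120]
            pairs.append(_pair(f"f{i}", frag[:50], revcomp(frag[-50:])))
        _, report = run_triage(pairs, toy_reference, build_nuclear_only(toy_reference))
        assert (
            report.n_input
            >= report.n_pass1_mito_unique
            >= report.n_pass2_nuclear_unmapped
            >= report.n_pass3_confirmed
        )

    def test_nuclear_ref_containing_mito_rejected(self, toy_reference):
        with pytest.raises(ValueError, match="nuclear-only"):
            run_triage([], toy_reference, toy_reference)

    def test_identical_numt_reads_are_excluded(self, default_simulation):
        """Reads from the mitochondrial interval duplicated as an identical NUMT
        cannot be attributed and must not survive; precision stays perfect."""
        cfg, full, nuclear, truth, meth, pairs, origins = default_simulation
        retained, _ = run_triage(pairs[:2000], full, nuclear)
        precision, _, _ = evaluate_triage(origins, retained)
        assert precision == 1.0
        spec = cfg.numts[0]
        assert spec.divergence == 0.0
        lo, hi = spec.source_start, spec.source_stop
        # no retained fragment starts inside the identical homology interval
        inner = [p for p in retained.positions() if lo <= p <= hi - 320]
        assert inner == []

    def test_report_bytes_deterministic(self, default_simulation):
        cfg, full, nuclear, truth, meth, pairs, origins = default_simulation
        _, r1 = run_triage(pairs[:500], full, nuclear)
        _, r2 = run_triage(pairs[:500], full, nuclear)
        assert r1.to_tsv() == r2.to_tsv()


class TestSamIngestion:
    def test_sam_flags_and_mapq_drive_uniqueness(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "@SQ\tSN:chrM\tLN:1000\n"
            "@SQ\tSN:chr1\tLN:1000\n"
            "u\t65\tchrM\t11\t37\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "u\t129\tchrM\t61\t37\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "m\t65\tchrM\t11\t0\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "s\t65\tchrM\t11\t37\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            "s\t321\tchr1\t11\t37\t50M\t*\t0\t0\t*\t*\n"
            "x\t69\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
        )
        alns = alignments_from_sam(sam)
        assert alns[("u", 1)].unique and alns[("u", 2)].unique
        assert alns[("u", 1)].pos == 11
        assert not alns[("m", 1)].unique  # MAPQ 0
        assert not alns[("s", 1)].unique  # has a secondary placement
        assert not alns[("x", 1)].mapped

    def test_pass_logic_is_backend_agnostic(self, tmp_path):
        """The pass functions consume only (mapped, unique, target); SAM-derived
        alignments flow through identically to toy-aligner ones."""
        sam = tmp_path / "p.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrM\tLN:1000\n"
            "a\t65\tchrM\t101\t37\t50M\t*\t0\t0\t" + "C" * 50 + "\t" + "I" * 50 + "\n"
            "a\t129\tchrM\t301\t37\t50M\t*\t0\t0\t" + "C" * 50 + "\t" + "I" * 50 + "\n"
        )
        alns = alignments_from_sam(sam)
        assert pass1_select(alns, "chrM") == {"a"}
        retained = pass3_confirm({"a"}, alns, "chrM")
        assert retained.fragments["a"] == ("chrM", 101, 250)
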