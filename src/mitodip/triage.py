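"""Three-pass NUMT-exclusion triage of paired-end reads.

NUMTs (nuclear-mitochondrial pseudogenes) are nuclear loci nearly identical to
stretches of the mitochondrial genome; reads originating from them are easily
mis-attributed to the mitochondrion.  The triage keeps only reads that can be
confidently attributed to mtDNA:

pass 1
    align to the FULL reference; keep reads uniquely mapped to the
    mitochondrial record.  Reads from a NUMT identical to its mitochondrial
    paralogue produce co-optimal placements and are dropped here.
pass 2
    re-align the survivors to the nuclear-only reference; keep reads that do
    NOT map — i.e. reads with no plausible nuclear home, even a diverged one.
pass 3
    re-align the survivors to the full reference and confirm they are still
    uniquely mitochondrial; final positions come from this pass.

The pass logic consumes only (mapped, unique, target, position), so alignments
may come from the built-in toy aligner or from any external aligner via SAM.
A fragment is retained only when both mates survive every pass (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .readqc import ReadPair
from .refgenome import ReferenceGenome

__all__ = [
    "Alignment",
    "AlignParams",
    "TriageReport",
    "RetainedReadSet",
    "SeedIndex",
    "align_reads",
    "alignments_from_sam",
    "pass1_select",
    "pass2_filter",
    "pass3_confirm",
    "run_triage",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Alignment:
    read_id: str
    mate: int  # 1 or 2
    target: str | None  # record name, None when unmapped
    pos: int  # 1-based leftmost aligned base (0 when unmapped)
    mapq: int
    unique: bool  # no co-optimal secondary placement
    mapped: bool
    span: int  # aligned bases on the reference

    def __post_init__(self) -> None:
        if self.mapped and self.pos < 1:
            raise ValueError("mapped alignment requires pos >= 1")
        if self.unique and not self.mapped:
            raise ValueError("unique implies mapped")


@dataclass
class AlignParams:
    """Toy aligner settings: k-mer seeds, ungapped extension, no indels."""

    seed_k: int = 15
    max_mismatch: int = 5  # per 50 bp read
    mapq_unique: int = 37


@dataclass
class TriageReport:
    n_input: int = 0
    n_pass1_mito_unique: int = 0
    n_pass2_nuclear_unmapped: int = 0
    n_pass3_confirmed: int = 0
    discard_reasons: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        counts = (
            self.n_input,
            self.n_pass1_mito_unique,
            self.n_pass2_nuclear_unmapped,
            self.n_pass3_confirmed,
        )
        if any(a < b for a, b in zip(counts, counts[1:])) or counts[-1] < 0:
            raise ValueError(f"triage counts not monotone non-increasing: {counts}")

    def to_tsv(self) -> str:
        lines = ["stage\tfragments"]
        lines.append(f"input\t{self.n_input}")
        lines.append(f"pass1_mito_unique\t{self.n_pass1_mito_unique}")
        lines.append(f"pass2_nuclear_unmapped\t{self.n_pass2_nuclear_unmapped}")
        lines.append(f"pass3_confirmed\t{self.n_pass3_confirmed}")
        for reason in sorted(self.discard_reasons):
            lines.append(f"discard:{reason}\t{self.discard_reasons[reason]}")
        return "\n".join(lines) + "\n"


@dataclass
class RetainedReadSet:
    """Fragments confidently attributed to the mitochondrial record.

    ``fragments`` maps read id -> (record, leftmost position, outer span),
    where position/span describe the mate-pair outer interval from pass 3.
    """

    mito_name: str
    fragments: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fragments)

    def positions(self) -> list[int]:
        return [pos for _, pos, _ in self.fragments.values()]

    def to_tsv(self) -> str:
        lines = ["read_id\trecord\tpos\tspan"]
        for rid in sorted(self.fragments):
            rec, pos, span = self.fragments[rid]
            lines.append(f"{rid}\t{rec}\t{pos}\t{span}")
        return "\n".join(lines) + "\n"


class SeedIndex:
    """Exact k-mer index over all records of a reference."""

    def __init__(self, ref: ReferenceGenome, k: int):
        self.k = k
        self.record_names = list(ref.records)
        self.sequences = ref.records
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ridx, name in enumerate(self.record_names):
            seq = ref.records[name]
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((ridx, i))

    def candidates(self, read: str) -> set[tuple[int, int]]:
        """Candidate (record_idx, start) placements from 3 spaced seeds."""
        k, n = self.k, len(read)
        offsets = {0, (n - k) // 2, n - k}
        out: set[tuple[int, int]] = set()
        for off in offsets:
            for ridx, pos in self.index.get(read[off : off + k], ()):
                start = pos - off
                if start >= 0 and start + n <= len(self.sequences[self.record_names[ridx]]):
                    out.add((ridx, start))
        return out


def _mismatches(a: str, ref: str, start: int, limit: int) -> int:
    n = 0
    for i, base in enumerate(a):
        if base != ref[start + i]:
            n += 1
            if n > limit:
                return n
    return n


def _align_one(index: SeedIndex, read_id: str, mate: int, seq: str, params: AlignParams) -> Alignment:
    if params.seed_k > len(seq):
        raise ValueError(f"seed_k={params.seed_k} larger than read length {len(seq)}")
    best_score = params.max_mismatch + 1
    best: list[tuple[int, int, int]] = []  # (record_idx, start, strand)
    for strand, oriented in enumerate((seq, revcomp(seq))):
        for ridx, start in index.candidates(oriented):
            ref_seq = index.sequences[index.record_names[ridx]]
            mm = _mismatches(oriented, ref_seq, start, best_score)
            if mm < best_score:
                best_score, best = mm, [(ridx, start, strand)]
            elif mm == best_score and best_score <= params.max_mismatch:
                if (ridx, start, strand) not in best:
                    best.append((ridx, start, strand))
    if best_score > params.max_mismatch or not best:
        return Alignment(read_id, mate, None, 0, 0, False, False, 0)
    unique = len(best) == 1
    # leftmost tie-break (record order, then coordinate) for reporting only
    ridx, start, _ = min(best, key=lambda t: (t[0], t[1]))
    return Alignment(
        read_id,
        mate,
        index.record_names[ridx],
        start + 1,
        params.mapq_unique if unique else 0,
        unique,
        True,
        len(seq),
    )


def align_reads(
    pairs: Iterable[ReadPair],
    ref: ReferenceGenome,
    params: AlignParams | None = None,
    index: SeedIndex | None = None,
) -> dict[tuple[str, int], Alignment]:
    """Align both mates of every pair with the toy seed-and-extend aligner.

    Deterministic given inputs and params.  Returns a mapping keyed by
    (read_id, mate).
    """
    params = params or AlignParams()
    if index is None:
        index = SeedIndex(ref, params.seed_k)
    out: dict[tuple[str, int], Alignment] = {}
    for pair in pairs:
        out[(pair.read_id, 1)] = _align_one(index, pair.read_id, 1, pair.seq1, params)
        out[(pair.read_id, 2)] = _align_one(index, pair.read_id, 2, pair.seq2, params)
    return out


def alignments_from_sam(path: str | Path) -> dict[tuple[str, int], Alignment]:
    """Ingest alignments from SAM/BAM (any external aligner).

    Uniqueness for SAM input: primary, mapped, MAPQ > 0, and no secondary or
    supplementary record observed for the same mate.
    """
    import pysam

    primary: dict[tuple[str, int], "pysam.AlignedSegment"] = {}
    has_alt: set[tuple[str, int]] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            mate = 2 if seg.is_read2 else 1
            key = (seg.query_name, mate)
            if seg.is_secondary or seg.is_supplementary:
                has_alt.add(key)
                continue
            primary[key] = seg
    out: dict[tuple[str, int], Alignment] = {}
    for (rid, mate), seg in primary.items():
        if seg.is_unmapped:
            out[(rid, mate)] = Alignment(rid, mate, None, 0, 0, False, False, 0)
            continue
        unique = (rid, mate) not in has_alt and seg.mapping_quality > 0
        span = seg.reference_length or seg.query_length or 0
        out[(rid, mate)] = Alignment(
            rid, mate, seg.reference_name, seg.reference_start + 1,
            seg.mapping_quality, unique, True, span,
        )
    return out


def _mates_of(alignments: Mapping[tuple[str, int], Alignment], rid: str) -> list[Alignment]:
    return [alignments[(rid, m)] for m in (1, 2) if (rid, m) in alignments]


def pass1_select(
    alignments_full: Mapping[tuple[str, int], Alignment],
    mito_name: str,
    min_mapq: int = 1,
    pair_mode: str = "both",
) -> set[str]:
    """Read ids uniquely mapped to the mitochondrial record on the full reference."""
    ids = {rid for rid, _ in alignments_full}

    def ok(a: Alignment) -> bool:
        return a.mapped and a.unique and a.target == mito_name and a.mapq >= min_mapq

    selected = set()
    for rid in ids:
        mates = _mates_of(alignments_full, rid)
        hits = [ok(a) for a in mates]
        if (all(hits) if pair_mode == "both" else any(hits)):
            selected.add(rid)
    return selected


def pass2_filter(
    selected: set[str],
    alignments_nuclear: Mapping[tuple[str, int], Alignment],
    pair_mode: str = "both",
) -> set[str]:
    """Keep ids whose mates are unmapped on the nuclear-only reference."""
    for rid in selected:
        if not _mates_of(alignments_nuclear, rid):
            raise KeyError(f"read {rid!r} missing from nuclear-only alignments")
    out = set()
    for rid in selected:
        unmapped = [not a.mapped for a in _mates_of(alignments_nuclear, rid)]
        if (all(unmapped) if pair_mode == "both" else any(unmapped)):
            out.add(rid)
    return out


def pass3_confirm(
    ids: set[str],
    alignments_full: Mapping[tuple[str, int], Alignment],
    mito_name: str,
    min_mapq: int = 1,
    pair_mode: str = "both",
) -> RetainedReadSet:
    """Re-confirm unique mitochondrial placement; record final fragment positions."""
    for rid in ids:
        if not _mates_of(alignments_full, rid):
            raise KeyError(f"read {rid!r} missing from confirmation alignments")
    confirmed = pass1_select(
        {k: v for k, v in alignments_full.items() if k[0] in ids},
        mito_name, min_mapq, pair_mode,
    )
    retained = RetainedReadSet(mito_name=mito_name)
    for rid in confirmed:
        mates = [a for a in _mates_of(alignments_full, rid) if a.mapped and a.target == mito_name]
        left = min(a.pos for a in mates)
        right = max(a.pos + a.span - 1 for a in mates)
        retained.fragments[rid] = (mito_name, left, right - left + 1)
    return retained


def run_triage(
    pairs: list[ReadPair],
    full_ref: ReferenceGenome,
    nuclear_ref: ReferenceGenome,
    params: AlignParams | None = None,
    min_mapq: int = 1,
    pair_mode: str = "both",
) -> tuple[RetainedReadSet, TriageReport]:
    """Run the complete three-pass triage with the built-in aligner."""
    if full_ref.mito_name is None:
        raise ValueError("full reference must designate a mitochondrial record")
    if full_ref.mito_name in nuclear_ref.records:
        raise ValueError("nuclear-only reference still contains the mitochondrial record")
    params = params or AlignParams()
    report = TriageReport(n_input=len(pairs))
    if not pairs:
        return RetainedReadSet(mito_name=full_ref.mito_name), report

    full_index = SeedIndex(full_ref, params.seed_k)
    aln_full = align_reads(pairs, full_ref, params, index=full_index)
    p1 = pass1_select(aln_full, full_ref.mito_name, min_mapq, pair_mode)
    report.n_pass1_mito_unique = len(p1)
    report.discard_reasons["pass1_not_mito_unique"] = len(pairs) - len(p1)

    surv1 = [p for p in pairs if p.read_id in p1]
    aln_nuc = align_reads(surv1, nuclear_ref, params)
    p2 = pass2_filter(p1, aln_nuc, pair_mode)
    report.n_pass2_nuclear_unmapped = len(p2)
    report.discard_reasons["pass2_nuclear_mapped"] = len(p1) - len(p2)

    surv2 = [p for p in pairs if p.read_id in p2]
    aln_confirm = align_reads(surv2, full_ref, params, index=full_index)
    retained = pass3_confirm(p2, aln_confirm, full_ref.mito_name, min_mapq, pair_mode)
    report.n_pass3_confirmed = len(retained)
    report.discard_reasons["pass3_not_confirmed"] = len(p2) - len(retained)
    report.validate()
    return retained, report
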