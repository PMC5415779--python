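"""Adapter and quality trimming of paired-end reads before alignment.

Trimming follows the common aligner-preprocessor convention: an exact
adapter-prefix match at the 3' end is clipped first, then low-quality 3' tails
are removed by the maximal-partial-sum rule (drop the suffix starting at the
position that maximises the running sum of ``q_threshold - q_i`` computed from
the 3' end).  A simple hard-clip-at-first-low-base mode is available for
comparison.  Reads trimmed below a minimum length are flagged discarded; a
fragment is dropped when either mate is discarded.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = ["ReadPair", "QCReport", "trim_read", "qc_stream", "read_fastq_pairs"]


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: tuple[int, ...]
    seq2: str
    qual2: tuple[int, ...]
    origin_label: str | None = None  # simulation truth tag

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.read_id!r}: sequence/quality length mismatch")


@dataclass
class QCReport:
    n_in: int = 0
    n_kept: int = 0
    n_discarded: int = 0
    bases_trimmed: int = 0

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        for k in ("n_in", "n_kept", "n_discarded", "bases_trimmed"):
            lines.append(f"{k}\t{getattr(self, k)}")
        return "\n".join(lines) + "\n"


def _adapter_clip(seq: str, adapter: str, min_overlap: int) -> int:
    """Return the cut position after 3' adapter removal (len(seq) if none).

    Scans for the longest adapter *prefix* that matches a suffix of the read
    exactly, requiring at least `min_overlap` matching bases.
    """
    n = len(seq)
    for start in range(max(0, n - len(adapter)), n - min_overlap + 1):
        tail = seq[start:]
        if adapter.startswith(tail):
            return start
    return n


def _quality_cut(quals: tuple[int, ...], q_threshold: int) -> int:
    """BWA-style maximal-partial-sum 3' cut position.

    Drops the suffix from the index maximising ``sum(q_threshold - q_i)`` over
    suffixes; returns len(quals) when every suffix sum is non-positive.
    """
    best, cut, s = 0, len(quals), 0
    for i in range(len(quals) - 1, -1, -1):
        s += q_threshold - quals[i]
        if s > best:
            best, cut = s, i
    return cut


def trim_read(
    seq: str,
    quals: tuple[int, ...],
    adapter: str | None = None,
    q_threshold: int = 20,
    min_overlap: int = 5,
    hard_clip: bool = False,
) -> tuple[str, tuple[int, ...]]:
    """Trim one read: 3' adapter removal, then 3' quality trimming.

    With ``hard_clip=True`` quality trimming instead cuts at the first base
    with quality below `q_threshold` (everything 3' of it is removed).
    """
    if adapter is not None:
        if not adapter:
            raise ValueError("adapter must be non-empty when adapter trimming is enabled")
        cut = _adapter_clip(seq, adapter, min_overlap)
        seq, quals = seq[:cut], quals[:cut]
    if hard_clip:
        cut = len(quals)
        for i, q in enumerate(quals):
            if q < q_threshold:
                cut = i
                break
    else:
        cut = _quality_cut(quals, q_threshold)
    return seq[:cut], quals[:cut]


def _open_maybe_gz(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(path1: str | Path, path2: str | Path, phred_offset: int = 33) -> Iterator[ReadPair]:
    """Iterate synchronised mate pairs from two (optionally gzipped) FASTQ files."""
    with _open_maybe_gz(path1) as fh1, _open_maybe_gz(path2) as fh2:
        while True:
            block1 = [fh1.readline() for _ in range(4)]
            block2 = [fh2.readline() for _ in range(4)]
            if not block1[0] and not block2[0]:
                return
            if bool(block1[0]) != bool(block2[0]) or "" in (block1[3], block2[3]):
                raise ValueError("desynchronised or truncated FASTQ mate files")
            id1 = block1[0].strip().split()[0].lstrip("@")
            id2 = block2[0].strip().split()[0].lstrip("@")
            base1 = id1[:-2] if id1.endswith(("/1", "/2")) else id1
            base2 = id2[:-2] if id2.endswith(("/1", "/2")) else id2
            if base1 != base2:
                raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
            yield ReadPair(
                read_id=base1,
                seq1=block1[1].strip().upper(),
                qual1=tuple(ord(c) - phred_offset for c in block1[3].strip()),
                seq2=block2[1].strip().upper(),
                qual2=tuple(ord(c) - phred_offset for c in block2[3].strip()),
            )


def qc_stream(
    pairs: Iterator[ReadPair] | list[ReadPair],
    adapter: str | None = None,
    q_threshold: int = 20,
    min_length: int = 30,
    hard_clip: bool = False,
) -> tuple[list[ReadPair], QCReport]:
    """Trim a stream of read pairs; drop fragments with any mate below `min_length`."""
    report = QCReport()
    kept: list[ReadPair] = []
    for pair in pairs:
        report.n_in += 1
        s1, q1 = trim_read(pair.seq1, pair.qual1, adapter, q_threshold, hard_clip=hard_clip)
        s2, q2 = trim_read(pair.seq2, pair.qual2, adapter, q_threshold, hard_clip=hard_clip)
        report.bases_trimmed += (len(pair.seq1) - len(s1)) + (len(pair.seq2) - len(s2))
        if len(s1) < min_length or len(s2) < min_length:
            report.n_discarded += 1
            continue
        report.n_kept += 1
        kept.append(ReadPair(pair.read_id, s1, q1, s2, q2, origin_label=pair.origin_label))
    return kept, report
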