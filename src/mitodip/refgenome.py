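"""Reference genome handling, window tiling and gene annotation.

The analysis universe is the human mitochondrial genome (rCRS, 16,569 bp)
embedded in a larger reference that also carries nuclear sequence — including
nuclear-mitochondrial pseudogenes (NUMTs).  This module loads references,
derives the nuclear-only reference used by the middle triage pass, tiles the
mitochondrial genome into non-overlapping 100 bp windows, and labels each
window with the genes it overlaps.

Coordinates are 1-based inclusive throughout the public API (matching the
convention of mitochondrial annotation tables); BED input is converted on
load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "WindowGrid",
    "MitoAnnotation",
    "load_reference",
    "build_nuclear_only",
    "circularize_reference",
    "tile_windows",
    "annotate_windows",
]

#: record names recognised as the mitochondrial chromosome (case-insensitive)
MITO_ALIASES = ("chrm", "mt", "chrmt")

_VALID_BASES = frozenset("ACGTN")


@dataclass
class ReferenceGenome:
    """Named nucleotide sequences with a designated mitochondrial record.

    Parameters
    ----------
    records
        Ordered mapping of record name to upper-case sequence (A/C/G/T/N).
    mito_name
        Name of the mitochondrial record, or ``None`` for a nuclear-only
        reference.
    circular
        Whether the mitochondrial record is circular.  Recorded for
        provenance; alignment and windowing treat the sequence as linear by
        default (see :func:`mitodip.triage.align_reads`).
    """

    records: dict[str, str]
    mito_name: str | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        cleaned = {}
        for name, seq in self.records.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"record {name!r} contains invalid bases: {sorted(bad)}")
            cleaned[name] = seq
        self.records = cleaned
        if self.mito_name is not None and self.mito_name not in self.records:
            raise ValueError(f"mito_name {self.mito_name!r} names no record")

    @property
    def mito_sequence(self) -> str:
        if self.mito_name is None:
            raise ValueError("reference has no mitochondrial record")
        return self.records[self.mito_name]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.records.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def load_reference(fasta_path: str | Path, mito_name: str | None = None) -> ReferenceGenome:
    """Load a FASTA reference and auto-detect the mitochondrial record.

    Detection accepts ``chrM``/``MT``/``chrMT`` case-insensitively; an explicit
    `mito_name` overrides detection and must exist in the file.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record name {rec.id!r} in {fasta_path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    if mito_name is not None:
        if mito_name not in records:
            raise ValueError(f"requested mitochondrial record {mito_name!r} not in {fasta_path}")
        detected = mito_name
    else:
        detected = next((n for n in records if n.lower() in MITO_ALIASES), None)
    return ReferenceGenome(records=records, mito_name=detected)


def build_nuclear_only(ref: ReferenceGenome) -> ReferenceGenome:
    """Drop the mitochondrial record, keeping all other sequences byte-identical.

    This is the "custom reference" used by the second triage pass: a read of
    true mitochondrial origin should find no placement here, while a
    NUMT-origin read still maps to its nuclear locus.
    """
    if ref.mito_name is None:
        raise ValueError("reference has no mitochondrial record to remove")
    records = {n: s for n, s in ref.records.items() if n != ref.mito_name}
    return ReferenceGenome(records=records, mito_name=None, circular=False)


def circularize_reference(ref: ReferenceGenome, overhang: int = 500) -> ReferenceGenome:
    """Circular-aware alignment mode: extend the mitochondrial record with a
    copy of its first `overhang` bases so reads spanning the origin align
    contiguously.  Positions past the original length wrap back via
    ``pos % L`` (map position p to ``((p - 1) % L) + 1`` before windowing).
    By default the pipeline treats the genome as linear; this helper backs
    the opt-in circular mode.
    """
    if ref.mito_name is None:
        raise ValueError("reference has no mitochondrial record to circularize")
    mito = ref.mito_sequence
    if not 0 < overhang < len(mito):
        raise ValueError("overhang must be positive and shorter than the genome")
    records = dict(ref.records)
    records[ref.mito_name] = mito + mito[:overhang]
    return ReferenceGenome(records=records, mito_name=ref.mito_name, circular=True)


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping tiling of ``[1, genome_length]`` into fixed-size windows.

    ``windows`` holds truncated (actual) 1-based inclusive bounds; the last
    window may be shorter than ``window_size``.  ``nominal_bounds`` gives the
    un-truncated label for a window (the convention used when a 16,569 bp
    genome is reported on a grid labelled to 16,600).
    """

    windows: tuple[tuple[int, int], ...]
    window_size: int
    genome_length: int

    def __len__(self) -> int:
        return len(self.windows)

    def nominal_bounds(self, index: int) -> tuple[int, int]:
        start = index * self.window_size + 1
        return (start, start + self.window_size - 1)

    def window_of(self, pos: int) -> int:
        """Grid index of the window containing 1-based position `pos`."""
        if not 1 <= pos <= self.genome_length:
            raise ValueError(f"position {pos} outside [1, {self.genome_length}]")
        return (pos - 1) // self.window_size

    def window_length(self, index: int) -> int:
        start, stop = self.windows[index]
        return stop - start + 1


def tile_windows(genome_length: int, window_size: int = 100) -> WindowGrid:
    """Tile ``[1, genome_length]`` into ``ceil(L/w)`` non-overlapping windows."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n = math.ceil(genome_length / window_size)
    windows = tuple(
        (i * window_size + 1, min((i + 1) * window_size, genome_length)) for i in range(n)
    )
    return WindowGrid(windows=windows, window_size=window_size, genome_length=genome_length)


@dataclass
class MitoAnnotation:
    """Mitochondrial gene intervals: (name, start, stop, strand), 1-based inclusive."""

    genes: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, start, stop, _ in self.genes:
            if not 1 <= start <= stop:
                raise ValueError(f"gene {name!r} has invalid interval ({start}, {stop})")
            if name in seen:
                raise ValueError(f"duplicate gene name {name!r}")
            seen.add(name)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MitoAnnotation":
        """4-column TSV: name, start, stop, strand (1-based inclusive, header allowed)."""
        genes = []
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if not fields or fields[0] in ("", "name") or line.startswith("#"):
                    continue
                name, start, stop, strand = fields[:4]
                genes.append((name, int(start), int(stop), strand))
        return cls(genes=genes)

    @classmethod
    def from_bed(cls, path: str | Path) -> "MitoAnnotation":
        """BED input (0-based half-open); converted to 1-based inclusive on load."""
        genes = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                start0, end0 = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"feature_{len(genes) + 1}"
                strand = fields[5] if len(fields) > 5 else "+"
                genes.append((name, start0 + 1, end0, strand))
        return cls(genes=genes)


def annotate_windows(
    grid: WindowGrid,
    ann: MitoAnnotation,
    intergenic_label: str = "D-Loop",
) -> list[str]:
    """Label every window with the "/"-joined names of overlapping genes.

    Genes are listed in genomic order (by start, then stop).  Windows that
    overlap no annotated gene receive `intergenic_label` — on the
    mitochondrial genome the un-annotated territory is the control region
    (D-Loop), hence the default.
    """
    ordered = sorted(ann.genes, key=lambda g: (g[1], g[2]))
    labels = []
    for start, stop in grid.windows:
        hit = [name for name, gs, ge, _ in ordered if gs <= stop and ge >= start]
        labels.append("/".join(hit) if hit else intergenic_label)
    return labels
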