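"""Synthetic MeDIP-seq data with planted NUMTs and DMRs, plus truth labels.

The generator emulates the study design this package analyzes: a small
circular mitochondrial genome profiled by methylation-enriched paired-end
sequencing across brain regions and blood from a few matched individuals,
with nuclear-mitochondrial pseudogenes (NUMTs) of controlled divergence
planted in a nuclear decoy so the triage has real contamination to remove.

Model, in order of construction:

* reference — a random mitochondrial sequence (rCRS length by default) and a
  random nuclear record; each NUMT copy is a mitochondrial source interval
  mutated i.i.d. at a per-base divergence rate and written into the nuclear
  record at a fixed locus (substitutions only, matching the ungapped built-in
  aligner).
* methylomes — per (individual, tissue): window methylation = baseline +
  planted tissue effect + Gaussian sample-level noise, clipped to [0, 1].
* fragments — MeDIP enrichment acts at fragment level: a fragment's sampling
  weight is ``base_weight + slope * methylation`` of the window containing
  its midpoint.  Fragment lengths are uniform on the configured range
  (220-320 bp, the study's size selection); two read-length mates are taken
  from the fragment ends (mate 2 reverse-complemented) with i.i.d.
  substitution errors.  A configurable fraction of fragments originates from
  the planted NUMT loci to exercise the triage.

Everything is driven by a single :class:`numpy.random.Generator`, so a fixed
seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .readqc import ReadPair
from .refgenome import ReferenceGenome, build_nuclear_only, tile_windows
from .triage import RetainedReadSet, revcomp

__all__ = [
    "NumtSpec",
    "DmrSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_reference",
    "simulate_methylomes",
    "simulate_fragment_positions",
    "simulate_medip_reads",
    "simulate_window_counts",
    "evaluate_triage",
    "write_fastq_pair",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CORTICAL_TISSUES = ("BA8", "BA9", "BA10", "ECX", "STG")


@dataclass(frozen=True)
class NumtSpec:
    """One NUMT: mitochondrial source interval copied into a nuclear record."""

    source_start: int  # 1-based inclusive on the mitochondrial record
    source_stop: int
    target_record: str
    target_pos: int  # 1-based position where the copy is written
    divergence: float = 0.0  # per-base substitution probability
    copies: int = 1

    @property
    def length(self) -> int:
        return self.source_stop - self.source_start + 1


@dataclass(frozen=True)
class DmrSpec:
    """Planted tissue effect on window methylation over a bp interval."""

    start: int  # 1-based inclusive, aligned to the analysis grid
    stop: int
    tissues: tuple[str, ...]
    effect: float  # added to baseline methylation in the listed tissues


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the profiled study: rCRS-length mitochondrion, 50 bp
    paired-end reads from 220-320 bp fragments, five cortical regions plus
    cerebellum and blood in three individuals with one missing blood sample,
    one identical and one 10%-diverged NUMT, and 10,000 fragments per sample.
    """

    mito_length: int = 16569
    mito_name: str = "chrM"
    nuclear_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 40000})
    numts: tuple[NumtSpec, ...] = (
        NumtSpec(4501, 6500, "chr1", 10001, divergence=0.0),
        NumtSpec(12401, 13400, "chr1", 25001, divergence=0.10),
    )
    tissues: tuple[str, ...] = CORTICAL_TISSUES + ("CER", "BLD")
    individuals: tuple[str, ...] = ("ind1", "ind2", "ind3")
    missing: frozenset[tuple[str, str]] = frozenset({("ind2", "BLD")})
    window_size: int = 100
    baseline_methylation: float = 0.3
    noise_sd: float = 0.05
    dmrs: tuple[DmrSpec, ...] = (
        DmrSpec(16101, 16500, CORTICAL_TISSUES, +0.3),
        DmrSpec(10301, 10600, CORTICAL_TISSUES, -0.2),
    )
    base_weight: float = 0.1
    enrichment_slope: float = 1.0
    fragment_length: tuple[int, int] = (220, 320)
    read_length: int = 50
    error_rate: float = 0.002
    n_fragments: int = 10_000
    numt_fraction: float = 0.1  # fraction of fragments of NUMT origin

    def __post_init__(self) -> None:
        if not 0 <= self.numt_fraction < 1:
            raise ValueError("numt_fraction must be in [0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be a probability")
        lo, hi = self.fragment_length
        if not 0 < lo <= hi <= self.mito_length:
            raise ValueError("fragment length range must fit inside the genome")
        for dmr in self.dmrs:
            m = self.baseline_methylation + dmr.effect
            if not 0 <= m <= 1:
                raise ValueError(f"DMR effect {dmr.effect} pushes methylation outside [0, 1]")

    @property
    def samples(self) -> list[tuple[str, str]]:
        return [
            (ind, tis)
            for ind in self.individuals
            for tis in self.tissues
            if (ind, tis) not in self.missing
        ]

    @property
    def n_windows(self) -> int:
        return math.ceil(self.mito_length / self.window_size)


@dataclass
class SimulationTruth:
    """Planted ground truth: NUMT coordinates, methylomes, per-read origins."""

    numt_intervals: dict[str, list[tuple[int, int, NumtSpec]]] = field(default_factory=dict)
    methylation: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    dmrs: tuple[DmrSpec, ...] = ()
    read_origins: dict[str, dict[str, tuple] ] = field(default_factory=dict)
    # read_origins[sample_key][read_id] = ("mito", start) | ("numt", record, start)

    def mito_homology_windows(self, window_size: int = 100, max_divergence: float = 0.0) -> set[int]:
        """Grid indices of mitochondrial windows covered by a NUMT source
        interval with divergence <= max_divergence (the homology footprint)."""
        out: set[int] = set()
        for intervals in self.numt_intervals.values():
            for _, _, spec in intervals:
                if spec.divergence <= max_divergence:
                    first = (spec.source_start - 1) // window_size
                    last = (spec.source_stop - 1) // window_size
                    out.update(range(first, last + 1))
        return out

    def confusable_windows(
        self, window_size: int = 100, read_length: int = 50, max_divergence: float = 0.0
    ) -> set[int]:
        """Windows whose every possible read start keeps the read fully inside
        an identical homology interval — reads counted there are inherently
        unattributable and the windows must go ND after triage.  Windows at
        the interval's right edge admit reads extending past the homology
        boundary (uniquely attributable), so they are excluded here."""
        out: set[int] = set()
        for intervals in self.numt_intervals.values():
            for _, _, spec in intervals:
                if spec.divergence > max_divergence:
                    continue
                first = spec.source_start - 1
                last_start = spec.source_stop - read_length + 1
                for w in range(first // window_size, (spec.source_stop - 1) // window_size + 1):
                    w_start, w_stop = w * window_size + 1, (w + 1) * window_size
                    if w_start >= spec.source_start and w_stop <= last_start:
                        out.add(w)
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < divergence)
    for i in hits:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator, mito_sequence: str | None = None
) -> tuple[ReferenceGenome, ReferenceGenome, SimulationTruth]:
    """Build the full and nuclear-only references with planted NUMT copies."""
    mito = mito_sequence or _random_seq(rng, config.mito_length)
    if len(mito) != config.mito_length:
        raise ValueError("supplied mitochondrial sequence has the wrong length")
    records = {name: _random_seq(rng, length) for name, length in config.nuclear_lengths.items()}
    truth = SimulationTruth(dmrs=config.dmrs)
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in records}
    for spec in config.numts:
        source = mito[spec.source_start - 1 : spec.source_stop]
        for copy in range(spec.copies):
            pos = spec.target_pos + copy * (spec.length + 100)
            end = pos + spec.length - 1
            if end > len(records[spec.target_record]):
                raise ValueError("NUMT insertion exceeds nuclear record length")
            for a, b in occupied[spec.target_record]:
                if pos <= b and end >= a:
                    raise ValueError("overlapping NUMT insertion loci")
            occupied[spec.target_record].append((pos, end))
            mutated = _mutate(source, spec.divergence, rng)
            s = records[spec.target_record]
            records[spec.target_record] = s[: pos - 1] + mutated + s[end:]
            truth.numt_intervals.setdefault(spec.target_record, []).append((pos, end, spec))
    full = ReferenceGenome(records={config.mito_name: mito, **records}, mito_name=config.mito_name)
    return full, build_nuclear_only(full), truth


def simulate_methylomes(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, str], np.ndarray]:
    """Per-sample window methylation: baseline + planted effects + noise."""
    grid = tile_windows(config.mito_length, config.window_size)
    base = np.full(len(grid), config.baseline_methylation)
    effects = {tis: np.zeros(len(grid)) for tis in config.tissues}
    for dmr in config.dmrs:
        first, last = grid.window_of(dmr.start), grid.window_of(min(dmr.stop, config.mito_length))
        for tis in dmr.tissues:
            if tis in effects:  # planted tissues absent from a restricted design are ignored
                effects[tis][first : last + 1] += dmr.effect
    out = {}
    for ind, tis in config.samples:
        noise = rng.normal(0.0, config.noise_sd, size=len(grid))
        out[(ind, tis)] = np.clip(base + effects[tis] + noise, 0.0, 1.0)
    return out


def _window_weights(methylation: np.ndarray, config: SimulationConfig) -> np.ndarray:
    w = config.base_weight + config.enrichment_slope * methylation
    if (w <= 0).any():
        raise ValueError("enrichment weights must be positive")
    return w


def simulate_fragment_positions(
    methylation: np.ndarray, config: SimulationConfig, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n mitochondrial fragments: (1-based starts, lengths).

    A fragment's midpoint window is drawn with probability proportional to
    window weight x window length, the midpoint uniformly within the window,
    and the length uniformly on the configured range; the start is clipped so
    the fragment lies inside the (linearised) genome.
    """
    grid = tile_windows(config.mito_length, config.window_size)
    weights = _window_weights(methylation, config)
    lens = np.array([grid.window_length(i) for i in range(len(grid))], dtype=float)
    p = weights * lens
    p /= p.sum()
    widx = rng.choice(len(grid), size=n, p=p)
    starts_w = np.array([grid.windows[i][0] for i in range(len(grid))])
    mids = starts_w[widx] + rng.integers(0, lens[widx].astype(int))
    lo, hi = config.fragment_length
    lengths = rng.integers(lo, hi + 1, size=n)
    starts = np.clip(mids - lengths // 2, 1, config.mito_length - lengths + 1)
    return starts.astype(int), lengths.astype(int)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in np.flatnonzero(rng.random(len(arr)) < rate):
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_medip_reads(
    full_ref: ReferenceGenome,
    methylation: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: SimulationTruth | None = None,
    sample_key: str = "sample",
    n_fragments: int | None = None,
) -> tuple[list[ReadPair], dict[str, tuple]]:
    """Generate paired 50 bp reads for one sample, with per-read truth origins.

    ``numt_fraction`` of fragments are drawn uniformly from the planted NUMT
    loci of the nuclear records (requires `truth`); the rest are enriched
    mitochondrial fragments.
    """
    n = config.n_fragments if n_fragments is None else n_fragments
    n_numt = int(round(config.numt_fraction * n)) if truth and truth.numt_intervals else 0
    n_mito = n - n_numt
    mito = full_ref.mito_sequence
    q = 40 if config.error_rate <= 0 else min(40, round(-10 * math.log10(config.error_rate)))
    qual = tuple([q] * config.read_length)

    pairs: list[ReadPair] = []
    origins: dict[str, tuple] = {}
    starts, lengths = simulate_fragment_positions(methylation, config, rng, n_mito)
    for i in range(n_mito):
        s, ln = int(starts[i]), int(lengths[i])
        frag = mito[s - 1 : s - 1 + ln]
        rid = f"{sample_key}:m{i:06d}"
        pairs.append(_fragment_to_pair(rid, frag, config, rng, qual, origin="mito"))
        origins[rid] = ("mito", s)

    if n_numt:
        loci = [
            (record, a, b)
            for record, intervals in truth.numt_intervals.items()
            for a, b, _ in intervals
        ]
        lo, hi = config.fragment_length
        for i in range(n_numt):
            record, a, b = loci[rng.integers(0, len(loci))]
            ln = int(rng.integers(lo, hi + 1))
            seq = full_ref.records[record]
            # fragment overlaps the NUMT: start anywhere that keeps >=50% overlap
            smin = max(1, a - ln // 2)
            smax = min(len(seq) - ln + 1, b - ln // 2)
            s = int(rng.integers(smin, max(smin + 1, smax + 1)))
            frag = seq[s - 1 : s - 1 + ln]
            rid = f"{sample_key}:n{i:06d}"
            pairs.append(_fragment_to_pair(rid, frag, config, rng, qual, origin="numt"))
            origins[rid] = ("numt", record, s)
    return pairs, origins


def _fragment_to_pair(rid, frag, config, rng, qual, origin) -> ReadPair:
    L = config.read_length
    mate1 = _apply_errors(frag[:L], config.error_rate, rng)
    mate2 = _apply_errors(revcomp(frag[-L:]), config.error_rate, rng)
    return ReadPair(rid, mate1, qual, mate2, qual, origin_label=origin)


def simulate_window_counts(
    config: SimulationConfig, rng: np.random.Generator, n_fragments: int | None = None
) -> tuple[dict[tuple[str, str], np.ndarray], dict[tuple[str, str], np.ndarray]]:
    """Fast path: per-sample window counts drawn multinomially from the
    enrichment weights, skipping sequence generation and alignment.

    Returns (counts per sample, true methylation per sample).  This is the
    count distribution that fragment sampling + start-window assignment
    induces up to the ~half-fragment offset between midpoint and start
    windows, and is what the statistical power analyses use.
    """
    n = config.n_fragments if n_fragments is None else n_fragments
    grid = tile_windows(config.mito_length, config.window_size)
    lens = np.array([grid.window_length(i) for i in range(len(grid))], dtype=float)
    meth = simulate_methylomes(config, rng)
    counts = {}
    for key, m in meth.items():
        p = _window_weights(m, config) * lens
        counts[key] = rng.multinomial(n, p / p.sum()).astype(np.int64)
    return counts, meth


def evaluate_triage(
    origins: dict[str, tuple], retained: RetainedReadSet
) -> tuple[float | None, float, dict[str, int]]:
    """Precision and recall of mitochondrial attribution against truth labels.

    precision = retained fragments truly of mitochondrial origin / retained;
    recall = mitochondrial-origin fragments retained / mitochondrial-origin
    fragments.  Precision is None for an empty retained set.
    """
    unknown = set(retained.fragments) - set(origins)
    if unknown:
        raise KeyError(f"retained reads without truth labels: {sorted(unknown)[:3]}")
    n_mito_truth = sum(1 for o in origins.values() if o[0] == "mito")
    tp = sum(1 for rid in retained.fragments if origins[rid][0] == "mito")
    precision = tp / len(retained.fragments) if retained.fragments else None
    recall = tp / n_mito_truth if n_mito_truth else 0.0
    detail = {"tp": tp, "retained": len(retained.fragments), "mito_truth": n_mito_truth}
    return precision, recall, detail


def write_fastq_pair(
    pairs: list[ReadPair], path1: str | Path, path2: str | Path, phred_offset: int = 33
) -> None:
    """Write mates to two gzipped FASTQ files."""
    with gzip.open(str(path1), "wt") as f1, gzip.open(str(path2), "wt") as f2:
        for p in pairs:
            q1 = "".join(chr(q + phred_offset) for q in p.qual1)
            q2 = "".join(chr(q + phred_offset) for q in p.qual2)
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{q2}\n")
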