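"""Window counting, RPKM, coverage filtering and log2 transformation.

Retained mitochondrial fragments are assigned to 100 bp windows by the
leftmost aligned base of the fragment (start assignment), so every fragment
counts exactly once.  RPKM uses the post-triage mitochondrial fragment total
as denominator — after triage the analysis universe is the mitochondrial
genome.  Windows failing the coverage filter (count > min_count required in
every sample by default) are masked as ND ("not determined") and excluded
from all downstream statistics; the filter also guarantees positive RPKM, so
the log2 transform needs no pseudocount.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refgenome import WindowGrid, tile_windows
from .triage import RetainedReadSet

__all__ = [
    "WindowMatrix",
    "count_fragments",
    "rpkm",
    "rpkm_vector",
    "filter_windows",
    "log2_transform",
    "build_window_matrix",
    "window_matrix_from_counts_tsv",
]


def count_fragments(retained: RetainedReadSet, grid: WindowGrid) -> np.ndarray:
    """Per-window fragment counts by start assignment (leftmost aligned base)."""
    counts = np.zeros(len(grid), dtype=np.int64)
    for _, pos, _ in retained.fragments.values():
        counts[grid.window_of(pos)] += 1  # raises if pos outside the genome
    return counts


def rpkm(count: float, window_length_bp: int, total_fragments: int) -> float:
    """Reads per kilobase per million mapped reads for one window."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    if window_length_bp <= 0:
        raise ValueError("window_length_bp must be positive")
    return count / ((window_length_bp / 1000.0) * (total_fragments / 1e6))


def rpkm_vector(counts: np.ndarray, grid: WindowGrid, total_fragments: int | None = None) -> np.ndarray:
    """RPKM across all windows; denominator defaults to the column sum."""
    total = int(counts.sum()) if total_fragments is None else total_fragments
    lengths = np.array([grid.window_length(i) for i in range(len(grid))], dtype=float)
    if total <= 0:
        raise ValueError("cannot compute RPKM with zero total fragments")
    return counts / ((lengths / 1000.0) * (total / 1e6))


def filter_windows(counts: np.ndarray, min_count: int = 10, scope: str = "all") -> np.ndarray:
    """Analyzed mask: window count must be strictly greater than `min_count`.

    scope="all": every sample must pass (the default; makes a single ND flag
    per window well defined).  scope="total": the summed count across samples
    must pass.
    """
    counts = np.atleast_2d(counts)
    if scope == "all":
        return (counts > min_count).all(axis=0)
    if scope == "total":
        return counts.sum(axis=0) > min_count
    raise ValueError(f"unknown filter scope {scope!r}")


def log2_transform(rpkm_matrix: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise log2 on analyzed windows; ND columns are left as NaN."""
    rpkm_matrix = np.atleast_2d(np.asarray(rpkm_matrix, dtype=float))
    out = np.full_like(rpkm_matrix, np.nan)
    analyzed = rpkm_matrix[:, mask]
    if (analyzed <= 0).any():
        raise ValueError("non-positive RPKM in an analyzed window")
    out[:, mask] = np.log2(analyzed)
    return out


@dataclass
class WindowMatrix:
    """Samples x windows matrices of counts, RPKM and log2-RPKM with an ND mask.

    ``samples`` is a list of (individual, tissue) pairs; rows of every matrix
    follow its order.
    """

    samples: list[tuple[str, str]]
    grid: WindowGrid
    counts: np.ndarray
    rpkm: np.ndarray
    log2_rpkm: np.ndarray
    analyzed_mask: np.ndarray
    gene_labels: list[str] | None = None

    def __post_init__(self) -> None:
        n_s, n_w = len(self.samples), len(self.grid)
        for name in ("counts", "rpkm", "log2_rpkm"):
            m = getattr(self, name)
            if m.shape != (n_s, n_w):
                raise ValueError(f"{name} has shape {m.shape}, expected {(n_s, n_w)}")
        if (self.counts < 0).any() or (self.rpkm < 0).any():
            raise ValueError("counts and RPKM must be non-negative")

    @property
    def n_analyzed(self) -> int:
        return int(self.analyzed_mask.sum())

    def sample_index(self, individual: str, tissue: str) -> int:
        return self.samples.index((individual, tissue))

    def values(self, scale: str = "log2") -> np.ndarray:
        return {"log2": self.log2_rpkm, "rpkm": self.rpkm, "counts": self.counts}[scale]

    def to_tsv(self, path: str | Path | None = None, scale: str = "rpkm") -> str:
        """Windows as rows (start, stop, gene, ND flag), samples as columns."""
        df = pd.DataFrame(
            {
                "start": [w[0] for w in self.grid.windows],
                "stop": [w[1] for w in self.grid.windows],
                "gene": self.gene_labels or [""] * len(self.grid),
                "ND": np.where(self.analyzed_mask, "-", "ND"),
            }
        )
        vals = self.values(scale)
        for i, (ind, tis) in enumerate(self.samples):
            df[f"{ind}:{tis}"] = vals[i]
        text = df.to_csv(sep="\t", index=False, float_format="%.6g")
        if path is not None:
            Path(path).write_text(text)
        return text


def build_window_matrix(
    retained_per_sample: dict[tuple[str, str], RetainedReadSet],
    genome_length: int,
    window_size: int = 100,
    min_count: int = 10,
    scope: str = "all",
    gene_labels: list[str] | None = None,
    totals: dict[tuple[str, str], int] | None = None,
) -> WindowMatrix:
    """Assemble the full quantification from per-sample retained read sets.

    `totals` optionally supplies externally derived per-sample denominators;
    by default each sample's own retained fragment total is used.
    """
    grid = tile_windows(genome_length, window_size)
    samples = list(retained_per_sample)
    counts = np.vstack([count_fragments(retained_per_sample[s], grid) for s in samples])
    rpkms = np.vstack(
        [
            rpkm_vector(
                counts[i], grid,
                None if totals is None else totals[samples[i]],
            )
            for i in range(len(samples))
        ]
    )
    mask = filter_windows(counts, min_count=min_count, scope=scope)
    log2 = log2_transform(rpkms, mask)
    return WindowMatrix(
        samples=samples, grid=grid, counts=counts, rpkm=rpkms,
        log2_rpkm=log2, analyzed_mask=mask, gene_labels=gene_labels,
    )


def window_matrix_from_counts_tsv(path: str | Path) -> WindowMatrix:
    """Rebuild a :class:`WindowMatrix` from a counts TSV written by ``to_tsv``.

    The ND column is taken as the analyzed mask; RPKM and log2 values are
    recomputed deterministically from the counts, so a write/read round trip
    reproduces the original matrices exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "ND": str})
    grid = tile_windows(int(df["stop"].iloc[-1]), int(df["stop"].iloc[0] - df["start"].iloc[0] + 1))
    sample_cols = [c for c in df.columns if c not in ("start", "stop", "gene", "ND")]
    samples = [tuple(c.split(":", 1)) for c in sample_cols]
    counts = df[sample_cols].to_numpy(dtype=np.int64).T
    mask = (df["ND"] != "ND").to_numpy()
    rpkms = np.vstack([rpkm_vector(c, grid) for c in counts])
    genes = df["gene"].fillna("").tolist()
    return WindowMatrix(
        samples=samples, grid=grid, counts=counts, rpkm=rpkms,
        log2_rpkm=log2_transform(rpkms, mask), analyzed_mask=mask,
        gene_labels=genes if any(genes) else None,
    )
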