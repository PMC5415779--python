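"""Packaged results-table transcriptions and the reproduction report.

Two TSVs under ``mitodip/data`` transcribe the study's printed per-window
results on the 166-window grid (nominal bounds 1..16600):

* ``table2.tsv`` — five-region analysis: per window, paired-t p-value and
  delta-RPKM (cortex minus cerebellum) for each of BA8/BA9/BA10/ECX/STG vs
  cerebellum.  ``-`` marks a not-significant cell (only p < 0.05 values are
  printed), ``ND`` a window excluded by the NUMT-control pipeline.  The
  ``bold`` flag marks windows printed as conserved across the prefrontal
  areas.
* ``table3.tsv`` — total-cortex vs cerebellum mixed-model p-values, same
  conventions; ``bold`` marks Bonferroni-significant windows.

The ND patterns of the two tables agree except at two windows (3101-3200 and
4101-4200, analyzed only in the total-cortex table); ``load_fixture_tables``
validates shape and reports the difference rather than failing.  The printed
family-wise threshold is alpha divided by the five-region table's analyzed
(non-ND) window count, which is what :func:`reproduce_study_counts` recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dmr_stats import (
    bonferroni_threshold,
    conserved_windows,
    count_nominal,
    longest_adjacent_run,
)
from .refgenome import MitoAnnotation

__all__ = ["FixtureTables", "load_fixture_tables", "reproduce_study_counts", "load_mito_annotation"]

FIVE_REGION_COMPARISONS = ["BA8", "BA9", "BA10", "ECX", "STG"]

N_GRID_WINDOWS = 166


def _data_path(name: str) -> Path:
    return Path(resources.files("mitodip.data") / name)


@dataclass
class FixtureTables:
    """Tidy transcriptions of the two results tables.

    ``five_region`` and ``total_cortex`` share the columns
    (start, stop, gene, comparison, p, delta, analyzed); delta is NaN where
    the printed table carries none.
    """

    five_region: pd.DataFrame
    total_cortex: pd.DataFrame
    bold_five_region: set[int]
    bold_total_cortex: set[int]
    nd_mismatch_windows: list[int] = field(default_factory=list)

    @property
    def n_analyzed_five_region(self) -> int:
        per_window = self.five_region.groupby("start")["analyzed"].first()
        return int(per_window.sum())

    @property
    def n_analyzed_total_cortex(self) -> int:
        return int(self.total_cortex["analyzed"].sum())


def _parse_cell(value: str) -> float:
    return np.nan if value in ("-", "ND") else float(value)


def load_fixture_tables() -> FixtureTables:
    """Load and validate the packaged table transcriptions."""
    t2 = pd.read_csv(_data_path("table2.tsv"), sep="\t", dtype=str)
    t3 = pd.read_csv(_data_path("table3.tsv"), sep="\t", dtype=str)
    for name, df in (("table2", t2), ("table3", t3)):
        if len(df) != N_GRID_WINDOWS:
            raise ValueError(f"{name} has {len(df)} rows, expected {N_GRID_WINDOWS}")
    starts2 = t2["start"].astype(int)
    if not (starts2 == np.arange(1, 16600, 100)).all():
        raise ValueError("table2 window starts are not the 166-window grid")
    if not (t2["stop"].astype(int) == starts2 + 99).all():
        raise ValueError("table2 stops are not nominal 100 bp bounds")
    if (t2["start"] != t3["start"]).any() or (t2["gene"] != t3["gene"]).any():
        raise ValueError("table2/table3 window or gene columns disagree")

    rows = []
    for _, r in t2.iterrows():
        start, stop, gene = int(r["start"]), int(r["stop"]), r["gene"]
        for comp in FIVE_REGION_COMPARISONS:
            p_raw, d_raw = r[f"{comp}_p"], r[f"{comp}_delta"]
            analyzed = p_raw != "ND"
            p, delta = _parse_cell(p_raw), _parse_cell(d_raw)
            if np.isfinite(p) and not (0 < p < 0.05):
                raise ValueError(f"table2 printed p outside (0, 0.05) at {start} {comp}: {p}")
            rows.append((start, stop, gene, comp, p, delta, analyzed))
    five = pd.DataFrame(
        rows, columns=["start", "stop", "gene", "comparison", "p", "delta", "analyzed"]
    )

    rows = []
    for _, r in t3.iterrows():
        start, stop, gene = int(r["start"]), int(r["stop"]), r["gene"]
        analyzed = r["p"] != "ND"
        p = _parse_cell(r["p"])
        if np.isfinite(p) and not (0 < p < 0.05):
            raise ValueError(f"table3 printed p outside (0, 0.05) at {start}: {p}")
        rows.append((start, stop, gene, "CTX", p, np.nan, analyzed))
    total = pd.DataFrame(
        rows, columns=["start", "stop", "gene", "comparison", "p", "delta", "analyzed"]
    )

    nd2 = set(five.loc[~five["analyzed"], "start"])
    nd3 = set(total.loc[~total["analyzed"], "start"])
    mismatch = sorted(nd2 ^ nd3)
    return FixtureTables(
        five_region=five,
        total_cortex=total,
        bold_five_region=set(t2.loc[t2["bold"] == "1", "start"].astype(int)),
        bold_total_cortex=set(t3.loc[t3["bold"] == "1", "start"].astype(int)),
        nd_mismatch_windows=mismatch,
    )


def load_mito_annotation() -> MitoAnnotation:
    """Packaged rCRS mitochondrial gene annotation (37 genes, 1-based inclusive)."""
    return MitoAnnotation.from_tsv(_data_path("mito_genes.tsv"))


def reproduce_study_counts(fx: FixtureTables, alpha: float = 0.05) -> dict[str, float]:
    """Recompute every printed results count from the packaged tables.

    Nothing here is hard-coded: counts, conserved-window directions, adjacent
    runs and the family-wise threshold are all derived from the transcribed
    per-window values.
    """
    prefrontal = ["BA8", "BA9", "BA10"]
    conserved = conserved_windows(fx.five_region, prefrontal, alpha=alpha)
    directions = conserved["direction"].value_counts()
    n_analyzed = fx.n_analyzed_five_region
    threshold = bonferroni_threshold(n_analyzed, alpha=alpha)
    t3 = fx.total_cortex
    bonf = t3[t3["analyzed"] & (t3["p"] < threshold)]
    report = {
        "five_region_nominal_entries": count_nominal(fx.five_region, alpha, "entries"),
        "five_region_nominal_windows": count_nominal(fx.five_region, alpha, "windows"),
        "conserved_prefrontal_windows": len(conserved),
        "conserved_hypomethylated": int(directions.get("hypo", 0)),
        "conserved_hypermethylated": int(directions.get("hyper", 0)),
        "conserved_longest_adjacent_run": longest_adjacent_run(conserved.index),
        "total_cortex_nominal_windows": count_nominal(t3, alpha, "windows"),
        "analyzed_windows": n_analyzed,
        "bonferroni_threshold": threshold,
        "bonferroni_significant_windows": len(bonf),
        "bonferroni_longest_adjacent_run": longest_adjacent_run(bonf["start"]),
    }
    return report


def report_to_markdown(report: dict[str, float]) -> str:
    lines = [
        "# Window-level results reproduced from the packaged tables",
        "",
        "| quantity | value |",
        "| --- | --- |",
    ]
    for key, val in report.items():
        shown = f"{val:.3g}" if isinstance(val, float) and not float(val).is_integer() else val
        lines.append(f"| {key} | {shown} |")
    return "\n".join(lines) + "\n"


def report_to_tsv(report: dict[str, float]) -> str:
    lines = ["quantity\tvalue"]
    for key, val in report.items():
        lines.append(f"{key}\t{val}")
    return "\n".join(lines) + "\n"
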