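"""End-to-end validation scenarios run on synthetic data.

Each function builds its own inputs (via :mod:`mitodip.simulate` or the
packaged tables), runs the relevant pipeline stage, and returns measured
quantities.  They back both the test suite and the repository's
reproduction script, so the same computation is exercised in both places.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .dmr_stats import mixed_model_window, paired_t_window
from .quantify import build_window_matrix, filter_windows, log2_transform, rpkm_vector
from .refgenome import tile_windows
from .simulate import (
    SimulationConfig,
    evaluate_triage,
    simulate_medip_reads,
    simulate_methylomes,
    simulate_reference,
    simulate_window_counts,
)
from .structure import ProfileSet, cluster_profiles
from .triage import run_triage

__all__ = [
    "triage_soundness",
    "paired_t_parity",
    "mixed_model_type_i_error",
    "dmr_power_analysis",
    "clustering_recovery",
]


def triage_soundness(seed: int = 1, n_pairs: int = 10_000) -> dict:
    """Default-condition triage: one identical and one 10%-diverged NUMT,
    `n_pairs` read pairs, measured against per-read truth labels.

    Returns precision/recall of mitochondrial attribution, the per-pass
    counts, and whether every window of the identical-NUMT homology interval
    ends up ND under the default coverage filter.
    """
    cfg = replace(SimulationConfig(), n_fragments=n_pairs)
    rng = np.random.default_rng(seed)
    full, nuclear, truth = simulate_reference(cfg, rng)
    meth = simulate_methylomes(cfg, rng)
    pairs, origins = simulate_medip_reads(
        full, meth[("ind1", "BA8")], cfg, rng, truth=truth, sample_key="s"
    )
    retained, report = run_triage(pairs, full, nuclear)
    precision, recall, detail = evaluate_triage(origins, retained)
    wm = build_window_matrix({("ind1", "BA8"): retained}, cfg.mito_length)
    homology = sorted(truth.confusable_windows(read_length=cfg.read_length))
    nd_homology = [not wm.analyzed_mask[w] for w in homology]
    return {
        "precision": precision,
        "recall": recall,
        "pass_counts": (
            report.n_input,
            report.n_pass1_mito_unique,
            report.n_pass2_nuclear_unmapped,
            report.n_pass3_confirmed,
        ),
        "homology_windows": homology,
        "homology_windows_all_nd": all(nd_homology),
        "n_homology_nd": sum(nd_homology),
        "detail": detail,
    }


def paired_t_parity(seed: int = 1, n_instances: int = 1000) -> float:
    """Worst absolute disagreement between the paired-t engine and the
    textbook closed form over random instances."""
    from scipy import special

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(3, 12))
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0.2, 0.7, n)
        res = paired_t_window(x, y)
        d = x - y
        t = d.mean() / np.sqrt(d.var(ddof=1) / n)
        p_ref = float(special.betainc((n - 1) / 2.0, 0.5, (n - 1) / ((n - 1) + t * t)))
        worst = max(worst, abs(res.p - p_ref))
    return worst


def mixed_model_type_i_error(seed: int = 1, n_perms: int = 1000) -> float:
    """Permutation-null rejection rate of the mixed-model tissue test.

    One dataset with individual effects but no tissue effect; tissue labels
    are re-permuted within each individual (preserving the 5 cortex /
    1 cerebellum design) for every replicate.
    """
    rng = np.random.default_rng(seed)
    regions = ["BA8", "BA9", "BA10", "ECX", "STG", "CER"]
    inds = ["i1", "i2", "i3"]
    base = pd.DataFrame(
        [(i, r) for i in inds for r in regions], columns=["individual", "region"]
    )
    ind_eff = dict(zip(inds, rng.normal(0, 1, len(inds))))
    base["value"] = [ind_eff[i] for i in base["individual"]] + rng.normal(0, 0.5, len(base))
    labels = np.array(["cortex"] * 5 + ["cerebellum"])
    hits = 0
    for _ in range(n_perms):
        df = base.copy()
        df["tissue"] = np.concatenate([rng.permutation(labels) for _ in inds])
        res = mixed_model_window(df)
        if res.p is not None and res.p < 0.05:
            hits += 1
    return hits / n_perms


def dmr_power_analysis(
    seeds=range(1, 101), n_fragments: int = 50_000
) -> dict:
    """Window-level detection of planted DMRs by the paired t test.

    Per replicate seed: simulate window counts for 3 individuals x
    (cortex region, cerebellum) at the default enrichment, quantify, and test
    each analyzed window.  Power is reported for the +0.3 planted effect
    (and separately for the smaller -0.2 effect); the false-positive rate
    pools all non-DMR analyzed windows.
    """
    cfg = replace(
        SimulationConfig(), tissues=("BA8", "CER"), missing=frozenset(),
        n_fragments=n_fragments,
    )
    grid = tile_windows(cfg.mito_length, cfg.window_size)
    dmr_windows: dict[int, float] = {}
    for dmr in cfg.dmrs:
        for w in range(grid.window_of(dmr.start), grid.window_of(min(dmr.stop, cfg.mito_length)) + 1):
            dmr_windows[w] = dmr.effect
    tallies = {"hyper": [0, 0], "hypo": [0, 0], "null": [0, 0]}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        counts, _ = simulate_window_counts(cfg, rng)
        C = np.vstack(
            [counts[(ind, tis)] for ind in cfg.individuals for tis in ("BA8", "CER")]
        )
        mask = filter_windows(C, 10)
        L = log2_transform(np.vstack([rpkm_vector(c, grid) for c in C]), mask)
        x, y = L[0::2], L[1::2]
        for w in np.flatnonzero(mask):
            res = paired_t_window(x[:, w], y[:, w])
            if res.p is None:
                continue
            effect = dmr_windows.get(w, 0.0)
            group = "hyper" if effect > 0 else "hypo" if effect < 0 else "null"
            tallies[group][0] += res.p < 0.05
            tallies[group][1] += 1
    return {
        "power_effect_plus": tallies["hyper"][0] / tallies["hyper"][1],
        "power_effect_minus": tallies["hypo"][0] / tallies["hypo"][1],
        "false_positive_rate": tallies["null"][0] / tallies["null"][1],
        "n_null_tests": tallies["null"][1],
        "n_replicates": len(list(seeds)),
    }


def clustering_recovery(seed: int = 1, n_fragments: int = 50_000) -> dict:
    """Cluster per-sample RPKM profiles with planted tissue-specific DMRs and
    check that cutting at k=3 recovers the three tissues exactly."""
    from .simulate import DmrSpec

    cfg = replace(
        SimulationConfig(),
        tissues=("BA8", "CER", "BLD"), missing=frozenset(), n_fragments=n_fragments,
        dmrs=(
            DmrSpec(16101, 16500, ("BA8",), +0.3),
            DmrSpec(10301, 10600, ("BLD",), +0.3),
            DmrSpec(13301, 13700, ("CER",), +0.3),
        ),
    )
    rng = np.random.default_rng(seed)
    counts, _ = simulate_window_counts(cfg, rng)
    grid = tile_windows(cfg.mito_length, cfg.window_size)
    keys = list(counts)
    C = np.vstack([counts[k] for k in keys])
    mask = filter_windows(C, 10)
    profiles = ProfileSet(
        labels=[f"{ind}:{tis}" for ind, tis in keys],
        matrix=np.vstack([rpkm_vector(c, grid) for c in C])[:, mask],
    )
    flat = cluster_profiles(profiles).flat_clusters(3)
    by_tissue: dict[str, set[int]] = {}
    for (ind, tis), cluster in zip(keys, flat.values()):
        by_tissue.setdefault(tis, set()).add(cluster)
    pure = all(len(v) == 1 for v in by_tissue.values())
    distinct = len({next(iter(v)) for v in by_tissue.values()}) == len(by_tissue)
    return {"exact_recovery": pure and distinct, "clusters_by_tissue": by_tissue}
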