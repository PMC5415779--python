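"""Quantify windows and test planted DMRs with the paired t engine.

Window counts are simulated directly from the MeDIP enrichment model for
3 matched individuals (one cortical region vs cerebellum), converted to
RPKM, coverage-filtered (count > 10 in every sample), log2-transformed and
tested per window.  The default config plants a +0.3 methylation effect in
the D-Loop (windows 16101-16500) and a -0.2 effect at 10301-10600.
"""

from dataclasses import replace

import numpy as np

from mitodip.dmr_stats import bonferroni_threshold, count_nominal, paired_t_window
from mitodip.quantify import filter_windows, log2_transform, rpkm_vector
from mitodip.refgenome import tile_windows
from mitodip.simulate import SimulationConfig, simulate_window_counts

cfg = replace(SimulationConfig(), tissues=("BA8", "CER"), missing=frozenset(),
              n_fragments=50_000)
rng = np.random.default_rng(1)
counts, _ = simulate_window_counts(cfg, rng)
grid = tile_windows(cfg.mito_length, cfg.window_size)

C = np.vstack([counts[(ind, tis)] for ind in cfg.individuals for tis in ("BA8", "CER")])
mask = filter_windows(C, min_count=10)
L = log2_transform(np.vstack([rpkm_vector(c, grid) for c in C]), mask)

hits = []
for w in np.flatnonzero(mask):
    res = paired_t_window(L[0::2, w], L[1::2, w])
    if res.p is not None and res.p < 0.05:
        hits.append((grid.nominal_bounds(w), res.p, res.delta))

print(f"analyzed windows: {int(mask.sum())}/166, "
      f"Bonferroni threshold {bonferroni_threshold(int(mask.sum())):.2E}")
print(f"nominally significant windows (p < 0.05): {len(hits)}")
for (start, stop), p, delta in hits:
    tag = "planted" if 16101 <= start <= 16401 or 10301 <= start <= 10501 else "noise"
    print(f"  {start:>5}-{stop:<5}  p={p:.3g}  delta(log2)={delta:+.2f}  [{tag}]")
print("Planted windows surface with the planted sign; the remainder are the")
print("expected ~5% false positives of a nominal threshold.")
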