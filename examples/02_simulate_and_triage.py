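"""Simulate MeDIP-seq reads with planted NUMTs and run the three-pass triage.

The synthetic reference carries one NUMT identical to its mitochondrial
source and one diverged by 10%.  Reads from the identical copy cannot be
attributed to either genome and must be discarded; the per-read truth labels
let us score the triage.
"""

import numpy as np

from mitodip import run_triage
from mitodip.simulate import (SimulationConfig, evaluate_triage, simulate_medip_reads,
                              simulate_methylomes, simulate_reference)

cfg = SimulationConfig()  # rCRS-length mitochondrion, 2 kb identical + 1 kb 10%-diverged NUMT
rng = np.random.default_rng(1)
full, nuclear, truth = simulate_reference(cfg, rng)
meth = simulate_methylomes(cfg, rng)
pairs, origins = simulate_medip_reads(full, meth[("ind1", "BA8")], cfg, rng,
                                      truth=truth, sample_key="demo", n_fragments=5000)

retained, report = run_triage(pairs, full, nuclear)
precision, recall, detail = evaluate_triage(origins, retained)

print(report.to_tsv())
print(f"precision of mitochondrial attribution: {precision:.4f}")
print(f"recall of true mitochondrial fragments: {recall:.4f}")
print("Reads lost to the identical NUMT are the price of certainty: every")
print("retained fragment is uniquely attributable to the mitochondrial genome,")
print("so windows inside the homology interval go ND instead of being wrong.")
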