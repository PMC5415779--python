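# Methods

`mitodip` quantifies mitochondrial DNA (mtDNA) methylation from MeDIP-seq
data while controlling for nuclear-mitochondrial pseudogenes (NUMTs) —
nuclear loci so similar to stretches of the mitochondrial genome that reads
from one are routinely mis-assigned to the other. This note describes the
models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic-data validation does and
does not establish.

## The triage model

A read is worth counting only if it can be attributed to the mitochondrial
genome with confidence. The triage formalises this as three alignment
passes over two references:

1. **Full reference** (nuclear genome + mitochondrial record): keep reads
   uniquely mapped to the mitochondrial record. A read whose sequence also
   occurs at a NUMT produces co-optimal placements, is flagged non-unique,
   and is dropped here.
2. **Nuclear-only reference** (the same genome with the mitochondrial
   record removed): re-align the survivors and keep only reads that find
   *no* placement. This catches reads whose nuclear paralogue is diverged —
   they map uniquely to chrM in pass 1, but still have a plausible nuclear
   home and cannot be trusted.
3. **Full reference again**: confirm the survivors are still uniquely
   mitochondrial; final positions are taken from this pass. With the
   built-in deterministic aligner this pass cannot contradict pass 1, but it
   is kept as an independent pass because with an external aligner the runs
   may use different settings, and the confirmation is cheap.

The pass logic consumes only `(mapped, unique, target, position)` per mate,
so the built-in aligner and SAM/BAM input from any external aligner are
interchangeable. "Unique" means: primary alignment, no co-optimal (or
recorded secondary/supplementary) placement, mapping quality ≥ 1. Both
mates must survive every pass for the fragment to be retained; this is the
conservative default and a single-mate mode exists. The procedure trades
recall for precision by construction: reads from an identical NUMT interval
are unattributable in principle, and the windows they would have covered are
reported ND (not determined) rather than wrong.

The built-in aligner is seed-and-extend (15-mer exact seeds at three read
offsets, ungapped extension, ≤ 5 mismatches per 50 bp read, no indels),
deterministic, and intended for synthetic genomes at desk scale; real data
should arrive as SAM/BAM from BWA or minimap2.

## Quantification

Retained fragments are assigned to non-overlapping 100 bp windows by the
leftmost aligned base of the pair, so each fragment counts exactly once and
column sums equal fragment totals. RPKM uses the per-sample post-triage
mitochondrial fragment total as denominator: after triage the analysis
universe *is* the mitochondrial genome. An externally supplied denominator
is accepted for users who prefer genome-wide totals. A window is analyzed
only if its count is strictly greater than 10 in **every** sample (the
all-samples scope makes a single ND flag per window well defined; a
summed-count scope is available). Analyzed RPKM values are log2-transformed
with no pseudocount — the coverage filter guarantees positivity.

Window coordinates are 1-based inclusive. The mitochondrial genome is
16,569 bp, giving 166 windows with the last truncated at 16,569; window
*labels* use the nominal bounds (…, 16501–16600), matching the convention of
the packaged results tables. Circularity is recorded on the reference but
alignment and windowing treat the sequence as linear by default.

## Per-window statistics

**Paired t.** Each cortical region is compared with cerebellum across
matched individuals by a two-tailed paired t test on log2 RPKM. Δ is
cortex − cerebellum (negative = hypomethylated relative to cerebellum),
reported on raw RPKM by default. Zero-variance differences return a
distinct status code, not a fabricated p-value.

**Mixed model.** Total cortex vs cerebellum uses a multilevel model,
`value ~ tissue` with a random intercept per individual, fitted by ML and
tested by likelihood-ratio model comparison against the null without the
tissue term. At the design sizes this package targets (three individuals,
eighteen observations) the asymptotic χ²(1) reference is measurably
anticonservative: label-permutation experiments put its rejection rate near
0.065–0.07 at nominal 0.05. The default therefore refers the signed root of
the LRT statistic to a Student-t distribution with containment degrees of
freedom, `N − #groups − #non-intercept fixed effects` (ν = 14 for the 3 × 6
design), which permutation shows to be calibrated (0.046/0.052 at two
seeds, 1000 permutations). The asymptotic reference remains available as
`method="lrt_chi2"`, and a Wald test as `method="wald"`. A "as-published"
mode with individual as the fixed effect and brain region as the grouping
factor is preserved for comparison; as written it contains no tissue term,
so the package tests it by adding tissue to that model — only the default
parameterisation directly contrasts cortex and cerebellum, which is why it
is the default.

**Multiple testing.** The Bonferroni threshold is α divided by the number
of analyzed (non-ND) windows, not by 166. With the ND pattern of the
packaged five-region table (71 analyzed windows) this recovers the printed
threshold 7.04E−04.

**Counting.** Nominal results can be counted as table entries
(window × comparison pairs — how a multi-column results table tallies its
printed values) or as distinct windows; conserved windows are those
significant in every comparison of a subset, with a hyper/hypo/mixed
direction summary from the Δ signs; adjacent runs are maximal runs of
consecutive grid windows. Direction concordance between two comparisons is
the percentage of sign agreement over windows with nonzero Δ in both.

## Tissue-level structure

Average (or per-sample) RPKM profiles over analyzed windows are clustered
agglomeratively on Euclidean distance with complete linkage (the classic
`hclust` default); dendrograms export as Newick, with labels quoted when
they carry metacharacters. Pearson correlation matrices reject
zero-variance profiles. The corrgram-style ordering sorts samples by the
angle `atan2(PC2, PC1)` of the correlation matrix's first two eigenvectors,
with each eigenvector's sign fixed so its largest-magnitude loading is
positive — stated explicitly so orderings reproduce across platforms.

## The packaged results tables

Two TSVs transcribe the profiled study's per-window results (five-region
paired-t table and total-cortex mixed-model table) on the 166-window grid,
including ND flags and bold-face annotations. Every headline count is
recomputed from these values by the counting operations; nothing is
hard-coded. Two transcription quirks are preserved as printed and handled
explicitly: the two tables' ND patterns differ at windows 3101–3200 and
4101–4200 (analyzed only in the total-cortex table — the Bonferroni n is
taken from the five-region table, which is what reproduces the printed
threshold), and one five-region row (12301–12400) prints a Δ with no
p-value, which counts as not significant. The packaged gene annotation uses
standard rCRS coordinates; it reproduces the printed per-window gene labels
at 162/166 windows, and the four divergences (a shifted label pair around
MT-TR, an abbreviated tRNA name, one omitted tRNA) are pinned in the tests
as properties of the printed table rather than silently adopted.

## The simulator

The generator emulates the study conditions end to end: an rCRS-length
random mitochondrial genome; a 40 kb nuclear decoy carrying one NUMT
identical to its 2 kb mitochondrial source and one 1 kb copy at 10 %
divergence (substitutions only, matching the ungapped aligner — a
documented limitation); seven tissues (five cortical regions, cerebellum,
blood) × three individuals with one missing blood sample; fragments of
220–320 bp sequenced as 50 bp paired ends with i.i.d. substitution errors
at rate 0.002.

Methylation truth is per window and per sample: baseline 0.3 + planted
tissue effects + Gaussian sample-level noise (sd 0.05), clipped to [0, 1].
The defaults plant a +0.3 cortical effect in the D-Loop block (16101–16500)
and a −0.2 effect at 10301–10600, mirroring the hyper/hypo mixture and the
D-Loop location of the study's conserved windows. Baseline, noise and
enrichment (weight = 0.1 + 1.0 × methylation) were chosen once as
plausible MeDIP behaviour — enrichment roughly proportional to methylation
with a small unmethylated background pulldown — and are documented here
rather than revisited. Enrichment acts at fragment level through the
midpoint window, keeping truth aligned to the analysis grid; 10 % of
fragments originate from the NUMT loci to exercise the triage. A fast path
draws window counts multinomially from the same enrichment weights,
skipping sequence generation; the statistical power analyses use it so that
one hundred replicates of 3 × 2 × 50,000 fragments run in seconds.

What the simulator does **not** model: CpG-density-dependent capture
efficiency, PCR duplicates, indels, realistic base-quality profiles, copy
number variation, or the compositional magnitude of real RPKM values.
Passing tests therefore establish that the pipeline's logic and statistics
behave as designed under a faithful abstraction of the study design — not
that real-data RPKM magnitudes or the study's correlation coefficients are
reproduced, which requires the raw sequencing data.

## Validation scale and numerical choices

The repository's tests and reproduction script use: 10,000 read pairs for
triage soundness (precision ≥ 0.99 against truth labels); 1,000 random
instances for paired-t parity with a closed-form oracle (agreement to
1e−10); 1,000 within-individual label permutations for mixed-model
calibration; 100 replicate seeds × 50,000 fragments/sample for DMR power
(≥ 0.8 at the +0.3 effect) and pooled false-positive rate; and a 3-tissue ×
3-individual design for exact clustering recovery at k = 3. These sizes
were chosen so the full suite completes in about a minute on one CPU while
leaving the binomial error of each estimate well inside its acceptance
band. Ties in alignment score are reported at the leftmost placement but
always flagged non-unique; degenerate statistical inputs (zero variance,
singular mixed fits) return status codes instead of numbers.
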