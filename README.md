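# pansv

Population-scale structural-variant (SV) analysis for pan-genome call
sets: multi-caller consensus merging, breakpoint mechanism
classification, SV population genetics, a composite selection scan,
windowed ABBA-BABA introgression statistics, and permutation region
enrichment — with a synthetic cohort generator that plants ground truth
for every stage.

## The problem

Pan-genome studies in livestock genotype SVs (variants ≥ 50 bp) across
hundreds of resequenced individuals.  The surrounding questions are
always the same: which multi-caller short-read calls are real and where
are their true breakpoints; what mutational mechanism formed each SV;
how do SV frequencies differ between strains; which SVs are tagged by
nearby SNPs and which carry independent information; which genomic
windows show selection between phenotype-contrasted groups; did a
haplotype introgress from one population into another; and are SVs
over-represented in particular regulatory annotation classes.
`pansv` implements these stages as a reusable, tested library for
anyone analysing SV call sets and cohort genotype matrices — the
built-in simulator replaces the sequencing data, so every claim the
package makes is verified against planted truth.

## The methods in brief

* **Consensus merge** — size filter (50 bp–100 kb), breakpoint
  recurrence ≥ 3 at 50-bp clustering distance, type-aware
  single-linkage clustering, representative = the most frequently
  reported exact coordinates.
* **Mechanism classes** — VNTR (tandem/low-complexity coverage ≥ 30%),
  NAHR (junction homology ≥ 200 bp for SVs ≥ 1 kb, ≥ 20 bp below),
  STEI/MTEI (TE-library coverage > 30%, one vs several families), NHR
  (no signature), with fractional tandem copy numbers (span/unit).
* **Population statistics** — QC (call rate > 0.3, MAC > 3), frequency
  classes (rare ≤ 0.01 < low ≤ 0.05 < common ≤ 0.3 < high), deltaAF,
  LD tagging (r² ≥ 0.2; molQTL link at r² ≥ 0.6), IBS distances
  (MAF ≥ 0.05), nIBD = cIBD/tIBD, windowed π, Fisher-exact case-control
  association with Bonferroni correction.
* **Selection scan** — Weir–Cockerham F_ST and XP-EHH in 30-kb/10-kb
  sliding windows, each rank-normalized to R ∈ [0, 1], scaled to
  S = R/(1.001 − R), averaged (XP-CLR scores importable), top 0.1%
  called.
* **Introgression** — ABBA-BABA D and the dynamic-donor fdM under
  (((P1,P2),P3),O), plus two-sided Wilcoxon contrasts of window fdM
  distributions.
* **Enrichment** — observed vs 100 random per-chromosome re-placements
  of the SV set; Z-scores and add-one empirical p-values.

Formulas, thresholds, and the reasoning behind every default are in
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic cohort (two 2-Mb chromosomes, 200 planted SVs, five strains ×
20 samples) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py 1   # seed 1
python analysis/02_consensus_merge.py
python analysis/03_mechanisms.py
python analysis/04_popgen_stats.py
python analysis/05_selection_scan.py
python analysis/06_introgression.py
python analysis/07_enrichment.py
```

Output of the run above, abridged:

```
cohort seed=1: 200 planted SVs ({'NHR': 40, 'STEI': 40, 'MTEI': 40,
  'NAHR': 40, 'VNTR': 40}), 4200 variants x 100 samples, 8220 raw calls
  in 60 call sets, causal SV truth_126
merged 8220 raw calls from 60 call sets into 200 consensus SVs;
  200/200 planted SVs recovered within 50 bp (100.0%)
label accuracy vs planted truth: 100.0% on 200 matched SVs
QC: kept 4115/4200 variants (85 removed)
LD tagging: 63/198 SVs tagged by a nearby SNP (r^2 >= 0.2); 135 independent
nIBD within the swept strain over ('chr1', 400000, 430000): 1.00
association: top hit truth_126 at chr1:105177 (p_bonf=1.05e-19)
scanned 400 windows; top 0.1% -> 1 selected
  selected chr1:400000-430000 fst=0.616 composite=642.2
planted sweep window chr1:400000-430000 recovered
fdM of the planted window chr1:700000-730000: 0.976 (D = 0.198,
  38 informative sites)
planted_svs  enhancer  observed=100  perm_mean=12.72  Z=26.8  p=0.0099 **
```

Reading this: the consensus merge reconstructed every planted SV from
8220 jittered, incomplete per-tool calls; the mechanism rules recovered
all 200 planted labels; the causal SV is the top association hit; the
single top-0.1% composite window is exactly the planted sweep; the
planted introgressed window shows fdM ≈ 1 (donor haplotypes fully
shared); and the annotation class planted at 10× enrichment stands at
Z ≈ 27 while the null classes stay near zero.

The same stages are exposed as a CLI (`pansv simulate | merge |
mechanism | popgen | scan | abba | enrich | run-all`) for use on real
call sets and genotype VCFs.

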