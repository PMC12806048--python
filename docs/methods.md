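# Methods

`pansv` implements the bespoke computational stages of a pan-genome
structural-variant (SV) population study in chickens: consensus merging
of multi-caller short-read SV calls, breakpoint-signature mechanism
classification, genotype-matrix population statistics, a composite
rank-based selection scan, windowed ABBA-BABA introgression statistics,
and permutation-based region enrichment.  Every stage is exercised
against a synthetic cohort generator that plants known ground truth, so
the pipeline is testable without multi-gigabase sequencing data.

## Consensus merging of multi-caller call sets

Raw calls carry `(chrom, start, end, svtype, length, sample, tool)` in
0-based half-open coordinates.  The merge is:

1. **Size filter** — keep calls with 50 bp ≤ length ≤ 100 kb.
2. **Recurrence filter** — keep breakpoints observed ≥ 3 times across
   all (sample, tool) call sets.  Recurrence is counted on clusters at
   the 50-bp merge distance because exact-coordinate recurrence is
   vacuous under breakpoint jitter; an `exact` mode is available.
3. **Clustering** — single linkage: two calls join when they share
   chromosome and type and both breakpoints lie within 50 bp.  Single
   linkage matches the chaining behaviour of interval-intersection
   clustering.
4. **Representative selection** — the exact `(start, end)` pair observed
   most often in the cluster; ties break to the pair seen by more
   distinct tools, then to the smaller start.  Deletion sequence comes
   from the reference span; insertion sequence from a sequence-reporting
   member, preferring one at the representative coordinates.

The output is deterministic, invariant to input order, idempotent under
re-merging, and every representative coordinate is an actual input
coordinate.

## Mechanism classification

Each sequence-resolved SV is assigned one of five formation-mechanism
classes from breakpoint signatures, evaluated in a fixed precedence
order (configurable; VNTR → NAHR → TEI → NHR by default):

1. **VNTR** — tandem arrays plus low-complexity runs cover ≥ 30% of the
   SV sequence.
2. **NAHR** — the two breakpoint-junction regions share a local
   alignment block (identity ≥ 90%) at least as long as the size-class
   cutoff: ≥ 200 bp for SVs ≥ 1 kb (junction 1 kb, flank 1 kb), ≥ 20 bp
   for SVs < 1 kb (junction 50 bp, flank 200 bp).  SVs of exactly 1 kb
   use the large-SV parameter set.
3. **STEI / MTEI** — alignments to the TE consensus library cover
   > 30% of the SV sequence; single contributing family → STEI,
   several → MTEI (a family counts when it covers ≥ 50 bp).
4. **NHR** — none of the above signatures; SVs without a resolvable
   sequence are reported `UNRESOLVED`, never NHR.

Evidence for all rules is always computed and reported, so calls are
auditable and class counts always sum to the input count.

**Tandem detection.** For each candidate unit length *u* (1–2000 bp)
the sequence is compared with itself shifted by *u*; a maximal run of
*L* matches implies a tandem span *L + u* with fractional copy number
(*L + u*)/*u* (a 430-bp unit with 6 full copies and a 340-bp partial
copy spans 2920 bp = 6.79 copies).  Overlaps across unit lengths
resolve longest-span-first with smaller units preferred on ties, so a
pure array reports its fundamental period.  Only exact copies extend a
run; the estimator targets recent, low-divergence arrays, which is what
SV-length alleles carry.  On 500-bp i.i.d. sequence the detected
coverage stays below the 30% rule threshold across 100 seeds.

**TE coverage.** Exact 15-mer seeds shared with a consensus mark
covered positions; the union over families gives the coverage fraction.
Exact 15-mer seeding requires local identity well above 80% and is
calibrated for recent TE copies; seed length is configurable.

**Junction homology.** Local alignment (match +1, mismatch −1, gap
open −2, extend −1) via Biopython's pairwise aligner; the reported
homology length is the aligned span when column identity ≥ 90%, else 0.
For insertions the junction part of each region comes from the inserted
sequence, and the junction extent is capped at half the SV length so
the two regions never share sequence by construction.  The aligner is
verified against a plain dynamic-programming Smith–Waterman oracle in
the tests.

Alignment identity thresholds (80% TE-equivalent seeding, 90%
homology) separate planted signal from i.i.d. background at the tested
lengths; both are configurable.

## Population-genetic statistics

* **QC** — keep variants with call rate > 0.3 and minor allele count
  > 3 (both strict), with a reasoned removal report.
* **Frequencies** — per-group alternate-allele frequencies from called
  alleles; overall classes rare (≤ 0.01), low (≤ 0.05), common (≤ 0.3),
  high (> 0.3); strain-specific means the alternate allele is observed
  in exactly one strain; deltaAF is the difference between two named
  groups.
* **LD tagging** — r² is the squared Pearson correlation of unphased
  genotype dosages (composite LD) between each SV and every SNP within
  ±100 kb (pairwise-complete over missing data).  Tagged ⇔ best r² ≥
  0.2; molQTL-linked ⇔ best r² ≥ 0.6 against a designated SNP set.  The
  ±100 kb window is a documented default spanning typical chicken LD
  decay; it is configurable.
* **IBS** — distance(i, j) = mean over variants (MAF ≥ 0.05, both
  called) of |dosage_i − dosage_j| / 2; the strain matrix averages all
  cross-strain sample pairs (within-strain: unordered pairs).  The
  dosage form of the PLINK distance family is used and documented.
* **nIBD** — for a region and group pair, cIBD counts sample pairs with
  ≥ 1 overlapping IBD segment, tIBD is |A|·|B| (within-group
  n(n−1)/2), nIBD = cIBD/tIBD.  A sample pair counts once regardless of
  how many haplotype pairs share.
* **π** — per window, Σ over SNP sites of 2p(1−p)·n/(n−1) divided by
  window length (n = called alleles), equal to mean pairwise allele
  differences.
* **Association** — allelic 2×2 Fisher exact test per variant (default;
  robust at strain sample sizes), logistic regression on dosage behind
  a flag; Bonferroni factor = number of tested variants.

## Composite selection scan

Sliding 30-kb windows with 10-kb step.  Per window and method:

* **F_ST** — Weir & Cockerham (1984) variance components per SNP,
  window estimate = Σa / Σ(a+b+c) (ratio of sums).  Negative estimates
  are floored at zero for ranking; the raw value is retained.
* **XP-EHH** — per core SNP, EHH is the probability two random
  haplotypes are identical from the core outward (conditioning on the
  core allele), integrated by trapezoid over physical distance until
  EHH < 0.05 on each side; the score is ln(iHH_A/iHH_B), standardized
  genome-wide to mean 0, sd 1.  The window value is the standardized
  score of largest magnitude (sign retained); windows rank on the
  magnitude.  Unphased input raises an error directing to the
  F_ST-only composite.
* **Imported scores** (e.g. XP-CLR) join from a per-window table and
  enter the composite identically; they are never computed internally.

Each method's window scores are rank-normalized, R = (rank − 1)/(n − 1)
ascending with average ranks for ties (so the stated [0, 1] range is
achieved exactly), scaled to S = R/(1.001 − R) (top window ↦ exactly
1000), and averaged over available methods (windows missing a method
average the rest and are flagged).  The top 0.1% of windows by
composite — k = max(1, ⌈0.001·n⌉) in stable position order — are called
candidate sweep regions, with a degeneracy flag when the selection
boundary falls inside a tie.

## ABBA-BABA statistics

Sites are polarized by the outgroup: the derived allele is the minor
allele in O; sites with no called outgroup alleles or exactly 0.5
outgroup frequency are dropped and counted.  When phased haplotypes are
available group frequencies come from haplotype counts (exact), else
from genotypes.  Per site,

    ABBA = (1 − p1)·p2·p3·(1 − pO),  BABA = p1·(1 − p2)·p3·(1 − pO)

and per 30-kb window D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA).  Windows with
fewer than 20 informative sites (default) report missing.

**fdM.**  The admixture-fraction estimator uses the dynamic-donor
denominator: at each site the donor allele frequency max(p2, p3) is
substituted into both the P2 and P3 slots (for windows with positive
numerator), or max(p1, p3) into the P1 and P3 slots with the sign
mirrored (negative windows).  Choosing the donor scheme by the
window-level direction — rather than site by site — makes the estimator
exactly 1 when the recipient's window is a complete copy of the donor
pool (the denominator then equals the numerator site by site), exactly
antisymmetric under a P1/P2 swap, and bounded in [−1, 1] on all
simulated inputs; the site-wise case-split variant found in some
windowed ABBA-BABA tools loses all three properties in windows that mix
both flow directions.

Group-level fdM contrasts use the two-sided Wilcoxon rank-sum test,
exact for tie-free samples up to n = 25 per group, otherwise the normal
approximation with continuity correction.

## Permutation enrichment

An SV overlaps a region class when they share ≥ 1 bp (half-open
intervals; the common intersect convention — a strict mode exists
because "more than 1 bp" can also be read exclusively).  Each of 100
permutations re-places every SV uniformly at random on its own
chromosome, preserving length; Z = (observed − mean)/sd over
permutations and the empirical p uses the add-one rule
(1 + #extreme)/(N + 1).  A region set that forces identical counts in
every permutation is flagged saturated (Z undefined).  Significance
stars follow the 0.05/0.01/0.001 convention.  SVs are permuted by
default; permuting the annotation elements instead is the flag-selected
alternative reading.

## Synthetic cohort generator

All randomness flows from one seeded generator; a fixed seed reproduces
every output byte for byte.  Defaults (the study conditions at desk
scale): two 2-Mb chromosomes, six TE families (CR1-dominated consensus
lengths 500–2500 bp), tandem units of 11 bp and 430 bp, 40 SVs per
mechanism class (200 total), five strains × 20 samples (white and
colored focal groups, two layer strains, a junglefowl outgroup), 4000
SNPs, six callers of which three support insertions and one reports
insertion sequences, breakpoint jitter sd 10 bp, FNR 0.05, FPR 0.02.

* **Reference** — i.i.d. uniform ACGT, which guarantees that NHR
  negatives carry no accidental repeat/TE/homology signatures at the
  tested lengths.
* **SV planting** — VNTR alleles are tandem arrays (5–12 copies,
  fractional); NAHR deletions get two identical flanking homology
  blocks (300 bp for ≥ 1 kb SVs, 40 bp below); STEI insertions are ≥
  90% one 3′-anchored TE fragment; MTEI insertions concatenate
  fragments of ≥ 2 families; NHR SVs are random sequence.  Every
  planted SV is re-classified with the classifier's own evidence
  functions at generation time and redrawn on disagreement
  (self-consistency assert).  Deletion alleles are written into the
  reference; placements keep a 2.5-kb margin so junction windows never
  overlap neighbouring edits.
* **Call sets** — per sample and tool; deletions from all tools,
  insertions from the capable subset; breakpoints jittered by
  round(Normal(0, sd)); false negatives per call, Poisson false
  positives at random positions.
* **Population** — haplotype-level (two haplotypes per sample).
  Ancestral SNP frequencies are uniform on [0.05, 0.95]; each strain
  draws Balding–Nichols frequencies (drift F = 0.05) and a pool of 8
  founder haplotypes; sample haplotypes are founder mosaics with
  per-site switch probability 0.02, which creates block LD so EHH decay
  is meaningful.  The paper's populations' demography is not modelled —
  only the statistical structure each stage assumes.
* **Sweep** — inside the sweep window, each focal-strain haplotype is
  replaced by one designated founder haplotype with probability equal
  to the sweep strength (default 0.95), creating both a frequency shift
  toward fixation and an extended haplotype.
* **Introgression** — recipient haplotypes in the introgressed window
  are dealt donor haplotypes round-robin from a shuffled deck, so at
  fraction 1.0 the recipient reproduces the donor pool's window
  frequencies exactly (a with-replacement resample would leave
  fdM ≈ 0.7–0.85 at these group sizes purely from resampling noise).
  Every haplotype copy is recorded as a ground-truth IBD segment
  (sweep-sharing pairs likewise).
* **SVs in the cohort** — 30% of SVs copy the haplotypes of their
  nearest SNP (perfect LD, the "tagged" truth); the rest draw
  independent Balding–Nichols frequencies.  One common independent SV
  is designated causal; the binary phenotype is 1 for carriers with the
  configured penetrance (default 1.0) and for non-carriers at the
  phenocopy rate (default 0).
* **Annotations** — three interval classes at 5% genomic coverage; the
  target class places intervals over a fold-determined share of SV
  positions (default 10×) plus uniform filler, the others are uniform.
* **Missingness** — 2% of genotype entries are masked; haplotypes keep
  the truth (emulating genotyping dropout while phase-based statistics
  remain exact).

**What passing tests show.**  The generator reproduces the *structure*
the methods assume — jittered multi-tool call sets, planted sequence
signatures, block LD, drift, a sweep, an introgressed segment, an
SV-linked phenotype, an enriched annotation class — but not read-level
error, reference bias, caller-specific artefacts, real chicken
demography, or genome-wide repeat landscapes.  Recovery rates measured
here are upper bounds on real-data performance, not estimates of it.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in minutes on one CPU: 200 planted SVs for mechanism
recovery; 60 SVs × 10 samples × 6 tools for the merge oracle; 20
replicate 3-Mb cohorts (2500 SNPs, 30 + 30 samples) for sweep-detection
power and the same number for the null; 2-Mb four-group cohorts (2000
SNPs, 4 × 20 samples) for ABBA-BABA; 200 replicates of a 500-kb null
design for enrichment calibration.

## Known limitations

* Tandem detection requires exact unit copies; diverged, interrupted
  arrays under-report coverage (TRF-style alignment scoring would be
  needed for those).
* TE detection by exact seeds misses highly diverged copies (identity
  well below ~93% for 15-mers).
* XP-EHH integrates over physical distance (no recombination map) and
  is O(cores × extension) in pure numpy; genome-scale data would want a
  compiled EHH kernel.
* The enrichment null preserves SV lengths and chromosome assignment
  but not local features (GC, gaps); regioneR-style masked
  randomization is out of scope.
* nIBD counts a sample pair once whatever the number of sharing
  haplotype pairs; haplotype-resolution counting sits behind a flag.
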