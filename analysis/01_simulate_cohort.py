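#!/usr/bin/env python
"""Generate the synthetic study cohort and write every input file.

Produces, under results/data/: the reference and TE-library FASTAs, the
planted-SV truth table, per-sample per-tool call-set VCFs, the cohort
genotype VCF with the sample table, ground-truth IBD segments, and the
annotation interval classes.  Downstream scripts start from these files.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pansv import io, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = simulate.SimulationConfig(seed=SEED)
    cohort = simulate.simulate_cohort(cfg)
    layout = io.GenomeLayout.from_sequences(cohort.reference.sequences)

    io.write_fasta(OUT / "reference.fa", cohort.reference.sequences)
    io.write_fasta(OUT / "te_library.fa", cohort.reference.te_library)
    io.write_tsv(OUT / "truth_svs.tsv", cohort.truth.svs.drop(columns=["seq"]))
    io.write_tsv(OUT / "samples.tsv", cohort.genotypes.samples)
    io.write_genotype_vcf(OUT / "genotypes.vcf", cohort.genotypes, layout)
    io.write_ibd_bed(OUT / "ibd_segments.bed", cohort.ibd_segments)
    for cls, df in cohort.annotations.items():
        io.write_bed(OUT / f"annotation_{cls}.bed", df)

    calldir = OUT / "callsets"
    calldir.mkdir(exist_ok=True)
    n_calls = 0
    for (sample, tool), calls in cohort.callsets.items():
        frame = pd.DataFrame(
            [
                {"id": f"{sample}_{tool}_{i}", "chrom": c.chrom, "start": c.start,
                 "end": c.end, "svtype": c.svtype, "length": c.length,
                 "seq": c.alt_seq}
                for i, c in enumerate(calls)
            ]
        )
        io.write_sv_vcf(calldir / f"{sample}.{tool}.vcf", frame, layout)
        n_calls += len(calls)

    print(f"cohort seed={SEED}: {len(cohort.truth.svs)} planted SVs "
          f"({cohort.truth.svs['mechanism'].value_counts().to_dict()}), "
          f"{cohort.genotypes.n_variants} variants x {cohort.genotypes.n_samples} "
          f"samples, {n_calls} raw calls in {len(cohort.callsets)} call sets, "
          f"causal SV {cohort.truth.causal_sv_id}")
    print(f"wrote inputs under {OUT}")


if __name__ == "__main__":
    main()
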