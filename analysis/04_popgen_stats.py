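#!/usr/bin/env python
"""Population-genetic characterization of the genotyped cohort.

QC (call rate > 0.3, MAC > 3), frequency classes and deltaAF between
the focal strain and the donor layer strain, SV-SNP LD tagging
(r^2 >= 0.2), strain-averaged IBS distances, nIBD over the sweep
region, windowed nucleotide diversity, and the SV case-control
association scan with Bonferroni correction.
"""

from pathlib import Path

import numpy as np

from pansv import io
from pansv.popgen import (
    assoc_case_control,
    frequencies,
    ibs_matrix,
    ld_tagging,
    nibd,
    nucleotide_diversity,
    qc_genotypes,
)
from pansv.selection import make_windows

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"


def main() -> None:
    samples = io.read_sample_table(DATA / "samples.tsv")
    gm = io.read_genotype_vcf(DATA / "genotypes.vcf", samples)
    reference = io.read_fasta(DATA / "reference.fa")
    lengths = {c: len(s) for c, s in reference.items()}

    kept, removed = qc_genotypes(gm)
    io.write_tsv(BASE / "qc_removed.tsv", removed)
    print(f"QC: kept {kept.n_variants}/{gm.n_variants} variants "
          f"({len(removed)} removed)")

    freq = frequencies(kept, delta_groups=("WC_white", "WL"))
    io.write_tsv(BASE / "frequencies.tsv", freq)
    mix = freq["frequency_class"].value_counts().to_dict()
    print(f"frequency classes: {mix}; "
          f"{(freq['strain_sharing'] == 'specific').sum()} strain-specific variants")

    ld = ld_tagging(kept)
    io.write_tsv(BASE / "ld_tagging.tsv", ld)
    tagged = int((ld["tag_class"] == "tagged").sum())
    print(f"LD tagging: {tagged}/{len(ld)} SVs tagged by a nearby SNP "
          f"(r^2 >= 0.2); {len(ld) - tagged} independent")

    sample_ibs, group_ibs = ibs_matrix(kept)
    group_ibs.to_csv(BASE / "ibs_groups.tsv", sep="\t")
    print("strain-averaged IBS distances written to ibs_groups.tsv")

    from pansv import simulate

    ibd = io.read_ibd_bed(DATA / "ibd_segments.bed")
    sw = simulate.SimulationConfig().sweep  # region planted by 01
    sweep_region = (sw.chrom, sw.start, sw.end)
    if len(ibd):
        res = nibd(ibd, kept.samples, "strain", sweep_region)
        io.write_tsv(BASE / "nibd.tsv", res)
        within = res[(res["group_a"] == "WC_white") & (res["group_b"] == "WC_white")]
        if len(within):
            print(f"nIBD within the swept strain over {sweep_region}: "
                  f"{within['nIBD'].iat[0]:.2f}")

    windows = make_windows(lengths)
    pi = nucleotide_diversity(kept, list(windows.itertuples(index=False, name=None)))
    io.write_tsv(BASE / "pi_windows.tsv", pi)

    sv_gm = kept.subset_variants((kept.variants["type"] == "SV").to_numpy())
    assoc = assoc_case_control(sv_gm)
    io.write_tsv(BASE / "assoc_sv.tsv", assoc)
    top = assoc.iloc[0]
    print(f"association: top hit {top['id']} at {top['chrom']}:{top['pos']} "
          f"(p_bonf={top['p_bonf']:.2e}); "
          f"{int((assoc['p_bonf'] <= 0.01).sum())} SVs significant at "
          f"Bonferroni 0.01")


if __name__ == "__main__":
    main()
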