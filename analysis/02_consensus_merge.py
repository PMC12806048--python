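#!/usr/bin/env python
"""Merge the per-sample per-tool call sets into cohort consensus SVs.

Reads the call-set VCFs written by 01, applies the size filter
(50 bp - 100 kb), the breakpoint-recurrence rule (>= 3 observations at
50-bp clustering distance), single-linkage clustering, and
representative selection, then writes the merged VCF and a cluster
report under results/.
"""

import sys
from pathlib import Path

from pansv import io
from pansv.consensus import SVCall, merge_cohort, records_to_frame

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"


def main() -> None:
    reference = io.read_fasta(DATA / "reference.fa")
    layout = io.GenomeLayout.from_sequences(reference)
    callsets = {}
    for path in sorted((DATA / "callsets").glob("*.vcf")):
        sample, tool = path.stem.split(".")
        frame = io.read_sv_vcf(path)
        callsets[(sample, tool)] = [
            SVCall(r.chrom, r.start, r.end, r.svtype, r.length, sample, tool,
                   r.seq if isinstance(r.seq, str) else None)
            for r in frame.itertuples(index=False)
        ]
    n_in = sum(len(v) for v in callsets.values())
    records = merge_cohort(callsets, reference=reference)
    frame = records_to_frame(records)
    io.write_sv_vcf(BASE / "merged_svs.vcf", frame, layout)
    io.write_tsv(BASE / "cluster_report.tsv", frame.drop(columns=["seq"]))

    truth = io.read_tsv(DATA / "truth_svs.tsv")
    recovered = sum(
        any(
            r.chrom == row.chrom and r.svtype == row.svtype
            and abs(r.start - row.start) <= 50 and abs(r.end - row.end) <= 50
            for r in records
        )
        for row in truth.itertuples(index=False)
    )
    print(f"merged {n_in} raw calls from {len(callsets)} call sets into "
          f"{len(records)} consensus SVs; {recovered}/{len(truth)} planted SVs "
          f"recovered within 50 bp "
          f"({100 * recovered / len(truth):.1f}%)")
    print(f"wrote {BASE / 'merged_svs.vcf'} and cluster_report.tsv")


if __name__ == "__main__":
    main()
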