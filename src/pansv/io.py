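"""Format boundary: FASTA, VCF, BED, and TSV readers/writers.

Every coordinate inside the package is 0-based half-open.  The 1-based
inclusive conventions of VCF are converted exactly once, here.  The VCF
dialect written by the package follows the merged-SV style of short-read
callers: deletions as symbolic ``<DEL>`` ALT with an ``END`` INFO key,
insertions as full-sequence ALT, with ``SVTYPE``/``SVLEN`` and the
cluster metadata ``SUPP``/``CLUSTER_SIZE``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF


class FormatError(ValueError):
    """Raised when an input file violates the subset of a format we consume."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths (0-based half-open internally)."""

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate chromosome names in layout")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise FormatError(f"non-positive length for chromosome {name!r}")

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "GenomeLayout":
        return cls(tuple(seqs), {n: len(s) for n, s in seqs.items()})

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read named sequences; case preserved (lowercase = soft-masked)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                if name in seqs:
                    raise FormatError(f"duplicate FASTA record name {name!r}")
                chunks = []
            elif line:
                if name is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
    if name is not None:
        if name in seqs:
            raise FormatError(f"duplicate FASTA record name {name!r}")
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path: str | Path, seqs: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/6 as a DataFrame with 0-based half-open intervals.

    Zero-length intervals (start == end) are accepted with a warning;
    end < start is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = _BED_COLS[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df["end"] < df["start"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"BED interval with end < start at data line {i + 1}")
    zero = df["end"] == df["start"]
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-length BED intervals", stacklevel=2)
    return df


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def check_bounds(df: pd.DataFrame, layout: GenomeLayout) -> list[str]:
    """Return human-readable warnings for intervals outside the layout."""
    problems = []
    for row in df.itertuples(index=False):
        if row.chrom not in layout:
            problems.append(f"unknown chromosome {row.chrom!r}")
        elif row.start < 0 or row.end > layout.lengths[row.chrom]:
            problems.append(f"{row.chrom}:{row.start}-{row.end} outside chromosome")
    return problems


# ---------------------------------------------------------------------------
# VCF: merged SV records
# ---------------------------------------------------------------------------

_SV_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length, negative for DEL">
##INFO=<ID=END,Number=1,Type=Integer,Description="Last affected reference base, 1-based">
##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Observations of the representative coordinates">
##INFO=<ID=CLUSTER_SIZE,Number=1,Type=Integer,Description="Total calls in the cluster">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _contig_lines(layout: GenomeLayout | None, chroms: Iterable[str]) -> str:
    if layout is not None:
        return "".join(
            f"##contig=<ID={n},length={layout.lengths[n]}>\n" for n in layout.names
        )
    return "".join(f"##contig=<ID={c}>\n" for c in dict.fromkeys(chroms))


def write_sv_vcf(
    path: str | Path,
    records: pd.DataFrame,
    layout: GenomeLayout | None = None,
) -> None:
    """Write merged SV records (columns: id, chrom, start, end, svtype,
    length, seq, optionally support/cluster_size) as sites-only VCF."""
    with open(path, "w") as fh:
        fh.write(_SV_VCF_HEADER)
        fh.write(_contig_lines(layout, records["chrom"]))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in records.itertuples(index=False):
            info = [f"SVTYPE={row.svtype}"]
            if row.svtype == "DEL":
                pos, end = row.start + 1, row.end
                alt, svlen = "<DEL>", -int(row.length)
            else:  # INS
                pos, end = row.start + 1, row.start + 1
                seq = getattr(row, "seq", None)
                alt = "N" + seq if isinstance(seq, str) and seq else "<INS>"
                svlen = int(row.length)
            info += [f"SVLEN={svlen}", f"END={end}"]
            if hasattr(row, "support"):
                info.append(f"SUPP={int(row.support)}")
            if hasattr(row, "cluster_size"):
                info.append(f"CLUSTER_SIZE={int(row.cluster_size)}")
            fh.write(
                f"{row.chrom}\t{pos}\t{row.id}\tN\t{alt}\t.\tPASS\t{';'.join(info)}\n"
            )


def read_sv_vcf(path: str | Path) -> pd.DataFrame:
    """Read SV records back to 0-based half-open coordinates.

    Symbolic ``<DEL>`` length comes from END - POS + 1; sequence-resolved
    insertions recover their inserted sequence from the ALT allele.
    """
    rows = []
    vcf = VCF(str(path))
    for i, var in enumerate(_iter_vcf(vcf)):
        svtype = var.INFO.get("SVTYPE")
        end_info = var.INFO.get("END")
        if end_info is not None and end_info < var.POS:
            raise FormatError(f"END < POS for record {i + 1} at {var.CHROM}:{var.POS}")
        alt = var.ALT[0] if var.ALT else "."
        seq = None
        if svtype == "DEL":
            start = var.POS - 1
            end = int(end_info) if end_info is not None else start + abs(
                int(var.INFO.get("SVLEN"))
            )
            length = end - start
        elif svtype == "INS":
            start = var.POS - 1
            end = start
            if not alt.startswith("<"):
                seq = alt[1:]
            length = int(abs(var.INFO.get("SVLEN"))) if var.INFO.get(
                "SVLEN"
            ) is not None else len(seq or "")
        else:
            start = var.POS - 1
            end = int(end_info) if end_info is not None else start + 1
            length = end - start
        rows.append(
            {
                "id": var.ID,
                "chrom": var.CHROM,
                "start": start,
                "end": end,
                "svtype": svtype,
                "length": length,
                "seq": seq,
                "support": var.INFO.get("SUPP"),
                "cluster_size": var.INFO.get("CLUSTER_SIZE"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "chrom",
            "start",
            "end",
            "svtype",
            "length",
            "seq",
            "support",
            "cluster_size",
        ],
    )


def _iter_vcf(vcf: VCF):
    """Iterate a cyvcf2 VCF, converting htslib parse failures to FormatError."""
    it = iter(vcf)
    n = 0
    while True:
        try:
            var = next(it)
        except StopIteration:
            return
        except Exception as exc:  # htslib reports position on stderr
            raise FormatError(
                f"malformed VCF record after {n} parsed records: {exc}"
            ) from exc
        n += 1
        yield var


# ---------------------------------------------------------------------------
# VCF: genotype matrices
# ---------------------------------------------------------------------------


def write_genotype_vcf(path: str | Path, gm, layout: GenomeLayout | None = None) -> None:
    """Write a GenotypeMatrix (SNPs as A/C biallelic, SVs symbolic) with
    phased GTs when haplotypes are present."""
    variants, samples = gm.variants, gm.samples
    phased = gm.haplotypes is not None
    with open(path, "w") as fh:
        fh.write(_SV_VCF_HEADER)
        fh.write(_contig_lines(layout, variants["chrom"]))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples["id"])
            + "\n"
        )
        for vi, row in enumerate(variants.itertuples(index=False)):
            if row.type == "SNP":
                ref, alt, info = "A", "C", "."
            else:
                ref, alt = "N", f"<{row.svtype}>" if hasattr(row, "svtype") else "<DEL>"
                info = f"SVTYPE={alt[1:-1]};SVLEN={int(row.length)};END={row.pos + int(row.length)}"
            gts = []
            for si in range(len(samples)):
                if phased:
                    a, b = gm.haplotypes[vi, si]
                    gt = f"{a}|{b}"
                else:
                    g = gm.genotypes[vi, si]
                    gt = "./." if g < 0 else ("0/0", "0/1", "1/1")[g]
                if gm.genotypes[vi, si] < 0:
                    gt = "./."
                gts.append(gt)
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_genotype_vcf(path: str | Path, sample_table: pd.DataFrame):
    """Read a genotype VCF plus its sample table into a GenotypeMatrix."""
    from .popgen import GenotypeMatrix

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    rows, genos, haps = [], [], []
    any_unphased = False
    for i, var in enumerate(_iter_vcf(vcf)):
        svtype = var.INFO.get("SVTYPE")
        is_sv = svtype is not None
        rows.append(
            {
                "id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS - 1,
                "type": "SV" if is_sv else "SNP",
                "length": abs(int(var.INFO.get("SVLEN"))) if is_sv else 1,
            }
        )
        g = np.empty(len(vcf_samples), dtype=np.int8)
        h = np.empty((len(vcf_samples), 2), dtype=np.int8)
        for si, call in enumerate(var.genotypes):
            a, b = call[0], call[1]
            if a < 0 or b < 0:
                g[si], h[si] = -1, (-1, -1)
            else:
                if a > 1 or b > 1:
                    raise FormatError(
                        f"non-biallelic genotype for record {i + 1} at "
                        f"{var.CHROM}:{var.POS}"
                    )
                g[si] = a + b
                h[si] = (a, b)
                if not call[2]:
                    any_unphased = True
        genos.append(g)
        haps.append(h)
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "type", "length"])
    sample_table = sample_table.set_index("id").loc[vcf_samples].reset_index()
    G = np.array(genos, dtype=np.int8) if genos else np.empty((0, len(vcf_samples)), np.int8)
    H = None if any_unphased else (
        np.array(haps, dtype=np.int8) if haps else None
    )
    return GenotypeMatrix(variants, sample_table, G, H)


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "strain"} - set(df.columns)
    if missing:
        raise FormatError(f"sample table missing columns: {sorted(missing)}")
    return df


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ibd_bed(path: str | Path) -> pd.DataFrame:
    """IBD segments: chrom, start, end, sample_a, sample_b."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "sample_a", "sample_b"],
        dtype={"chrom": str, "sample_a": str, "sample_b": str},
    )
    return df


def write_ibd_bed(path: str | Path, segments: pd.DataFrame) -> None:
    segments.to_csv(
        path, sep="\t", header=False, index=False,
        columns=["chrom", "start", "end", "sample_a", "sample_b"],
    )
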