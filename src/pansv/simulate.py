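"""Synthetic cohort generator with planted ground truth for every stage.

The generator emulates the statistical structure each downstream stage
assumes, not any particular demography: an i.i.d.-uniform background
reference (so negative controls carry no accidental repeat/TE/homology
signatures at the tested lengths), SVs planted with explicit mechanism
signatures, multi-tool call sets with breakpoint jitter and per-tool
type support, and a stratified haplotype-level population with
founder-pool linkage disequilibrium, Balding-Nichols strain drift, a
planted sweep, a planted introgressed window, SV-SNP tagging, and an
SV-driven binary phenotype.  All randomness flows from one seeded
generator, so a fixed seed reproduces every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mechanism as mech
from .consensus import SVCall

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    chrom: str = "chr1"
    start: int = 400_000
    end: int = 430_000
    focal: str = "WC_white"
    contrast: str = "WC_colored"
    strength: float = 0.95  # fraction of focal haplotypes carrying the sweep


@dataclass(frozen=True)
class IntrogressionSpec:
    chrom: str = "chr1"
    start: int = 700_000
    end: int = 730_000
    donor: str = "WL"
    recipient: str = "WC_white"
    fraction: float = 1.0


@dataclass(frozen=True)
class EnrichmentSpec:
    target_class: str = "enhancer"
    fold: float = 10.0
    classes: tuple[str, ...] = ("promoter", "enhancer", "repressed")
    class_coverage: float = 0.05
    interval_length: int = 2_000


@dataclass(frozen=True)
class PhenotypeSpec:
    penetrance: float = 1.0
    phenocopy: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults give two 1-Mb chromosomes, six CR1-dominated TE families,
    tandem units of 11 and 430 bp, 40 SVs per mechanism class, five
    strains of 20 samples each (layers, broilers stand-ins, and a
    junglefowl outgroup), six callers of which three support insertions
    and one reports insertion sequences, and 10-bp breakpoint jitter.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (2_000_000, 2_000_000)
    te_consensus_lengths: tuple[int, ...] = (2500, 1800, 1200, 900, 700, 500)
    tandem_units: tuple[int, ...] = (11, 430)
    mechanism_counts: Mapping[str, int] = field(
        default_factory=lambda: {m: 40 for m in mech.MECHANISMS}
    )
    strains: tuple[str, ...] = ("WC_white", "WC_colored", "WL", "BL", "RJF")
    n_samples: int = 100
    n_tools: int = 6
    n_ins_tools: int = 3
    n_seq_tools: int = 1  # tools reporting insertion sequences
    n_callset_samples: int = 10
    breakpoint_jitter_sd: float = 10.0
    fnr: float = 0.05
    fpr: float = 0.02
    n_snps: int = 4_000
    n_founders: int = 8
    drift: float = 0.05
    recomb_switch: float = 0.02
    missing_rate: float = 0.02
    sv_tagged_fraction: float = 0.3
    sweep: SweepSpec = SweepSpec()
    introgression: IntrogressionSpec = IntrogressionSpec()
    enrichment: EnrichmentSpec = EnrichmentSpec()
    phenotype: PhenotypeSpec = PhenotypeSpec()

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.mechanism_counts.values()):
            raise ConfigError("mechanism counts must be non-negative")
        if self.breakpoint_jitter_sd < 0:
            raise ConfigError("jitter sd must be non-negative")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ConfigError("chromosome lengths must be positive")
        lengths = dict(zip(self.chrom_names, self.chrom_lengths))
        for spec in (self.sweep, self.introgression):
            if spec.chrom in lengths and not (
                0 <= spec.start < spec.end <= lengths[spec.chrom]
            ):
                raise ConfigError(f"window {spec} outside chromosome bounds")
        if len(self.strains) < 2:
            raise ConfigError("need at least two strains")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(len(self.chrom_lengths)))

    @property
    def tools(self) -> tuple[str, ...]:
        return tuple(f"tool{i}" for i in range(self.n_tools))

    @property
    def ins_tools(self) -> tuple[str, ...]:
        return self.tools[: self.n_ins_tools]

    @property
    def seq_tools(self) -> tuple[str, ...]:
        return self.tools[: self.n_seq_tools]


@dataclass
class Reference:
    sequences: dict[str, str]
    te_library: dict[str, str]
    repeat_annotation: pd.DataFrame  # planted repeats: chrom, start, end, name

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class TruthSet:
    """Planted ground truth: SV table (id, chrom, start, end, svtype,
    length, seq, mechanism), the sweep and introgressed windows, the
    causal SV, and annotation classes with their planted fold."""

    svs: pd.DataFrame
    sweep_window: tuple[str, int, int] | None = None
    introgressed_window: tuple[str, int, int] | None = None
    causal_sv_id: str | None = None
    tagged_sv_ids: tuple[str, ...] = ()
    annotations: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichment_fold: float | None = None

    def __post_init__(self) -> None:
        if len(self.svs):
            assert (self.svs["length"] >= 50).all(), "planted SV below 50 bp"
            assert self.svs["mechanism"].isin(mech.MECHANISMS).all()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# Reference and TE library
# ---------------------------------------------------------------------------

_TE_NAMES = ("CR1_A", "CR1_B", "CR1_C", "CR1_F2", "ERV_A", "SINE_A", "LTR_A", "CR1_D")


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Reference:
    """Uniform-random reference sequences plus a named TE consensus
    library; deterministic for a fixed seed."""
    if any(L < 10_000 for L in config.chrom_lengths):
        raise ConfigError("chromosomes must be at least 10 kb")
    rng = rng or np.random.default_rng(config.seed)
    sequences = {
        name: _random_seq(rng, L)
        for name, L in zip(config.chrom_names, config.chrom_lengths)
    }
    te_library = {}
    for i, L in enumerate(config.te_consensus_lengths):
        name = _TE_NAMES[i] if i < len(_TE_NAMES) else f"TE_{i}"
        te_library[name] = _random_seq(rng, L)
    annot = pd.DataFrame(columns=["chrom", "start", "end", "name"])
    return Reference(sequences, te_library, annot)


# ---------------------------------------------------------------------------
# SV planting
# ---------------------------------------------------------------------------

_PLACEMENT_MARGIN = 2_500  # keeps planted flank edits and junction windows disjoint
_MAX_ATTEMPTS = 200


class _Placer:
    """Uniform placement with margin-separated, non-overlapping slots."""

    def __init__(self, chrom_lengths: Mapping[str, int], rng: np.random.Generator):
        self.lengths = dict(chrom_lengths)
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in self.lengths}

    def place(self, span: int) -> tuple[str, int]:
        for _ in range(_MAX_ATTEMPTS):
            chrom = list(self.lengths)[self.rng.integers(len(self.lengths))]
            L = self.lengths[chrom]
            if L < span + 2 * _PLACEMENT_MARGIN:
                continue
            start = int(self.rng.integers(_PLACEMENT_MARGIN, L - span - _PLACEMENT_MARGIN))
            lo, hi = start - _PLACEMENT_MARGIN, start + span + _PLACEMENT_MARGIN
            if all(e <= lo or s >= hi for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((lo, hi))
                return chrom, start
        raise ConfigError("could not place SV after bounded attempts")


def _make_vntr(rng, units: Sequence[int]) -> tuple[str, dict]:
    unit_len = int(rng.choice(units))
    unit = _random_seq(rng, unit_len)
    copies = float(rng.uniform(5.0, 12.0))
    span = max(50, int(round(copies * unit_len)))
    seq = (unit * (span // unit_len + 2))[:span]
    return seq, {"unit_length": unit_len, "copies": span / unit_len}


def _make_stei(rng, te_library: Mapping[str, str]) -> str:
    fam = list(te_library)[rng.integers(len(te_library))]
    consensus = te_library[fam]
    frag_len = int(rng.integers(300, min(1500, len(consensus)) + 1))
    frag = consensus[len(consensus) - frag_len :]  # 3'-anchored, CR1-style
    pad = int(rng.integers(0, max(1, frag_len // 25)))
    return _random_seq(rng, pad) + frag + _random_seq(rng, pad)


def _make_mtei(rng, te_library: Mapping[str, str]) -> str:
    fams = rng.choice(len(te_library), size=int(rng.integers(2, 4)), replace=False)
    names = list(te_library)
    parts = []
    for f in fams:
        consensus = te_library[names[int(f)]]
        frag_len = int(rng.integers(200, min(800, len(consensus)) + 1))
        parts.append(consensus[len(consensus) - frag_len :])
    return "".join(parts)


def plant_svs(
    reference: Reference,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Plant SVs with mechanism signatures; every planted SV is verified
    at generation time with the classifier's own evidence functions.

    VNTR: the SV allele is a tandem array (integer-or-fractional copies
    of a unit).  NAHR: a deletion whose junctions are flanked by two
    identical homology blocks above the size-class cutoff (300 bp for
    >= 1 kb SVs, 40 bp below).  STEI: an insertion that is >= 90% one TE
    consensus fragment.  MTEI: an insertion concatenating fragments of
    >= 2 distinct families.  NHR: i.i.d.-random sequence carrying none
    of these signatures.  Deletion alleles are written into the
    reference; insertions leave it untouched.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    chrom_arrays = {c: bytearray(s.encode()) for c, s in reference.sequences.items()}
    placer = _Placer(reference.chrom_lengths, rng)
    rows = []
    repeat_rows = []
    cfg = mech.ClassifierConfig()
    sv_i = 0
    for mechanism in mech.MECHANISMS:
        count = config.mechanism_counts.get(mechanism, 0)
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > count * 20 + 50:
                raise ConfigError(f"failed to construct {mechanism} SVs")
            meta = {}
            if mechanism == "VNTR":
                seq, meta = _make_vntr(rng, config.tandem_units)
                svtype = "DEL" if made % 2 == 0 else "INS"
            elif mechanism == "NAHR":
                svtype = "DEL"
                if made % 2 == 0:
                    length, block = int(rng.integers(1200, 5001)), 300
                else:
                    length, block = int(rng.integers(150, 901)), 40
                seq = None  # reference span; homology blocks written below
            elif mechanism == "STEI":
                seq, svtype = _make_stei(rng, reference.te_library), "INS"
            elif mechanism == "MTEI":
                seq, svtype = _make_mtei(rng, reference.te_library), "INS"
            else:  # NHR
                svtype = "DEL" if made % 2 == 0 else "INS"
                seq = _random_seq(rng, int(rng.integers(100, 2001)))
            span = length if mechanism == "NAHR" else (len(seq) if svtype == "DEL" else 0)
            chrom, start = placer.place(span)
            end = start + span if svtype == "DEL" else start
            # apply edits to a local window first; commit only if the
            # classifier's own evidence recovers the intended label
            lo, hi = start - _PLACEMENT_MARGIN, end + _PLACEMENT_MARGIN
            local = bytearray(chrom_arrays[chrom][lo:hi])
            if svtype == "DEL" and mechanism != "NAHR":
                local[start - lo : end - lo] = seq.encode()
            if mechanism == "NAHR":
                homology = _random_seq(rng, block).encode()
                local[start - block - lo : start - lo] = homology
                local[end - block - lo : end - lo] = homology
                seq = local[start - lo : end - lo].decode()
            ev = mech.gather_evidence(
                svtype, local.decode(), start - lo, end - lo, seq,
                reference.te_library, cfg,
            )
            if mech.classify_from_evidence(ev, cfg) != mechanism:
                continue  # slot abandoned; retry with a fresh draw
            chrom_arrays[chrom][lo:hi] = local
            if svtype == "DEL" and mechanism == "VNTR":
                repeat_rows.append(
                    {"chrom": chrom, "start": start, "end": end,
                     "name": f"tandem_{meta['unit_length']}bp"}
                )
            length_bp = len(seq)
            rows.append(
                {
                    "id": f"truth_{sv_i}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "svtype": svtype,
                    "length": length_bp,
                    "seq": seq,
                    "mechanism": mechanism,
                    **{k: meta.get(k) for k in ("unit_length", "copies")},
                }
            )
            sv_i += 1
            made += 1
    reference.sequences = {c: a.decode() for c, a in chrom_arrays.items()}
    reference.repeat_annotation = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "name"]
    )
    columns = [
        "id", "chrom", "start", "end", "svtype", "length", "seq",
        "mechanism", "unit_length", "copies",
    ]
    svs = pd.DataFrame(rows, columns=columns)
    if len(svs):
        svs = svs.sort_values(["chrom", "start"]).reset_index(drop=True)
    return TruthSet(svs=svs)


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------


def simulate_callsets(
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, str], list[SVCall]]:
    """Per-sample, per-tool call sets with breakpoint jitter, per-tool
    type support (deletions from all tools, insertions only from the
    insertion-capable subset), false negatives, and random false
    positives; insertion sequences only from sequence-reporting tools."""
    if config.n_tools < 1:
        raise ConfigError("need at least one tool")
    rng = rng or np.random.default_rng(config.seed + 2)
    samples = [f"cs{i}" for i in range(config.n_callset_samples)]
    chrom_lengths = {
        c: L for c, L in zip(config.chrom_names, config.chrom_lengths)
    }
    callsets: dict[tuple[str, str], list[SVCall]] = {}
    sd = config.breakpoint_jitter_sd
    for sample in samples:
        for tool in config.tools:
            calls: list[SVCall] = []
            for row in truth.svs.itertuples(index=False):
                if row.svtype == "INS" and tool not in config.ins_tools:
                    continue
                if rng.random() < config.fnr:
                    continue
                js = int(row.start + round(rng.normal(0, sd))) if sd > 0 else row.start
                js = max(0, js)
                if row.svtype == "DEL":
                    je = int(row.end + round(rng.normal(0, sd))) if sd > 0 else row.end
                    je = max(js + 1, je)
                    length = je - js
                else:
                    je, length = js, row.length
                calls.append(
                    SVCall(
                        chrom=row.chrom,
                        start=js,
                        end=je,
                        svtype=row.svtype,
                        length=length,
                        sample_id=sample,
                        tool_id=tool,
                        alt_seq=row.seq
                        if row.svtype == "INS" and tool in config.seq_tools
                        else None,
                    )
                )
            n_fp = rng.poisson(config.fpr * max(len(truth.svs), 1))
            for _ in range(n_fp):
                chrom = config.chrom_names[rng.integers(len(config.chrom_names))]
                length = int(rng.integers(60, 5000))
                start = int(rng.integers(0, chrom_lengths[chrom] - length))
                svtype = "DEL" if (tool not in config.ins_tools or rng.random() < 0.5) else "INS"
                calls.append(
                    SVCall(
                        chrom=chrom,
                        start=start,
                        end=start + length if svtype == "DEL" else start,
                        svtype=svtype,
                        length=length,
                        sample_id=sample,
                        tool_id=tool,
                    )
                )
            callsets[(sample, tool)] = calls
    return callsets


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------


def _strain_freqs(rng, p: np.ndarray, drift: float) -> np.ndarray:
    """Balding-Nichols draw of strain frequencies around ancestral p."""
    if drift <= 0:
        return p.copy()
    a = p * (1 - drift) / drift
    b = (1 - p) * (1 - drift) / drift
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def _mosaic_haplotype(rng, founders: np.ndarray, switch: float) -> np.ndarray:
    m = founders.shape[1]
    sw = rng.random(m) < switch
    sw[0] = True
    seg = np.cumsum(sw) - 1
    choice = rng.integers(0, founders.shape[0], size=int(seg[-1]) + 1)
    return founders[choice[seg], np.arange(m)]


def simulate_population(
    truth: TruthSet,
    config: SimulationConfig,
    reference: Reference,
    rng: np.random.Generator | None = None,
):
    """Haplotype-level cohort: SNPs with founder-pool LD and strain
    drift, a planted sweep, a planted introgressed window, SV-SNP
    tagging, an SV-driven binary phenotype, and ground-truth IBD
    segments wherever haplotypes were copied.

    Returns (GenotypeMatrix, ibd_segments DataFrame, updated TruthSet).
    """
    from .popgen import GenotypeMatrix

    rng = rng or np.random.default_rng(config.seed + 3)
    strains = config.strains
    per = config.n_samples // len(strains)
    if per == 0:
        raise ConfigError("group sizes of zero")
    sample_rows = [
        {"id": f"{s}_{i:02d}", "strain": s, "population": s}
        for s in strains
        for i in range(per)
    ]
    samples = pd.DataFrame(sample_rows)
    n_samp = len(samples)

    # SNP scaffold
    chrom_lengths = reference.chrom_lengths
    total = sum(chrom_lengths.values())
    snp_rows = []
    for chrom, L in chrom_lengths.items():
        n = int(round(config.n_snps * L / total))
        pos = np.sort(rng.choice(L, size=n, replace=False))
        snp_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    snps = pd.concat(snp_rows, ignore_index=True)
    n_snp = len(snps)
    p_anc = rng.uniform(0.05, 0.95, n_snp)

    # founder pools and mosaic haplotypes per strain
    H_snp = np.zeros((n_snp, n_samp, 2), dtype=np.int8)
    chrom_arr = snps["chrom"].to_numpy()
    strain_founders = {}
    for s in strains:
        p_s = _strain_freqs(rng, p_anc, config.drift)
        founders = (rng.random((config.n_founders, n_snp)) < p_s).astype(np.int8)
        strain_founders[s] = founders
        idx = np.flatnonzero((samples["strain"] == s).to_numpy())
        for si in idx:
            for h in range(2):
                hap = np.empty(n_snp, dtype=np.int8)
                for chrom in chrom_lengths:
                    m = chrom_arr == chrom
                    hap[m] = _mosaic_haplotype(
                        rng, founders[:, m], config.recomb_switch
                    )
                H_snp[:, si, h] = hap

    ibd_rows = []

    # sweep: a single focal-founder haplotype rises toward fixation
    sw = config.sweep
    if sw is not None and sw.strength > 0:
        win = (
            (chrom_arr == sw.chrom)
            & (snps["pos"].to_numpy() >= sw.start)
            & (snps["pos"].to_numpy() < sw.end)
        )
        sweep_hap = strain_founders[sw.focal][0, win]
        focal_idx = np.flatnonzero((samples["strain"] == sw.focal).to_numpy())
        carriers = set()
        for si in focal_idx:
            for h in range(2):
                if rng.random() < sw.strength:
                    H_snp[win, si, h] = sweep_hap
                    carriers.add(si)
        carrier_list = sorted(carriers)
        for i, a in enumerate(carrier_list):
            for b in carrier_list[i + 1 :]:
                ibd_rows.append(
                    {
                        "chrom": sw.chrom,
                        "start": sw.start,
                        "end": sw.end,
                        "sample_a": samples["id"].iat[a],
                        "sample_b": samples["id"].iat[b],
                    }
                )
        truth = replace(truth, sweep_window=(sw.chrom, sw.start, sw.end))

    # introgression: recipient haplotypes copied from donor samples
    ig = config.introgression
    if ig is not None and ig.fraction > 0:
        win = (
            (chrom_arr == ig.chrom)
            & (snps["pos"].to_numpy() >= ig.start)
            & (snps["pos"].to_numpy() < ig.end)
        )
        donor_idx = np.flatnonzero((samples["strain"] == ig.donor).to_numpy())
        recip_idx = np.flatnonzero((samples["strain"] == ig.recipient).to_numpy())
        # donor haplotypes are dealt round-robin from a shuffled deck so a
        # fully introgressed window reproduces the donor pool's window
        # frequencies (not a with-replacement resample of them)
        deck = [(int(dj), dh) for dj in donor_idx for dh in range(2)]
        deck = [deck[k] for k in rng.permutation(len(deck))]
        source_of: dict[int, set[tuple[int, int]]] = {}
        k = 0
        for si in recip_idx:
            for h in range(2):
                if rng.random() < ig.fraction:
                    dj, dh = deck[k % len(deck)]
                    k += 1
                    H_snp[win, si, h] = H_snp[win, dj, dh]
                    source_of.setdefault(si, set()).add((dj, dh))
        for si, sources in sorted(source_of.items()):
            for dj, _ in sorted(sources):
                ibd_rows.append(
                    {
                        "chrom": ig.chrom,
                        "start": ig.start,
                        "end": ig.end,
                        "sample_a": samples["id"].iat[si],
                        "sample_b": samples["id"].iat[dj],
                    }
                )
        truth = replace(truth, introgressed_window=(ig.chrom, ig.start, ig.end))

    # SV genotypes: tagged SVs copy a neighbouring SNP's haplotypes
    svs = truth.svs
    n_sv = len(svs)
    H_sv = np.zeros((n_sv, n_samp, 2), dtype=np.int8)
    n_tagged = int(round(config.sv_tagged_fraction * n_sv))
    tagged_rows = rng.choice(n_sv, size=n_tagged, replace=False) if n_tagged else []
    tagged_ids = []
    pos_arr = snps["pos"].to_numpy()
    for vi in range(n_sv):
        chrom = svs["chrom"].iat[vi]
        pos = svs["start"].iat[vi]
        if vi in set(np.atleast_1d(tagged_rows)):
            near = np.flatnonzero(
                (chrom_arr == chrom) & (np.abs(pos_arr - pos) <= 100_000)
            )
            if near.size:
                j = int(near[np.argmin(np.abs(pos_arr[near] - pos))])
                H_sv[vi] = H_snp[j]
                tagged_ids.append(svs["id"].iat[vi])
                continue
        p_sv = float(rng.uniform(0.05, 0.9))
        for s in strains:
            idx = np.flatnonzero((samples["strain"] == s).to_numpy())
            p_s = float(
                np.clip(
                    rng.beta(
                        p_sv * (1 - config.drift) / config.drift,
                        (1 - p_sv) * (1 - config.drift) / config.drift,
                    ),
                    1e-4,
                    1 - 1e-4,
                )
            )
            H_sv[vi, idx] = (rng.random((idx.size, 2)) < p_s).astype(np.int8)

    # causal SV and phenotype
    causal_id = None
    if n_sv:
        dosage = H_sv.sum(axis=2)
        freq = dosage.mean(axis=1) / 2
        independent = ~svs["id"].isin(tagged_ids).to_numpy()
        candidates = np.flatnonzero(independent & (freq > 0.2) & (freq < 0.6))
        ci = int(candidates[0]) if candidates.size else int(np.argmin(np.abs(freq - 0.4)))
        causal_id = svs["id"].iat[ci]
        carrier = dosage[ci] >= 1
        ph = config.phenotype
        pheno = np.where(
            carrier,
            rng.random(n_samp) < ph.penetrance,
            rng.random(n_samp) < ph.phenocopy,
        ).astype(int)
        samples["phenotype"] = pheno

    # assemble matrix
    variants = pd.concat(
        [
            pd.DataFrame(
                {
                    "id": [f"snp_{i}" for i in range(n_snp)],
                    "chrom": chrom_arr,
                    "pos": pos_arr,
                    "type": "SNP",
                    "length": 1,
                }
            ),
            pd.DataFrame(
                {
                    "id": svs["id"],
                    "chrom": svs["chrom"],
                    "pos": svs["start"],
                    "type": "SV",
                    "length": svs["length"],
                }
            ),
        ],
        ignore_index=True,
    )
    H = np.concatenate([H_snp, H_sv], axis=0)
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    H = H[order]
    G = H.sum(axis=2).astype(np.int8)
    if config.missing_rate > 0:
        G = G.copy()
        G[rng.random(G.shape) < config.missing_rate] = -1
    gm = GenotypeMatrix(variants, samples, G, H)
    ibd = pd.DataFrame(
        ibd_rows, columns=["chrom", "start", "end", "sample_a", "sample_b"]
    )
    truth = replace(truth, causal_sv_id=causal_id, tagged_sv_ids=tuple(tagged_ids))
    return gm, ibd, truth


# ---------------------------------------------------------------------------
# Annotation intervals with planted enrichment
# ---------------------------------------------------------------------------


def simulate_annotations(
    truth: TruthSet,
    config: SimulationConfig,
    reference: Reference,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Annotation interval classes; the target class is constructed so
    SV overlap exceeds the uniform expectation by the configured fold."""
    rng = rng or np.random.default_rng(config.seed + 4)
    spec = config.enrichment
    chrom_lengths = reference.chrom_lengths
    total = sum(chrom_lengths.values())
    n_filler = int(spec.class_coverage * total / spec.interval_length)
    out: dict[str, pd.DataFrame] = {}
    chrom_names = list(chrom_lengths)
    for cls in spec.classes:
        rows = []
        n_planted = 0
        if cls == spec.target_class and len(truth.svs):
            target = min(1.0, spec.fold * spec.class_coverage)
            n_planted = int(round(target * len(truth.svs)))
            chosen = rng.choice(len(truth.svs), size=n_planted, replace=False)
            for vi in chosen:
                chrom = truth.svs["chrom"].iat[vi]
                center = int(truth.svs["start"].iat[vi])
                half = spec.interval_length // 2
                start = max(0, center - half)
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": min(chrom_lengths[chrom], start + spec.interval_length),
                    }
                )
        for _ in range(max(0, n_filler - n_planted)):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            start = int(rng.integers(0, chrom_lengths[chrom] - spec.interval_length))
            rows.append(
                {"chrom": chrom, "start": start, "end": start + spec.interval_length}
            )
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out[cls] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    reference: Reference
    truth: TruthSet
    callsets: dict
    genotypes: "object"  # GenotypeMatrix
    ibd_segments: pd.DataFrame
    annotations: dict[str, pd.DataFrame]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run every generator stage from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config, rng)
    truth = plant_svs(reference, config, rng)
    callsets = simulate_callsets(truth, config, rng)
    gm, ibd, truth = simulate_population(truth, config, reference, rng)
    annotations = simulate_annotations(truth, config, reference, rng)
    truth = replace(
        truth, annotations=annotations, enrichment_fold=config.enrichment.fold
    )
    return SimulatedCohort(config, reference, truth, callsets, gm, ibd, annotations)
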