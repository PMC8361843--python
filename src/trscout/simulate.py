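"""Noisy long-read simulator with exact truth alignments.

The simulator builds toy references — one synthetic contig per disease
locus, a pure repeat tract embedded in random flanks — plants alleles of
chosen sizes by replacing the tract with the desired number of motif
copies, and emits reads with i.i.d. substitution/insertion/deletion
errors (defaults total 12%, indel-dominated, as is typical for raw long
reads).  Because every error is logged, the exact alignment of each read
to the *reference* is known and written as a truth SAM: reads crossing an
expanded tract carry an ``I`` operation of the expansion size adjusted by
local indel errors, and when the insertion exceeds
``split_emit_threshold`` the read is emitted as a soft-clipped primary /
supplementary pair instead, mimicking how aligners fragment reads around
long repeat insertions.

Read names encode the ground truth (contig, start, mappability, serial,
haplotype, allele size, aligned reference span), so downstream benchmark
code can recover the spanning-read truth sets without the FASTA.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pysam

from .model import AlignmentRecord, TRLocus
from .params import Parameters
from .trfind import canonical_motif, decode, encode, revcomp

# The 17 disease loci used throughout the simulations: contig name
# (the chromosome the real locus lives on), gene, motif, and the length
# of the repeat tract in the reference genome.
DISEASE_LOCI: tuple[tuple[str, str, str, int], ...] = (
    ("chr2", "HOXD13", "GGC", 42),
    ("chr3", "ATXN7", "CAG", 30),
    ("chr4", "HTT", "CAG", 57),
    ("chr5", "PPP2R2B", "CTG", 30),
    ("chr6", "ATXN1", "CTG", 87),
    ("chr7", "HOXA13", "CGC", 42),
    ("chr9", "FXN", "GAA", 18),
    ("chr11", "CBL", "CGG", 33),
    ("chr12", "ATXN2", "CTG", 69),
    ("chr13", "ATXN8", "CTG", 45),
    ("chr14", "ATXN3", "CTG", 24),
    ("chr16", "JPH3", "CTG", 42),
    ("chr19", "DMPK", "CAG", 60),
    ("chr20", "NOP56", "GGCCTG", 42),
    ("chr21", "CSTB", "CGCGGGGCGGGG", 36),
    ("chr22", "ATXN10", "ATTCT", 70),
    ("chrX", "FMR1", "CGG", 60),
)

FMR1_PM_COPIES = 150
FMR1_FM_COPIES = 500


@dataclass
class SimParams:
    """Simulation knobs.

    Error-rate defaults total 12% (substitution 3%, insertion 4%,
    deletion 5%); read lengths are log-normal with a 5 kb median, scaled
    to the toy contigs.
    """

    flank_len: int = 20000
    read_len_median: int = 5000
    read_len_sigma: float = 0.35
    read_len_min: int = 300
    depth: float = 30.0
    sub_rate: float = 0.03
    ins_rate: float = 0.04
    del_rate: float = 0.05
    split_emit_threshold: int = 1000
    min_aligned_segment: int = 50

    def __post_init__(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must be non-negative and sum to < 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class TruthRow:
    """Ground truth for one simulated read."""

    read_id: str
    chrom: str
    ref_start: int
    ref_aln_len: int
    mappable: bool
    haplotype: str
    allele_len: int
    hap_start: int
    hap_end: int
    strand: str
    err_pos: np.ndarray = field(repr=False, default=None)
    err_op: np.ndarray = field(repr=False, default=None)  # 0 sub, 1 ins, 2 del
    err_char: np.ndarray = field(repr=False, default=None)


def make_read_name(chrom: str, ref_start: int, mappable: bool, serial: int,
                   haplotype: str, allele_len: int, ref_aln_len: int) -> str:
    flag = "aligned" if mappable else "unaligned"
    return f"{chrom}_{ref_start}_{flag}_{serial}_{haplotype}_{allele_len}_{ref_aln_len}"


def decode_read_name(name: str) -> dict:
    chrom, start, flag, serial, hap, allele, aln_len = name.rsplit("_", 6)
    return {
        "chrom": chrom,
        "ref_start": int(start),
        "mappable": flag == "aligned",
        "serial": int(serial),
        "haplotype": hap,
        "allele_len": int(allele),
        "ref_aln_len": int(aln_len),
    }


def random_flank(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, length))


def build_toy_reference(loci_spec=DISEASE_LOCI, flank_len: int = 20000,
                        seed: int = 0) -> tuple[dict[str, str], list[TRLocus]]:
    """One contig per locus: random flank + pure repeat tract + random flank."""
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    loci: list[TRLocus] = []
    for chrom, gene, motif, ref_len in loci_spec:
        tract = (motif * (ref_len // len(motif) + 1))[:ref_len]
        left = random_flank(rng, flank_len)
        right = random_flank(rng, flank_len)
        reference[chrom] = left + tract + right
        loci.append(
            TRLocus(chrom=chrom, start=flank_len, end=flank_len + ref_len,
                    motifs=[motif])
        )
    return reference, loci


def build_haplotype(reference, locus: TRLocus, motif: str,
                    copies: int) -> tuple[str, tuple[int, int, int]]:
    """Replace the locus tract with ``copies`` motif copies.

    Returns the modified sequence and the coordinate map
    (locus_start, ref_tract_len, new_tract_len) needed to convert
    haplotype positions back to reference positions.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    chrom_seq = reference[locus.chrom]
    if not isinstance(chrom_seq, str):
        chrom_seq = str(chrom_seq)
    if locus.end > len(chrom_seq):
        raise ValueError("locus outside reference")
    new_tract = motif * copies
    hap = chrom_seq[: locus.start] + new_tract + chrom_seq[locus.end :]
    return hap, (locus.start, locus.end - locus.start, len(new_tract))


def build_haplotype_len(reference, locus: TRLocus, motif: str,
                        allele_len: int) -> tuple[str, tuple[int, int, int]]:
    """Like :func:`build_haplotype` but with a target tract length in bp
    (rounded down to whole copies when not a multiple of the motif)."""
    copies = allele_len // len(motif)
    return build_haplotype(reference, locus, motif, copies)


def hap_to_ref(pos: int, cmap: tuple[int, int, int]) -> int:
    ls, ref_len, new_len = cmap
    if pos < ls:
        return pos
    if pos < ls + new_len:
        return ls + min(pos - ls, ref_len)
    return pos - (new_len - ref_len)


_OPCODES = {"M": 0, "I": 1, "D": 2, "S": 4}


class _ReadBuild:
    """Token-level construction of one read and its truth alignment."""

    __slots__ = ("seq", "segments", "err", "n_src")

    def __init__(self, seq, segments, err, n_src):
        self.seq = seq  # emitted read, reference orientation (str)
        self.segments = segments  # list of (ref_start, cigar, is_supp)
        self.err = err  # (err_pos, err_op, err_char)
        self.n_src = n_src


def _build_read(hap_arr: np.ndarray, s: int, e: int,
                cmap: tuple[int, int, int], rng: np.random.Generator,
                sp: SimParams) -> _ReadBuild:
    ls, ref_len, new_len = cmap
    src = hap_arr[s:e]
    n0 = len(src)
    pos = np.arange(s, e)
    aligned_tract = min(ref_len, new_len)
    in_tract = (pos >= ls) & (pos < ls + new_len)
    # region 1 = part of the expansion insertion (beyond the ref tract)
    region = (in_tract & (pos - ls >= aligned_tract)).astype(np.int8)
    ref_pos = np.where(
        pos < ls,
        pos,
        np.where(in_tract, ls + np.minimum(pos - ls, aligned_tract),
                 pos - (new_len - ref_len)),
    )

    pd, ps, pi = sp.del_rate, sp.sub_rate, sp.ins_rate
    r = rng.random(n0)
    del_m = r < pd
    sub_m = (~del_m) & (r < pd + ps)
    ins_m = (~del_m) & (~sub_m) & (r < pd + ps + pi)
    sub_chars = ((src + rng.integers(1, 4, n0)) % 4).astype(np.uint8)
    ins_chars_all = rng.integers(0, 4, n0).astype(np.uint8)

    t1 = np.where(del_m & (region == 1), 0, 1)
    t2 = ins_m.astype(np.int64)
    counts = t1 + t2
    total = int(counts.sum())
    starts = np.zeros(n0, dtype=np.int64)
    np.cumsum(counts[:-1], out=starts[1:])

    tok_op = np.zeros(total, dtype=np.int8)
    tok_region = np.zeros(total, dtype=np.int8)
    tok_char = np.full(total, 255, dtype=np.uint8)
    tok_ref = np.zeros(total, dtype=np.int64)

    has1 = t1 == 1
    p1 = starts[has1]
    base_op = np.where(del_m, 2, np.where(region == 1, 1, 0)).astype(np.int8)
    tok_op[p1] = base_op[has1]
    tok_region[p1] = region[has1]
    tok_ref[p1] = ref_pos[has1]
    kept = has1 & ~del_m
    char1 = np.where(sub_m, sub_chars, src)
    tok_char[starts[kept]] = char1[kept]

    pins = (starts + t1)[ins_m]
    tok_op[pins] = 1
    tok_region[pins] = region[ins_m]
    tok_ref[pins] = ref_pos[ins_m]
    tok_char[pins] = ins_chars_all[ins_m]

    read_arr = tok_char[tok_char != 255]
    seq = decode(read_arr)

    err_pos = np.flatnonzero(sub_m | ins_m | del_m).astype(np.int32)
    op_arr = np.where(sub_m, 0, np.where(ins_m, 1, 2))[err_pos].astype(np.int8)
    char_arr = np.where(sub_m, sub_chars, ins_chars_all)[err_pos].astype(np.uint8)
    err = (err_pos, op_arr, char_arr)

    # split the token stream into aligned segments
    is_read = tok_char != 255
    read_idx = np.cumsum(is_read) - 1  # emitted-read index per token
    exp_tokens = tok_region == 1
    insertion_size = new_len - ref_len
    segments: list[tuple[int, list[tuple[str, int]], bool]] = []

    def _segment(t0: int, t1_: int, supp: bool):
        """Trim to M-bounded token range [t0,t1_) and emit a record."""
        ops = tok_op[t0:t1_]
        m_idx = np.flatnonzero(ops == 0)
        if len(m_idx) < sp.min_aligned_segment:
            return
        a, b = t0 + int(m_idx[0]), t0 + int(m_idx[-1]) + 1
        lead_clip = int(read_idx[a - 1] + 1) if a > 0 else 0
        n_read = len(read_arr)
        end_read = int(read_idx[b - 1] + 1)
        tail_clip = n_read - end_read
        cig: list[tuple[str, int]] = []
        if lead_clip:
            cig.append(("S", lead_clip))
        seg_ops = tok_op[a:b]
        # run-length encode M/I/D
        change = np.flatnonzero(np.diff(seg_ops)) + 1
        bounds = np.concatenate([[0], change, [len(seg_ops)]])
        for x, y in zip(bounds[:-1], bounds[1:]):
            cig.append(("MID"[seg_ops[x]], int(y - x)))
        if tail_clip:
            cig.append(("S", tail_clip))
        segments.append((int(tok_ref[a]), cig, supp))

    if insertion_size > sp.split_emit_threshold and exp_tokens.any():
        b0 = int(np.argmax(exp_tokens))
        b1 = total - int(np.argmax(exp_tokens[::-1]))
        _segment(0, b0, False)
        _segment(b1, total, len(segments) > 0)
    else:
        _segment(0, total, False)

    return _ReadBuild(seq, segments, err, n0)


def apply_error_log(src_seq: str, err_pos, err_op, err_char) -> str:
    """Reconstruct the emitted read from the error-free source read."""
    src = encode(src_seq)
    out = []
    errors = {int(p): (int(o), int(c)) for p, o, c in zip(err_pos, err_op, err_char)}
    for i, c in enumerate(src):
        if i in errors:
            op, ch = errors[i]
            if op == 0:  # substitution
                out.append(ch)
            elif op == 1:  # insertion after this base
                out.append(int(c))
                out.append(ch)
            # op == 2: deletion, emit nothing
        else:
            out.append(int(c))
    return decode(out)


@dataclass
class Haplotype:
    label: str
    chrom: str
    seq: str
    cmap: tuple[int, int, int]
    weight: float
    allele_len: int


@dataclass
class Sample:
    """One simulated sample: reads + truth files + planted alleles."""

    name: str
    reads_fasta: str
    truth_sam: str
    truth_tsv: str
    truth: list[TruthRow]
    planted: dict[str, list[int]]  # chrom -> allele tract lengths
    planted_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def alignments(self, params: Optional[Parameters] = None) -> Iterator[AlignmentRecord]:
        from .alignio import read_alignments

        yield from read_alignments(self.truth_sam, params=params)


@dataclass
class ExperimentBundle:
    design: str
    outdir: str
    ref_fasta: str
    reference: dict[str, str]
    loci: list[TRLocus]
    loci_bed: str
    samples: list[Sample]


def _sam_header(reference: dict[str, str]):
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in reference.items()],
    }


class _SampleWriter:
    def __init__(self, name: str, outdir: str, reference: dict[str, str]):
        self.name = name
        self.reads_fasta = os.path.join(outdir, f"{name}.reads.fa")
        self.truth_sam = os.path.join(outdir, f"{name}.truth.sam")
        self.truth_tsv = os.path.join(outdir, f"{name}.truth.tsv")
        self.reference = reference
        self.chrom_ids = {c: i for i, c in enumerate(reference)}
        self.records: list[tuple[int, int, object]] = []
        self.truth: list[TruthRow] = []
        self.fasta_entries: list[tuple[str, str]] = []

    def add_read(self, build: _ReadBuild, chrom: str, hap: Haplotype,
                 s: int, e: int, serial: int, strand: str):
        mappable = bool(build.segments)
        if mappable:
            ref_start = min(seg[0] for seg in build.segments)
            ref_end = max(
                seg_ref + sum(n for op, n in cig if op in "MD")
                for seg_ref, cig, _ in build.segments
            )
            aln_len = ref_end - ref_start
        else:
            ref_start = hap_to_ref(s, hap.cmap)
            aln_len = 0
        name = make_read_name(chrom, ref_start, mappable, serial, hap.label,
                              hap.allele_len, aln_len)
        err_pos, err_op, err_char = build.err
        self.truth.append(
            TruthRow(
                read_id=name, chrom=chrom, ref_start=ref_start,
                ref_aln_len=aln_len, mappable=mappable, haplotype=hap.label,
                allele_len=hap.allele_len, hap_start=s, hap_end=e,
                strand=strand, err_pos=err_pos, err_op=err_op, err_char=err_char,
            )
        )
        fasta_seq = build.seq if strand == "+" else revcomp(build.seq)
        self.fasta_entries.append((name, fasta_seq))
        for seg_ref, cig, supp in build.segments:
            flag = 0
            if strand == "-":
                flag |= 16
            if supp:
                flag |= 2048
            cigtuples = [(_OPCODES[op], n) for op, n in cig]
            self.records.append(
                (self.chrom_ids[chrom], seg_ref,
                 (name, flag, chrom, seg_ref, cigtuples, build.seq))
            )

    def finish(self) -> None:
        with open(self.reads_fasta, "w") as fh:
            for name, seq in self.fasta_entries:
                fh.write(f">{name}\n{seq}\n")
        header = _sam_header(self.reference)
        self.records.sort(key=lambda r: (r[0], r[1]))
        with pysam.AlignmentFile(self.truth_sam, "wh", header=header) as out:
            for _, _, (name, flag, chrom, pos, cig, seq) in self.records:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.flag = flag
                a.reference_id = self.chrom_ids[chrom]
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigartuples = cig
                a.query_sequence = seq
                out.write(a)
        with open(self.truth_tsv, "w") as fh:
            fh.write("#read_id\tchrom\tref_start\tref_aln_len\tmappable"
                     "\thaplotype\tallele_len\thap_start\thap_end\tstrand\n")
            for row in self.truth:
                fh.write(
                    f"{row.read_id}\t{row.chrom}\t{row.ref_start}\t"
                    f"{row.ref_aln_len}\t{int(row.mappable)}\t{row.haplotype}\t"
                    f"{row.allele_len}\t{row.hap_start}\t{row.hap_end}\t{row.strand}\n"
                )


def simulate_reads(
    haplotypes: Sequence[Haplotype],
    writer: _SampleWriter,
    rng: np.random.Generator,
    sp: SimParams,
    serial_start: int = 0,
) -> int:
    """Emit reads over weighted haplotypes at SimParams.depth coverage."""
    weights = [h.weight for h in haplotypes]
    if abs(sum(weights) - 1.0) > 1e-6:
        raise ValueError("haplotype weights must sum to 1")
    serial = serial_start
    for hap in haplotypes:
        hap_arr = encode(hap.seq)
        hap_len = len(hap_arr)
        target = sp.depth * hap.weight * hap_len
        emitted = 0.0
        while emitted < target:
            length = int(round(sp.read_len_median
                               * np.exp(sp.read_len_sigma * rng.standard_normal())))
            length = max(sp.read_len_min, min(length, hap_len))
            s = int(rng.integers(0, hap_len - length + 1))
            e = s + length
            strand = "+" if rng.random() < 0.5 else "-"
            build = _build_read(hap_arr, s, e, hap.cmap, rng, sp)
            writer.add_read(build, hap.chrom, hap, s, e, serial, strand)
            serial += 1
            emitted += length
    return serial


def _spanning_reads(hap: Haplotype, n_reads: int, writer: _SampleWriter,
                    rng: np.random.Generator, sp: SimParams, serial: int,
                    margin: int = 1000) -> int:
    """Emit exactly ``n_reads`` reads guaranteed to span the locus tract
    with at least ``margin`` bp of flank on both sides."""
    hap_arr = encode(hap.seq)
    ls, _, new_len = hap.cmap
    span = new_len + 2 * margin
    hap_len = len(hap_arr)
    for _ in range(n_reads):
        length = int(round(sp.read_len_median
                           * np.exp(sp.read_len_sigma * rng.standard_normal())))
        length = max(span + 200, min(max(length, span + 200), hap_len))
        lo = max(0, ls + new_len + margin - length)
        hi = min(ls - margin, hap_len - length)
        s = int(rng.integers(lo, hi + 1))
        e = s + length
        strand = "+" if rng.random() < 0.5 else "-"
        build = _build_read(hap_arr, s, e, hap.cmap, rng, sp)
        writer.add_read(build, hap.chrom, hap, s, e, serial, strand)
        serial += 1
    return serial


def truth_spanning_reads(truth: Sequence[TruthRow], locus: TRLocus,
                         expansion_size: int,
                         params: Optional[Parameters] = None) -> set[str]:
    """Ground-truth spanning reads for one locus.

    A read qualifies when it is mappable and its simulated interval
    covers the expanded locus footprint with at least ``truth_overlap_min``
    margin on both sides.
    """
    if params is None:
        params = Parameters()
    m = params.truth_overlap_min
    lo = locus.start - m
    hi = locus.end + expansion_size + m
    out = set()
    for row in truth:
        if not row.mappable or row.chrom != locus.chrom:
            continue
        if row.hap_start <= lo and row.hap_end >= hi:
            out.add(row.read_id)
    return out


def truth_spanning_by_allele(truth: Sequence[TruthRow], locus: TRLocus,
                             params: Optional[Parameters] = None) -> dict[str, set[str]]:
    """Spanning-read truth sets per haplotype, each with its own
    expansion size (allele length minus the reference tract length)."""
    if params is None:
        params = Parameters()
    by_hap: dict[str, set[str]] = {}
    haps = {row.haplotype: row.allele_len for row in truth if row.chrom == locus.chrom}
    for hap, allele_len in haps.items():
        expansion = allele_len - locus.ref_len
        rows = [r for r in truth if r.haplotype == hap and r.chrom == locus.chrom]
        by_hap[hap] = truth_spanning_reads(rows, locus, expansion, params)
    return by_hap


def _write_reference(reference: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_loci_bed(loci: Sequence[TRLocus], path: str) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                     + ",".join(locus.motifs) + "\n")


def make_experiment(design: str, outdir: str, seed: int,
                    sim: Optional[SimParams] = None,
                    **kwargs) -> ExperimentBundle:
    """Build a full simulated experiment.

    Designs
    -------
    ``het17``: 17 toy disease loci, each heterozygous reference +
    expanded allele (default 500 bp tract) at ~30X combined coverage.

    ``resolve_grid``: bi- or tri-allelic samples over base tract sizes
    {100, 500, 1000, 2000} x separations {100, 200} bp at 10X per allele
    (8 kb flanks, mirroring a locus-targeted simulation).

    ``mosaic_series``: FMR1 premutation/full-mutation mixtures; eleven
    30-read samples from 100% PM (150 CGG copies) to 100% FM (500
    copies) in 10% steps, ten replicates each.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    if design == "het17":
        return _design_het17(outdir, rng, sim, **kwargs)
    if design == "resolve_grid":
        return _design_resolve_grid(outdir, rng, sim, **kwargs)
    if design == "mosaic_series":
        return _design_mosaic(outdir, rng, sim, **kwargs)
    raise ValueError(f"unknown design {design!r}")


def _design_het17(outdir, rng, sim, allele_size: int = 500,
                  loci_spec=DISEASE_LOCI) -> ExperimentBundle:
    sp = sim or SimParams()
    reference, loci = build_toy_reference(loci_spec, sp.flank_len,
                                          seed=int(rng.integers(2**31)))
    ref_fasta = os.path.join(outdir, "ref.fa")
    loci_bed = os.path.join(outdir, "loci.bed")
    _write_reference(reference, ref_fasta)
    _write_loci_bed(loci, loci_bed)
    writer = _SampleWriter("het17", outdir, reference)
    planted = {}
    serial = 0
    for (chrom, gene, motif, ref_len), locus in zip(loci_spec, loci):
        exp_seq, exp_map = build_haplotype_len(reference, locus, motif, allele_size)
        haps = [
            Haplotype("h0", chrom, reference[chrom],
                      (locus.start, ref_len, ref_len), 0.5, ref_len),
            Haplotype("h1", chrom, exp_seq, exp_map, 0.5, exp_map[2]),
        ]
        planted[chrom] = [ref_len, exp_map[2]]
        serial = simulate_reads(haps, writer, rng, sp, serial)
    writer.finish()
    sample = Sample("het17", writer.reads_fasta, writer.truth_sam,
                    writer.truth_tsv, writer.truth, planted)
    return ExperimentBundle("het17", outdir, ref_fasta, reference, loci,
                            loci_bed, [sample])


def _design_resolve_grid(outdir, rng, sim,
                         bases: Sequence[int] = (100, 500, 1000, 2000),
                         seps: Sequence[int] = (100, 200),
                         n_alleles: int = 2,
                         depth_per_allele: float = 10.0,
                         loci_spec=DISEASE_LOCI) -> ExperimentBundle:
    sp = sim or SimParams(flank_len=8000)
    reference, loci = build_toy_reference(loci_spec, sp.flank_len,
                                          seed=int(rng.integers(2**31)))
    ref_fasta = os.path.join(outdir, "ref.fa")
    loci_bed = os.path.join(outdir, "loci.bed")
    _write_reference(reference, ref_fasta)
    _write_loci_bed(loci, loci_bed)
    samples = []
    for base in bases:
        for sep in seps:
            name = f"base{base}_sep{sep}"
            sp_sample = replace(sp, depth=depth_per_allele * n_alleles)
            writer = _SampleWriter(name, outdir, reference)
            planted = {}
            serial = 0
            for (chrom, gene, motif, ref_len), locus in zip(loci_spec, loci):
                haps = []
                sizes = []
                for i in range(n_alleles):
                    size = base + i * sep
                    seq, cmap = build_haplotype_len(reference, locus, motif, size)
                    haps.append(Haplotype(f"h{i}", chrom, seq, cmap,
                                          1.0 / n_alleles, cmap[2]))
                    sizes.append(cmap[2])
                planted[chrom] = sizes
                serial = simulate_reads(haps, writer, rng, sp_sample, serial)
            writer.finish()
            samples.append(Sample(name, writer.reads_fasta, writer.truth_sam,
                                  writer.truth_tsv, writer.truth, planted))
    return ExperimentBundle("resolve_grid", outdir, ref_fasta, reference,
                            loci, loci_bed, samples)


def _design_mosaic(outdir, rng, sim,
                   fractions: Sequence[float] = tuple(i / 10 for i in range(11)),
                   replicates: int = 10,
                   n_reads: int = 30,
                   pm_copies: int = FMR1_PM_COPIES,
                   fm_copies: int = FMR1_FM_COPIES) -> ExperimentBundle:
    fmr1 = [spec for spec in DISEASE_LOCI if spec[1] == "FMR1"]
    sp = sim or SimParams()
    reference, loci = build_toy_reference(fmr1, sp.flank_len,
                                          seed=int(rng.integers(2**31)))
    locus = loci[0]
    chrom, _, motif, ref_len = fmr1[0]
    ref_fasta = os.path.join(outdir, "ref.fa")
    loci_bed = os.path.join(outdir, "loci.bed")
    _write_reference(reference, ref_fasta)
    _write_loci_bed(loci, loci_bed)
    pm_seq, pm_map = build_haplotype(reference, locus, motif, pm_copies)
    fm_seq, fm_map = build_haplotype(reference, locus, motif, fm_copies)
    pm = Haplotype("PM", chrom, pm_seq, pm_map, 0.5, pm_map[2])
    fm = Haplotype("FM", chrom, fm_seq, fm_map, 0.5, fm_map[2])
    samples = []
    for frac in fractions:
        n_fm = int(round(n_reads * frac))
        n_pm = n_reads - n_fm
        for rep in range(replicates):
            name = f"fm{int(round(frac * 100)):03d}_rep{rep}"
            writer = _SampleWriter(name, outdir, reference)
            serial = _spanning_reads(pm, n_pm, writer, rng, sp, 0)
            _spanning_reads(fm, n_fm, writer, rng, sp, serial)
            writer.finish()
            samples.append(
                Sample(name, writer.reads_fasta, writer.truth_sam,
                       writer.truth_tsv, writer.truth,
                       {chrom: sorted({pm_map[2], fm_map[2]})},
                       planted_counts={chrom: {"PM": n_pm, "FM": n_fm}})
            )
    return ExperimentBundle("mosaic_series", outdir, ref_fasta, reference,
                            loci, loci_bed, samples)
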