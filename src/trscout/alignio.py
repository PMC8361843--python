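"""Alignment, reference and locus I/O.

SAM/BAM parsing goes through pysam; internal coordinates are 0-based
half-open (BED convention), with SAM's 1-based POS converted at this
boundary.  The genotype table is a tab-separated file with one row per
supporting read and a single '#'-prefixed header line.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

import pysam

from .model import Allele, AlignmentRecord, Genotype, ReadCall, TRLocus
from .params import Parameters  # noqa: F401  (re-exported module surface)
from .trfind import canonical_motif

_CIGAR_OPS = "MIDNSHP=X"


def _record_from_pysam(a: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = [(_CIGAR_OPS[op], ln) for op, ln in (a.cigartuples or [])]
    seq = a.query_sequence  # None for SEQ='*' (e.g. hard-clipped supplementary)
    return AlignmentRecord(
        read_id=a.query_name,
        ref_name=a.reference_name,
        ref_start=a.reference_start,
        strand="-" if a.is_reverse else "+",
        mapq=a.mapping_quality,
        cigar=cigar,
        read_seq=seq,
        is_supplementary=a.is_supplementary,
    )


def read_alignments(
    path: str,
    region: Optional[tuple[str, int, int]] = None,
    params: Optional[Parameters] = None,
    include_secondary: bool = False,
) -> Iterator[AlignmentRecord]:
    """Stream mapped alignment records from a SAM/BAM file.

    ``region`` is 0-based half-open; without an index the file is scanned
    linearly and filtered.  Unmapped records are skipped; secondary
    alignments are skipped by default (insertion detection uses primary
    and supplementary records only).
    """
    if params is None:
        params = Parameters()
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if region is not None and fh.has_index():
            it = fh.fetch(region[0], region[1], region[2])
        else:
            it = fh
        for a in it:
            if a.is_unmapped:
                continue
            if a.is_secondary and not include_secondary:
                continue
            if a.mapping_quality < params.mapq_min:
                continue
            if region is not None and not fh.has_index():
                chrom, start, end = region
                if a.reference_name != chrom:
                    continue
                if a.reference_end <= start or a.reference_start >= end:
                    continue
            yield _record_from_pysam(a)


def load_loci_bed(path: str, params: Optional[Parameters] = None,
                  strict: bool = True) -> list[TRLocus]:
    """Read target loci from a BED file with >= 4 columns:
    chrom, start, end, motif(s); multiple motifs comma-separated."""
    if params is None:
        params = Parameters()
    loci: list[TRLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            chrom, start_s, end_s, motif_s = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            motifs = []
            for m in motif_s.split(","):
                m = m.strip().upper()
                if not m or any(b not in "ACGT" for b in m):
                    raise ValueError(f"{path}:{lineno}: invalid motif {m!r}")
                if strict and not (
                    params.motif_len_min <= len(m) <= params.motif_len_max
                ):
                    raise ValueError(
                        f"{path}:{lineno}: motif length {len(m)} outside "
                        f"[{params.motif_len_min}, {params.motif_len_max}]"
                    )
                motifs.append(m)
            loci.append(TRLocus(chrom=chrom, start=start, end=end, motifs=motifs))
    return loci


_TSV_COLUMNS = [
    "chrom", "start", "end", "motif",
    "allele_index", "allele_size_bp", "allele_copy_number", "allele_support",
    "read_id", "read_size_bp", "read_copy_number", "read_tract_start",
]


def write_genotype_tsv(genotypes: Iterable[Genotype], path: str) -> None:
    """One row per supporting read; alleles sorted ascending by size."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for gt in genotypes:
            calls = {c.read_id: c for c in gt.calls}
            motif = ",".join(gt.locus.motifs)
            for idx, allele in enumerate(sorted(gt.alleles, key=lambda a: a.size)):
                for read_id in allele.members:
                    call = calls.get(read_id)
                    row = [
                        gt.locus.chrom, gt.locus.start, gt.locus.end, motif,
                        idx, f"{allele.size:g}", f"{allele.copy_number:g}",
                        allele.support, read_id,
                        call.repeat_size if call else "NA",
                        f"{call.copy_number:g}" if call else "NA",
                        call.read_tract_start if call else "NA",
                    ]
                    fh.write("\t".join(str(x) for x in row) + "\n")


def read_genotype_tsv(path: str) -> list[Genotype]:
    """Parse a genotype table written by :func:`write_genotype_tsv`."""
    rows = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        for line in fh:
            if not line.strip():
                continue
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    by_locus: dict[tuple, list[dict]] = {}
    for r in rows:
        by_locus.setdefault((r["chrom"], int(r["start"]), int(r["end"]), r["motif"]), []).append(r)
    genotypes = []
    for (chrom, start, end, motif), lrows in by_locus.items():
        locus = TRLocus(chrom=chrom, start=start, end=end, motifs=motif.split(","))
        alleles: dict[int, Allele] = {}
        calls = []
        for r in lrows:
            idx = int(r["allele_index"])
            a = alleles.setdefault(
                idx,
                Allele(
                    size=float(r["allele_size_bp"]),
                    copy_number=float(r["allele_copy_number"]),
                    support=int(r["allele_support"]),
                    members=[],
                ),
            )
            a.members.append(r["read_id"])
            if r["read_size_bp"] != "NA":
                calls.append(
                    ReadCall(
                        locus=locus,
                        read_id=r["read_id"],
                        repeat_size=int(r["read_size_bp"]),
                        copy_number=float(r["read_copy_number"]),
                        read_tract_start=int(r["read_tract_start"]),
                        method="spanning",
                    )
                )
        genotype = Genotype(
            locus=locus,
            alleles=[alleles[i] for i in sorted(alleles)],
            total_reads=sum(a.support for a in alleles.values()),
            calls=calls,
        )
        genotypes.append(genotype)
    genotypes.sort(key=lambda g: (g.locus.chrom, g.locus.start))
    return genotypes


def write_loci_bed(loci: Iterable[TRLocus], path: str) -> None:
    """Scan output: chrom, start, end, motif(s), support_events."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(locus.start),
                        str(locus.end),
                        ",".join(locus.motifs),
                        str(locus.support_events),
                    ]
                )
                + "\n"
            )


def fetch_ref(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence from a pyfaidx.Fasta, a dict of strings,
    or anything mapping chrom -> sliceable sequence."""
    start = max(0, start)
    seq = reference[chrom][start:end]
    if not isinstance(seq, str):
        seq = str(seq)
    return seq.upper()


def open_reference(path: str):
    """Open a FASTA reference with pyfaidx (builds the .fai if absent)."""
    import pyfaidx

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pyfaidx.Fasta(path, sequence_always_upper=True)
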