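"""Tunable parameters shared across the scan, genotype and benchmark stages.

All coordinates handled with these parameters are 0-based half-open.
Defaults follow the conventions of long-read tandem-repeat genotyping:
insertions are only interesting once they exceed ``min_ins_size``,
an insertion counts as a repeat expansion only when at least
``insertion_purity_min`` of it is a single tandem repeat, and genotypes
are mixtures of at most ``max_alleles`` Gaussian components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Parameters:
    """Knobs for the whole pipeline.

    Attributes
    ----------
    min_ins_size:
        Minimum insertion length (bp) considered by the genome scan.
    insertion_purity_min:
        Fraction of an insertion that must be covered by tracts of a single
        (canonical) motif for the insertion to be kept.
    genomic_tract_purity_min:
        Purity required of a tract extracted from an assembly scaffold
        before its size is reported.
    flank_probe_len:
        Length (bp) of the reference flank probes used to locate a locus
        in an assembly.
    rescue_flank_len:
        Length (bp) of the reference flank aligned into a clipped read to
        recover a missing repeat boundary.
    truth_overlap_min:
        Margin (bp) a simulated read must cover on both sides of an
        expansion to count as a ground-truth spanning read.
    match_abs_tol / match_rel_tol:
        Allele-match rule: called and truth allele agree when they differ
        by at most ``match_abs_tol`` bp or by at most ``match_rel_tol``
        of the truth allele size.
    max_alleles:
        Maximum number of Gaussian components tried during genotyping.
    ks_alpha:
        Significance level for the two-sample Kolmogorov-Smirnov test.
    motif_len_min / motif_len_max:
        Motif sizes (bp) considered; homopolymers are excluded by default.
    min_support:
        Minimum reads per merged insertion cluster and per reported allele.
    merge_window:
        Maximum gap (bp) between insertion anchors merged into one cluster.
    split_max_ref_gap:
        Maximum reference-coordinate gap (bp) between paired split
        alignments interpreted as one insertion.
    min_flank_anchor:
        Aligned bases required on each side of a locus for a read to count
        as spanning.
    min_repeat_score:
        Report threshold for the wraparound alignment score
        (match +1, mismatch -1, indel -2).
    scan_window:
        Reference neighborhood (bp, each side of the insertion anchor)
        searched when delineating the genomic tandem-repeat locus.
    rescue_max_div:
        Maximum edit-distance fraction of the rescue flank tolerated for a
        successful rescue alignment.
    merge_close_means_bp:
        Gaussian components whose means differ by less than this are merged
        before reporting, to avoid spurious near-duplicate alleles.
    use_revcomp:
        Canonicalize motifs over reverse complements as well as rotations.
    mapq_min:
        Records below this mapping quality are skipped (0 keeps everything).
    random_seed:
        Seed for the Gaussian-mixture initializations.
    """

    min_ins_size: int = 100
    insertion_purity_min: float = 0.70
    genomic_tract_purity_min: float = 0.80
    flank_probe_len: int = 500
    rescue_flank_len: int = 80
    truth_overlap_min: int = 50
    match_abs_tol: int = 20
    match_rel_tol: float = 0.10
    max_alleles: int = 2
    ks_alpha: float = 0.05
    motif_len_min: int = 2
    motif_len_max: int = 100
    min_support: int = 2
    merge_window: int = 50
    split_max_ref_gap: int = 50
    min_flank_anchor: int = 100
    min_repeat_score: int = 8
    scan_window: int = 1000
    rescue_max_div: float = 0.15
    merge_close_means_bp: float = 2.0
    use_revcomp: bool = True
    mapq_min: int = 0
    random_seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.insertion_purity_min <= 1):
            raise ValueError("insertion_purity_min must be in (0, 1]")
        if not (0 < self.genomic_tract_purity_min <= 1):
            raise ValueError("genomic_tract_purity_min must be in (0, 1]")
        if self.motif_len_min < 1:
            raise ValueError("motif_len_min must be >= 1")
        if self.motif_len_max < self.motif_len_min:
            raise ValueError("motif_len_max must be >= motif_len_min")
        if self.max_alleles < 1:
            raise ValueError("max_alleles must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)
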