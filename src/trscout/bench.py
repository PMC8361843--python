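"""Benchmark machinery: truth-based read classification, assembly-derived
repeat sizing, the allele-match rule, and distribution comparison.

The allele-match criterion declares a called allele concordant with a
truth allele when the sizes differ by at most 20 bp or by at most 10% of
the truth allele size; heterozygous genotypes are compared after sorting,
smaller-with-smaller and larger-with-larger.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import edlib
import numpy as np
from scipy import stats

from .alignio import fetch_ref
from .model import Genotype, MatchResult, TRLocus
from .params import Parameters
from .trfind import find_repeats, tract_purity


def support_reads(genotype: Genotype) -> set[str]:
    out: set[str] = set()
    for allele in genotype.alleles:
        out.update(allele.members)
    return out


def classify_support_reads(genotype: Union[Genotype, set[str]],
                           truth_ids: set[str]) -> tuple[int, int, int]:
    """(TP, FP, FN) of a genotype's supporting reads against truth ids."""
    supports = genotype if isinstance(genotype, set) else support_reads(genotype)
    tp = len(supports & truth_ids)
    fp = len(supports - truth_ids)
    fn = len(truth_ids - supports)
    return tp, fp, fn


def sensitivity(tp: int, fn: int) -> float:
    return tp / (tp + fn) if tp + fn else 1.0


def _probe_placement(probe: str, scaffold: str, max_div: float = 0.2):
    """Unique end-to-end placement of a probe within one scaffold, or None."""
    if len(scaffold) < len(probe):
        return None
    res = edlib.align(probe, scaffold, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_div * len(probe):
        return None
    starts = sorted({s if s is not None else 0 for s, _ in res["locations"]})
    if starts[-1] - starts[0] > 10:
        return None  # ambiguous within the scaffold
    s, e = res["locations"][0]
    return (s if s is not None else 0), e + 1


def assembly_tr_size(assembly: dict, locus: TRLocus, reference,
                     params: Optional[Parameters] = None) -> list[int]:
    """Repeat-tract sizes of a locus in assembly scaffolds.

    Reference flanks (flank_probe_len bp each side of the locus) are
    placed in every scaffold; a size is reported per scaffold where both
    probes place uniquely end-to-end, as the gap between the left probe's
    end and the right probe's start, and only when the enclosed sequence
    is at least genomic_tract_purity_min pure single-motif repeat.
    """
    if params is None:
        params = Parameters()
    left = fetch_ref(reference, locus.chrom,
                     locus.start - params.flank_probe_len, locus.start)
    right = fetch_ref(reference, locus.chrom, locus.end,
                      locus.end + params.flank_probe_len)
    sizes = []
    for name in sorted(assembly):
        scaffold = assembly[name]
        if not isinstance(scaffold, str):
            scaffold = str(scaffold)
        lp = _probe_placement(left, scaffold)
        rp = _probe_placement(right, scaffold)
        if lp is None or rp is None:
            continue
        size = rp[0] - lp[1]
        if size < 0:
            continue
        tract = scaffold[lp[1] : rp[0]]
        if size == 0:
            continue
        purity = tract_purity(tract, find_repeats(tract, params))
        if purity >= params.genomic_tract_purity_min:
            sizes.append(size)
    return sizes


def _pair_matches(a: float, b_truth: float, params: Parameters) -> bool:
    d = abs(a - b_truth)
    return d <= params.match_abs_tol or d <= params.match_rel_tol * b_truth


def match_genotype(called: Union[Genotype, Sequence[float]],
                   truth_sizes: Sequence[float],
                   params: Optional[Parameters] = None,
                   locus: Optional[TRLocus] = None) -> MatchResult:
    """Compare called allele sizes with truth sizes (1-2 truth alleles).

    Both sides are sorted ascending and paired rank-for-rank; each pair
    is tested with the 20 bp / 10% rule (relative tolerance anchored on
    the truth allele).  A mono-allelic call against bi-allelic truth can
    classify as one_match at best.
    """
    if params is None:
        params = Parameters()
    if isinstance(called, Genotype):
        locus = called.locus
        called_sizes = sorted(called.allele_sizes())
    else:
        called_sizes = sorted(float(x) for x in called)
    truth = sorted(float(x) for x in truth_sizes)
    if not (1 <= len(truth) <= 2):
        raise ValueError("match_genotype expects 1-2 truth alleles")
    flags = [False] * len(truth)
    if len(called_sizes) >= len(truth):
        for i, t in enumerate(truth):
            flags[i] = _pair_matches(called_sizes[i], t, params)
    elif called_sizes:
        # single called allele vs two truth alleles: credit the best pairing
        c = called_sizes[0]
        matched = [i for i, t in enumerate(truth) if _pair_matches(c, t, params)]
        if matched:
            flags[matched[0]] = True
    n_true = sum(flags)
    if n_true == len(truth) and len(called_sizes) >= len(truth):
        classification = "both_match"
    elif n_true >= 1:
        classification = "one_match"
    else:
        classification = "no_match"
    return MatchResult(
        locus=locus,
        truth_alleles=truth,
        called_alleles=called_sizes,
        flags=flags,
        classification=classification,
    )


def ks_compare(sizes_a: Sequence[float], sizes_b: Sequence[float],
               params: Optional[Parameters] = None) -> tuple[float, float, bool]:
    """Two-sample Kolmogorov-Smirnov comparison of size distributions.

    Returns (D, p, significant-at-ks_alpha)."""
    if params is None:
        params = Parameters()
    if not len(sizes_a) or not len(sizes_b):
        raise ValueError("ks_compare: empty sample")
    res = stats.ks_2samp(np.asarray(sizes_a, float), np.asarray(sizes_b, float))
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < params.ks_alpha)


def summarize_matches(results: Sequence[MatchResult]) -> dict:
    """Call-level and allele-level concordance over a set of loci."""
    n = len(results)
    both = sum(r.classification == "both_match" for r in results)
    one = sum(r.classification == "one_match" for r in results)
    none = sum(r.classification == "no_match" for r in results)
    alleles_total = sum(len(r.truth_alleles) for r in results)
    alleles_matched = sum(sum(r.flags) for r in results)
    return {
        "n_loci": n,
        "both_match": both,
        "one_match": one,
        "no_match": none,
        "call_concordance": both / n if n else float("nan"),
        "allele_concordance": alleles_matched / alleles_total if alleles_total else float("nan"),
    }


def write_benchmark_tsv(results: Sequence[MatchResult], path: str) -> None:
    summary = summarize_matches(results)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\ttruth_alleles\tcalled_alleles\tclassification\n")
        for r in results:
            loc = r.locus
            fh.write(
                "\t".join(
                    [
                        loc.chrom if loc else ".",
                        str(loc.start) if loc else ".",
                        str(loc.end) if loc else ".",
                        ",".join(f"{x:g}" for x in r.truth_alleles),
                        ",".join(f"{x:g}" for x in r.called_alleles),
                        r.classification,
                    ]
                )
                + "\n"
            )
        for key, value in summary.items():
            fh.write(f"##{key}\t{value}\n")
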