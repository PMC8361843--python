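"""Genotyping stage: per-read repeat sizing and Gaussian-mixture allele
clustering.

For every read overlapping a target locus the repeat tract is the read
sequence sandwiched between the reference coordinates flanking the locus,
found by a CIGAR walk.  Reads clipped inside the locus (typical when an
expansion provokes a split alignment) are rescued by aligning a short
reference flank into the clipped sequence; a unique hit supplies the
missing boundary.  Per-read tract sizes are then clustered with 1-D
Gaussian mixtures (k = 1..max_alleles), the Akaike information criterion
selects the number of alleles, and each allele is reported as the exact
median size of its member reads.
"""

from __future__ import annotations

from collections import defaultdict
from statistics import median
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .alignio import fetch_ref
from .model import Allele, AlignmentRecord, Genotype, ReadCall, TRLocus
from .params import Parameters
from .trfind import find_repeats, motifs_match


def _boundary_walk(rec: AlignmentRecord, locus: TRLocus):
    """Map locus boundaries onto read coordinates via the CIGAR.

    Returns (r_start, r_end, left_anchor, right_anchor):
    r_start — read position just after the last aligned base left of the
    locus; r_end — read position of the first aligned base at or beyond
    locus.end; anchors — reference bases the alignment covers outside
    each boundary (deletion-robust, so a read covering N reference bases
    of flank anchors with N regardless of read-level indel errors).
    Either boundary may be None when the alignment does not reach it.
    """
    r_start = r_end = None
    left_anchor = max(0, locus.start - rec.ref_start)
    right_anchor = max(0, rec.ref_end - locus.end)
    rpos = rec.ref_start
    qpos = 0
    for op, n in rec.cigar:
        if op in "M=X":
            if rpos < locus.start:
                ov = min(n, locus.start - rpos)
                r_start = qpos + ov
            if rpos + n > locus.end and r_end is None:
                r_end = qpos + max(0, locus.end - rpos)
            rpos += n
            qpos += n
        elif op in "DN":
            rpos += n
        elif op in "IS":
            qpos += n
        # H: no read_seq bases
    return r_start, r_end, left_anchor, right_anchor


def extract_read_tract(rec: AlignmentRecord, locus: TRLocus,
                       params: Optional[Parameters] = None) -> Optional[tuple[int, int]]:
    """Read interval holding the repeat tract, for fully spanning reads.

    Requires both flanks aligned with >= min_flank_anchor aligned bases;
    otherwise None (the read is a candidate for clip rescue).
    """
    if params is None:
        params = Parameters()
    if rec.read_seq is None:
        return None
    r_start, r_end, left_anchor, right_anchor = _boundary_walk(rec, locus)
    if r_start is None or r_end is None:
        return None
    if left_anchor < params.min_flank_anchor or right_anchor < params.min_flank_anchor:
        return None
    if r_end < r_start:
        return None
    return r_start, r_end


def _unique_hit(flank: str, text: str, params: Parameters):
    """Best placement of ``flank`` inside ``text`` (edlib infix mode).

    Returns (start, end_exclusive) or None when the hit is too divergent
    or multiple distinct optimal placements exist (ambiguity rule)."""
    if not flank or not text or len(text) < len(flank) // 2:
        return None
    res = edlib.align(flank, text, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return None
    if res["editDistance"] > params.rescue_max_div * len(flank):
        return None
    locs = res["locations"]
    starts = sorted({s if s is not None else 0 for s, _ in locs})
    if starts[-1] - starts[0] > 10:  # genuinely different placements
        return None
    s, e = locs[0]
    return (s if s is not None else 0), e + 1


def rescue_clipped(rec: AlignmentRecord, locus: TRLocus, reference,
                   params: Optional[Parameters] = None) -> Optional[tuple[int, int]]:
    """Recover the repeat interval of a read clipped inside the locus.

    The reference flank immediately beyond the missing boundary
    (rescue_flank_len bp) is aligned into the clipped read sequence; a
    unique sufficiently-identical hit supplies the boundary, the other
    boundary coming from the aligned portion as usual.
    """
    if params is None:
        params = Parameters()
    if rec.read_seq is None:
        return None
    r_start, r_end, left_anchor, right_anchor = _boundary_walk(rec, locus)
    n = len(rec.read_seq)
    # clip lengths in stored-sequence coordinates (soft clips only carry seq)
    lead_s = rec.cigar[0][1] if rec.cigar and rec.cigar[0][0] == "S" else 0
    tail_s = rec.cigar[-1][1] if rec.cigar and rec.cigar[-1][0] == "S" else 0
    if r_end is None and r_start is not None and left_anchor >= params.min_flank_anchor:
        # read aligned on the left of the locus, clipped through the right
        if tail_s == 0:
            return None
        clip = rec.read_seq[n - tail_s :]
        flank = fetch_ref(reference, locus.chrom, locus.end,
                          locus.end + params.rescue_flank_len)
        hit = _unique_hit(flank, clip, params)
        if hit is None:
            return None
        r_end = (n - tail_s) + hit[0]
        if r_end < r_start:
            return None
        return r_start, r_end
    if r_start is None and r_end is not None and right_anchor >= params.min_flank_anchor:
        if lead_s == 0:
            return None
        clip = rec.read_seq[:lead_s]
        flank = fetch_ref(reference, locus.chrom,
                          locus.start - params.rescue_flank_len, locus.start)
        hit = _unique_hit(flank, clip, params)
        if hit is None:
            return None
        r_start = hit[1]
        if r_end < r_start:
            return None
        return r_start, r_end
    return None


def call_read(seq: str, motifs: Sequence[str], params: Optional[Parameters] = None,
              locus: Optional[TRLocus] = None, read_id: str = "",
              tract_offset: int = 0, method: str = "spanning") -> Optional[ReadCall]:
    """Size the repeat in an extracted read interval.

    The tract is screened for repeats; only tracts whose motif matches a
    target motif count.  ``repeat_size`` is the total bases covered by
    matching tracts, the copy number divides by the best-matching target
    motif's length.  None when nothing matches (no genotype from this
    read).
    """
    if params is None:
        params = Parameters()
    if not seq:
        return None
    hits = find_repeats(seq, params)
    matched = []
    for h in hits:
        for target in motifs:
            if motifs_match(h.motif, target, params):
                matched.append((h, target))
                break
    if not matched:
        return _call_read_direct(seq, motifs, params, locus, read_id,
                                 tract_offset, method)
    ivs = sorted((h.start, h.end) for h, _ in matched)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    if covered < 0.5 * len(seq):
        # a marginal accidental match inside a sequence that mostly does
        # NOT resemble the target repeat is no genotype evidence
        return _call_read_direct(seq, motifs, params, locus, read_id,
                                 tract_offset, method)
    best_hit, best_target = max(matched, key=lambda ht: ht[0].score)
    return ReadCall(
        locus=locus,
        read_id=read_id,
        repeat_size=covered,
        copy_number=covered / len(best_target),
        read_tract_start=tract_offset + min(s for s, _ in ivs),
        method=method,
    )


def _call_read_direct(seq, motifs, params, locus, read_id, tract_offset, method):
    """Last-resort sizing with the known target motif.

    Very short or very noisy tracts can defeat de-novo motif discovery
    (a handful of errors in a few copies).  In genotype mode the target
    motif is known, so the extracted sequence is aligned directly against
    a circular repeat of each target; the call stands only when the
    alignment clears the usual report threshold AND explains at least
    half of the extracted sequence — an insertion that does not resemble
    the target repeat still yields no call.
    """
    from .trfind import encode, revcomp, wrap_align_local

    best = None
    arr = encode(seq)
    for target in motifs:
        for motif in (target, revcomp(target)) if params.use_revcomp else (target,):
            score, start, end, m, cols, _ = wrap_align_local(arr, encode(motif))
            if score < params.min_repeat_score:
                continue
            span = end - start
            if span < 2 * len(target) or span < 0.5 * len(seq):
                continue
            if best is None or score > best[0]:
                best = (score, start, end, target)
    if best is None:
        return None
    score, start, end, target = best
    return ReadCall(
        locus=locus,
        read_id=read_id,
        repeat_size=end - start,
        copy_number=(end - start) / len(target),
        read_tract_start=tract_offset + start,
        method=method,
    )


def _merge_close_components(means, labels, k, tol):
    """Group component indices whose means lie within ``tol`` bp."""
    order = sorted(range(k), key=lambda c: means[c])
    groups = [[order[0]]]
    for c in order[1:]:
        if means[c] - means[groups[-1][-1]] < tol:
            groups[-1].append(c)
        else:
            groups.append([c])
    return groups


def fit_genotype(calls: Sequence[ReadCall],
                 params: Optional[Parameters] = None) -> Optional[Genotype]:
    """Cluster per-read repeat sizes into alleles.

    1-D Gaussian mixtures with k = 1..max_alleles components are fitted
    (per-component variances, 5 initializations, fixed seed) and the k
    with the smallest AIC wins, ties toward fewer alleles.  Reads go to
    their maximum-responsibility component; components supported by fewer
    than min_support reads are dropped, near-duplicate components (means
    < merge_close_means_bp apart) are merged.  Allele size is the exact
    median of member sizes.  Returns None when no allele clears the
    support threshold.
    """
    from sklearn.mixture import GaussianMixture

    if params is None:
        params = Parameters()
    if not calls:
        raise ValueError("fit_genotype: no read calls")
    sizes = np.array([c.repeat_size for c in calls], dtype=float).reshape(-1, 1)
    n = len(calls)
    if n == 1:
        if params.min_support > 1:
            return None
        call = calls[0]
        allele = Allele(size=float(call.repeat_size),
                        copy_number=float(call.copy_number),
                        support=1, members=[call.read_id])
        return Genotype(locus=call.locus, alleles=[allele], total_reads=1,
                        calls=list(calls))
    best_k, best_aic, best_model = 1, np.inf, None
    for k in range(1, min(params.max_alleles, n) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=5,
            reg_covar=1e-2,
            random_state=params.random_seed,
        )
        gm.fit(sizes)
        aic = gm.aic(sizes)
        if aic < best_aic:
            best_k, best_aic, best_model = k, aic, gm
    labels = best_model.predict(sizes)
    means = best_model.means_.ravel()
    groups = _merge_close_components(means, labels, best_k, params.merge_close_means_bp)
    alleles = []
    for comps in groups:
        idx = [i for i in range(n) if labels[i] in comps]
        if len(idx) < params.min_support:
            continue
        member_sizes = [calls[i].repeat_size for i in idx]
        member_cns = [calls[i].copy_number for i in idx]
        alleles.append(
            Allele(
                size=float(median(member_sizes)),
                copy_number=float(median(member_cns)),
                support=len(idx),
                members=[calls[i].read_id for i in idx],
            )
        )
    if not alleles:
        return None
    alleles.sort(key=lambda a: a.size)
    return Genotype(
        locus=calls[0].locus,
        alleles=alleles,
        total_reads=n,
        calls=list(calls),
    )


def collect_read_calls(
    alignments: Iterable[AlignmentRecord],
    reference,
    loci: Sequence[TRLocus],
    params: Optional[Parameters] = None,
) -> dict[int, dict[str, ReadCall]]:
    """Per-locus, per-read repeat calls (spanning preferred over rescued)."""
    if params is None:
        params = Parameters()
    by_chrom: dict[str, list[tuple[int, TRLocus]]] = defaultdict(list)
    for i, locus in enumerate(loci):
        by_chrom[locus.chrom].append((i, locus))
    calls: dict[int, dict[str, ReadCall]] = defaultdict(dict)
    rank = {"spanning": 2, "rescued": 1}
    for rec in alignments:
        for i, locus in by_chrom.get(rec.ref_name, ()):
            if rec.ref_end <= locus.start or rec.ref_start >= locus.end:
                # reads clipped right at a boundary still overlap the locus
                # footprint once the clip is considered; requiring simple
                # coordinate overlap of the aligned part is enough here
                if not (rec.ref_end > locus.start - 1 and rec.ref_start < locus.end + 1):
                    continue
            method = "spanning"
            interval = extract_read_tract(rec, locus, params)
            if interval is None:
                interval = rescue_clipped(rec, locus, reference, params)
                method = "rescued"
            if interval is None:
                continue
            prev = calls[i].get(rec.read_id)
            if prev is not None and rank[prev.method] >= rank[method]:
                continue
            seq = rec.read_seq[interval[0] : interval[1]]
            call = call_read(
                seq, locus.motifs, params,
                locus=locus, read_id=rec.read_id,
                tract_offset=interval[0], method=method,
            )
            if call is not None:
                calls[i][rec.read_id] = call
    return calls


def genotype_loci(
    alignments: Iterable[AlignmentRecord],
    reference,
    loci: Sequence[TRLocus],
    params: Optional[Parameters] = None,
) -> list[Genotype]:
    """Genotype every locus with at least one matching read call.

    Reference-sized alleles are captured alongside expansions, so the
    result is the complete allele list per locus; loci with no matching
    calls produce no output.
    """
    if params is None:
        params = Parameters()
    calls = collect_read_calls(alignments, reference, loci, params)
    genotypes = []
    for i, locus in enumerate(loci):
        locus_calls = list(calls.get(i, {}).values())
        if not locus_calls:
            continue
        gt = fit_genotype(locus_calls, params)
        if gt is not None:
            genotypes.append(gt)
    return genotypes
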