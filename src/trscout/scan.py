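"""Genome-scan stage: insertion extraction, merging, purity filtering and
locus delineation.

Large insertions betray repeat expansions.  They are read off CIGAR
strings directly (``I`` operations) or reconstructed from paired split
alignments, where a long insertion shows up as nearby reference
breakpoints separated by a long stretch of read sequence.  Insertions
composed of at least ``insertion_purity_min`` of a single tandem repeat
are clustered across reads, and each surviving cluster is anchored to the
tandem-repeat tract found in the reference neighborhood, so no repeat
annotation is needed.
"""

from __future__ import annotations

from collections import defaultdict
from statistics import median
from typing import Iterable, Optional, Sequence

from .alignio import fetch_ref
from .model import AlignmentRecord, InsertionEvent, TRLocus
from .params import Parameters
from .trfind import canonical_motif, find_repeats, motifs_match, revcomp, tract_purity


def insertions_from_cigar(rec: AlignmentRecord, params: Parameters) -> list[InsertionEvent]:
    """One event per I operation of length >= min_ins_size.

    ``ref_pos`` is the reference position at which the insertion begins
    (the coordinate of the first aligned base after it);
    ``read_span`` indexes into the stored (reference-strand) read_seq.
    """
    if rec.read_seq is None:
        return []
    events = []
    rpos = rec.ref_start
    qpos = 0
    for op, n in rec.cigar:
        if op in "M=X":
            rpos += n
            qpos += n
        elif op in "DN":
            rpos += n
        elif op == "I":
            if n >= params.min_ins_size:
                events.append(
                    InsertionEvent(
                        read_id=rec.read_id,
                        ref_name=rec.ref_name,
                        ref_pos=rpos,
                        ins_seq=rec.read_seq[qpos : qpos + n],
                        source="cigar",
                        read_span=(qpos, qpos + n),
                    )
                )
            qpos += n
        elif op == "S":
            qpos += n
        # H consumes neither read_seq nor reference
    return events


def insertions_from_splits(recs: Sequence[AlignmentRecord],
                           params: Parameters) -> list[InsertionEvent]:
    """Insertions implied by paired split alignments of one read.

    Adjacent (by original-read coordinate) same-chromosome, same-strand
    pairs whose reference breakpoints are within ``split_max_ref_gap``
    but whose read breakpoints are >= min_ins_size apart yield one event
    anchored at the earlier alignment's reference end.
    """
    if not recs:
        return []
    read_id = recs[0].read_id
    lengths = {r.read_len for r in recs}
    if any(r.read_id != read_id for r in recs):
        raise ValueError("insertions_from_splits: records from different reads")
    if len(lengths) > 1:
        raise ValueError(
            f"read {read_id}: inconsistent read lengths across split records: {lengths}"
        )
    # full-length original-strand sequence, if any record carries it
    orig_seq = None
    for r in recs:
        if r.read_seq is not None and len(r.read_seq) == r.read_len:
            orig_seq = r.read_seq if r.strand == "+" else revcomp(r.read_seq)
            break
    ordered = sorted(recs, key=lambda r: r.read_interval()[0])
    events = []
    for a, b in zip(ordered, ordered[1:]):
        if a.ref_name != b.ref_name or a.strand != b.strand:
            continue
        a_read_end = a.read_interval()[1]
        b_read_start = b.read_interval()[0]
        if a.strand == "+":
            g = b.ref_start - a.ref_end
            anchor = a.ref_end
        else:
            g = a.ref_start - b.ref_end
            anchor = b.ref_end
        d = b_read_start - a_read_end
        if abs(g) > params.split_max_ref_gap:
            continue
        if d - g < params.min_ins_size:
            continue
        length = d - max(g, 0)
        if length <= 0:
            continue
        seq = ""
        if orig_seq is not None:
            seq = orig_seq[a_read_end : a_read_end + length]
            if a.strand == "-":
                seq = revcomp(seq)
        events.append(
            InsertionEvent(
                read_id=read_id,
                ref_name=a.ref_name,
                ref_pos=anchor,
                ins_seq=seq,
                source="split",
                read_span=(a_read_end, a_read_end + length),
            )
        )
    return events


def merge_events(events: Sequence[InsertionEvent],
                 params: Parameters) -> list[list[InsertionEvent]]:
    """Single-linkage clustering of events by anchor proximity.

    At most one event (the largest) is kept per read per cluster;
    clusters supported by fewer than ``min_support`` reads are dropped.
    """
    ordered = sorted(events, key=lambda e: (e.ref_name, e.ref_pos, e.read_id))
    clusters: list[list[InsertionEvent]] = []
    cur: list[InsertionEvent] = []
    for ev in ordered:
        if cur and (
            ev.ref_name != cur[-1].ref_name
            or ev.ref_pos - cur[-1].ref_pos > params.merge_window
        ):
            clusters.append(cur)
            cur = []
        cur.append(ev)
    if cur:
        clusters.append(cur)
    out = []
    for cluster in clusters:
        per_read: dict[str, InsertionEvent] = {}
        for ev in cluster:
            prev = per_read.get(ev.read_id)
            if prev is None or len(ev) > len(prev):
                per_read[ev.read_id] = ev
        if len(per_read) >= params.min_support:
            out.append(sorted(per_read.values(), key=lambda e: (e.ref_pos, e.read_id)))
    return out


def _dominant_motif(seq: str, hits) -> tuple[Optional[str], float]:
    """Motif whose tracts cover the most of ``seq`` plus that coverage."""
    best_motif, best_cov = None, 0.0
    groups: dict[str, list] = {}
    for h in hits:
        groups.setdefault(h.motif, []).append(h)
    for motif, ghits in groups.items():
        cov = tract_purity(seq, ghits)
        if cov > best_cov or (cov == best_cov and best_motif and motif < best_motif):
            best_motif, best_cov = motif, cov
    return best_motif, best_cov


def filter_by_purity(cluster: Sequence[InsertionEvent],
                     params: Parameters) -> Optional[tuple[list[InsertionEvent], str]]:
    """Keep a cluster when >= min_support of its insertions are pure
    single-motif repeats agreeing on a motif; returns the majority motif."""
    passing: list[tuple[InsertionEvent, str]] = []
    for ev in cluster:
        if not ev.ins_seq:
            continue
        hits = find_repeats(ev.ins_seq, params)
        motif, cov = _dominant_motif(ev.ins_seq, hits)
        if motif is not None and cov >= params.insertion_purity_min:
            passing.append((ev, motif))
    if len(passing) < params.min_support:
        return None
    # majority motif under approximate matching
    best: Optional[tuple[list[InsertionEvent], str]] = None
    for _, motif in passing:
        members = [e for e, m in passing if motifs_match(m, motif, params)]
        if best is None or len(members) > len(best[0]) or (
            len(members) == len(best[0]) and motif < best[1]
        ):
            best = (members, motif)
    if best is None or len(best[0]) < params.min_support:
        return None
    return best


def delineate_locus(chrom: str, anchor_pos: int, motif: str, reference,
                    params: Parameters) -> Optional[TRLocus]:
    """Find the reference tandem-repeat tract behind an insertion cluster.

    The reference neighborhood (anchor +/- scan_window) is screened for
    repeats; the tract overlapping or nearest the anchor whose motif
    matches the insertion motif defines the locus.  Returns None when the
    reference carries no concordant tract (the cluster is then dropped:
    insertion and genomic motifs must agree).
    """
    try:
        chrom_len = len(reference[chrom])
    except KeyError as exc:
        raise ValueError(f"unknown chromosome {chrom!r}") from exc
    if not (0 <= anchor_pos < chrom_len):
        raise ValueError(f"anchor {anchor_pos} outside {chrom} (len {chrom_len})")
    wstart = max(0, anchor_pos - params.scan_window)
    wend = min(chrom_len, anchor_pos + params.scan_window)
    window = fetch_ref(reference, chrom, wstart, wend)
    hits = [
        h
        for h in find_repeats(window, params)
        if motifs_match(h.motif, motif, params)
    ]
    if not hits:
        # short or low-complexity reference tracts can evade de-novo
        # detection inside a large window; the insertion motif is known,
        # so align it directly over the window as a targeted fallback
        from .model import RepeatHit
        from .trfind import encode, wrap_align_local

        arr = encode(window)
        best = None
        for m in (motif, revcomp(motif)) if params.use_revcomp else (motif,):
            score, start, end, matches, cols, _ = wrap_align_local(arr, encode(m))
            if score >= params.min_repeat_score and end - start >= 2 * len(motif):
                if best is None or score > best.score:
                    best = RepeatHit(
                        motif=canonical_motif(motif, params.use_revcomp),
                        start=start, end=end,
                        purity=matches / cols if cols else 0.0,
                        score=float(score),
                    )
        if best is None:
            return None
        hits = [best]
    anchor_off = anchor_pos - wstart

    def distance(h):
        if h.start <= anchor_off < h.end:
            return 0
        return min(abs(h.start - anchor_off), abs(h.end - anchor_off))

    best = min(hits, key=lambda h: (distance(h), -h.score, h.start))
    return TRLocus(
        chrom=chrom,
        start=wstart + best.start,
        end=wstart + best.end,
        motifs=[canonical_motif(motif, params.use_revcomp)],
        source="scan",
    )


def _in_regions(chrom: str, pos: int, regions) -> bool:
    for c, s, e in regions:
        if c == chrom and s <= pos < e:
            return True
    return False


def genome_scan(
    alignments: Iterable[AlignmentRecord],
    reference,
    exclude_regions: Sequence[tuple[str, int, int]] = (),
    params: Optional[Parameters] = None,
) -> list[TRLocus]:
    """Full scan stage: candidate expanded-repeat loci from alignments."""
    if params is None:
        params = Parameters()
    events: list[InsertionEvent] = []
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in alignments:
        if rec.read_seq is not None:
            events.extend(insertions_from_cigar(rec, params))
        by_read[rec.read_id].append(rec)
    for read_id, recs in by_read.items():
        if len(recs) >= 2:
            events.extend(insertions_from_splits(recs, params))
    if exclude_regions:
        events = [
            e for e in events if not _in_regions(e.ref_name, e.ref_pos, exclude_regions)
        ]
    loci: list[TRLocus] = []
    for cluster in merge_events(events, params):
        kept = filter_by_purity(cluster, params)
        if kept is None:
            continue
        members, motif = kept
        anchor = int(median(e.ref_pos for e in members))
        locus = delineate_locus(members[0].ref_name, anchor, motif, reference, params)
        if locus is None:
            continue
        locus.support_events = len(members)
        loci.append(locus)
    # deduplicate overlapping loci: keep the better-supported, ties leftmost
    loci.sort(key=lambda l: (l.chrom, l.start, l.end))
    deduped: list[TRLocus] = []
    for locus in loci:
        if deduped:
            prev = deduped[-1]
            if prev.chrom == locus.chrom and locus.start < prev.end:
                if (locus.support_events, -locus.start) > (prev.support_events, -prev.start):
                    deduped[-1] = locus
                continue
        deduped.append(locus)
    return deduped
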