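"""Insertion extraction, event merging and genome-scan composition."""

from __future__ import annotations

import random

import numpy as np
import pytest

from helpers import plant_insertion, recover_insertion
from trscout.model import AlignmentRecord, InsertionEvent, TRLocus
from trscout.params import Parameters
from trscout.scan import (
    delineate_locus,
    filter_by_purity,
    genome_scan,
    insertions_from_cigar,
    insertions_from_splits,
    merge_events,
)
from trscout.simulate import SimParams, make_experiment
from trscout.trfind import canonical_motif, motifs_match


def _rec(read_id, ref_start, cigar, seq, strand="+", supp=False, ref_name="chr1"):
    return AlignmentRecord(read_id, ref_name, ref_start, strand, 60, cigar, seq,
                           is_supplementary=supp)


def test_cigar_insertion_basic(params):
    rec = _rec("r1", 1000, [("M", 100), ("I", 150), ("M", 100)], "A" * 350)
    (ev,) = insertions_from_cigar(rec, params)
    assert ev.ref_pos == 1100
    assert len(ev) == 150
    assert ev.read_span == (100, 250)
    assert ev.source == "cigar"


def test_cigar_insertion_thresholds(params):
    assert insertions_from_cigar(_rec("r", 0, [("M", 200)], "A" * 200), params) == []
    rec = _rec("r", 0, [("M", 50), ("I", 99), ("M", 50)], "A" * 199)
    assert insertions_from_cigar(rec, params) == []  # below min_ins_size


def test_cigar_insertion_matches_realignment_oracle(params):
    """CIGAR-walk extraction equals a brute-force re-alignment of read
    against reference on toy records (<= 200 bp)."""
    rng = random.Random(42)
    for trial in range(25):
        ref = "".join(rng.choice("ACGT") for _ in range(200))
        pos = rng.randrange(20, 180)
        ins = "".join(rng.choice("ACGT") for _ in range(rng.randrange(100, 140)))
        read, cigar = plant_insertion(ref, pos, ins)
        rec = _rec(f"t{trial}", 0, cigar, read)
        (ev,) = insertions_from_cigar(rec, params)
        oracle_pos, oracle_ins = recover_insertion(ref, read)
        assert ev.ref_pos == pos
        assert ev.ins_seq == ins
        # the re-alignment anchor may slide by a few bases when the
        # insertion starts with the same bases as the reference; both
        # representations must reconstruct the read exactly
        assert abs(oracle_pos - ev.ref_pos) <= 8
        assert len(oracle_ins) == len(ev.ins_seq)
        assert ref[: ev.ref_pos] + ev.ins_seq + ref[ev.ref_pos :] == read
        assert ref[:oracle_pos] + oracle_ins + ref[oracle_pos:] == read


def test_cigar_insertion_repeat_context_reconstructs(params):
    """Inside a repeat the anchor is ambiguous; the event must still
    reconstruct the read exactly."""
    ref = "G" * 50 + "CAG" * 20 + "T" * 50
    pos = 50 + 30
    ins = "CAG" * 40
    read, cigar = plant_insertion(ref, pos, ins)
    rec = _rec("rep", 0, cigar, read)
    (ev,) = insertions_from_cigar(rec, params)
    assert ref[: ev.ref_pos] + ev.ins_seq + ref[ev.ref_pos :] == read


def test_split_insertion_geometry(params):
    """Reference gap 10, read gap 2010 -> one 2000 bp event at the first
    alignment's reference end."""
    seq = "A" * 3010
    a = _rec("r", 4200, [("M", 800), ("S", 2210)], seq)
    b = _rec("r", 5010, [("S", 2810), ("M", 200)], seq, supp=True)
    (ev,) = insertions_from_splits([a, b], params)
    assert ev.ref_pos == 5000
    assert len(ev) == 2000
    assert ev.source == "split"


def test_split_insertion_rejections(params):
    seq = "A" * 3010
    a = _rec("r", 4200, [("M", 800), ("S", 2210)], seq)
    b_other = _rec("r", 5010, [("S", 2810), ("M", 200)], seq, supp=True, ref_name="chr2")
    assert insertions_from_splits([a, b_other], params) == []
    b_far = _rec("r", 5500, [("S", 2810), ("M", 200)], seq, supp=True)
    assert insertions_from_splits([a, b_far], params) == []  # ref gap 500 > 50


def test_split_insertion_inconsistent_lengths(params):
    a = _rec("r", 4200, [("M", 800), ("S", 2210)], "A" * 3010)
    b = _rec("r", 5010, [("S", 100), ("M", 200)], "A" * 300, supp=True)
    with pytest.raises(ValueError):
        insertions_from_splits([a, b], params)


def _ev(read_id, pos, size=200, chrom="chr1"):
    return InsertionEvent(read_id, chrom, pos, "A" * size, "cigar", (0, size))


def test_merge_events_chain_and_windows(params):
    clusters = merge_events([_ev("a", 1000), _ev("b", 1020), _ev("c", 1035)], params)
    assert len(clusters) == 1 and len(clusters[0]) == 3
    clusters = merge_events([_ev("a", 1000), _ev("b", 1200), _ev("c", 1210)], params)
    # 1000 is alone -> dropped by min_support; 1200+1210 cluster together
    assert len(clusters) == 1
    assert {e.read_id for e in clusters[0]} == {"b", "c"}


def test_merge_events_per_read_dedup(params):
    clusters = merge_events(
        [_ev("a", 1000, 100), _ev("a", 1010, 300), _ev("b", 1020, 200)], params
    )
    assert len(clusters) == 1
    (cluster,) = clusters
    assert len(cluster) == 2  # one event per read, the larger one kept
    sizes = {e.read_id: len(e) for e in cluster}
    assert sizes == {"a": 300, "b": 200}


def test_filter_by_purity_keep_and_majority(params):
    pure = [
        InsertionEvent(f"r{i}", "chr1", 1000, "CAG" * 40, "cigar", (0, 120))
        for i in range(3)
    ]
    kept = filter_by_purity(pure, params)
    assert kept is not None
    members, motif = kept
    assert len(members) == 3
    assert canonical_motif(motif) == "AGC"
    # a random-sequence event does not break the majority
    rng = np.random.default_rng(1)
    junk = InsertionEvent("rx", "chr1", 1005,
                          "".join(rng.choice(list("ACGT"), 120)), "cigar", (0, 120))
    kept = filter_by_purity(pure[:2] + [junk], params)
    assert kept is not None and len(kept[0]) == 2


def test_filter_by_purity_drops_impure(params):
    rng = np.random.default_rng(2)
    half = "CAG" * 20 + "".join(rng.choice(list("ACGT"), 140))  # ~30% repeat
    events = [
        InsertionEvent(f"r{i}", "chr1", 1000, half, "cigar", (0, len(half)))
        for i in range(3)
    ]
    assert filter_by_purity(events, params) is None


def test_delineate_locus(params):
    rng = np.random.default_rng(3)
    left = "".join(rng.choice(list("ACGT"), 1500))
    right = "".join(rng.choice(list("ACGT"), 1500))
    reference = {"chr9": left + "GAA" * 10 + right}
    locus = delineate_locus("chr9", 1505, "GAA", reference, params)
    assert locus is not None
    assert abs(locus.start - 1500) <= 3 and abs(locus.end - 1530) <= 3
    assert motifs_match(locus.motifs[0], "GAA", params)
    # reverse-complement-rotation equivalent motif still matches
    locus2 = delineate_locus("chr9", 1505, "TTC", reference, params)
    assert locus2 is not None
    # no concordant tract in the window -> cluster discarded
    assert delineate_locus("chr9", 400, "ATTCT", reference, params) is None
    with pytest.raises(ValueError):
        delineate_locus("chr9", 10**7, "GAA", reference, params)


def test_genome_scan_recovers_planted_loci(small_het_bundle, params):
    bundle = small_het_bundle
    sample = bundle.samples[0]
    loci = genome_scan(sample.alignments(params), bundle.reference, (), params)
    truth = {l.chrom: l for l in bundle.loci}
    assert len(loci) == len(bundle.loci)
    for locus in loci:
        t = truth[locus.chrom]
        assert motifs_match(locus.motifs[0], t.motifs[0], params)
        assert min(locus.end, t.end) > max(locus.start, t.start)
        assert locus.support_events >= params.min_support
        assert locus.source == "scan"


def test_genome_scan_exclude_regions(small_het_bundle, params):
    bundle = small_het_bundle
    sample = bundle.samples[0]
    exclude = [(l.chrom, l.start - 500, l.end + 500) for l in bundle.loci]
    loci = genome_scan(sample.alignments(params), bundle.reference, exclude, params)
    assert loci == []


def test_genome_scan_no_expansion_no_loci(clean_het_bundle, params):
    """Reads simulated from the unmodified reference produce no candidate
    expansions (specificity)."""
    bundle = clean_het_bundle
    sample = bundle.samples[0]
    ref_only = [
        r for r in sample.alignments(params)
        if r.read_id.split("_")[-3] == "h0"
    ]
    assert genome_scan(ref_only, bundle.reference, (), params) == []


def test_genome_scan_order_invariant(small_het_bundle, params):
    bundle = small_het_bundle
    sample = bundle.samples[0]
    recs = list(sample.alignments(params))
    loci_fwd = genome_scan(recs, bundle.reference, (), params)
    rng = random.Random(0)
    shuffled = recs[:]
    rng.shuffle(shuffled)
    loci_shuf = genome_scan(shuffled, bundle.reference, (), params)
    key = lambda l: (l.chrom, l.start, l.end, tuple(l.motifs), l.support_events)
    assert sorted(map(key, loci_fwd)) == sorted(map(key, loci_shuf))


def test_split_and_cigar_events_agree(tmp_path, params):
    """The same planted expansion yields concordant events through the
    CIGAR path and the split-alignment path."""
    spec = [("chr4", "HTT", "CAG", 57)]
    sim_cigar = SimParams(flank_len=6000, depth=12, read_len_median=4000,
                          split_emit_threshold=10**9)
    sim_split = SimParams(flank_len=6000, depth=12, read_len_median=4000,
                          split_emit_threshold=200)
    out = {}
    for name, sim in (("cigar", sim_cigar), ("split", sim_split)):
        bundle = make_experiment("het17", str(tmp_path / name), seed=21, sim=sim,
                                 allele_size=500, loci_spec=spec)
        sample = bundle.samples[0]
        events = []
        by_read = {}
        for rec in sample.alignments(params):
            events.extend(insertions_from_cigar(rec, params))
            by_read.setdefault(rec.read_id, []).append(rec)
        for recs in by_read.values():
            if len(recs) >= 2:
                events.extend(insertions_from_splits(recs, params))
        out[name] = [e for e in events if e.source == name]
    assert out["cigar"] and out["split"]
    med = lambda evs: sorted(len(e) for e in evs)[len(evs) // 2]
    pos = lambda evs: sorted(e.ref_pos for e in evs)[len(evs) // 2]
    assert abs(pos(out["cigar"]) - pos(out["split"])) <= params.merge_window
    assert abs(med(out["cigar"]) - med(out["split"])) <= 0.1 * med(out["cigar"])
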