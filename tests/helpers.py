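"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch (plain loops,
relaxation-style dynamic programming) so that it shares no code path
with the package implementation it checks.
"""

from __future__ import annotations

from itertools import product

MATCH, MISMATCH, GAP = 1, -1, -2


def min_rotation(s: str) -> str:
    d = s + s
    return min(d[i : i + len(s)] for i in range(len(s)))


def rotation_classes(length: int) -> list[str]:
    """One minimal-rotation representative per rotation class, ACGT,
    homopolymers excluded."""
    seen, reps = set(), []
    for tup in product("ACGT", repeat=length):
        s = "".join(tup)
        if len(set(s)) == 1:
            continue
        r = min_rotation(s)
        if r not in seen:
            seen.add(r)
            reps.append(r)
    return reps


def naive_wrap_local(seq: str, motif: str):
    """Local alignment of seq against a circular repeat of motif.

    Match +1, mismatch -1, indel -2, zero floor.  Row values are settled
    by repeated relaxation of the cyclic within-row (motif-deletion)
    edges until a fixed point, which is slow but obviously correct.
    Returns (score, start, end) of the best-scoring tract.
    """
    n, m = len(seq), len(motif)
    H = [[0] * m for _ in range(n + 1)]
    best = (0, 0, 0)
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        for j in range(m):
            s = MATCH if seq[i - 1] == motif[j] else MISMATCH
            row[j] = max(0, prev[(j - 1) % m] + s, prev[j] + GAP)
        changed = True
        while changed:
            changed = False
            for j in range(m):
                cand = row[(j - 1) % m] + GAP
                if cand > row[j]:
                    row[j] = cand
                    changed = True
        for j in range(m):
            if row[j] > best[0]:
                best = (row[j], i, j)
    score, i_end, j_end = best
    if score <= 0:
        return 0, 0, 0
    # traceback for the start coordinate (diag > up > left preference)
    i, j = i_end, j_end
    while i > 0 and H[i][j] > 0:
        s = MATCH if seq[i - 1] == motif[j] else MISMATCH
        jp = (j - 1) % m
        if H[i][j] == H[i - 1][jp] + s:
            i -= 1
            j = jp
        elif H[i][j] == H[i - 1][j] + GAP:
            i -= 1
        elif H[i][j] == H[i][jp] + GAP:
            j = jp
        else:
            break
    return score, i, i_end


def oracle_best_hit(seq: str, max_motif: int = 6, min_motif: int = 2,
                    min_score: int = 8):
    """Exhaustive search over every short motif, boundaries from the
    naive DP.  Candidates ranked the way the detector ranks them: by
    score minus motif length (one self-copy is free for any motif), then
    shorter motif, then lexicographic representative.  Hits below the
    report threshold or with fewer than two motif copies are ignored.
    Returns (score, motif_rep, start, end) or None."""
    best = None
    for length in range(min_motif, min(max_motif, len(seq) // 2) + 1):
        for rep in rotation_classes(length):
            score, start, end = naive_wrap_local(seq, rep)
            if score < min_score or end - start < 2 * length:
                continue
            key = (-(score - length), length, rep)
            if best is None or key < best[0]:
                best = (key, score, rep, start, end)
    if best is None:
        return None
    _, score, rep, start, end = best
    return score, rep, start, end


def plant_insertion(ref: str, pos: int, ins: str):
    """Read = ref with ins planted at pos; returns (read, cigar)."""
    read = ref[:pos] + ins + ref[pos:]
    cigar = [("M", pos), ("I", len(ins)), ("M", len(ref) - pos)]
    return read, cigar


def recover_insertion(ref: str, read: str):
    """Infer a single planted insertion by re-aligning read to ref with
    longest common prefix/suffix — the brute-force counterpart of the
    CIGAR walk.  Returns (ref_pos, insertion_sequence)."""
    if len(read) <= len(ref):
        raise ValueError("read carries no insertion")
    p = 0
    while p < len(ref) and read[p] == ref[p]:
        p += 1
    s = 0
    while s < len(ref) - p and read[len(read) - 1 - s] == ref[len(ref) - 1 - s]:
        s += 1
    ins_len = len(read) - len(ref)
    # maximal prefix/suffix overlap can overshoot inside a repeat; clamp
    p = min(p, len(ref) - s)
    return p, read[p : p + ins_len]
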