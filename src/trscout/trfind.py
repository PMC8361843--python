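"""Native tandem-repeat detection and motif algebra.

Detection works in two steps, in the spirit of classic tandem-repeat
finders: candidate repeat periods are proposed from a self-match profile
(the fraction of positions ``i`` with ``seq[i] == seq[i + p]``), then the
sequence is aligned against a perfect repeat of the candidate motif with
wraparound dynamic programming.  Scoring is match +1, mismatch -1,
indel -2; tracts are reported when the local alignment score reaches
``Parameters.min_repeat_score`` and the tract holds at least two motif
copies.  Purity is the fraction of aligned columns that are matches.

For short sequences (<= 64 bp) candidate motifs of 2-6 bp are enumerated
exhaustively (one representative per rotation class), which makes the
detector's best hit identical to an exhaustive motif/boundary search under
the same scoring scheme.  Longer sequences use profile candidates plus a
consensus-refinement pass that repairs sequencing errors in the seed
motif.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import RepeatHit
from .params import Parameters

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# sequences up to this length get the exhaustive candidate-motif path
_EXHAUSTIVE_LEN = 64
_EXHAUSTIVE_MOTIF_MAX = 6

GAP = 2  # linear gap penalty (positive magnitude)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    return motif


def canonical_motif(motif: str, use_revcomp: bool = True) -> str:
    """Lexicographically smallest rotation of ``motif`` (and optionally of
    its reverse complement).  Idempotent; strand- and phase-normalizing."""
    motif = _validate_motif(motif)
    doubled = motif + motif
    best = min(doubled[i : i + len(motif)] for i in range(len(motif)))
    if use_revcomp:
        rc = revcomp(motif)
        doubled = rc + rc
        best = min(best, min(doubled[i : i + len(motif)] for i in range(len(motif))))
    return best


def _min_rotation(motif: str) -> str:
    doubled = motif + motif
    return min(doubled[i : i + len(motif)] for i in range(len(motif)))


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGTN character {bad!r} in sequence")
    return arr


def decode(arr: Sequence[int]) -> str:
    return "".join("ACGTN"[int(c)] for c in arr)


class _Hit:
    __slots__ = ("score", "start", "end", "matches", "columns", "motif")

    def __init__(self, score, start, end, matches, columns, motif):
        self.score = score
        self.start = start
        self.end = end
        self.matches = matches
        self.columns = columns
        self.motif = motif  # str, as aligned (not canonical)


def wrap_align_local(sub: np.ndarray, motif: np.ndarray):
    """Local alignment of ``sub`` against a circular repeat of ``motif``.

    Returns ``(score, start, end, matches, columns, column_chars)`` where
    ``column_chars`` maps motif column -> list of sub codes aligned to it
    (diagonal steps only, for consensus building).  Scoring: match +1,
    mismatch -1, indel -2, 0-floored (Smith-Waterman with wraparound
    motif columns).
    """
    n, m = len(sub), len(motif)
    if n == 0 or m == 0:
        return 0, 0, 0, 0, 0, {}
    S = np.where(sub[:, None] == motif[None, :], 1, -1).astype(np.int32)
    S[sub == 4] = -1  # N never matches
    H = np.zeros((n + 1, m), dtype=np.int32)
    off = (GAP * np.arange(2 * m)).astype(np.int32)
    row_max = np.zeros(n + 1, dtype=np.int32)
    if m == 1:
        for i in range(1, n + 1):
            prev = H[i - 1]
            t = max(prev[0] + S[i - 1, 0], prev[0] - GAP, 0)
            H[i, 0] = t
            row_max[i] = t
    else:
        buf = np.empty(2 * m, dtype=np.int32)
        for i in range(1, n + 1):
            prev = H[i - 1]
            diag = np.roll(prev, 1)
            diag += S[i - 1]
            T = np.maximum(diag, prev - GAP)
            buf[:m] = T
            buf[m:] = T
            buf += off
            np.maximum.accumulate(buf, out=buf)
            row = buf[m:] - off[m:]
            np.maximum(row, 0, out=row)
            H[i] = row
            row_max[i] = row.max()
    i_end = int(np.argmax(row_max))
    score = int(row_max[i_end])
    if score <= 0:
        return 0, 0, 0, 0, 0, {}
    j = int(np.argmax(H[i_end]))
    # traceback (prefer diagonal, then up, then left)
    i = i_end
    matches = columns = 0
    col_chars: dict[int, list[int]] = {}
    while i > 0 and H[i, j] > 0:
        h = H[i, j]
        jp = j - 1 if j else m - 1
        if h == H[i - 1, jp] + S[i - 1, j]:
            if S[i - 1, j] == 1:
                matches += 1
            col_chars.setdefault(j, []).append(int(sub[i - 1]))
            columns += 1
            i -= 1
            j = jp
        elif h == H[i - 1, j] - GAP:
            columns += 1
            i -= 1
        elif h == H[i, jp] - GAP:
            columns += 1
            j = jp
        else:  # pragma: no cover - defensive
            break
    return score, i, i_end, matches, columns, col_chars


@lru_cache(maxsize=8)
def _rotation_classes(length: int) -> tuple[str, ...]:
    """One representative (minimal rotation) per rotation class of ACGT
    strings of the given length, homopolymers excluded."""
    seen = set()
    reps = []
    for tup in product("ACGT", repeat=length):
        s = "".join(tup)
        if len(set(s)) == 1:
            continue
        r = _min_rotation(s)
        if r not in seen:
            seen.add(r)
            reps.append(r)
    return tuple(reps)


def _self_match_profile(sub: np.ndarray, pmin: int, pmax: int) -> dict[int, float]:
    prof = {}
    for p in range(pmin, pmax + 1):
        a = sub[:-p] == sub[p:]
        if len(a):
            prof[p] = float(a.mean())
    return prof


def _seeds_for_period(sub: np.ndarray, p: int, k: int = 3) -> list[str]:
    """Up to ``k`` seed motifs for period ``p``, from the strongest
    non-overlapping self-match windows.

    The self-match signal is evaluated over windows of at least 12 bp so
    that a genuine short tract outranks accidental perfect matches of
    tiny windows; several windows are tried because a sequencing error
    inside the best window can phase-lock alignment onto a wrong seed.
    """
    if len(sub) <= p:
        return []
    a = (sub[:-p] == sub[p:]).astype(np.int32)
    if len(a) < p:
        return []
    w_len = min(max(p, 12), len(a))
    w = np.convolve(a, np.ones(w_len, dtype=np.int32), mode="valid").astype(float)
    seeds: list[str] = []
    for _ in range(k):
        i = int(np.argmax(w))
        if w[i] <= 0:
            break
        seed = decode(sub[i : i + p])
        w[max(0, i - w_len) : i + w_len] = -1.0
        if "N" in seed or len(set(seed)) == 1:
            continue
        if seed not in seeds:
            seeds.append(seed)
    return seeds


def _seed_for_period(sub: np.ndarray, p: int) -> Optional[str]:
    seeds = _seeds_for_period(sub, p, k=1)
    return seeds[0] if seeds else None


@lru_cache(maxsize=8)
def _rotation_class_matrix(length: int) -> np.ndarray:
    reps = _rotation_classes(length)
    return _CODE[
        np.frombuffer("".join(reps).encode("ascii"), dtype=np.uint8)
    ].reshape(len(reps), length)


def _batch_scores(sub: np.ndarray, motif_matrix: np.ndarray) -> np.ndarray:
    """Best local wraparound alignment score of ``sub`` against every
    motif in ``motif_matrix`` (all of one length), vectorized over motifs."""
    n = len(sub)
    K, m = motif_matrix.shape
    H = np.zeros((K, m), dtype=np.int32)
    off = (GAP * np.arange(2 * m)).astype(np.int32)
    buf = np.empty((K, 2 * m), dtype=np.int32)
    best = np.zeros(K, dtype=np.int32)
    for i in range(n):
        S = np.where(motif_matrix == sub[i], 1, -1).astype(np.int32)
        diag = np.roll(H, 1, axis=1)
        diag += S
        T = np.maximum(diag, H - GAP)
        buf[:, :m] = T
        buf[:, m:] = T
        buf += off[None, :]
        np.maximum.accumulate(buf, axis=1, out=buf)
        H = np.maximum(buf[:, m:] - off[None, m:], 0)
        np.maximum(best, H.max(axis=1), out=best)
    return best


def _candidate_motifs(sub: np.ndarray, params: Parameters) -> list[str]:
    """Profile-driven candidate motifs for long sequences."""
    n = len(sub)
    pmax = min(params.motif_len_max, n // 2)
    pmin = max(1, params.motif_len_min)
    if pmax < pmin:
        return []
    cands: list[str] = []
    seen = set()

    def add(motif: Optional[str]):
        if motif is None:
            return
        key = _min_rotation(motif)
        if key not in seen:
            seen.add(key)
            cands.append(key)

    prof = _self_match_profile(sub, pmin, pmax)
    short_ps = [p for p in prof if p <= _EXHAUSTIVE_MOTIF_MAX]
    if short_ps:
        best = max(prof[p] for p in short_ps)
        if best >= 0.5:
            # a dominant periodicity: try the smallest period near the top
            p_short = min(p for p in short_ps if prof[p] >= best - 0.02)
            for seed in _seeds_for_period(sub, p_short):
                add(seed)
            others = [p for p in short_ps
                      if p != p_short and prof[p] >= max(0.55, best - 0.05)]
            if others:
                for seed in _seeds_for_period(sub, min(others)):
                    add(seed)
        else:
            # no dominant period (a short tract inside a long window):
            # the profile mean is uninformative, try every short period
            for p in short_ps:
                for seed in _seeds_for_period(sub, p):
                    add(seed)
    long_ps = [p for p in prof if p > _EXHAUSTIVE_MOTIF_MAX and prof[p] >= 0.55]
    if long_ps:
        best = max(prof[p] for p in long_ps)
        p_long = min(p for p in long_ps if prof[p] >= best - 0.02)
        for seed in _seeds_for_period(sub, p_long):
            add(seed)
    return cands


def adjusted_score(score: float, motif_len: int) -> float:
    """Parsimony-adjusted score used to rank candidate motifs.

    Any motif matches one copy of itself for free, which otherwise lets
    long composite motifs (near-concatemers of a short unit, with
    sequencing errors absorbed into the unit) outscore the true short
    motif on short tracts.  Subtracting one motif length charges each
    candidate for that free copy, so only genuine repetition counts.
    """
    return score - motif_len


def _better(a: _Hit, b: Optional[_Hit]) -> bool:
    """True when hit ``a`` beats ``b`` under the deterministic tie rules:
    higher parsimony-adjusted score, then shorter motif, then
    lexicographic canonical form (strand-invariant), then leftmost
    start."""
    if b is None:
        return True
    ka = (-adjusted_score(a.score, len(a.motif)), len(a.motif),
          canonical_motif(a.motif, True), a.start)
    kb = (-adjusted_score(b.score, len(b.motif)), len(b.motif),
          canonical_motif(b.motif, True), b.start)
    return ka < kb


def _eligible(hit: Optional[_Hit], params: Parameters) -> Optional[_Hit]:
    """Reportability filter applied per candidate BEFORE ranking, so a
    strong long-motif hit is not masked by a higher-parsimony but
    sub-threshold short-motif hit."""
    if hit is None:
        return None
    if hit.score < params.min_repeat_score:
        return None
    if hit.end - hit.start < 2 * len(hit.motif):
        return None
    if not (params.motif_len_min <= len(hit.motif) <= params.motif_len_max):
        return None
    return hit


def _consensus(motif: str, col_chars: dict[int, list[int]]) -> str:
    out = []
    for j, base in enumerate(motif):
        obs = col_chars.get(j)
        if not obs:
            out.append(base)
            continue
        counts = np.bincount(obs, minlength=5)[:4]
        best = int(np.argmax(counts))  # argmax ties -> smaller code (lexicographic)
        out.append("ACGT"[best])
    return "".join(out)


def _align_candidate(sub: np.ndarray, motif: str, refine: bool) -> Optional[_Hit]:
    score, start, end, matches, cols, col_chars = wrap_align_local(sub, encode(motif))
    if score <= 0:
        return None
    hit = _Hit(score, start, end, matches, cols, motif)
    if refine:
        current = motif
        for _ in range(2):
            cons = _consensus(current, col_chars)
            if cons == current or len(set(cons)) == 1:
                break
            s2, st2, en2, m2, c2, cc2 = wrap_align_local(sub, encode(cons))
            cand = _Hit(s2, st2, en2, m2, c2, cons) if s2 > 0 else None
            if cand is not None and _better(cand, hit):
                hit = cand
                current = cons
                col_chars = cc2
            else:
                break
    return hit


def _primitive_submotif(motif: str, params: Parameters) -> Optional[str]:
    """Smallest approximate repeat unit of a long motif.

    Indel-biased sequencing noise can make a quasi-doubled motif (e.g. a
    23-mer standing in for a 12 bp unit) fit a long tract marginally
    better than the true unit.  This probes whether the motif is itself
    a near-concatemer of a shorter unit; returns that unit, or None when
    the motif is primitive.
    """
    m = len(motif)
    if m <= 2 * params.motif_len_min:
        return None
    arr = encode(motif)
    best: Optional[_Hit] = None
    tri = encode(motif * 3)
    for p in range(max(2, params.motif_len_min), m // 2 + 2):
        # cyclic self-similarity at offset p
        rolled = np.roll(arr, -p)
        if float((arr == rolled).mean()) < 0.6:
            continue
        for seed in _seeds_for_period(tri, p, k=1):
            hit = _align_candidate(tri, seed, True)
            if hit is None or hit.columns == 0:
                continue
            if (hit.end - hit.start >= 0.8 * len(tri)
                    and hit.matches >= 0.8 * hit.columns
                    and (best is None or _better(hit, best))):
                best = hit
    return best.motif if best is not None else None


def _best_hit(sub: np.ndarray, params: Parameters) -> Optional[_Hit]:
    n = len(sub)
    pmax = min(params.motif_len_max, n // 2)
    pmin = max(1, params.motif_len_min)
    if pmax < pmin:
        return None
    best: Optional[_Hit] = None
    if n <= _EXHAUSTIVE_LEN:
        for length in range(pmin, min(_EXHAUSTIVE_MOTIF_MAX, pmax) + 1):
            matrix = _rotation_class_matrix(length)
            reps = _rotation_classes(length)
            scores = _batch_scores(sub, matrix)
            # walk candidates of this length best-first until one passes
            # the eligibility filter (argmax ties: first occurrence is
            # the lexicographically smallest representative)
            order = np.argsort(-scores, kind="stable")
            for k in order:
                if scores[k] < params.min_repeat_score:
                    break
                hit = _eligible(_align_candidate(sub, reps[int(k)], False), params)
                if hit is not None:
                    if _better(hit, best):
                        best = hit
                    break
        for p in range(_EXHAUSTIVE_MOTIF_MAX + 1, pmax + 1):
            for seed in _seeds_for_period(sub, p, k=2):
                hit = _eligible(_align_candidate(sub, seed, False), params)
                if hit is not None and _better(hit, best):
                    best = hit
    else:
        for motif in _candidate_motifs(sub, params):
            hit = _eligible(_align_candidate(sub, motif, True), params)
            if hit is not None and _better(hit, best):
                best = hit
        if best is not None and len(best.motif) > _EXHAUSTIVE_MOTIF_MAX:
            unit = _primitive_submotif(best.motif, params)
            if unit is not None and len(unit) < len(best.motif):
                hit = _eligible(_align_candidate(sub, unit, True), params)
                if hit is not None and _better(hit, best):
                    best = hit
    return best


def _scan_segment(arr: np.ndarray, lo: int, hi: int, params: Parameters,
                  out: list[RepeatHit]) -> None:
    n = hi - lo
    if n < 2 * params.motif_len_min or n < params.min_repeat_score:
        return
    sub = arr[lo:hi]
    best = _best_hit(sub, params)
    if best is None:
        return
    out.append(
        RepeatHit(
            motif=canonical_motif(best.motif, params.use_revcomp),
            start=lo + best.start,
            end=lo + best.end,
            purity=best.matches / best.columns,
            score=float(best.score),
        )
    )
    _scan_segment(arr, lo, lo + best.start, params, out)
    _scan_segment(arr, lo + best.end, hi, params, out)


def find_repeats(seq: str, params: Optional[Parameters] = None) -> list[RepeatHit]:
    """Detect maximal tandem-repeat tracts in ``seq``.

    Returns hits sorted by start coordinate; empty list when nothing
    reaches the report threshold.
    """
    if params is None:
        params = Parameters()
    if len(seq) < 2 * params.motif_len_min:
        return []
    arr = encode(seq)
    hits: list[RepeatHit] = []
    _scan_segment(arr, 0, len(arr), params, hits)
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def tract_purity(seq: str, hits: Iterable[RepeatHit]) -> float:
    """Fraction of ``seq`` covered by tracts of the single best motif.

    "Single" means one canonical motif: coverage is computed per motif
    group and the maximum group coverage is returned, so two different
    motifs each covering 40% yield 0.40, not 0.80.
    """
    n = len(seq)
    if n == 0:
        return 0.0
    groups: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        groups.setdefault(h.motif, []).append((max(0, h.start), min(n, h.end)))
    best = 0.0
    for ivs in groups.values():
        ivs.sort()
        covered = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
        best = max(best, covered / n)
    return best


def _concatemer_divergence(query: str, unit: str, copies: int) -> float:
    """Edit-distance fraction of ``query`` aligned end-to-end (on the
    query) inside ``copies`` concatenated copies of ``unit``."""
    import edlib

    text = unit * copies
    if not query or not text:
        return 1.0
    res = edlib.align(query, text, mode="HW")
    if res["editDistance"] < 0:  # pragma: no cover
        return 1.0
    return res["editDistance"] / len(query)


def motifs_match(detected: str, target: str, params: Optional[Parameters] = None) -> bool:
    """Whether two repeat motifs denote the same repeat.

    Exact path: equality of canonical (rotation/strand-normalized) forms.
    Approximate path (both motifs > 6 bp, where sequencing noise makes
    exact identity unrealistic): a local alignment of one motif against a
    three-copy concatenation of the other must reach >= 80% identity over
    >= 80% of the shorter motif.  Symmetric in its arguments.
    """
    if params is None:
        params = Parameters()
    detected = _validate_motif(detected)
    target = _validate_motif(target)
    if canonical_motif(detected, params.use_revcomp) == canonical_motif(
        target, params.use_revcomp
    ):
        return True
    if max(len(detected), len(target)) <= _EXHAUSTIVE_MOTIF_MAX:
        return False
    # Approximate path.  For two long motifs the shorter one must align
    # within the other's concatemer at >= 80% identity; for mixed lengths
    # the LONG motif must be an approximate concatemer of the short one
    # (otherwise a tiny shared substring would spuriously match).
    if min(len(detected), len(target)) > _EXHAUSTIVE_MOTIF_MAX:
        # both long: the shorter motif must fit the other's concatemer;
        # equal lengths try both role assignments (symmetry)
        pairs = [tuple(sorted((detected, target), key=len))]
        if len(detected) == len(target):
            pairs.append((target, detected))
    else:
        short_m, long_m = sorted((detected, target), key=len)
        pairs = [(long_m, short_m)]
    for query, unit in pairs:
        copies = -(-len(query) // len(unit)) + 2
        for q in (query, revcomp(query)) if params.use_revcomp else (query,):
            if _concatemer_divergence(q, unit, copies) <= 0.2:
                return True
    return False
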