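"""Local alignment engine: affine-gap Smith-Waterman with k-mer seeding.

Small problems run exact dynamic programming against every reference; large
reads are first seeded with exact k-mer matches, clustered by diagonal, and
aligned only inside candidate windows.  Multiple non-overlapping hits per
read/reference pair are recovered by recursing into the query segments left
and right of each accepted alignment (equivalent to Waterman-Eggert style
masking, since no local path can cross an accepted interval's mask).

Sequences are encoded A=0 C=1 G=2 T=3, N=4 (mismatches everything), 5 is a
hard mask that no alignment may cross.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import AlignmentHit
from .seq import encode, revcomp, validate_alphabet

_NEG = -(10**9)


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring; a gap of length L costs ``gap_open + L*gap_extend``."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise ValueError("need gap_open <= 0 and gap_extend < 0")


@dataclass(frozen=True)
class RawHit:
    """Engine-internal hit in query-strand coordinates."""

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    score: int
    matches: int
    columns: int


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = len(a)
    m = len(b)
    NEG = -(10**9)
    prev_h = np.zeros(m + 1, np.int64)
    prev_f = np.full(m + 1, NEG, np.int64)
    # per cell: bits 0-1 H pointer (0 stop, 1 diag, 2 E, 3 F),
    # bit 2 E opened here, bit 3 F opened here
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur_h = np.zeros(m + 1, np.int64)
        cur_f = np.empty(m + 1, np.int64)
        cur_f[0] = NEG
        e = NEG
        for j in range(1, m + 1):
            bjc = b[j - 1]
            if ai >= 4 or bjc >= 4:
                s = NEG if (ai == 5 or bjc == 5) else mismatch
            else:
                s = match if ai == bjc else mismatch
            e_open = cur_h[j - 1] + gap_open + gap_extend
            e_ext = e + gap_extend
            if e_open >= e_ext:
                e = e_open
                eo = 1
            else:
                e = e_ext
                eo = 0
            f_open = prev_h[j] + gap_open + gap_extend
            f_ext = prev_f[j] + gap_extend
            if f_open >= f_ext:
                f = f_open
                fo = 1
            else:
                f = f_ext
                fo = 0
            cur_f[j] = f
            h = 0
            p = 0
            d = prev_h[j - 1] + s
            if d > h:
                h = d
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            cur_h[j] = h
            ptr[i, j] = p | (eo << 2) | (fo << 3)
            if h > best:
                best = h
                bi = i
                bj = j
        prev_h = cur_h
        prev_f = cur_f
    return best, bi, bj, ptr


@njit(cache=True)
def _sw_traceback(a, b, ptr, bi, bj):  # pragma: no cover
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0
    while True:
        p = ptr[i, j]
        if state == 0:
            d = p & 3
            if d == 0:
                break
            if d == 1:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif d == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # gap column consuming b[j-1]
            columns += 1
            opened = (ptr[i, j] >> 2) & 1
            j -= 1
            if opened:
                state = 0
        else:  # gap column consuming a[i-1]
            columns += 1
            opened = (ptr[i, j] >> 3) & 1
            i -= 1
            if opened:
                state = 0
    return i, j, matches, columns


def sw_align(a_codes: np.ndarray, b_codes: np.ndarray, scoring: Scoring) -> RawHit | None:
    """Best local alignment between two encoded sequences, or None if score 0."""
    if len(a_codes) == 0 or len(b_codes) == 0:
        return None
    score, bi, bj, ptr = _sw_fill(
        a_codes, b_codes, scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend,
    )
    if score <= 0:
        return None
    qi, rj, matches, columns = _sw_traceback(a_codes, b_codes, ptr, bi, bj)
    return RawHit(qi, bi, rj, bj, int(score), int(matches), int(columns))


def _hits_in_segment(
    a_codes: np.ndarray,
    b_codes: np.ndarray,
    scoring: Scoring,
    floor: int,
    offset: int,
    out: list[RawHit],
    depth: int = 0,
) -> None:
    if len(a_codes) < 30 or depth > 8:
        return
    hit = sw_align(a_codes, b_codes, scoring)
    if hit is None or hit.score < floor:
        return
    out.append(
        RawHit(
            hit.q_start + offset, hit.q_end + offset,
            hit.r_start, hit.r_end, hit.score, hit.matches, hit.columns,
        )
    )
    _hits_in_segment(
        a_codes[: hit.q_start], b_codes, scoring, floor, offset, out, depth + 1
    )
    _hits_in_segment(
        a_codes[hit.q_end:], b_codes, scoring, floor, offset + hit.q_end, out,
        depth + 1,
    )


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer codes; positions containing N/mask yield -1."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes < 4
    vals = codes.astype(np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for i in range(k):
        seg = vals[i : n - k + 1 + i]
        out = out * 4 + seg if i else seg.copy()
        ok &= valid[i : n - k + 1 + i]
    out[~ok] = -1
    return out


class Aligner:
    """Align reads against a fixed reference set on both strands."""

    def __init__(
        self,
        refs: list[tuple[str, str]],
        scoring: Scoring | None = None,
        *,
        k: int = 13,
        min_score: int = 60,
        window_pad: int = 150,
        diag_band: int = 150,
        min_seeds: int = 2,
        exact_max_cells: int = 262_144,
    ) -> None:
        if not refs:
            raise ValueError("empty reference set")
        self.scoring = scoring or Scoring()
        self.k = k
        self.min_score = min_score
        self.window_pad = window_pad
        self.diag_band = diag_band
        self.min_seeds = min_seeds
        self.exact_max_cells = exact_max_cells
        self.ref_ids: list[str] = []
        self.ref_codes: list[np.ndarray] = []
        index: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for ridx, (ref_id, ref_seq) in enumerate(refs):
            validate_alphabet(ref_seq, name=f"reference {ref_id!r}")
            codes = encode(ref_seq.upper())
            self.ref_ids.append(ref_id)
            self.ref_codes.append(codes)
            for pos, km in enumerate(_kmer_codes(codes, k)):
                if km >= 0:
                    index[int(km)].append((ridx, pos))
        self._index = dict(index)

    # -- seeding -----------------------------------------------------------

    def _seed_windows(self, q_codes: np.ndarray) -> list[tuple[int, int, int]]:
        """Candidate (ref_idx, q_start, q_end) windows from clustered seeds."""
        n = len(q_codes)
        kms = _kmer_codes(q_codes, self.k)
        seeds: dict[int, list[tuple[int, int]]] = defaultdict(list)
        idx = self._index
        for qpos, km in enumerate(kms):
            entry = idx.get(int(km))
            if entry is None:
                continue
            for ridx, rpos in entry:
                seeds[ridx].append((qpos - rpos, qpos))
        windows: list[tuple[int, int, int]] = []
        for ridx, pairs in seeds.items():
            ref_len = len(self.ref_codes[ridx])
            pairs.sort()
            cluster: list[tuple[int, int]] = []
            for diag, qpos in pairs + [(10**12, 0)]:
                if cluster and diag - cluster[-1][0] > self.diag_band:
                    if len(cluster) >= self.min_seeds:
                        diags = [d for d, _ in cluster]
                        q_lo = max(0, min(diags) - self.window_pad)
                        q_hi = min(
                            n, max(diags) + ref_len + self.window_pad
                        )
                        windows.append((ridx, q_lo, q_hi))
                    cluster = []
                cluster.append((diag, qpos))
        return windows

    # -- alignment ---------------------------------------------------------

    def _align_one_strand(
        self, q_codes: np.ndarray, floor: int
    ) -> list[tuple[int, RawHit]]:
        hits: list[tuple[int, RawHit]] = []
        n = len(q_codes)
        exact_refs = [
            ridx
            for ridx in range(len(self.ref_codes))
            if n * len(self.ref_codes[ridx]) <= self.exact_max_cells
        ]
        for ridx in exact_refs:
            out: list[RawHit] = []
            _hits_in_segment(q_codes, self.ref_codes[ridx], self.scoring, floor, 0, out)
            hits.extend((ridx, h) for h in out)
        exact_set = set(exact_refs)
        for ridx, q_lo, q_hi in self._seed_windows(q_codes):
            if ridx in exact_set:
                continue
            out = []
            _hits_in_segment(
                q_codes[q_lo:q_hi], self.ref_codes[ridx], self.scoring, floor,
                q_lo, out,
            )
            hits.extend((ridx, h) for h in out)
        return hits

    @staticmethod
    def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
        """Drop hits mostly covered by a better hit on the same ref/strand."""
        kept: list[AlignmentHit] = []
        for hit in sorted(hits, key=lambda h: (-h.score, h.read_start)):
            shadowed = False
            for other in kept:
                if other.ref_id != hit.ref_id or other.strand != hit.strand:
                    continue
                ov = min(other.read_end, hit.read_end) - max(
                    other.read_start, hit.read_start
                )
                if ov > 0.5 * hit.read_span:
                    shadowed = True
                    break
            if not shadowed:
                kept.append(hit)
        kept.sort(key=lambda h: (h.read_start, -h.score))
        return kept

    def align(
        self, read_seq: str, read_id: str = "read", floor: int | None = None
    ) -> list[AlignmentHit]:
        """All locally optimal non-overlapping hits on both strands.

        Hits are reported in forward-read coordinates, sorted by read start.
        """
        validate_alphabet(read_seq, name=f"read {read_id!r}")
        seq = read_seq.upper()
        floor = self.min_score if floor is None else floor
        n = len(seq)
        all_hits: list[AlignmentHit] = []
        for strand in "+-":
            q = seq if strand == "+" else revcomp(seq)
            q_codes = encode(q)
            for ridx, raw in self._align_one_strand(q_codes, floor):
                if strand == "+":
                    rs, re_ = raw.q_start, raw.q_end
                else:
                    rs, re_ = n - raw.q_end, n - raw.q_start
                identity = raw.matches / raw.columns if raw.columns else 0.0
                all_hits.append(
                    AlignmentHit(
                        read_id=read_id,
                        ref_id=self.ref_ids[ridx],
                        read_start=rs,
                        read_end=re_,
                        ref_start=raw.r_start,
                        ref_end=raw.r_end,
                        strand=strand,
                        identity=identity,
                        score=raw.score,
                        matches=raw.matches,
                    )
                )
        return self._dedupe(all_hits)


def align_pair(query: str, ref: str, scoring: Scoring | None = None) -> RawHit | None:
    """Exact best local alignment of two sequences (test/oracle front door)."""
    scoring = scoring or Scoring()
    return sw_align(encode(query.upper()), encode(ref.upper()), scoring)
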