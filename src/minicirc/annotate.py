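"""Annotation of assembled minicircles.

Pipeline: canonical rotation (ORF-anchored by default), ORF finding under
translation table 4 (TGA = Trp), constant-region/cassette segmentation by
cross-circle local alignment, tandem/dispersed repeat detection, and
single-linkage grouping of constant regions.

Circular coordinates: intervals are 0-based half-open on the canonical
rotation; ``end > len(seq)`` marks a feature wrapping past the origin.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from ._align import Aligner, Scoring, align_pair
from .core import MinicircleSpec, RepeatAnnotation
from .seq import encode, revcomp, rotate, validate_alphabet


# ---------------------------------------------------------------------------
# canonical rotation


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    d = s + s
    f = [-1] * len(d)
    k = 0
    for j in range(1, len(d)):
        sj = d[j]
        i = f[j - k - 1]
        while i != -1 and sj != d[k + i + 1]:
            if sj < d[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != d[k + i + 1]:
            if sj < d[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonicalize_rotation(seq: str, mode: str = "orf_anchored") -> str:
    """Return the canonical rotation of a circular sequence (idempotent).

    ``lexicographic``: the least rotation.  ``orf_anchored``: rotate (and
    strand-flip if needed) so the longest table-4 ORF starts at position 0;
    ties and ORF-free sequences fall back to the lexicographically smallest
    candidate/rotation.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if mode == "lexicographic":
        return rotate(seq, _least_rotation(seq))
    if mode != "orf_anchored":
        raise ValueError(f"unknown canonicalization mode {mode!r}")
    orfs = find_orfs_table4(seq, min_len_aa=10) if len(seq) >= 3 else []
    if not orfs:
        return rotate(seq, _least_rotation(seq))
    best_len = max(len(o.protein) for o in orfs)
    candidates = []
    for orf in orfs:
        if len(orf.protein) != best_len:
            continue
        if orf.strand == "+":
            candidates.append(rotate(seq, orf.start))
        else:
            rc = revcomp(seq)
            # ORF start on the reverse-complement strand
            rc_start = (len(seq) - orf.end) % len(seq)
            candidates.append(rotate(rc, rc_start))
    return min(candidates)


# ---------------------------------------------------------------------------
# ORF finding (translation table 4)


@dataclass(frozen=True)
class OrfHit:
    """An open reading frame on a circular sequence.

    ``start``/``end`` are forward-strand circle coordinates of the full ORF
    including the stop codon; ``end > circle length`` means the ORF wraps.
    """

    start: int
    end: int
    strand: str
    frame: int
    protein: str


_STOPS = {"TAA", "TAG"}  # table 4: TGA codes Trp


def _scan_frames(s: str, L: int, min_len_aa: int, circular: bool) -> list[tuple[int, int, int]]:
    """(start, end, frame) of ATG..stop ORFs on one strand."""
    d = s + s if circular else s
    found: list[tuple[int, int, int]] = []
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(d) - 2, 3):
            codon = d[pos : pos + 3]
            if codon in _STOPS:
                if start is not None:
                    aa = (pos - start) // 3
                    if aa >= min_len_aa and (pos + 3 - start) <= L and start < L:
                        found.append((start, pos + 3, frame))
                start = None
            elif start is None and codon == "ATG":
                start = pos
    # dedupe wrapped duplicates (same ORF seen at start and start+L)
    uniq: dict[int, tuple[int, int, int]] = {}
    for start, end, frame in found:
        uniq.setdefault(start % L, (start, end, frame))
    return list(uniq.values())


def find_orfs_table4(
    seq: str, min_len_aa: int, circular: bool = True, min_len_nt: int = 3
) -> list[OrfHit]:
    """Six-frame ORF search requiring an ATG start; wrap-aware if circular.

    Returned proteins exclude the stop codon; under table 4 only TAA/TAG
    terminate and TGA is translated as tryptophan.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    validate_alphabet(seq)
    seq = seq.upper()
    L = len(seq)
    hits: list[OrfHit] = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for start, end, frame in _scan_frames(s, L, min_len_aa, circular):
            nt = (s + s)[start : end - 3]
            protein = str(Seq(nt).translate(table=4))
            if strand == "+":
                fwd_start, fwd_end = start, end
            else:
                fwd_start = (L - (end % L)) % L
                fwd_end = fwd_start + (end - start)
            hits.append(OrfHit(fwd_start, fwd_end, strand, frame, protein))
    hits.sort(key=lambda o: (-len(o.protein), o.strand, o.start))
    return hits


# ---------------------------------------------------------------------------
# tandem and dispersed repeats


@dataclass(frozen=True)
class TandemArray:
    unit_seq: str
    copies: float
    interval: tuple[int, int]
    tandem: bool = True

    @property
    def period(self) -> int:
        return len(self.unit_seq)


def _smallest_period(codes: np.ndarray, p_max: int) -> int:
    n = len(codes)
    for q in range(1, p_max + 1):
        if n - q <= 0 or bool(np.all(codes[: n - q] == codes[q:])):
            return q
    return p_max


def detect_tandem_repeats(
    region: str, max_unit: int = 50, min_copies: float = 2.0
) -> list[TandemArray]:
    """Maximal tandem arrays with primitive (smallest-period) units.

    Copy numbers may be fractional for partial terminal units.  An array is
    reported only at its smallest period, so ``ACGACGACG`` yields one entry
    (unit ``ACG``, 3.0 copies), not additional period-6 duplicates.
    """
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    region = region.upper()
    n = len(region)
    codes = encode(region)
    out: list[TandemArray] = []
    for p in range(1, min(max_unit, n // 2) + 1):
        eq = codes[: n - p] == codes[p:]
        # maximal runs of equality at lag p
        i = 0
        while i < len(eq):
            if not eq[i]:
                i += 1
                continue
            j = i
            while j < len(eq) and eq[j]:
                j += 1
            start, end = i, j + p  # array interval in region coordinates
            copies = (end - start) / p
            if copies >= min_copies:
                sub = codes[start:end]
                if _smallest_period(sub, p) == p:
                    out.append(
                        TandemArray(
                            unit_seq=region[start : start + p],
                            copies=copies,
                            interval=(start, end),
                        )
                    )
            i = j + 1
    out.sort(key=lambda t: (t.interval, t.period))
    return out


def find_dispersed_repeats(
    region: str, min_len: int = 15
) -> list[TandemArray]:
    """Maximal exact repeats occurring >= 2 times non-adjacently.

    Greedy seed-and-extend on exact ``min_len``-mers; each family is the
    maximal common extension of all its occurrences.  Used to catalogue
    dispersed (non-tandem) repeat-region copies.
    """
    region = region.upper()
    n = len(region)
    occ: dict[str, list[int]] = defaultdict(list)
    for i in range(n - min_len + 1):
        occ[region[i : i + min_len]].append(i)
    seeds = [(k, v) for k, v in occ.items() if len(v) >= 2]
    seeds.sort(key=lambda kv: (-len(kv[1]), kv[1][0]))
    covered = np.zeros(n, dtype=bool)
    out: list[TandemArray] = []
    for kmer, positions in seeds:
        if any(covered[p] for p in positions):
            continue
        left = 0
        while all(
            p - left - 1 >= 0 and region[p - left - 1] == region[positions[0] - left - 1]
            for p in positions
        ):
            left += 1
        right = 0
        while all(
            p + min_len + right < n
            and region[p + min_len + right] == region[positions[0] + min_len + right]
            for p in positions
        ):
            right += 1
        start0 = positions[0] - left
        length = min_len + left + right
        # skip families that are really one tandem run
        if all(b - a == length for a, b in zip(positions, positions[1:])):
            continue
        for p in positions:
            covered[p - left : p - left + length] = True
        out.append(
            TandemArray(
                unit_seq=region[start0 : start0 + length],
                copies=float(len(positions)),
                interval=(start0, start0 + length),
                tandem=False,
            )
        )
    out.sort(key=lambda t: t.interval)
    return out


# ---------------------------------------------------------------------------
# segmentation and grouping


@dataclass
class AnnotationResult:
    circles: list[MinicircleSpec]
    groups: dict[str, str]  # circle_id -> group label
    repeat_catalog: dict[str, list[TandemArray]]
    flags: list[str] = field(default_factory=list)
    low_confidence: set[str] = field(default_factory=set)


def _covered_runs(mask: np.ndarray, max_gap: int = 50) -> list[tuple[int, int]]:
    """Maximal True runs, bridging internal gaps up to ``max_gap``.

    Wrap-aware: the mask describes a circular coordinate system, so a run
    touching both ends is reported once with ``end > len(mask)``.
    """
    L = len(mask)
    idx = np.flatnonzero(np.concatenate([mask, mask]))
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev > max_gap:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    out = []
    for a, b in runs:
        if a >= L:  # duplicate image of a run already seen
            continue
        out.append((a, min(b, a + L)))
    # drop non-wrapping runs that are contained in a wrapping run's image
    wrapped = [(a, b) for a, b in out if b > L]
    if wrapped:
        filtered = []
        for a, b in out:
            inside = any(
                (a >= wa and b <= wb) or (a + L >= wa and b + L <= wb)
                for wa, wb in wrapped
                if (a, b) != (wa, wb)
            )
            if not inside:
                filtered.append((a, b))
        out = filtered
    return out


def _linear_runs(mask: np.ndarray, max_gap: int = 50) -> list[tuple[int, int]]:
    """Maximal True runs on a linear mask, bridging gaps up to ``max_gap``."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev > max_gap:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def group_constant_regions(
    arcs: dict[str, str], link_identity: float = 0.80
) -> dict[str, str]:
    """Single-linkage clustering of constant arcs by alignment identity.

    Pairwise similarity is local-alignment matches over the mean arc
    length; cluster labels G1, G2, ... are assigned by the smallest member
    circle id, so the partition is input-order independent.
    """
    ids = sorted(arcs)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i_idx, a in enumerate(ids):
        for b in ids[i_idx + 1 :]:
            sa, sb = arcs[a], arcs[b]
            if not sa or not sb:
                continue
            best = 0
            for query in (sa, revcomp(sa)):  # arcs may be on either strand
                hit = align_pair(query, sb)
                if hit is not None:
                    best = max(best, hit.matches)
            sim = best / ((len(sa) + len(sb)) / 2)
            if sim >= link_identity:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, list[str]] = defaultdict(list)
    for cid in ids:
        clusters[find(cid)].append(cid)
    labels: dict[str, str] = {}
    for gi, root in enumerate(sorted(clusters), start=1):
        for cid in clusters[root]:
            labels[cid] = f"G{gi}"
    return labels


def segment_constant_cassette(
    circles: Sequence[tuple[str, str]] | Sequence[str],
    min_share: int = 2,
    min_identity: float = 0.90,
    link_identity: float = 0.80,
    max_gap: int = 50,
    scoring: Scoring | None = None,
) -> AnnotationResult:
    """Infer constant-region vs cassette segmentation across circles.

    The constant region of a circle is the longest arc locally aligned at
    >= ``min_identity`` identity in >= ``min_share`` circles (the circle
    itself included); the cassette is the complementary arc and must
    contain the longest ORF.  Constant arcs are then clustered into
    constant groups and scanned for tandem/dispersed repeats.
    """
    if len(circles) < 2:
        raise ValueError("segmentation requires at least 2 circles")
    named: list[tuple[str, str]] = []
    for i, item in enumerate(circles):
        if isinstance(item, str):
            named.append((f"circle{i:02d}", item))
        else:
            named.append((str(item[0]), item[1]))
    ids = [cid for cid, _ in named]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate circle ids")

    canon = {cid: canonicalize_rotation(seq) for cid, seq in named}
    flags: list[str] = []
    seen: dict[str, str] = {}
    for cid, seq in canon.items():
        if seq in seen:
            flags.append(f"identical_circles:{seen[seq]}+{cid}")
        else:
            seen[seq] = cid

    aligner = Aligner(
        [(cid, canon[cid]) for cid in ids],
        scoring=scoring or Scoring(),
        min_score=100,
    )
    share: dict[str, np.ndarray] = {cid: np.zeros(len(canon[cid]), dtype=int) for cid in ids}
    for cid in ids:
        hits = aligner.align(canon[cid], read_id=cid)
        partner_cover: dict[str, np.ndarray] = {}
        for h in hits:
            if h.ref_id == cid:
                continue
            # gap-tolerant support: repeat copy-number differences open large
            # gaps that depress column identity without implying divergence
            den = min(h.read_span, h.ref_span)
            if den == 0 or h.matches / den < min_identity:
                continue
            cover = partner_cover.setdefault(
                h.ref_id, np.zeros(len(canon[cid]), dtype=bool)
            )
            cover[h.read_start : h.read_end] = True
        for cover in partner_cover.values():
            share[cid] += cover

    specs: list[MinicircleSpec] = []
    arcs: dict[str, str] = {}
    low_confidence: set[str] = set()
    for cid in ids:
        seq = canon[cid]
        L = len(seq)
        mask = share[cid] >= (min_share - 1)
        runs = _covered_runs(mask, max_gap=max_gap)
        orfs = find_orfs_table4(seq, min_len_aa=10)
        cds_iv = (orfs[0].start, orfs[0].end) if orfs else None
        if runs:
            const_iv = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
            # majority refinement: a single partner's chance overhang into the
            # cassette should not move the boundary when many circles agree
            doubled = np.concatenate([share[cid], share[cid]])
            a0, b0 = const_iv
            peak = int(doubled[a0:b0].max())
            strong_thr = max(min_share - 1, (peak + 1) // 2)
            if strong_thr > min_share - 1:
                sub = _linear_runs(doubled[a0:b0] >= strong_thr, max_gap=max_gap)
                if sub:
                    ra, rb = max(sub, key=lambda r: (r[1] - r[0], -r[0]))
                    # refinement may only trim edges, not re-segment
                    if rb - ra >= 0.7 * (b0 - a0):
                        const_iv = (a0 + ra, a0 + rb)
        else:
            const_iv = (L, L)
            low_confidence.add(cid)
            flags.append(f"no_shared_arc:{cid}")
        a, b = const_iv
        if (a, b) == (L, L):
            cassette_iv = (0, L)
        elif b > L:  # constant wraps the origin
            cassette_iv = (b - L, a)
        else:
            cassette_iv = (b, a + L)
        if cds_iv is not None and (a, b) != (L, L) and b <= L:
            # longest ORF must fall in the cassette arc (contains position 0)
            if not (cds_iv[0] >= b or cds_iv[1] <= a or cds_iv[0] == 0):
                low_confidence.add(cid)
                flags.append(f"orf_overlaps_constant:{cid}")
        spec = MinicircleSpec(
            circle_id=cid,
            sequence=seq,
            gene=f"{cid}_orf",
            cassette_interval=cassette_iv,
            constant_interval=const_iv,
            constant_group="",
            cds_interval=cds_iv,
        )
        arcs[cid] = spec.constant_seq
        specs.append(spec)

    groups = group_constant_regions(arcs, link_identity=link_identity)
    catalog: dict[str, list[TandemArray]] = {}
    for spec in specs:
        spec.constant_group = groups[spec.circle_id]
        arc = arcs[spec.circle_id]
        offset = spec.constant_interval[0]
        if not arc:  # singleton group: no shared arc, scan the whole circle
            arc = spec.sequence
            offset = 0
        entries = detect_tandem_repeats(arc, max_unit=50, min_copies=2.0)
        entries += find_dispersed_repeats(arc, min_len=15)
        catalog[spec.circle_id] = [
            TandemArray(
                t.unit_seq, t.copies,
                (t.interval[0] + offset, t.interval[1] + offset), t.tandem,
            )
            for t in entries
        ]
        spec.repeat_regions = [
            RepeatAnnotation(
                region_id=f"R{k + 1}",
                interval=t.interval,
                unit_seq=t.unit_seq,
                copies=float(int(t.copies)),  # floored for integer reporting
                tandem=t.tandem,
            )
            for k, t in enumerate(catalog[spec.circle_id])
        ]

    return AnnotationResult(
        circles=specs,
        groups=groups,
        repeat_catalog=catalog,
        flags=flags,
        low_confidence=low_confidence,
    )


# ---------------------------------------------------------------------------
# GFF3 output


def write_annotation_gff(result: AnnotationResult, path) -> None:
    """Write a GFF3-like annotation (wrapping features split in two)."""
    lines = ["##gff-version 3"]
    for spec in result.circles:
        L = len(spec.sequence)
        lines.append(f"##sequence-region {spec.circle_id} 1 {L}")

        def emit(ftype: str, iv: tuple[int, int], attrs: str) -> None:
            a, b = iv
            if b - a <= 0:
                return
            parts = [(a % L, min(b, L) if b <= L else L)] if a < L else []
            if b > L:
                parts = [(a, L), (0, b - L)]
            for pa, pb in parts:
                if pb - pa <= 0:
                    continue
                lines.append(
                    "\t".join(
                        [
                            spec.circle_id, "minicirc", ftype,
                            str(pa + 1), str(pb), ".", "+", ".", attrs,
                        ]
                    )
                )

        emit("cassette", spec.cassette_interval, f"ID={spec.circle_id}.cassette")
        if spec.cds_interval:
            emit("CDS", spec.cds_interval, f"ID={spec.circle_id}.cds")
        emit(
            "constant_region",
            spec.constant_interval,
            f"ID={spec.circle_id}.constant;group={spec.constant_group}",
        )
        for r in spec.repeat_regions:
            emit(
                "repeat_region",
                r.interval,
                f"ID={spec.circle_id}.{r.region_id};unit_seq={r.unit_seq};"
                f"copies={r.copies:g};tandem={str(r.tandem).lower()}",
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
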