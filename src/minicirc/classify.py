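"""Read-to-reference alignment, identity/coverage filters and length stats.

Reads are aligned locally to mitochondrial CDS references on both strands;
hits are filtered in one of three modes:

* ``collect``     — identity >= 0.80 (read collection threshold);
* ``strict``      — identity >= 0.90 and reference coverage >= 80% of the
  CDS length (length-distribution threshold);
* ``intron_rich`` — identity >= 0.90 and hit length >= 200 bp, for genes
  where full-CDS coverage is unattainable in a single exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import Aligner, Scoring
from .core import AlignmentHit, MinicircleSpec, ReadRecord

FILTER_MODES = ("collect", "strict", "intron_rich")


@dataclass(frozen=True)
class ClassifierConfig:
    min_identity_collect: float = 0.80
    min_identity_strict: float = 0.90
    min_cds_fraction: float = 0.80
    min_hit_len_intron_rich: int = 200
    scoring: Scoring = field(default_factory=Scoring)
    min_score: int = 60
    kmer_size: int = 13
    max_read_overlap: int = 20

    def __post_init__(self) -> None:
        for name in ("min_identity_collect", "min_identity_strict", "min_cds_fraction"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.min_hit_len_intron_rich < 1:
            raise ValueError("min_hit_len_intron_rich must be >= 1")


def build_aligner(
    refs: Sequence[tuple[str, str]], config: ClassifierConfig | None = None
) -> Aligner:
    """Construct the shared alignment engine from a reference set."""
    config = config or ClassifierConfig()
    return Aligner(
        list(refs),
        scoring=config.scoring,
        k=config.kmer_size,
        min_score=config.min_score,
    )


def align_read_to_refs(
    read: ReadRecord,
    refs: Sequence[tuple[str, str]],
    config: ClassifierConfig | None = None,
    aligner: Aligner | None = None,
) -> list[AlignmentHit]:
    """Locally align one read against all references, both strands.

    Returns every locally optimal, per-reference non-overlapping hit with
    score above the configured floor; pass a prebuilt ``aligner`` when
    calling in a loop to avoid re-indexing the references.
    """
    config = config or ClassifierConfig()
    if aligner is None:
        aligner = build_aligner(refs, config)
    return aligner.align(read.sequence, read_id=read.read_id)


def filter_hits(
    hits: Sequence[AlignmentHit],
    refs: Mapping[str, str] | Sequence[tuple[str, str]],
    config: ClassifierConfig | None = None,
    mode: str = "collect",
) -> list[AlignmentHit]:
    """Apply the identity/coverage filter for the given mode."""
    config = config or ClassifierConfig()
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown filter mode {mode!r}; expected one of {FILTER_MODES}")
    ref_lens = {
        rid: len(seq)
        for rid, seq in (refs.items() if isinstance(refs, Mapping) else refs)
    }
    kept: list[AlignmentHit] = []
    for hit in hits:
        if hit.ref_id not in ref_lens:
            raise ValueError(f"hit references unknown reference {hit.ref_id!r}")
        if mode == "collect":
            ok = hit.identity >= config.min_identity_collect
        elif mode == "strict":
            ok = (
                hit.identity >= config.min_identity_strict
                and hit.ref_span >= config.min_cds_fraction * ref_lens[hit.ref_id]
            )
        else:  # intron_rich
            ok = (
                hit.identity >= config.min_identity_strict
                and hit.read_span >= config.min_hit_len_intron_rich
            )
        if ok:
            kept.append(hit)
    return kept


def resolve_read_overlaps(
    hits: Sequence[AlignmentHit], max_overlap: int = 20
) -> list[AlignmentHit]:
    """Greedy score-descending selection of hits on one read.

    Hits overlapping an already kept hit by more than ``max_overlap`` bp on
    the read are discarded (tolerates alignment end wobble).
    """
    kept: list[AlignmentHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.read_start, h.ref_id)):
        ok = True
        for other in kept:
            ov = min(other.read_end, hit.read_end) - max(
                other.read_start, hit.read_start
            )
            if ov > max_overlap:
                ok = False
                break
        if ok:
            kept.append(hit)
    kept.sort(key=lambda h: h.read_start)
    return kept


@dataclass
class GeneLengthStats:
    """Read-length histogram for reads assigned to one gene."""

    gene: str
    lengths: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_length: float
    empty: bool
    circle_length: int | None = None
    mode_relative_error: float | None = None


def length_distribution(
    reads: Sequence[ReadRecord],
    kept_hits: Sequence[AlignmentHit],
    circles: Sequence[MinicircleSpec] | None = None,
    bin_width: int = 50,
) -> dict[str, GeneLengthStats]:
    """Per-gene histograms of full read lengths for reads with a kept hit.

    ``kept_hits`` should already be strict-filtered.  The modal length is
    the count-weighted mean length inside the modal bin, so a degenerate
    distribution reports its exact length.  When truth circles are given,
    ``mode_relative_error`` is |mode - circle length| / circle length.
    """
    read_len = {r.read_id: len(r.sequence) for r in reads}
    genes = sorted({h.ref_id for h in kept_hits})
    circle_len = {c.gene: len(c) for c in circles} if circles else {}
    genes = sorted(set(genes) | set(circle_len))

    by_gene: dict[str, set[str]] = {g: set() for g in genes}
    for hit in kept_hits:
        by_gene[hit.ref_id].add(hit.read_id)

    out: dict[str, GeneLengthStats] = {}
    for gene in genes:
        lengths = np.array(
            sorted(read_len[rid] for rid in by_gene[gene]), dtype=float
        )
        if lengths.size == 0:
            out[gene] = GeneLengthStats(
                gene, lengths, np.empty(0), np.empty(0), float("nan"), True,
                circle_len.get(gene), None,
            )
            continue
        lo = np.floor(lengths.min() / bin_width) * bin_width
        hi = np.ceil((lengths.max() + 1) / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(lengths, bins=edges)
        modal_bin = int(np.argmax(counts))
        in_bin = lengths[
            (lengths >= edges[modal_bin]) & (lengths < edges[modal_bin + 1])
        ]
        modal_length = float(in_bin.mean())
        rel_err = None
        if gene in circle_len:
            rel_err = abs(modal_length - circle_len[gene]) / circle_len[gene]
        out[gene] = GeneLengthStats(
            gene, lengths, edges, counts, modal_length, False,
            circle_len.get(gene), rel_err,
        )
    return out


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    """Hits as the TSV-ready table used by the CLI."""
    return pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "ref_id": h.ref_id,
                "read_start": h.read_start,
                "read_end": h.read_end,
                "ref_start": h.ref_start,
                "ref_end": h.ref_end,
                "strand": h.strand,
                "identity": round(h.identity, 6),
                "score": h.score,
            }
            for h in hits
        ],
        columns=[
            "read_id", "ref_id", "read_start", "read_end",
            "ref_start", "ref_end", "strand", "identity", "score",
        ],
    )


def frame_to_hits(df: pd.DataFrame) -> list[AlignmentHit]:
    return [
        AlignmentHit(
            read_id=row.read_id,
            ref_id=row.ref_id,
            read_start=int(row.read_start),
            read_end=int(row.read_end),
            ref_start=int(row.ref_start),
            ref_end=int(row.ref_end),
            strand=row.strand,
            identity=float(row.identity),
            score=int(row.score),
        )
        for row in df.itertuples()
    ]
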