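"""Decompose mitochondrial reads into minicircle units and classify them.

A read is an ordered list of units (gene cassettes and constant regions in
read coordinates).  Categories:

* ``non_mito``  — no gene unit;
* ``single``    — exactly one gene unit;
* ``homo``      — >= 2 co-oriented units of one gene (rolling-circle candidate);
* ``hetero``    — >= 2 distinct genes joined (recombination evidence);
* ``ambiguous`` — conflicting or inverted alignments that fit no category.

A linearized single circle cut inside its cassette produces two partial
same-gene hits flanking one constant region; these are recognised by their
near-disjoint reference intervals (one circular traversal) and merged into
one wrapped unit, so they do not inflate the concatemer count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .classify import ClassifierConfig, filter_hits, resolve_read_overlaps
from .core import AlignmentHit

CATEGORIES = ("single", "homo", "hetero", "non_mito", "ambiguous")


@dataclass
class Unit:
    """One decomposed element of a read."""

    kind: str  # "gene" | "constant"
    label: str
    read_start: int
    read_end: int
    strand: str
    ref_intervals: list[tuple[int, int]]
    ref_len: int
    identity: float
    wrapped: bool = False

    @property
    def coverage(self) -> float:
        covered = sum(b - a for a, b in _merge_intervals(self.ref_intervals))
        return covered / self.ref_len if self.ref_len else 0.0


@dataclass
class ReadClassification:
    read_id: str
    units: list[Unit]
    unit_count: int
    category: str
    confidence: str  # "high" | "low"
    structure: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class ConcatemerReport:
    counts: dict[str, int]
    edges: dict[tuple[str, str], int]
    structures: list[str]
    flagged_edges: dict[tuple[str, str], bool] = field(default_factory=dict)


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _interval_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    for a0, a1 in a:
        for b0, b1 in b:
            total += max(0, min(a1, b1) - max(a0, b0))
    return total


@dataclass
class Decomposition:
    units: list[Unit]
    conflict: bool  # a discarded distinct-gene hit overlapped a kept gene hit


def decompose_read(
    read_id: str,
    gene_hits: Sequence[AlignmentHit],
    constant_hits: Sequence[AlignmentHit],
    gene_ref_lengths: Mapping[str, int],
    constant_ref_lengths: Mapping[str, int],
    max_overlap: int = 20,
    wrap_tolerance: int = 20,
) -> Decomposition:
    """Order collect-filtered hits into minicircle units on the read.

    Adjacent same-gene hits without an intervening constant unit are merged
    (split alignments); a terminal same-gene pair with near-disjoint
    reference intervals is merged as a wrapped single traversal.
    """
    resolved = resolve_read_overlaps(
        list(gene_hits) + list(constant_hits), max_overlap=max_overlap
    )
    kept_gene = [h for h in resolved if h.ref_id in gene_ref_lengths]

    conflict = False
    for hit in gene_hits:
        if hit in resolved:
            continue
        for kept in kept_gene:
            if kept.ref_id == hit.ref_id:
                continue
            ov = min(kept.read_end, hit.read_end) - max(kept.read_start, hit.read_start)
            if ov > 0.5 * hit.read_span:
                conflict = True

    units: list[Unit] = []
    for hit in resolved:
        if hit.ref_id in gene_ref_lengths:
            kind, ref_len = "gene", gene_ref_lengths[hit.ref_id]
        elif hit.ref_id in constant_ref_lengths:
            kind, ref_len = "constant", constant_ref_lengths[hit.ref_id]
        else:
            raise ValueError(f"hit references unknown sequence {hit.ref_id!r}")
        units.append(
            Unit(
                kind=kind,
                label=hit.ref_id,
                read_start=hit.read_start,
                read_end=hit.read_end,
                strand=hit.strand,
                ref_intervals=[(hit.ref_start, hit.ref_end)],
                ref_len=ref_len,
                identity=hit.identity,
            )
        )
    units.sort(key=lambda u: u.read_start)

    # merge adjacent same-gene units with no constant unit between them
    merged: list[Unit] = []
    for unit in units:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and unit.kind == "gene"
            and prev.kind == "gene"
            and prev.label == unit.label
            and prev.strand == unit.strand
            and _interval_overlap(prev.ref_intervals, unit.ref_intervals)
            <= wrap_tolerance
            and prev.coverage + unit.coverage <= 1.05
        ):
            prev.read_end = unit.read_end
            prev.ref_intervals.extend(unit.ref_intervals)
            continue
        merged.append(unit)
    units = merged

    # wrapped single traversal: first/last gene units are complementary parts
    gene_idx = [i for i, u in enumerate(units) if u.kind == "gene"]
    if len(gene_idx) >= 2:
        first, last = units[gene_idx[0]], units[gene_idx[-1]]
        if (
            first is not last
            and first.label == last.label
            and first.strand == last.strand
            and _interval_overlap(first.ref_intervals, last.ref_intervals)
            <= wrap_tolerance
            and first.coverage + last.coverage <= 1.05
        ):
            first.ref_intervals.extend(last.ref_intervals)
            first.wrapped = True
            del units[gene_idx[-1]]

    return Decomposition(units=units, conflict=conflict)


def classify_read(
    decomposition: Decomposition | list[Unit],
    config: ClassifierConfig | None = None,
    read_id: str = "read",
    junction_constant_fraction: float = 0.8,
    junction_min_identity: float = 0.8,
) -> ReadClassification:
    """Assign a category and confidence to a decomposed read."""
    config = config or ClassifierConfig()
    if isinstance(decomposition, Decomposition):
        units, conflict = decomposition.units, decomposition.conflict
    else:
        units, conflict = list(decomposition), False

    gene_units = [u for u in units if u.kind == "gene"]
    distinct = {u.label for u in gene_units}

    if not gene_units:
        category = "non_mito"
    elif len(gene_units) == 1:
        category = "single"
    else:
        # a junction with no constant copy between distinct genes, or a
        # conflicting overlapped alignment, is treated as a possible chimera
        bad_junction = False
        positions = [i for i, u in enumerate(units) if u.kind == "gene"]
        for a, b in zip(positions, positions[1:]):
            between = units[a + 1 : b]
            if units[a].label != units[b].label and not any(
                u.kind == "constant" for u in between
            ):
                bad_junction = True
        co_oriented = len({u.strand for u in gene_units}) == 1
        if conflict or bad_junction:
            category = "ambiguous"
        elif len(distinct) == 1:
            category = "homo" if co_oriented else "ambiguous"
        else:
            category = "hetero"

    confidence = "high"
    if gene_units:
        if any(u.coverage < config.min_cds_fraction for u in gene_units):
            confidence = "low"
        positions = [i for i, u in enumerate(units) if u.kind == "gene"]
        for a, b in zip(positions, positions[1:]):
            between = [u for u in units[a + 1 : b] if u.kind == "constant"]
            if not any(
                u.coverage >= junction_constant_fraction
                and u.identity >= junction_min_identity
                for u in between
            ):
                confidence = "low"
    if category == "ambiguous":
        confidence = "low"

    structure = "-".join(
        (f"{u.label}({u.strand})" + ("*" if u.wrapped else ""))
        if u.kind == "gene"
        else u.label
        for u in units
    )
    return ReadClassification(
        read_id=read_id,
        units=units,
        unit_count=len(gene_units),
        category=category,
        confidence=confidence,
        structure=structure,
    )


def classify_hits(
    read_id: str,
    hits: Sequence[AlignmentHit],
    gene_refs: Mapping[str, str],
    constant_refs: Mapping[str, str],
    config: ClassifierConfig | None = None,
) -> ReadClassification:
    """Collect-filter raw hits for one read, decompose and classify."""
    config = config or ClassifierConfig()
    all_refs = dict(gene_refs) | dict(constant_refs)
    kept = filter_hits(hits, all_refs, config, mode="collect")
    gene_hits = [h for h in kept if h.ref_id in gene_refs]
    constant_hits = [h for h in kept if h.ref_id in constant_refs]
    decomp = decompose_read(
        read_id,
        gene_hits,
        constant_hits,
        {g: len(s) for g, s in gene_refs.items()},
        {c: len(s) for c, s in constant_refs.items()},
        max_overlap=config.max_read_overlap,
    )
    return classify_read(decomp, config, read_id=read_id)


def summarize_concatemers(
    classifications: Sequence[ReadClassification],
) -> ConcatemerReport:
    """Category counts, gene-pair network and concatemer structure strings."""
    counts = {c: 0 for c in CATEGORIES}
    edges: Counter[tuple[str, str]] = Counter()
    structures: list[str] = []
    for cls in classifications:
        counts[cls.category] += 1
        if cls.category in {"homo", "hetero"}:
            structures.append(cls.structure)
        gene_labels = [u.label for u in cls.units if u.kind == "gene"]
        if cls.category == "hetero":
            for a, b in zip(gene_labels, gene_labels[1:]):
                if a != b:
                    edges[tuple(sorted((a, b)))] += 1
    return ConcatemerReport(
        counts=counts, edges=dict(edges), structures=structures
    )


def flag_incompatible_joins(
    report: ConcatemerReport, gene_to_group: Mapping[str, str]
) -> ConcatemerReport:
    """Flag gene-pair edges whose genes live in different constant groups.

    Such joins cannot arise from homologous recombination at shared
    constant regions and are suspect library/alignment artifacts.
    """
    flagged: dict[tuple[str, str], bool] = {}
    for a, b in report.edges:
        for gene in (a, b):
            if gene not in gene_to_group:
                raise ValueError(f"gene {gene!r} has no constant-group assignment")
        flagged[(a, b)] = gene_to_group[a] != gene_to_group[b]
    return replace(report, flagged_edges=flagged)
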