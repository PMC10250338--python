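"""Synthetic minicircle genomes and long-read sets with ground truth.

The generator produces species-level models of minicircular mitochondrial
genomes — each circle is one gene cassette (CDS plus short flanking NCR)
joined to a constant region shared within a constant group, with tandem
and dispersed repeat regions whose unit counts vary per circle — and
simulates nanopore-style long reads from them: single linearized circles,
homo-concatemers (tandem copies of one circle) and hetero-concatemers
(two distinct cassettes joined through a shared constant region).

Randomness uses one master seed; child streams are derived with fixed
offsets (``default_rng([seed, STREAM, index])``) so that every operation is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import MinicircleSpec, ReadRecord, ReadTruth, RepeatAnnotation
from .seq import DNA_BASES, encode, random_dna, revcomp

# fixed child-stream offsets
_STREAM_MODEL = 0
_STREAM_CASSETTE = 1
_STREAM_CIRCLE = 2
_STREAM_READ = 3

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# stop codons under translation table 4 (TGA = Trp)
_STOPS_TABLE4 = {"TAA", "TAG"}

DEFAULT_QUALITY_CHAR = "5"  # constant Q20 placeholder


# ---------------------------------------------------------------------------
# model types


@dataclass(frozen=True)
class RepeatRegionSlot:
    """A repeat-region slot inside a constant-region template."""

    region_id: str
    unit_seq: str
    min_units: int
    max_units: int
    tandem: bool = True
    anchor: int = 0
    spacers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.unit_seq) < 2:
            raise ValueError(f"repeat region {self.region_id}: unit length < 2 bp")
        if not 1 <= self.min_units <= self.max_units:
            raise ValueError(
                f"repeat region {self.region_id}: need 1 <= min_units <= max_units"
            )
        if not self.tandem and len(self.spacers) < self.max_units - 1:
            raise ValueError(
                f"repeat region {self.region_id}: non-tandem slot needs "
                f"{self.max_units - 1} spacers"
            )


@dataclass(frozen=True)
class ConstantTemplate:
    template_id: str
    backbone: str
    slots: tuple[RepeatRegionSlot, ...]

    def __post_init__(self) -> None:
        for slot in self.slots:
            if not 0 <= slot.anchor <= len(self.backbone):
                raise ValueError(
                    f"template {self.template_id}: slot {slot.region_id} anchor "
                    f"outside backbone"
                )


@dataclass(frozen=True)
class GeneSpec:
    name: str
    cds_length: int
    ncr_length: int
    gc: float

    def __post_init__(self) -> None:
        if self.cds_length % 3 != 0:
            raise ValueError(f"gene {self.name}: CDS length not divisible by 3")
        if self.cds_length < 9:
            raise ValueError(f"gene {self.name}: CDS too short")
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gene {self.name}: GC target must be in (0, 1)")


@dataclass(frozen=True)
class CirclePlanEntry:
    gene: str
    template: str
    units: dict[str, int] | None = None  # None => drawn within slot bounds


@dataclass
class SpeciesGenomeModel:
    """A species-level plan: genes, constant templates and circle layout."""

    species_id: str
    constant_templates: list[ConstantTemplate]
    genes: list[GeneSpec]
    circle_plan: list[CirclePlanEntry]
    gc_constant: float

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("model must contain at least one gene")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in model")
        if not 0.0 < self.gc_constant < 1.0:
            raise ValueError("gc_constant must be in (0, 1)")
        tids = {t.template_id for t in self.constant_templates}
        for entry in self.circle_plan:
            if entry.gene not in names:
                raise ValueError(f"circle plan references unknown gene {entry.gene!r}")
            if entry.template not in tids:
                raise ValueError(
                    f"circle plan references unknown template {entry.template!r}"
                )

    @property
    def gene_by_name(self) -> dict[str, GeneSpec]:
        return {g.name: g for g in self.genes}

    @property
    def template_by_id(self) -> dict[str, ConstantTemplate]:
        return {t.template_id: t for t in self.constant_templates}

    def gene_to_group(self) -> dict[str, str]:
        """Constant-group (template) label for every planned gene."""
        return {e.gene: e.template for e in self.circle_plan}


@dataclass(frozen=True)
class SimulationParams:
    """Read-simulation knobs; fractions partition the read mixture."""

    n_reads: int
    length_sigma_rel: float = 0.10
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    fraction_homo: float = 0.0
    fraction_hetero: float = 0.0
    fraction_background: float = 0.0
    background_gc: float = 0.45
    background_mean_len: int = 2000
    homo_copy_probs: tuple[float, ...] = (0.7, 0.2, 0.1)
    allow_cross_group_hetero: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.fraction_homo, self.fraction_hetero, self.fraction_background)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("mixture fractions must be in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("mixture fractions sum above 1")
        for rate in (self.sub_rate, self.indel_rate):
            if not 0.0 <= rate <= 0.3:
                raise ValueError("error rates must be in [0, 0.3]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


# ---------------------------------------------------------------------------
# model construction


def default_config() -> dict[str, Any]:
    """The bundled 13-circle / 3-constant-group demo configuration."""
    text = resources.files("minicirc.data").joinpath("demo_species.yaml").read_text()
    return yaml.safe_load(text)


def build_species_model(config: dict[str, Any]) -> SpeciesGenomeModel:
    """Validate a config document and realize template/unit sequences.

    Deterministic given the config (including its ``seed`` key): backbone,
    repeat-unit and spacer sequences are drawn from a child stream of the
    config seed.
    """
    seed = int(config.get("seed", 0))
    gc_constant = float(config.get("gc_constant", 0.5))
    rng = np.random.default_rng([seed, _STREAM_MODEL])

    genes_cfg = config.get("genes") or []
    if not genes_cfg:
        raise ValueError("config defines no genes")
    genes = [
        GeneSpec(
            name=g["name"],
            cds_length=int(g["cds_length"]),
            ncr_length=int(g.get("ncr_length", 150)),
            gc=float(g.get("gc", gc_constant)),
        )
        for g in genes_cfg
    ]

    templates: list[ConstantTemplate] = []
    for t in config.get("constant_templates") or []:
        backbone = random_dna(rng, int(t["length"]), gc_constant)
        slots_cfg = t.get("repeat_regions") or []
        n_slots = len(slots_cfg)
        slots = []
        for i, s in enumerate(slots_cfg):
            anchor = int(round(len(backbone) * (i + 1) / (n_slots + 1)))
            max_units = int(s["max_units"])
            tandem = bool(s.get("tandem", True))
            spacers: tuple[str, ...] = ()
            if not tandem:
                spacers = tuple(
                    random_dna(rng, int(s.get("spacer_length", 15)), gc_constant)
                    for _ in range(max(0, max_units - 1))
                )
            slots.append(
                RepeatRegionSlot(
                    region_id=str(s["id"]),
                    unit_seq=random_dna(rng, int(s["unit_length"]), gc_constant),
                    min_units=int(s["min_units"]),
                    max_units=max_units,
                    tandem=tandem,
                    anchor=anchor,
                    spacers=spacers,
                )
            )
        templates.append(
            ConstantTemplate(
                template_id=str(t["id"]), backbone=backbone, slots=tuple(slots)
            )
        )

    plan = [
        CirclePlanEntry(
            gene=str(e["gene"]),
            template=str(e["template"]),
            units={str(k): int(v) for k, v in e["units"].items()}
            if e.get("units")
            else None,
        )
        for e in config.get("circle_plan") or []
    ]
    return SpeciesGenomeModel(
        species_id=str(config.get("species_id", "species")),
        constant_templates=templates,
        genes=genes,
        circle_plan=plan,
        gc_constant=gc_constant,
    )


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + non-stop codons + TAA, codon bases drawn at the target GC."""
    n_codons = length // 3
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = random_dna(rng, 3, gc)
        if codon in _STOPS_TABLE4:
            continue
        codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def _realize_constant(
    template: ConstantTemplate, unit_counts: dict[str, int]
) -> tuple[str, list[RepeatAnnotation]]:
    """Insert repeat-region blocks into the backbone at their anchors."""
    pieces: list[str] = []
    annots: list[RepeatAnnotation] = []
    cursor = 0
    built = 0
    for slot in sorted(template.slots, key=lambda s: s.anchor):
        count = unit_counts.get(slot.region_id, slot.min_units)
        if not slot.min_units <= count <= slot.max_units:
            raise ValueError(
                f"region {slot.region_id}: unit count {count} outside "
                f"[{slot.min_units}, {slot.max_units}]"
            )
        pre = template.backbone[cursor : slot.anchor]
        pieces.append(pre)
        built += len(pre)
        if slot.tandem:
            block = slot.unit_seq * count
        else:
            parts = [slot.unit_seq]
            for i in range(count - 1):
                parts.append(slot.spacers[i])
                parts.append(slot.unit_seq)
            block = "".join(parts)
        annots.append(
            RepeatAnnotation(
                region_id=slot.region_id,
                interval=(built, built + len(block)),
                unit_seq=slot.unit_seq,
                copies=float(count),
                tandem=slot.tandem,
            )
        )
        pieces.append(block)
        built += len(block)
        cursor = slot.anchor
    pieces.append(template.backbone[cursor:])
    return "".join(pieces), annots


def generate_minicircles(
    model: SpeciesGenomeModel, seed: int
) -> list[MinicircleSpec]:
    """Realize the circle plan into concrete circular sequences.

    Circles sharing a gene share a byte-identical cassette; circles sharing
    a constant template are identical outside their repeat regions.  Unit
    counts not pinned in the plan are drawn uniformly within slot bounds.
    """
    gene_by_name = model.gene_by_name
    template_by_id = model.template_by_id

    cassettes: dict[str, tuple[str, str, str]] = {}
    for gi, gene in enumerate(model.genes):
        rng = np.random.default_rng([seed, _STREAM_CASSETTE, gi])
        half = gene.ncr_length // 2
        ncr5 = random_dna(rng, half, gene.gc)
        cds = _random_cds(rng, gene.cds_length, gene.gc)
        ncr3 = random_dna(rng, gene.ncr_length - half, gene.gc)
        cassettes[gene.name] = (ncr5, cds, ncr3)

    circles: list[MinicircleSpec] = []
    for idx, entry in enumerate(model.circle_plan):
        rng = np.random.default_rng([seed, _STREAM_CIRCLE, idx])
        template = template_by_id[entry.template]
        counts = dict(entry.units) if entry.units else {}
        for slot in template.slots:
            if slot.region_id not in counts:
                counts[slot.region_id] = int(
                    rng.integers(slot.min_units, slot.max_units + 1)
                )
        constant_seq, repeat_annots = _realize_constant(template, counts)
        ncr5, cds, ncr3 = cassettes[entry.gene]
        cassette = ncr5 + cds + ncr3
        sequence = cassette + constant_seq
        offset = len(cassette)
        circles.append(
            MinicircleSpec(
                circle_id=f"mc_{entry.gene}",
                sequence=sequence,
                gene=entry.gene,
                cassette_interval=(0, offset),
                constant_interval=(offset, len(sequence)),
                repeat_regions=[
                    RepeatAnnotation(
                        region_id=r.region_id,
                        interval=(offset + r.interval[0], offset + r.interval[1]),
                        unit_seq=r.unit_seq,
                        copies=r.copies,
                        tandem=r.tandem,
                    )
                    for r in repeat_annots
                ],
                constant_group=entry.template,
                cds_interval=(len(ncr5), len(ncr5) + len(cds)),
            )
        )
    return circles


# ---------------------------------------------------------------------------
# sequencing-error model


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    seed: int | np.random.Generator,
) -> str:
    """Inject substitutions and indels at the given per-base rates.

    Each base is substituted with probability ``sub_rate`` (always to a
    different base), deleted with probability ``indel_rate / 2``, and an
    insertion is placed before it with probability ``indel_rate / 2``.
    Deterministic given the seed.
    """
    for rate in (sub_rate, indel_rate):
        if not 0.0 <= rate <= 0.3:
            raise ValueError(f"rate {rate} outside [0, 0.3]")
    if not seq:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    codes = encode(seq).copy()
    n = len(codes)
    acgt = codes < 4

    u = rng.random(n)
    sub_mask = (u < sub_rate) & acgt
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        codes[sub_mask] = (codes[sub_mask] + shift) % 4

    v = rng.random(n)
    del_mask = v < indel_rate / 2.0
    ins_mask = v > 1.0 - indel_rate / 2.0
    if del_mask.any() or ins_mask.any():
        out = np.empty(n + int(ins_mask.sum()), dtype=np.uint8)
        ins_bases = rng.integers(0, 4, size=int(ins_mask.sum()))
        pos = 0
        k = 0
        for i in range(n):
            if ins_mask[i]:
                out[pos] = ins_bases[k]
                k += 1
                pos += 1
            if not del_mask[i]:
                out[pos] = codes[i]
                pos += 1
        codes = out[:pos]
    return _DECODE[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# read simulation


def _hetero_pool(
    circles: Sequence[MinicircleSpec], allow_cross_group: bool
) -> list[tuple[MinicircleSpec, MinicircleSpec]]:
    pairs: list[tuple[MinicircleSpec, MinicircleSpec]] = []
    for i, a in enumerate(circles):
        for b in circles[i + 1 :]:
            if a.gene == b.gene:
                continue
            if a.constant_group == b.constant_group or allow_cross_group:
                pairs.append((a, b))
    return pairs


def _apply_strand_and_error(
    seq: str, params: SimulationParams, rng: np.random.Generator
) -> tuple[str, str]:
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        seq = revcomp(seq)
    seq = mutate_sequence(seq, params.sub_rate, params.indel_rate, rng)
    return seq, strand


def simulate_reads(
    circles: Sequence[MinicircleSpec], params: SimulationParams
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a long-read set with per-read ground truth.

    Single reads are linear fragments of one circle cut at a uniform offset
    with length from a truncated normal peaking at circle length.  Homo
    reads are k >= 2 tandem copies of one circle.  Hetero reads carry the
    cassette--constant--cassette--constant structure of a recombinant dimer
    of two distinct-gene circles sharing a constant group, linearized
    inside the trailing constant region so both cassettes are complete.
    """
    if not circles:
        raise ValueError("need at least one circle")
    n = params.n_reads
    n_homo = int(round(params.fraction_homo * n))
    n_hetero = int(round(params.fraction_hetero * n))
    n_background = int(round(params.fraction_background * n))
    n_single = n - n_homo - n_hetero - n_background
    if n_single < 0:
        raise ValueError("mixture fractions leave no room for single reads")
    categories = (
        ["single"] * n_single
        + ["homo"] * n_homo
        + ["hetero"] * n_hetero
        + ["background"] * n_background
    )

    hetero_pairs = _hetero_pool(circles, params.allow_cross_group_hetero)
    if n_hetero > 0 and not hetero_pairs:
        raise ValueError(
            "fraction_hetero > 0 but no pair of distinct-gene circles shares "
            "a constant group"
        )

    copy_ks = np.arange(2, 2 + len(params.homo_copy_probs))

    reads: list[ReadRecord] = []
    rows: list[dict[str, Any]] = []
    for i, category in enumerate(categories):
        rng = np.random.default_rng([params.seed, _STREAM_READ, i])
        read_id = f"read{i:06d}"

        if category == "background":
            length = max(100, int(rng.normal(params.background_mean_len,
                                             0.25 * params.background_mean_len)))
            seq = random_dna(rng, length, params.background_gc)
            seq, strand = _apply_strand_and_error(seq, params, rng)
            truth = ReadTruth("background", (), 0, (), 0, strand)
        elif category == "hetero":
            a, b = hetero_pairs[int(rng.integers(len(hetero_pairs)))]
            const_b = b.constant_seq
            cut = int(rng.integers(len(const_b)))
            seq = (
                const_b[cut:]
                + a.cassette_seq
                + a.constant_seq
                + b.cassette_seq
                + const_b[:cut]
            )
            seq, strand = _apply_strand_and_error(seq, params, rng)
            truth = ReadTruth(
                "hetero", (a.gene, b.gene), 2, (a.circle_id, b.circle_id), cut, strand
            )
        else:
            circle = circles[int(rng.integers(len(circles)))]
            L = len(circle)
            off = int(rng.integers(L))
            if category == "homo":
                k = int(rng.choice(copy_ks, p=params.homo_copy_probs))
                seq = (circle.sequence * (k + 1))[off : off + k * L]
                unit_count = k
            else:
                length = int(
                    np.clip(rng.normal(L, params.length_sigma_rel * L), 50, L)
                )
                seq = (circle.sequence * 2)[off : off + length]
                unit_count = 1
            seq, strand = _apply_strand_and_error(seq, params, rng)
            truth = ReadTruth(
                category, (circle.gene,), unit_count, (circle.circle_id,), off, strand
            )

        reads.append(
            ReadRecord(
                read_id, seq, quality=DEFAULT_QUALITY_CHAR * len(seq), truth=truth
            )
        )
        rows.append(
            {
                "read_id": read_id,
                "category": truth.category,
                "genes": "+".join(truth.genes),
                "unit_count": truth.unit_count,
                "circle_ids": "+".join(truth.circle_ids),
                "origin_offset": truth.start_offset,
                "strand": truth.strand,
            }
        )

    truth_table = pd.DataFrame(
        rows,
        columns=[
            "read_id", "category", "genes", "unit_count",
            "circle_ids", "origin_offset", "strand",
        ],
    )
    return reads, truth_table


def cds_references(circles: Sequence[MinicircleSpec]) -> list[tuple[str, str]]:
    """Extract (gene, CDS sequence) references from truth circles."""
    refs = {}
    for c in circles:
        if c.cds_interval is None:
            raise ValueError(f"{c.circle_id}: no CDS interval recorded")
        a, b = c.cds_interval
        refs[c.gene] = c.sequence[a:b]
    return list(refs.items())


def constant_references(
    circles: Sequence[MinicircleSpec],
) -> list[tuple[str, str]]:
    """One representative constant-region sequence per constant group."""
    refs: dict[str, str] = {}
    for c in circles:
        refs.setdefault(c.constant_group, c.constant_seq)
    return list(refs.items())
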