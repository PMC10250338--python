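"""Shared domain types for minicircle annotation and read classification.

Coordinates are 0-based, half-open throughout.  Intervals on circular
sequences may have ``end > len(sequence)``, meaning the feature wraps past
the origin of the canonical rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


Interval = tuple[int, int]


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat region on a minicircle: unit sequence, span and copy count."""

    region_id: str
    interval: Interval
    unit_seq: str
    copies: float
    tandem: bool = True


@dataclass
class MinicircleSpec:
    """A single circular molecule with cassette/constant segmentation.

    ``sequence`` is stored in canonical rotation (cassette first).  The
    cassette and constant intervals partition the circle modulo wrap.
    """

    circle_id: str
    sequence: str
    gene: str
    cassette_interval: Interval
    constant_interval: Interval
    repeat_regions: list[RepeatAnnotation] = field(default_factory=list)
    constant_group: str = ""
    cds_interval: Interval | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError(f"{self.circle_id}: empty sequence")
        ca, cb = self.cassette_interval
        ka, kb = self.constant_interval
        if (cb - ca) + (kb - ka) != n:
            raise ValueError(
                f"{self.circle_id}: cassette + constant intervals "
                f"({cb - ca} + {kb - ka}) do not partition circle of length {n}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cassette_seq(self) -> str:
        return self._arc(self.cassette_interval)

    @property
    def constant_seq(self) -> str:
        return self._arc(self.constant_interval)

    def _arc(self, iv: Interval) -> str:
        a, b = iv
        n = len(self.sequence)
        if b <= n:
            return self.sequence[a:b]
        return self.sequence[a:] + self.sequence[: b - n]


@dataclass(frozen=True)
class ReadTruth:
    """Generator ground truth attached to a simulated read."""

    category: str  # single | homo | hetero | background
    genes: tuple[str, ...]
    unit_count: int
    circle_ids: tuple[str, ...]
    start_offset: int
    strand: str

    def __post_init__(self) -> None:
        if self.category not in {"single", "homo", "hetero", "background"}:
            raise ValueError(f"unknown truth category {self.category!r}")
        if self.category != "background" and self.unit_count < 1:
            raise ValueError("mitochondrial reads require unit_count >= 1")
        if self.category == "hetero" and len(set(self.genes)) < 2:
            raise ValueError("hetero truth requires >= 2 distinct origin genes")


@dataclass
class ReadRecord:
    """A simulated or real long read with optional truth labels."""

    read_id: str
    sequence: str
    quality: str | None = None
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment of a read interval to a reference.

    Minus-strand hits are reported in forward-read coordinates.  Identity is
    matches over alignment columns (gap columns included).
    """

    read_id: str
    ref_id: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    score: int
    matches: int = 0  # aligned match columns; 0 when unknown (e.g. from TSV)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must be in [0, 1], got {self.identity}")
        if self.read_start >= self.read_end or self.ref_start >= self.ref_end:
            raise ValueError("empty alignment interval")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start
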