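"""Parameter-recovery evaluation against generator ground truth.

Utilities to score the pipeline on simulated data: partition comparison
for constant groups, segmentation boundary errors mapped through the
canonical rotation, and precision/recall of concatemer calling.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .annotate import AnnotationResult
from .concatemer import ReadClassification
from .core import MinicircleSpec
from .seq import revcomp


def partition_of(assignment: Mapping[str, str]) -> set[frozenset[str]]:
    """Label-agnostic partition induced by a {member: group} mapping."""
    groups: dict[str, set[str]] = {}
    for member, label in assignment.items():
        groups.setdefault(label, set()).add(member)
    return {frozenset(v) for v in groups.values()}


def rotation_offset(canonical: str, original: str) -> tuple[int, str]:
    """Offset/strand mapping a canonical rotation back onto its original.

    Returns (offset, strand) such that the canonical sequence equals the
    original rotated by ``offset`` (strand '+') or the reverse complement
    rotated by ``offset`` (strand '-').
    """
    if len(canonical) != len(original):
        raise ValueError("sequences differ in length; not a rotation")
    i = (original + original).find(canonical)
    if i >= 0:
        return i, "+"
    rc = revcomp(original)
    i = (rc + rc).find(canonical)
    if i < 0:
        raise ValueError("canonical sequence is not a rotation of the original")
    return i, "-"


def constant_boundary_errors(
    result: AnnotationResult,
    truth_circles: Sequence[MinicircleSpec],
    originals: Mapping[str, str] | None = None,
) -> dict[str, tuple[int, int] | None]:
    """Circular distance of inferred constant boundaries from the truth.

    ``originals`` maps circle ids to the sequences actually segmented
    (e.g. substitution-mutated copies whose coordinates still match the
    truth); defaults to the truth sequences themselves.  Singleton circles
    with no inferred constant arc map to None.
    """
    truth = {c.circle_id: c for c in truth_circles}
    out: dict[str, tuple[int, int] | None] = {}
    for spec in result.circles:
        t = truth[spec.circle_id]
        original = (originals or {}).get(spec.circle_id, t.sequence)
        L = len(original)
        a, b = spec.constant_interval
        if (a, b) == (L, L):
            out[spec.circle_id] = None
            continue
        off, strand = rotation_offset(spec.sequence, original)
        ta, tb = t.constant_interval
        if strand == "+":
            ca = (ta - off) % L
        else:
            ca = (L - tb - off) % L
        cb = ca + (tb - ta)

        def circ_dist(x: int, y: int) -> int:
            d = abs(x % L - y % L)
            return min(d, L - d)

        out[spec.circle_id] = (circ_dist(a, ca), circ_dist(b, cb))
    return out


def category_precision_recall(
    truth_categories: Mapping[str, str],
    classifications: Sequence[ReadClassification],
    category: str,
) -> tuple[float, float, dict[str, int]]:
    """Precision and recall of one predicted category against truth labels."""
    tp = fp = fn = 0
    for cls in classifications:
        is_true = truth_categories[cls.read_id] == category
        is_called = cls.category == category
        tp += is_true and is_called
        fp += is_called and not is_true
        fn += is_true and not is_called
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return precision, recall, {"tp": tp, "fp": fp, "fn": fn}
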