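"""Error-rate-based clustering of amplicon variants.

Unique read sequences within an amplicon are tabulated and then greedily
clustered in descending depth order: a variant seeds a new cluster (a
"dominant", the putative true allele) if it is frequent enough relative
to the amplicon's top variant and has the expected length; otherwise it
is absorbed into the closest dominant whose platform error model can
explain it (substitutions and indels counted separately against
per-length ceilings). Variants explained by no dominant remain flagged
"unassigned". This is the strategy AmpliSAS applies to Ion Torrent
amplicon data; here the error ceilings and tie-breaks are explicit and
deterministic.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import edlib

from .amplicon_io import Amplicon

__all__ = [
    "Variant",
    "ErrorModel",
    "ClusteringParams",
    "VariantCluster",
    "EditSummary",
    "tabulate_variants",
    "align_pair",
    "cluster_amplicon",
    "clustering_gain",
    "ClusteringGain",
]


@dataclass(frozen=True)
class Variant:
    """A unique sequence within one amplicon with its read depth and PAF.

    PAF (per amplicon frequency) = depth / total filtered reads of the
    amplicon.
    """

    sequence: str
    depth: int
    paf: float

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("variant depth must be >= 1")
        if not 0 < self.paf <= 1:
            raise ValueError("PAF must be in (0, 1]")


@dataclass(frozen=True)
class ErrorModel:
    """Platform per-base error rates (Ion Torrent defaults: 0.5% / 1%)."""

    substitution_rate: float = 0.005
    indel_rate: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("error rates must lie in [0, 1)")

    def max_substitutions(self, length: int, ceiling: str = "round") -> int:
        return _ceiling(self.substitution_rate * length, ceiling)

    def max_indels(self, length: int, ceiling: str = "round") -> int:
        return _ceiling(self.indel_rate * length, ceiling)


def _ceiling(x: float, mode: str) -> int:
    if mode == "floor":
        value = math.floor(x)
    elif mode == "ceil":
        value = math.ceil(x)
    elif mode == "round":
        value = round(x)
    else:
        raise ValueError(f"unknown error ceiling mode {mode!r}")
    return max(1, value)


@dataclass(frozen=True)
class ClusteringParams:
    """Clustering thresholds.

    ``min_dominant_frequency`` is measured against the amplicon's single
    most frequent variant (the documented meaning of AmpliSAS's "minimum
    dominant frequency"); ``frequency_reference='running'`` switches to
    comparing against the running dominant being seeded.
    """

    error_model: ErrorModel = field(default_factory=ErrorModel)
    min_dominant_frequency: float = 0.25
    require_exact_length: bool = True
    expected_length: int | None = None
    error_ceiling: Literal["floor", "round", "ceil"] = "round"
    frequency_reference: Literal["top", "running"] = "top"

    def __post_init__(self) -> None:
        if not 0 < self.min_dominant_frequency <= 1:
            raise ValueError("min_dominant_frequency must be in (0, 1]")


@dataclass(frozen=True)
class EditSummary:
    """Counts of edit operations between two sequences."""

    substitutions: int
    insertions: int
    deletions: int

    @property
    def indels(self) -> int:
        return self.insertions + self.deletions

    @property
    def total(self) -> int:
        return self.substitutions + self.indels

    @property
    def edit_class(self) -> str:
        """Artefact class label used in clustering-gain reports."""
        if self.total == 0:
            return "identical"
        if self.indels == 0:
            return "1-substitution" if self.substitutions == 1 else "multi-substitution"
        if self.substitutions == 0:
            return "indel"
        return "mixed"


@dataclass
class VariantCluster:
    """A dominant sequence plus the artefact variants absorbed into it."""

    dominant: Variant
    members: list[tuple[Variant, EditSummary]] = field(default_factory=list)
    unassigned: bool = False

    @property
    def clustered_depth(self) -> int:
        return self.dominant.depth + sum(v.depth for v, _ in self.members)

    @property
    def clustered_paf(self) -> float:
        if self.dominant.depth == 0:
            return 0.0
        total = self.dominant.paf / self.dominant.depth  # 1 / amplicon depth
        return self.clustered_depth * total


def tabulate_variants(amplicon: Amplicon) -> list[Variant]:
    """Collapse exact-duplicate reads into variants, deepest first.

    Ties in depth break lexicographically on sequence, so the order is a
    deterministic function of the read multiset.
    """
    counts = Counter(read.sequence for read in amplicon.reads)
    total = sum(counts.values())
    variants = [
        Variant(sequence=seq, depth=depth, paf=depth / total)
        for seq, depth in counts.items()
    ]
    variants.sort(key=lambda v: (-v.depth, v.sequence))
    return variants


def align_pair(a: str, b: str) -> EditSummary:
    """Globally align two sequences and count substitutions and indels.

    Unit edit costs; among cost-equal alignments the engine's canonical
    traceback is reported. Insertions are bases present in ``b`` and
    absent from ``a``; deletions the reverse. The total cost is symmetric.
    """
    if not a or not b:
        raise ValueError("align_pair requires non-empty sequences")
    if a == b:
        return EditSummary(0, 0, 0)
    result = edlib.align(a, b, mode="NW", task="path")
    subs = ins = dels = 0
    count = ""
    for char in result["cigar"]:
        if char.isdigit():
            count += char
            continue
        n = int(count)
        count = ""
        if char == "X":
            subs += n
        elif char == "I":  # in query a, absent from target b
            dels += n
        elif char == "D":  # absent from query a, present in target b
            ins += n
    return EditSummary(subs, ins, dels)


def _absorbable(summary: EditSummary, model: ErrorModel, length: int, ceiling: str) -> bool:
    return (
        summary.substitutions <= model.max_substitutions(length, ceiling)
        and summary.indels <= model.max_indels(length, ceiling)
    )


def cluster_amplicon(
    variants: Sequence[Variant], params: ClusteringParams
) -> list[VariantCluster]:
    """Greedy descending-depth clustering of an amplicon's variants.

    Each variant, in depth order, either seeds a new cluster (frequency
    relative to the reference dominant >= ``min_dominant_frequency`` and,
    if required, exact expected length), is absorbed into the
    deepest-dominant cluster whose error model explains it (ties on depth
    break to the lexicographically smaller dominant sequence), or remains
    a singleton cluster flagged ``unassigned``.
    """
    if not variants:
        return []
    order = sorted(variants, key=lambda v: (-v.depth, v.sequence))
    expected_length = params.expected_length
    if expected_length is None and params.require_exact_length:
        # modal length of candidate dominants; ties to the shorter length
        lengths = Counter(len(v.sequence) for v in order)
        expected_length = min(
            lengths, key=lambda length: (-lengths[length], length)
        )
    clusters: list[VariantCluster] = []
    top = order[0]
    for variant in order:
        reference = top if params.frequency_reference == "top" else (
            clusters[-1].dominant if clusters else top
        )
        frequent = variant.depth / reference.depth >= params.min_dominant_frequency
        right_length = (
            not params.require_exact_length or len(variant.sequence) == expected_length
        )
        if frequent and right_length:
            clusters.append(VariantCluster(dominant=variant))
            continue
        # absorb into the deepest compatible dominant
        best: VariantCluster | None = None
        best_summary: EditSummary | None = None
        for cluster in clusters:
            if cluster.unassigned:
                continue
            dom = cluster.dominant
            summary = align_pair(variant.sequence, dom.sequence)
            if _absorbable(
                summary, params.error_model, len(dom.sequence), params.error_ceiling
            ):
                if best is None or (
                    cluster.dominant.depth,
                    _neg_lex(cluster.dominant.sequence),
                ) > (best.dominant.depth, _neg_lex(best.dominant.sequence)):
                    best, best_summary = cluster, summary
        if best is not None and best_summary is not None:
            best.members.append((variant, best_summary))
        else:
            clusters.append(VariantCluster(dominant=variant, unassigned=True))
    return clusters


class _neg_lex(str):
    """Reverse lexicographic comparison wrapper for max-by-tuple tie-breaks."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass(frozen=True)
class ClusteringGain:
    """Depth bookkeeping before vs after clustering.

    ``assigned_before`` is the fraction of amplicon depth carried by the
    dominant sequences themselves; ``assigned_after`` adds their absorbed
    artefacts. ``absorbed_by_class`` splits the absorbed depth by edit
    class (1-substitution, multi-substitution, indel, mixed).
    """

    assigned_before: float
    assigned_after: float
    absorbed_by_class: dict[str, int]

    @property
    def gain(self) -> float:
        return self.assigned_after - self.assigned_before

    def class_fraction(self, edit_class: str) -> float:
        total = sum(self.absorbed_by_class.values())
        if total == 0:
            return 0.0
        return self.absorbed_by_class.get(edit_class, 0) / total


def clustering_gain(
    before: Sequence[Variant], after: Sequence[VariantCluster]
) -> ClusteringGain:
    """Report how much amplicon depth clustering re-assigned to dominants."""
    total_depth = sum(v.depth for v in before)
    if total_depth == 0:
        return ClusteringGain(0.0, 0.0, {})
    dominants = [c for c in after if not c.unassigned]
    depth_before = sum(c.dominant.depth for c in dominants)
    depth_after = sum(c.clustered_depth for c in dominants)
    by_class: dict[str, int] = {}
    for cluster in dominants:
        for variant, summary in cluster.members:
            by_class[summary.edit_class] = (
                by_class.get(summary.edit_class, 0) + variant.depth
            )
    return ClusteringGain(
        assigned_before=depth_before / total_depth,
        assigned_after=depth_after / total_depth,
        absorbed_by_class=by_class,
    )
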