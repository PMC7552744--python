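"""Post-clustering allele determination.

The calling rules reproduce the amplicon-genotyping workflow for a
single-copy MHC class II DRB locus: clusters below a 1% per-amplicon
frequency are discarded as noise, PCR chimeras are flagged by exact
parent-prefix/suffix decomposition, a per-amplicon-frequency (PAF)
threshold separates the remaining artefact band from true alleles, and
at most two alleles are accepted per diploid individual. Sequences are
mapped to canonical allele names through a registry that can mint names
for putative new alleles. Sequence screening (translation for premature
stop codons, pairwise mutation counts) supports pseudogene checks and
network construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .clustering import VariantCluster

__all__ = [
    "CallingParams",
    "AlleleCall",
    "Genotype",
    "AlleleRegistry",
    "ThresholdProposal",
    "detect_paf_threshold",
    "detect_chimeras",
    "ChimeraHit",
    "call_genotype",
    "allele_frequencies",
    "frequencies_from_counts",
    "translate_and_screen",
    "TranslationReport",
    "pairwise_mutations",
]


@dataclass(frozen=True)
class CallingParams:
    """Allele-calling thresholds.

    Defaults follow the published workflow: discard clusters below 1%
    PAF, cut the artefact band at 14% PAF, and accept at most two
    alleles per individual (single-copy locus).
    """

    min_variant_frequency: float = 0.01
    paf_threshold: float = 0.14
    max_alleles_per_individual: int = 2
    auto_threshold: bool = False
    chimera_min_segment: int = 20
    # when set, cluster dominants are positionally trimmed of these
    # primers before registry lookup (registries store bare inserts)
    forward_primer: str = ""
    reverse_primer: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.min_variant_frequency <= self.paf_threshold <= 1:
            raise ValueError("require 0 <= min_variant_frequency <= paf_threshold <= 1")
        if self.max_alleles_per_individual < 1:
            raise ValueError("max_alleles_per_individual must be >= 1")


@dataclass
class AlleleCall:
    """Audit record for one cluster of one amplicon."""

    allele_name: str | None
    sequence: str
    paf: float
    depth: int
    accepted: bool = False
    chimera: bool = False
    below_min_frequency: bool = False
    below_threshold: bool = False
    supernumerary: bool = False
    putative_new: bool = False

    @property
    def category(self) -> str:
        """Single audit category; exactly one applies per cluster."""
        if self.below_min_frequency:
            return "below_min_frequency"
        if self.chimera:
            return "chimera"
        if self.below_threshold:
            return "below_paf_threshold"
        if self.supernumerary:
            return "supernumerary"
        return "accepted"


@dataclass(frozen=True)
class Genotype:
    """Accepted alleles (1-2) for one individual by one method."""

    individual_id: str
    method: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("duplicate allele names in genotype")

    @property
    def homozygous(self) -> bool:
        return len(self.alleles) == 1


class AlleleRegistry:
    """Bijective map between allele sequences and canonical names.

    Novel sequences are assigned names ``<prefix><number>`` continuing
    after the highest number already present (the published catalogue
    continued at *41 after 40 described alleles).
    """

    def __init__(
        self,
        known: Mapping[str, str] | Iterable[tuple[str, str]] = (),
        name_prefix: str = "Ruru-DRB*",
    ) -> None:
        self._seq_to_name: dict[str, str] = {}
        self._name_to_seq: dict[str, str] = {}
        self.name_prefix = name_prefix
        items = known.items() if isinstance(known, Mapping) else known
        for name, sequence in items:
            self.add(name, sequence)

    def add(self, name: str, sequence: str) -> None:
        sequence = sequence.upper()
        if name in self._name_to_seq and self._name_to_seq[name] != sequence:
            raise ValueError(f"allele name {name!r} already bound to another sequence")
        if sequence in self._seq_to_name and self._seq_to_name[sequence] != name:
            raise ValueError(f"sequence already registered as {self._seq_to_name[sequence]!r}")
        self._seq_to_name[sequence] = name
        self._name_to_seq[name] = sequence

    def name_of(self, sequence: str) -> str | None:
        return self._seq_to_name.get(sequence.upper())

    def sequence_of(self, name: str) -> str | None:
        return self._name_to_seq.get(name)

    def __len__(self) -> int:
        return len(self._name_to_seq)

    def __contains__(self, sequence: str) -> bool:
        return sequence.upper() in self._seq_to_name

    def items(self) -> list[tuple[str, str]]:
        return sorted(self._name_to_seq.items())

    def _next_number(self) -> int:
        best = 0
        for name in self._name_to_seq:
            digits = ""
            for ch in reversed(name):
                if ch.isdigit():
                    digits = ch + digits
                else:
                    break
            if digits:
                best = max(best, int(digits))
        return best + 1

    def register_novel(self, sequence: str) -> str:
        """Mint the next free name for an unseen sequence."""
        sequence = sequence.upper()
        if sequence in self._seq_to_name:
            return self._seq_to_name[sequence]
        name = f"{self.name_prefix}{self._next_number():02d}"
        self.add(name, sequence)
        return name


@dataclass(frozen=True)
class ThresholdProposal:
    """Outcome of the PAF-gap threshold scan (a proposal, never applied)."""

    threshold: float
    gap_upper: float | None
    gap_lower: float | None
    raised_for_chimera: bool
    fallback: bool


def detect_paf_threshold(
    cluster_pafs: Sequence[float],
    chimera_pafs: Sequence[float] = (),
    default: float = 0.14,
    chimera_margin: float = 0.01,
) -> ThresholdProposal:
    """Propose a PAF cutoff between the true-allele band and the artefact band.

    All clustered PAFs from the run are pooled and sorted descending. The
    artefact boundary is the largest gap between consecutive PAFs in the
    sub-50% region (true alleles of a heterozygote sit near or above 50%;
    anything separated from them by a wide gap is the artefact band). The
    proposal is the gap midpoint, raised just above any flagged chimera's
    PAF (chimeras are excluded from the gap scan itself). With no usable
    gap the published default of 14% is returned with a warning.
    """
    pafs = sorted((p for p in cluster_pafs if 0 < p <= 1), reverse=True)
    if len(set(pafs)) < 2:
        warnings.warn("no PAF gap detectable; falling back to default threshold")
        proposal = default
        fallback = True
        upper = lower = None
    else:
        band = [p for p in pafs if p < 0.5] + [0.0]
        if len(band) < 2:
            warnings.warn("no sub-50% PAF band; falling back to default threshold")
            proposal, fallback, upper, lower = default, True, None, None
        else:
            gaps = [
                (band[i] - band[i + 1], band[i], band[i + 1])
                for i in range(len(band) - 1)
            ]
            width, upper, lower = max(gaps, key=lambda g: g[0])
            if width <= 0:
                warnings.warn("uniform PAFs; falling back to default threshold")
                proposal, fallback, upper, lower = default, True, None, None
            else:
                proposal = (upper + lower) / 2
                fallback = False
    raised = False
    if chimera_pafs:
        ceiling = max(chimera_pafs) + chimera_margin
        if proposal < ceiling:
            proposal = ceiling
            raised = True
    return ThresholdProposal(
        threshold=proposal,
        gap_upper=upper,
        gap_lower=lower,
        raised_for_chimera=raised,
        fallback=fallback,
    )


@dataclass(frozen=True)
class ChimeraHit:
    """A detected chimera with its parents and valid breakpoint."""

    sequence: str
    parent_prefix: str
    parent_suffix: str
    breakpoint: int


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def detect_chimeras(
    sequences: Iterable[str],
    parents: Sequence[str],
    min_segment: int = 20,
) -> dict[str, ChimeraHit]:
    """Flag sequences that are exact prefix+suffix recombinants of two parents.

    ``s`` is chimeric iff it differs from every parent and there exist
    parents p, q and a breakpoint k with ``s == p[:k] + q[k:]`` and both
    segments at least ``min_segment`` long. The smallest valid breakpoint
    is reported. Parents are typically the run-wide accepted alleles.
    """
    hits: dict[str, ChimeraHit] = {}
    parent_set = set(parents)
    for s in sequences:
        if s in parent_set:
            continue
        found: ChimeraHit | None = None
        for p in parents:
            lcp = _common_prefix(s, p)
            if lcp < min_segment:
                continue
            for q in parents:
                if q == p or len(q) != len(s):
                    continue
                lcs = _common_prefix(s[::-1], q[::-1])
                if lcs < min_segment:
                    continue
                # valid breakpoints: max(min_segment, len(s)-lcs) <= k <= min(lcp, len(s)-min_segment)
                k_low = max(min_segment, len(s) - lcs)
                k_high = min(lcp, len(s) - min_segment)
                if k_low <= k_high:
                    candidate = ChimeraHit(s, p, q, k_low)
                    if found is None or candidate.breakpoint < found.breakpoint or (
                        candidate.breakpoint == found.breakpoint
                        and (candidate.parent_prefix, candidate.parent_suffix)
                        < (found.parent_prefix, found.parent_suffix)
                    ):
                        found = candidate
        if found is not None:
            hits[s] = found
    return hits


def call_genotype(
    clusters: Sequence[VariantCluster],
    params: CallingParams,
    registry: AlleleRegistry,
    individual_id: str,
    method: str = "NGS",
    run_alleles: Sequence[str] = (),
) -> tuple[Genotype | None, list[AlleleCall]]:
    """Call a 1-2 allele genotype from one amplicon's clusters.

    Filter order: the 1% minimum-frequency floor, then chimera flagging
    against ``run_alleles`` (run-wide accepted sequences; falls back to
    the amplicon's own above-threshold dominants), then the PAF
    threshold, then the two-allele cap by descending PAF (extras flagged
    supernumerary, never silently dropped). Novel surviving sequences
    get registry names and a ``putative_new`` flag. Returns ``None`` and
    the audit when nothing survives.
    """
    audits: list[AlleleCall] = []
    ordered = sorted(
        (c for c in clusters if not c.unassigned),
        key=lambda c: (-c.clustered_paf, c.dominant.sequence),
    )
    unassigned = [c for c in clusters if c.unassigned]
    parents = list(run_alleles)
    if not parents:
        parents = [
            c.dominant.sequence
            for c in ordered
            if c.clustered_paf >= params.paf_threshold
        ]
    chimera_hits = detect_chimeras(
        [c.dominant.sequence for c in ordered], parents, params.chimera_min_segment
    )
    cut_head, cut_tail = len(params.forward_primer), len(params.reverse_primer)
    accepted: list[AlleleCall] = []
    for cluster in ordered:
        seq = cluster.dominant.sequence
        insert = seq[cut_head : len(seq) - cut_tail] if cut_head + cut_tail else seq
        call = AlleleCall(
            allele_name=registry.name_of(insert),
            sequence=insert,
            paf=cluster.clustered_paf,
            depth=cluster.clustered_depth,
        )
        if call.paf < params.min_variant_frequency:
            call.below_min_frequency = True
        elif seq in chimera_hits:
            call.chimera = True
        elif call.paf < params.paf_threshold:
            call.below_threshold = True
        elif len(accepted) >= params.max_alleles_per_individual:
            call.supernumerary = True
        else:
            call.accepted = True
            if call.allele_name is None:
                call.allele_name = registry.register_novel(call.sequence)
                call.putative_new = True
            accepted.append(call)
        audits.append(call)
    for cluster in unassigned:
        audits.append(
            AlleleCall(
                allele_name=None,
                sequence=cluster.dominant.sequence,
                paf=cluster.clustered_paf,
                depth=cluster.clustered_depth,
                below_min_frequency=cluster.clustered_paf < params.min_variant_frequency,
                below_threshold=cluster.clustered_paf >= params.min_variant_frequency,
            )
        )
    if not accepted:
        return None, audits
    genotype = Genotype(
        individual_id=individual_id,
        method=method,
        alleles=tuple(c.allele_name for c in accepted if c.allele_name),
    )
    return genotype, audits


def frequencies_from_counts(
    counts: Mapping[str, int], n_individuals: int
) -> pd.DataFrame:
    """Allele frequencies from gene-copy observation counts.

    Observations count homozygotes twice (one per gene copy), so for a
    diploid single-copy locus they sum to 2N and frequencies to 1.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    total = 2 * n_individuals
    frame = pd.DataFrame(
        {
            "allele": list(counts.keys()),
            "observations": list(counts.values()),
            "frequency": [c / total for c in counts.values()],
        }
    )
    return frame


def allele_frequencies(
    genotypes: pd.DataFrame, method: str
) -> tuple[pd.DataFrame, list[str]]:
    """Per-allele observation counts and frequencies for one method.

    Homozygotes contribute two observations. Individuals with an empty
    call are excluded from N and returned separately.
    """
    subset = genotypes[genotypes["method"] == method]
    excluded = [
        str(row.individual_id)
        for row in subset.itertuples(index=False)
        if len(row.alleles) == 0
    ]
    called = subset[subset["alleles"].map(len) > 0]
    n = len(called)
    counts: dict[str, int] = {}
    for row in called.itertuples(index=False):
        alleles = list(row.alleles)
        if len(alleles) == 1:
            alleles = alleles * 2  # homozygote: two gene copies
        for allele in alleles:
            counts[allele] = counts.get(allele, 0) + 1
    if n == 0:
        return pd.DataFrame(columns=["allele", "observations", "frequency"]), excluded
    frame = frequencies_from_counts(counts, n)
    frame = frame.sort_values("allele", kind="stable").reset_index(drop=True)
    return frame, excluded


STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class TranslationReport:
    """Translation of a putative allele with pseudogene screening flags."""

    protein: str
    has_internal_stop: bool
    stop_positions: tuple[int, ...]  # 1-based codon positions
    trailing_bases: int
    ambiguous_codons: int


def translate_and_screen(sequence: str, frame_offset: int = 0) -> TranslationReport:
    """Translate DNA from a frame offset and flag premature stop codons.

    The exon 2 amplicon insert (236 bp) is not a codon multiple; trailing
    1-2 nt are ignored with a warning. Codons containing non-ACGT bases
    translate to 'X' with a warning.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    coding = sequence.upper()[frame_offset:]
    trailing = len(coding) % 3
    if trailing:
        warnings.warn(f"{trailing} trailing base(s) ignored in translation")
        coding = coding[: len(coding) - trailing]
    protein_chars: list[str] = []
    stops: list[int] = []
    ambiguous = 0
    for i in range(0, len(coding), 3):
        codon = coding[i : i + 3]
        if set(codon) - set("ACGT"):
            warnings.warn(f"ambiguous codon {codon!r} translated as X")
            protein_chars.append("X")
            ambiguous += 1
            continue
        if codon in STOP_CODONS:
            protein_chars.append("*")
            stops.append(i // 3 + 1)
        else:
            protein_chars.append(str(Seq(codon).translate()))
    return TranslationReport(
        protein="".join(protein_chars),
        has_internal_stop=bool(stops),
        stop_positions=tuple(stops),
        trailing_bases=trailing,
        ambiguous_codons=ambiguous,
    )


def pairwise_mutations(
    alleles: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, list[int]]:
    """Pairwise differing-position counts over aligned equal-length alleles.

    Returns the symmetric mutation-count matrix (named rows/columns) and
    the sorted list of variable column positions (1-based, the field's
    alignment convention). Unequal lengths are an error — align first.
    """
    items = list(alleles.items()) if isinstance(alleles, Mapping) else list(alleles)
    if not items:
        raise ValueError("no sequences given")
    names = [name for name, _ in items]
    seqs = [seq.upper() for _, seq in items]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths; align them first")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    diff = arr[:, None, :] != arr[None, :, :]
    matrix = diff.sum(axis=2)
    variable = sorted(int(i) + 1 for i in np.where((arr != arr[0]).any(axis=0))[0])
    frame = pd.DataFrame(matrix, index=names, columns=names)
    return frame, variable
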