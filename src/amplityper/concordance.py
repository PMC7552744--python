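"""Genotype concordance between two genotyping methods.

Compares per-individual allele sets called by a reference method
(method 1, e.g. SSCP/Sanger) and a second method (method 2, e.g.
amplicon NGS) and classifies each pair into one of five exhaustive,
mutually exclusive classes. For a diploid single-copy locus the classes
capture the two clinically relevant failure modes: allelic dropout
(method 1 sees only one of a heterozygote's alleles — a false
homozygote) and false positives (method 1 reports an allele method 2
does not confirm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "PairedGenotype",
    "DiscrepancyReport",
    "classify_pair",
    "summarize",
    "pair_tables",
    "compare_frequency_tables",
    "CLASSES",
]

CLASSES = (
    "concordant",
    "dropout_false_homozygote",
    "extension",
    "false_positive",
    "conflict",
)


@dataclass(frozen=True)
class PairedGenotype:
    """One individual's allele sets under both methods."""

    individual_id: str
    alleles_method1: frozenset[str]
    alleles_method2: frozenset[str]

    def __post_init__(self) -> None:
        if not self.alleles_method1 or not self.alleles_method2:
            raise ValueError(f"{self.individual_id}: empty allele set")


def classify_pair(pair: PairedGenotype) -> str:
    """Classify one individual's method-1 vs method-2 genotype pair.

    concordant: identical sets. dropout_false_homozygote: method 1 is a
    single-allele proper subset of a two-allele method-2 call (classic
    dropout). extension: any other proper subset (method 2 extends the
    genotype). false_positive: method 2 is a proper subset of method 1
    (method 1 reports an unconfirmed allele). conflict: neither set
    contains the other.
    """
    m1, m2 = pair.alleles_method1, pair.alleles_method2
    if m1 == m2:
        return "concordant"
    if m1 < m2:
        if len(m1) == 1 and len(m2) == 2:
            return "dropout_false_homozygote"
        return "extension"
    if m2 < m1:
        return "false_positive"
    return "conflict"


@dataclass(frozen=True)
class DiscrepancyReport:
    """Run-level concordance summary."""

    n: int
    counts: dict[str, int]
    per_individual: pd.DataFrame  # individual_id, class
    allele_agreement: float  # mean per-individual |intersection| / |union|

    @property
    def rates(self) -> dict[str, float]:
        return {cls: self.counts[cls] / self.n for cls in CLASSES}

    @property
    def discrepancy_rate(self) -> float:
        return 1.0 - self.counts["concordant"] / self.n

    def rate_percent(self, cls: str) -> int:
        """Class rate as a rounded integer percentage."""
        return round(100 * self.counts[cls] / self.n)

    @property
    def discrepancy_percent(self) -> int:
        return round(100 * self.discrepancy_rate)


def summarize(paired: Sequence[PairedGenotype]) -> DiscrepancyReport:
    """Classify every pair and report per-class counts and rates."""
    if not paired:
        raise ValueError("no paired genotypes")
    ids = [p.individual_id for p in paired]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual_id in paired genotypes")
    rows = []
    counts = {cls: 0 for cls in CLASSES}
    jaccard_sum = 0.0
    for pair in paired:
        cls = classify_pair(pair)
        counts[cls] += 1
        union = pair.alleles_method1 | pair.alleles_method2
        inter = pair.alleles_method1 & pair.alleles_method2
        jaccard_sum += len(inter) / len(union)
        rows.append((pair.individual_id, cls))
    frame = pd.DataFrame(rows, columns=["individual_id", "class"])
    return DiscrepancyReport(
        n=len(paired),
        counts=counts,
        per_individual=frame,
        allele_agreement=jaccard_sum / len(paired),
    )


def pair_tables(
    genotypes: pd.DataFrame, method1: str, method2: str
) -> list[PairedGenotype]:
    """Join one genotype table's two methods into per-individual pairs.

    Individuals lacking a non-empty call under either method are skipped.
    """
    by_method = {
        method: {
            str(row.individual_id): frozenset(row.alleles)
            for row in genotypes[genotypes["method"] == method].itertuples(index=False)
            if len(row.alleles) > 0
        }
        for method in (method1, method2)
    }
    shared = sorted(set(by_method[method1]) & set(by_method[method2]))
    return [
        PairedGenotype(i, by_method[method1][i], by_method[method2][i]) for i in shared
    ]


def compare_frequency_tables(
    freq1: pd.DataFrame, freq2: pd.DataFrame, label1: str = "method1", label2: str = "method2"
) -> pd.DataFrame:
    """Merge two allele-frequency tables and report detection differences.

    Output columns: allele, observations/frequency per method, delta
    (method2 - method1), and ``detected_only_by`` (empty, label1 or
    label2). Alleles absent from a table count as zero observations.
    """
    merged = freq1.merge(
        freq2, on="allele", how="outer", suffixes=(f"_{label1}", f"_{label2}")
    ).fillna(0.0)
    obs1, obs2 = f"observations_{label1}", f"observations_{label2}"
    frq1, frq2 = f"frequency_{label1}", f"frequency_{label2}"
    merged[obs1] = merged[obs1].astype(int)
    merged[obs2] = merged[obs2].astype(int)
    merged["delta_frequency"] = merged[frq2] - merged[frq1]
    merged["detected_only_by"] = ""
    merged.loc[(merged[obs1] > 0) & (merged[obs2] == 0), "detected_only_by"] = label1
    merged.loc[(merged[obs1] == 0) & (merged[obs2] > 0), "detected_only_by"] = label2
    return merged.sort_values("allele", kind="stable").reset_index(drop=True)
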