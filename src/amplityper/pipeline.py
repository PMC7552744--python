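"""End-to-end genotyping: QC -> variant tabulation -> clustering -> calling.

The unit of work is one amplicon (one individual's filtered read set).
Run-level genotyping is two-pass: a first pass clusters every amplicon
and provisionally accepts above-threshold dominants, pooling them as
run-wide chimera parents; the second pass calls final genotypes with
chimera screening against that pool. This matches how amplicon
genotyping is audited in practice — a chimera's parents are the
individual's own alleles, but checking against the whole run's accepted
alleles is strictly more sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .allele_calling import (
    AlleleCall,
    AlleleRegistry,
    CallingParams,
    Genotype,
    call_genotype,
    detect_paf_threshold,
)
from .amplicon_io import FORWARD_PRIMER, REVERSE_PRIMER, Amplicon, genotype_table
from .clustering import (
    ClusteringGain,
    ClusteringParams,
    VariantCluster,
    cluster_amplicon,
    clustering_gain,
    tabulate_variants,
)
from .read_qc import QCParams, filter_reads, subsample

__all__ = ["PipelineParams", "AmpliconResult", "RunResult", "process_amplicon", "genotype_run"]


@dataclass(frozen=True)
class PipelineParams:
    """Bundle of all stage parameters with study defaults."""

    qc: QCParams = field(default_factory=QCParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    calling: CallingParams = field(
        default_factory=lambda: CallingParams(
            forward_primer=FORWARD_PRIMER, reverse_primer=REVERSE_PRIMER
        )
    )
    method: str = "NGS"


@dataclass
class AmpliconResult:
    """Per-amplicon artefacts kept for auditing."""

    sample_id: str
    clusters: list[VariantCluster]
    gain: ClusteringGain
    genotype: Genotype | None = None
    audit: list[AlleleCall] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)


@dataclass
class RunResult:
    """Genotypes plus audits for a whole run."""

    amplicons: list[AmpliconResult]
    registry: AlleleRegistry
    threshold_proposal: float | None = None

    @property
    def genotypes(self) -> pd.DataFrame:
        rows = [
            (r.sample_id, r.genotype.method, r.genotype.alleles)
            for r in self.amplicons
            if r.genotype is not None
        ]
        return genotype_table(rows)

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for result in self.amplicons:
            for call in result.audit:
                rows.append(
                    (
                        result.sample_id,
                        call.allele_name,
                        call.category,
                        call.paf,
                        call.depth,
                        call.putative_new,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=["sample_id", "allele", "category", "paf", "depth", "putative_new"],
        )


def process_amplicon(amplicon: Amplicon, params: PipelineParams) -> AmpliconResult:
    """QC, tabulate and cluster one amplicon (no allele calling yet)."""
    cleaned = subsample(filter_reads(amplicon, params.qc), params.qc)
    variants = tabulate_variants(cleaned)
    clusters = cluster_amplicon(variants, params.clustering)
    return AmpliconResult(
        sample_id=amplicon.sample_id,
        clusters=clusters,
        gain=clustering_gain(variants, clusters),
        provenance=dict(cleaned.provenance),
    )


def genotype_run(
    amplicons: list[Amplicon] | list[AmpliconResult],
    params: PipelineParams | None = None,
    registry: AlleleRegistry | None = None,
) -> RunResult:
    """Genotype a full run of amplicons with run-wide chimera screening.

    Accepts raw amplicons or pre-clustered :class:`AmpliconResult`s.
    When ``calling.auto_threshold`` is set, the PAF threshold proposed by
    the run-wide gap scan replaces the configured one.
    """
    params = params or PipelineParams()
    registry = registry or AlleleRegistry()
    results = [
        a if isinstance(a, AmpliconResult) else process_amplicon(a, params)
        for a in amplicons
    ]
    # pass 1: provisional above-threshold dominants become chimera parents
    calling = params.calling
    parents: list[str] = []
    for result in results:
        for cluster in result.clusters:
            if not cluster.unassigned and cluster.clustered_paf >= calling.paf_threshold:
                parents.append(cluster.dominant.sequence)
    parents = sorted(set(parents))
    proposal = None
    if calling.auto_threshold:
        from .allele_calling import detect_chimeras

        pafs, chimera_pafs = [], []
        flagged = set()
        for result in results:
            hits = detect_chimeras(
                [c.dominant.sequence for c in result.clusters if not c.unassigned],
                parents,
                calling.chimera_min_segment,
            )
            flagged |= set(hits)
            for cluster in result.clusters:
                if cluster.unassigned:
                    continue
                if cluster.dominant.sequence in hits:
                    chimera_pafs.append(cluster.clustered_paf)
                else:
                    pafs.append(cluster.clustered_paf)
        proposed = detect_paf_threshold(pafs, chimera_pafs, default=calling.paf_threshold)
        proposal = proposed.threshold
        calling = replace(calling, paf_threshold=proposal, auto_threshold=False)
    # pass 2: final calls
    for result in results:
        genotype, audit = call_genotype(
            result.clusters,
            calling,
            registry,
            individual_id=result.sample_id,
            method=params.method,
            run_alleles=parents,
        )
        result.genotype = genotype
        result.audit = audit
    return RunResult(amplicons=results, registry=registry, threshold_proposal=proposal)
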