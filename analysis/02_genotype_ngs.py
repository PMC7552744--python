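"""Genotype the simulated cohort from its FASTQ files.

Runs the full NGS calling pipeline on the reads written by
01_simulate_cohort.py: mean-Q30 + 279-289 bp filtering, 5000-read cap,
error-rate clustering (0.5% substitutions / 1% indels, 25% minimum
dominant frequency), 1% variant floor, chimera screening, 14% PAF
threshold, two-allele cap. Writes genotypes, the per-cluster audit,
allele frequencies and the clustering depth-gain summary to results/.

Run:  python analysis/02_genotype_ngs.py  (after 01)
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from amplityper.allele_calling import AlleleRegistry, allele_frequencies
from amplityper.amplicon_io import Amplicon, read_fasta, read_fastq, write_fasta, write_genotype_table
from amplityper.pipeline import PipelineParams, genotype_run

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    reads_dir = ROOT / "scratch" / "cohort"
    results = ROOT / "results"
    fastqs = sorted(reads_dir.glob("*.fastq"))
    if not fastqs:
        sys.exit("no FASTQs found - run analysis/01_simulate_cohort.py first")

    registry = AlleleRegistry(read_fasta(results / "allele_pool.fasta"))
    amplicons = [
        Amplicon(sample_id=path.stem, reads=list(read_fastq(path))) for path in fastqs
    ]
    run = genotype_run(amplicons, PipelineParams(), registry)

    called = run.genotypes
    write_genotype_table(called, results / "ngs_genotypes.tsv")
    run.audit_frame().to_csv(results / "ngs_audit.tsv", sep="\t", index=False)
    write_fasta(run.registry.items(), results / "called_alleles.fasta")

    freqs, excluded = allele_frequencies(called, "NGS")
    freqs.to_csv(results / "ngs_frequencies.tsv", sep="\t", index=False)

    before = [r.gain.assigned_before for r in run.amplicons]
    after = [r.gain.assigned_after for r in run.amplicons]
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in run.amplicons],
            "assigned_before": np.round(before, 4),
            "assigned_after": np.round(after, 4),
        }
    ).to_csv(results / "clustering_gain.tsv", sep="\t", index=False)

    print(f"genotyped {len(called)} individuals ({len(excluded)} no-calls)")
    print(
        f"assigned depth: {100 * np.mean(before):.1f}% before clustering, "
        f"{100 * np.mean(after):.1f}% after "
        f"(increased in {sum(b < a for b, a in zip(before, after))}/{len(before)} amplicons)"
    )
    audit = run.audit_frame()
    new = audit[audit["putative_new"]]
    print(
        f"alleles accepted: {audit[audit['category'] == 'accepted']['allele'].nunique()}"
        f" ({new['allele'].nunique()} putative new)"
    )


if __name__ == "__main__":
    main()
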