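"""Simulate a ground-truthed 28-individual amplicon cohort.

Draws an 8-allele DRB exon 2 pool, Hardy-Weinberg diploid genotypes at
the study's allele frequencies, Ion-Torrent-style reads per individual
(656-5000x coverage, substitution + homopolymer-indel errors, chimeras,
amplification bias), and an SSCP/Sanger genotype table degraded by
allelic dropout. Reads go to scratch/cohort/ (large, regenerable);
small truth tables go to results/.

Run:  python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from amplityper.amplicon_io import write_fasta, write_fastq, write_genotype_table
from amplityper.synthetic_data import (
    SimConfig,
    emulate_sscp,
    make_allele_pool,
    simulate_genotypes,
    simulate_reads,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = SimConfig(rng_seed=args.seed)
    rng = cfg.rng()
    reads_dir = ROOT / "scratch" / "cohort"
    results = ROOT / "results"
    reads_dir.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    pool = make_allele_pool(cfg, rng)
    print(
        f"allele pool: {len(pool.sequences)} alleles, "
        f"{len(pool.variable_sites)} variable sites "
        f"({100 * pool.variable_fraction:.1f}% of {cfg.allele_length} bp)"
    )
    write_fasta(list(pool.sequences.items()), results / "allele_pool.fasta")

    truth = simulate_genotypes(cfg, pool, rng)
    n_het = sum(len(r.alleles) == 2 for r in truth.itertuples(index=False))
    print(f"genotypes: {cfg.n_individuals} individuals, {n_het} heterozygous")
    write_genotype_table(truth, results / "truth_genotypes.tsv")

    sscp, spurious = emulate_sscp(cfg, pool, truth, rng)
    lost = sum(
        len(s.alleles) < len(t.alleles)
        for t, s in zip(truth.itertuples(index=False), sscp.itertuples(index=False))
    )
    print(f"SSCP emulation: {lost} dropout individuals, {len(spurious)} spurious alleles")
    write_genotype_table(sscp, results / "sscp_genotypes.tsv")

    depths = []
    for amplicon, _ in simulate_reads(cfg, pool, truth, rng=rng):
        write_fastq(amplicon.reads, reads_dir / f"{amplicon.sample_id}.fastq")
        depths.append(len(amplicon))
    print(
        f"reads: {sum(depths)} total, coverage {min(depths)}-{max(depths)} "
        f"per amplicon -> {reads_dir}"
    )
    (results / "sim_config.json").write_text(
        json.dumps(
            {
                **{k: v for k, v in cfg.__dict__.items()},
                "allele_frequencies": list(cfg.allele_frequencies),
                "coverage_range": list(cfg.coverage_range),
            },
            indent=2,
        )
    )
    pd.DataFrame({"individual_id": truth["individual_id"], "depth": depths}).to_csv(
        results / "coverage.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
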