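"""Median-joining network of the called alleles (epsilon = 0).

Builds the sparsest median-joining network over the alleles accepted by
the NGS pipeline, annotates nodes with per-method gene-copy counts, and
writes GraphML plus a plain-text edge list. On the real data this
network (with inferred median vectors as small unlabelled nodes)
summarises the mutational relationships among the eight DRB alleles.

Run:  python analysis/04_haplotype_network.py  (after 01-03)
"""

import sys
from pathlib import Path

import pandas as pd

from amplityper.amplicon_io import read_fasta, read_genotype_table
from amplityper.mjn_network import annotate_counts, build_mjn, write_edge_list, write_graphml

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    try:
        alleles = read_fasta(results / "called_alleles.fasta")
        sscp = read_genotype_table(results / "sscp_genotypes.tsv")
        ngs = read_genotype_table(results / "ngs_genotypes.tsv")
    except FileNotFoundError as exc:
        sys.exit(f"{exc} - run analysis/01 and 02 first")

    network = build_mjn(alleles, epsilon=0)
    annotate_counts(network, pd.concat([sscp, ngs], ignore_index=True))
    write_graphml(network, results / "mjn_network.graphml")
    write_edge_list(network, results / "mjn_edges.tsv")

    observed = [n for n in network.nodes if network.nodes[n]["observed"]]
    medians = [n for n in network.nodes if not network.nodes[n]["observed"]]
    weights = [d["weight"] for _, _, d in network.edges(data=True)]
    print(
        f"network: {len(observed)} observed alleles, {len(medians)} median "
        f"vectors, {network.number_of_edges()} edges"
    )
    if weights:
        print(f"mutations per edge: min {min(weights)}, max {max(weights)}")


if __name__ == "__main__":
    main()
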