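"""Variant tabulation, pairwise alignment and artefact clustering."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from amplityper.amplicon_io import Amplicon, Read
from amplityper.clustering import (
    ClusteringParams,
    ErrorModel,
    Variant,
    align_pair,
    cluster_amplicon,
    clustering_gain,
    tabulate_variants,
)
from oracles import count_variants, edit_distance_dp, edit_summary_dp


def reads_from(seqs):
    return [Read(f"r{i}", s, (35,) * len(s)) for i, s in enumerate(seqs)]


class TestTabulateVariants:
    def test_direct_count(self):
        variants = tabulate_variants(Amplicon("s", reads_from(["AAA", "AAA", "AAT"])))
        assert [(v.sequence, v.depth) for v in variants] == [("AAA", 2), ("AAT", 1)]
        assert variants[0].paf == pytest.approx(2 / 3)

    def test_monoclonal_amplicon(self):
        variants = tabulate_variants(Amplicon("s", reads_from(["ACGT"] * 5000)))
        assert len(variants) == 1
        assert variants[0].paf == 1.0

    def test_empty_amplicon(self):
        assert tabulate_variants(Amplicon("s", [])) == []

    def test_matches_dictionary_counting(self, tiny_cfg, tiny_pool):
        from amplityper.synthetic_data import simulate_amplicon

        rng = np.random.default_rng(9)
        names = list(tiny_pool.sequences)[:2]
        amp, _ = simulate_amplicon(tiny_cfg, tiny_pool, "ind01", names, rng)
        variants = tabulate_variants(amp)
        expected = count_variants([r.sequence for r in amp.reads])
        assert [(v.sequence, v.depth) for v in variants] == expected


class TestAlignPair:
    def test_identity(self):
        assert align_pair("ACGT", "ACGT").total == 0

    def test_single_substitution(self):
        summary = align_pair("ACGT", "ACTT")
        assert (summary.substitutions, summary.insertions, summary.deletions) == (1, 0, 0)

    def test_homopolymer_contraction_is_one_indel(self):
        summary = align_pair("AAAACGT", "AAACGT")
        assert summary.substitutions == 0
        assert summary.indels == 1

    def test_total_cost_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            length = int(rng.integers(5, 120))
            a = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
            b = list(a)
            # mutate: substitutions plus indels
            for _ in range(int(rng.integers(0, 6))):
                op = rng.integers(0, 3)
                pos = int(rng.integers(0, len(b)))
                if op == 0:
                    b[pos] = "ACGT"[int(rng.integers(0, 4))]
                elif op == 1 and len(b) > 1:
                    del b[pos]
                else:
                    b.insert(pos, "ACGT"[int(rng.integers(0, 4))])
            b = "".join(b)
            summary = align_pair(a, b)
            assert summary.total == edit_distance_dp(a, b)

    def test_summary_matches_traceback_oracle_on_near_sequences(self):
        # near-identical pairs (the clustering regime) have a unique
        # optimal decomposition; both routes must agree exactly
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = "".join("ACGT"[b] for b in rng.integers(0, 4, size=284))
            b = list(a)
            pos = int(rng.integers(0, len(b)))
            if rng.random() < 0.5:
                b[pos] = "ACGT"[("ACGT".index(b[pos]) + 1) % 4]
            else:
                del b[pos]
            b = "".join(b)
            summary = align_pair(a, b)
            assert (
                summary.substitutions,
                summary.insertions,
                summary.deletions,
            ) == edit_summary_dp(a, b)

    def test_symmetric_total(self):
        a, b = "ACGTACGTAA", "AGGTCGTA"
        assert align_pair(a, b).total == align_pair(b, a).total


def variant(seq, depth, total):
    return Variant(sequence=seq, depth=depth, paf=depth / total)


class TestClusterAmplicon:
    def test_single_variant_single_cluster(self):
        params = ClusteringParams(expected_length=4)
        (cluster,) = cluster_amplicon([variant("ACGT", 100, 100)], params)
        assert cluster.clustered_paf == pytest.approx(1.0)
        assert not cluster.unassigned

    def test_one_substitution_artefact_absorbed(self):
        # 284 bp dominant at 800 reads; a 1-substitution variant at 150:
        # 150/800 < 25% and 1 <= round(0.005*284) = 1, so it is absorbed
        dom = "ACGT" * 71
        art = "T" + dom[1:]
        total = 950
        params = ClusteringParams(expected_length=284)
        clusters = cluster_amplicon(
            [variant(dom, 800, total), variant(art, 150, total)], params
        )
        assert len(clusters) == 1
        assert clusters[0].clustered_depth == 950
        assert clusters[0].clustered_paf == pytest.approx(1.0)

    def test_frequent_exact_length_variant_seeds(self):
        dom = "ACGT" * 71
        other = "TTTT" + dom[4:]
        params = ClusteringParams(expected_length=284)
        clusters = cluster_amplicon(
            [variant(dom, 800, 1100), variant(other, 300, 1100)], params
        )
        assert len(clusters) == 2
        assert not any(c.unassigned for c in clusters)

    def test_inexplicable_variant_stays_unassigned(self):
        dom = "ACGT" * 71
        far = "TTTTTTTT" + dom[8:]  # 8 substitutions: outside the error model
        params = ClusteringParams(expected_length=284)
        clusters = cluster_amplicon(
            [variant(dom, 800, 850), variant(far, 50, 850)], params
        )
        assert [c.unassigned for c in clusters] == [False, True]

    def test_depth_conservation(self, tiny_cfg, tiny_pool):
        from amplityper.synthetic_data import simulate_amplicon

        rng = np.random.default_rng(12)
        names = list(tiny_pool.sequences)[:2]
        amp, _ = simulate_amplicon(tiny_cfg, tiny_pool, "ind01", names, rng)
        variants = tabulate_variants(amp)
        clusters = cluster_amplicon(variants, ClusteringParams())
        assert sum(c.clustered_depth for c in clusters) == sum(v.depth for v in variants)

    def test_zero_rates_and_zero_threshold_is_identity(self):
        rng = np.random.default_rng(13)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, size=30)) for _ in range(10)]
        total = 10 * 11 // 2
        variants = [variant(s, i + 1, total) for i, s in enumerate(seqs)]
        params = ClusteringParams(
            error_model=ErrorModel(substitution_rate=0.0, indel_rate=0.0),
            min_dominant_frequency=1e-9,
            require_exact_length=False,
        )
        clusters = cluster_amplicon(variants, params)
        assert len(clusters) == len(variants)
        assert all(not c.members for c in clusters)

    def test_absorption_tie_goes_to_deeper_dominant(self):
        base = "ACGT" * 71
        dom_a = base
        dom_b = "G" + base[1:-1] + "A"  # two substitutions away from dom_a
        art = "G" + base[1:]  # one substitution from each dominant
        total = 2000
        params = ClusteringParams(expected_length=284)
        clusters = cluster_amplicon(
            [variant(dom_a, 1000, total), variant(dom_b, 900, total), variant(art, 100, total)],
            params,
        )
        assert len(clusters) == 2
        assert clusters[0].dominant.sequence == dom_a
        assert [v.sequence for v, _ in clusters[0].members] == [art]

    def test_true_alleles_seed_clusters_at_study_coverage(self, cfg, pool):
        """Both true alleles of simulated heterozygotes become dominants."""
        from amplityper.synthetic_data import simulate_amplicon

        rng = np.random.default_rng(14)
        names = list(pool.sequences)[:2]
        expected = {pool.sequences[n] for n in names}
        hits = 0
        n_rep = 8
        small = replace(cfg, coverage_range=(656, 1200))
        for _ in range(n_rep):
            amp, _ = simulate_amplicon(small, pool, "ind01", names, rng)
            variants = tabulate_variants(amp)
            clusters = cluster_amplicon(variants, ClusteringParams())
            dominants = {
                c.dominant.sequence[24:-24] for c in clusters if not c.unassigned
            }
            hits += expected <= dominants
        assert hits == n_rep


class TestClusteringGain:
    def test_no_absorption_no_gain(self):
        v = variant("ACGT" * 71, 100, 100)
        clusters = cluster_amplicon([v], ClusteringParams(expected_length=284))
        gain = clustering_gain([v], clusters)
        assert gain.gain == pytest.approx(0.0)

    def test_absorbed_fraction_and_class(self):
        dom = "ACGT" * 71
        art = "T" + dom[1:]
        variants = [variant(dom, 800, 950), variant(art, 150, 950)]
        clusters = cluster_amplicon(variants, ClusteringParams(expected_length=284))
        gain = clustering_gain(variants, clusters)
        assert gain.assigned_before == pytest.approx(800 / 950)
        assert gain.assigned_after == pytest.approx(1.0)
        assert gain.absorbed_by_class == {"1-substitution": 150}

    def test_substitution_only_errors_absorb_into_substitution_classes(
        self, tiny_cfg, tiny_pool
    ):
        from amplityper.synthetic_data import simulate_amplicon

        cfg = replace(
            tiny_cfg, homopolymer_indel_rate=0.0, chimera_fraction=0.0,
            substitution_rate=0.01,
        )
        rng = np.random.default_rng(15)
        names = list(tiny_pool.sequences)[:2]
        amp, _ = simulate_amplicon(cfg, tiny_pool, "ind01", names, rng)
        variants = tabulate_variants(amp)
        clusters = cluster_amplicon(variants, ClusteringParams())
        gain = clustering_gain(variants, clusters)
        absorbed = sum(gain.absorbed_by_class.values())
        assert absorbed > 0
        substitution_only = (
            gain.absorbed_by_class.get("1-substitution", 0)
            + gain.absorbed_by_class.get("multi-substitution", 0)
        )
        assert substitution_only == absorbed


@given(st.integers(0, 2**31 - 1))
def test_dominants_not_absorbable_into_each_other(seed):
    """Seeded dominants stay outside one another's error envelopes when
    sequences are well separated (>= 4 substitutions apart)."""
    rng = np.random.default_rng(seed)
    length = 60
    base = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
    other = list(base)
    for pos in rng.choice(length, size=6, replace=False):
        other[pos] = "ACGT"[("ACGT".index(other[pos]) + 1 + int(rng.integers(0, 3))) % 4]
    other = "".join(other)
    total = 180
    variants = [variant(base, 100, total), variant(other, 80, total)]
    clusters = cluster_amplicon(variants, ClusteringParams(expected_length=length))
    model = ErrorModel()
    for i, c in enumerate(clusters):
        for j, d in enumerate(clusters):
            if i == j:
                continue
            summary = align_pair(c.dominant.sequence, d.dominant.sequence)
            assert not (
                summary.substitutions <= model.max_substitutions(length)
                and summary.indels <= model.max_indels(length)
            )
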