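"""Threshold detection, chimera flagging, genotype calling and screening."""

from dataclasses import replace

import numpy as np
import pytest

from amplityper.allele_calling import (
    AlleleRegistry,
    CallingParams,
    allele_frequencies,
    call_genotype,
    detect_chimeras,
    detect_paf_threshold,
    frequencies_from_counts,
    pairwise_mutations,
    translate_and_screen,
)
from amplityper.clustering import Variant, VariantCluster
from amplityper.amplicon_io import genotype_table
from oracles import pairwise_matrix


def cluster(seq, depth, total, unassigned=False):
    return VariantCluster(
        dominant=Variant(sequence=seq, depth=depth, paf=depth / total),
        unassigned=unassigned,
    )


class TestDetectPafThreshold:
    def test_two_allele_heterozygote_nothing_to_cut(self):
        proposal = detect_paf_threshold([0.55, 0.45])
        assert proposal.threshold < 0.45
        assert not proposal.fallback

    def test_gap_rule_midpoint(self):
        proposal = detect_paf_threshold([0.60, 0.37, 0.03, 0.02, 0.01])
        assert proposal.threshold == pytest.approx(0.20)
        assert proposal.gap_upper == pytest.approx(0.37)
        assert proposal.gap_lower == pytest.approx(0.03)

    def test_chimera_raises_proposal(self):
        proposal = detect_paf_threshold(
            [0.60, 0.37, 0.03, 0.02, 0.01], chimera_pafs=[0.19]
        )
        assert proposal.threshold == pytest.approx(0.20)  # already above
        raised = detect_paf_threshold(
            [0.60, 0.45, 0.03, 0.02, 0.01], chimera_pafs=[0.30]
        )
        assert raised.threshold == pytest.approx(0.31)
        assert raised.raised_for_chimera

    def test_uniform_pafs_fall_back_to_default(self):
        with pytest.warns(UserWarning):
            proposal = detect_paf_threshold([0.5, 0.5, 0.5])
        assert proposal.threshold == pytest.approx(0.14)
        assert proposal.fallback


class TestDetectChimeras:
    def test_parent_itself_never_flagged(self):
        parents = ["A" * 30 + "C" * 30, "G" * 30 + "T" * 30]
        assert detect_chimeras([parents[0]], parents) == {}

    def test_constructed_chimera_with_breakpoint(self):
        p = "A" * 20 + "C" * 100 + "G" * 80
        q = "A" * 20 + "G" * 100 + "T" * 80
        s = p[:100] + q[100:]
        hits = detect_chimeras([s], [p, q])
        assert s in hits
        hit = hits[s]
        assert hit.parent_prefix == p and hit.parent_suffix == q
        # any breakpoint in the shared A-prefix .. first divergence window
        # reconstructs s; the smallest valid one is reported
        assert s == p[: hit.breakpoint] + q[hit.breakpoint :]
        assert hit.breakpoint >= 20

    def test_short_segment_not_flagged(self):
        p = "A" * 100
        q = "C" * 10 + "A" * 90
        s = q[:10] + p[10:]  # prefix segment shorter than 20
        assert detect_chimeras([s], [p, "C" * 100]) == {}

    def test_simulated_chimeras_with_called_parents_are_flagged(self, cfg, pool):
        """Chimeric insert sequences distinct from both parents are always
        detectable because the primer-adjacent segments are shared."""
        from amplityper.synthetic_data import simulate_amplicon

        boosted = replace(cfg, chimera_fraction=0.3, coverage_range=(400, 600))
        rng = np.random.default_rng(16)
        names = list(pool.sequences)[:2]
        parents = [pool.sequences[n] for n in names]
        flagged = total = 0
        for _ in range(10):
            _, truth = simulate_amplicon(boosted, pool, "ind01", names, rng)
            chimeric = truth[truth["source"] == "chimera"]
            for row in chimeric.itertuples(index=False):
                k = row.chimera_breakpoint
                seq = (
                    pool.sequences[row.chimera_parent_prefix][:k]
                    + pool.sequences[row.chimera_parent_suffix][k:]
                )
                if seq in parents:
                    continue  # breakpoint before the first divergence: not a new sequence
                total += 1
                flagged += seq in detect_chimeras([seq], parents)
        assert total > 50
        assert flagged / total >= 0.95


class TestCallGenotype:
    def test_heterozygote_with_low_frequency_artefact(self, registry, pool):
        names = list(pool.sequences)
        a, b = pool.sequences[names[0]], pool.sequences[names[1]]
        artefact = ("T" if a[0] != "T" else "G") + a[1:]
        clusters = [
            cluster(a, 550, 1000),
            cluster(b, 410, 1000),
            cluster(artefact, 20, 1000),
        ]
        genotype, audit = call_genotype(
            clusters, CallingParams(), registry, "ind01"
        )
        assert set(genotype.alleles) == {names[0], names[1]}
        categories = {c.sequence: c.category for c in audit}
        # 2% is above the 1% floor but below the 14% PAF threshold
        assert categories[artefact] == "below_paf_threshold"

    def test_single_cluster_homozygote(self, registry, pool):
        name, seq = next(iter(pool.sequences.items()))
        genotype, _ = call_genotype(
            [cluster(seq, 970, 1000)], CallingParams(), registry, "ind01"
        )
        assert genotype.alleles == (name,)
        assert genotype.homozygous

    def test_novel_sequence_gets_registry_name_and_flag(self, registry):
        rng = np.random.default_rng(17)
        novel = "".join("ACGT"[b] for b in rng.integers(0, 4, size=236))
        genotype, audit = call_genotype(
            [cluster(novel, 450, 1000)], CallingParams(), registry, "ind01"
        )
        call = next(c for c in audit if c.accepted)
        assert call.putative_new
        assert registry.name_of(novel) == call.allele_name
        assert genotype.alleles == (call.allele_name,)

    def test_supernumerary_flagged_not_dropped(self, registry, pool):
        names = list(pool.sequences)
        clusters = [
            cluster(pool.sequences[names[0]], 400, 1000),
            cluster(pool.sequences[names[1]], 350, 1000),
            cluster(pool.sequences[names[2]], 250, 1000),
        ]
        genotype, audit = call_genotype(clusters, CallingParams(), registry, "ind01")
        assert len(genotype.alleles) == 2
        assert sum(c.category == "supernumerary" for c in audit) == 1

    def test_no_surviving_cluster_is_no_call_with_audit(self, registry):
        genotype, audit = call_genotype(
            [cluster("ACGT" * 59, 5, 1000)], CallingParams(), registry, "ind01"
        )
        assert genotype is None
        assert len(audit) == 1

    def test_audit_categories_partition_clusters(self, registry, pool):
        rng = np.random.default_rng(18)
        names = list(pool.sequences)
        total = 1000
        clusters = [
            cluster(pool.sequences[names[0]], 500, total),
            cluster(pool.sequences[names[1]], 300, total),
            cluster(pool.sequences[names[2]], 150, total),
            cluster("A" + pool.sequences[names[0]][1:], 30, total),
            cluster("".join("ACGT"[b] for b in rng.integers(0, 4, 236)), 5, total),
        ]
        _, audit = call_genotype(clusters, CallingParams(), registry, "ind01")
        assert len(audit) == len(clusters)
        for call in audit:
            flags = [
                call.below_min_frequency,
                call.chimera,
                call.below_threshold,
                call.supernumerary,
                call.accepted,
            ]
            assert sum(flags) == 1


class TestAlleleFrequencies:
    def test_observations_and_frequency_from_counts(self):
        frame = frequencies_from_counts({"X": 20}, 28)
        assert frame.loc[0, "frequency"] == pytest.approx(20 / 56)

    def test_all_homozygous_single_allele(self):
        table = genotype_table([(f"i{k}", "NGS", ("A",)) for k in range(28)])
        freqs, excluded = allele_frequencies(table, "NGS")
        assert excluded == []
        assert freqs.loc[0, "observations"] == 56
        assert freqs.loc[0, "frequency"] == pytest.approx(1.0)

    def test_sums_to_one_and_two_n(self):
        rng = np.random.default_rng(19)
        rows = []
        for i in range(28):
            k = int(rng.integers(1, 3))
            alleles = tuple(
                f"A{j}" for j in sorted(rng.choice(8, size=k, replace=False))
            )
            rows.append((f"i{i}", "NGS", alleles))
        freqs, _ = allele_frequencies(genotype_table(rows), "NGS")
        assert freqs["observations"].sum() == 56
        assert freqs["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_calls_excluded_and_reported(self):
        table = genotype_table([("i1", "NGS", ("A",)), ("i2", "NGS", ())])
        freqs, excluded = allele_frequencies(table, "NGS")
        assert excluded == ["i2"]
        assert freqs["observations"].sum() == 2


class TestTranslateAndScreen:
    def test_internal_stop_flagged(self):
        report = translate_and_screen("ATGTAA")
        assert report.protein == "M*"
        assert report.has_internal_stop
        assert report.stop_positions == (2,)

    def test_stop_free_codons(self):
        report = translate_and_screen("ATGGCC")
        assert report.protein == "MA"
        assert not report.has_internal_stop

    def test_ambiguous_codon_translates_to_x(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            report = translate_and_screen("ATGNCC")
        assert report.protein == "MX"
        assert report.ambiguous_codons == 1

    def test_trailing_bases_ignored_with_warning(self):
        with pytest.warns(UserWarning, match="trailing"):
            report = translate_and_screen("ATGGC")
        assert report.protein == "M"
        assert report.trailing_bases == 2

    def test_simulated_pools_are_stop_free(self, pool, cfg):
        for seq in pool.sequences.values():
            with pytest.warns(UserWarning):  # 236 bp leaves 2 trailing bases
                report = translate_and_screen(seq, cfg.frame_offset)
            assert not report.has_internal_stop


class TestPairwiseMutations:
    def test_identical_pair_is_zero(self):
        matrix, variable = pairwise_mutations([("a", "AAAA"), ("b", "AAAA")])
        assert matrix.loc["a", "b"] == 0
        assert variable == []

    def test_single_difference(self):
        matrix, variable = pairwise_mutations([("a", "AAAA"), ("b", "AATA")])
        assert matrix.loc["a", "b"] == 1
        assert variable == [3]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="align"):
            pairwise_mutations([("a", "AAAA"), ("b", "AAA")])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(20)
        seqs = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, size=236)) for _ in range(8)
        ]
        matrix, _ = pairwise_mutations([(f"s{i}", s) for i, s in enumerate(seqs)])
        assert matrix.values.tolist() == pairwise_matrix(seqs)

    def test_cross_checks_simulated_pool(self, pool, cfg):
        """The generator's distance constraints hold under the analysis path."""
        matrix, variable = pairwise_mutations(list(pool.sequences.items()))
        off_diagonal = matrix.values[~np.eye(len(matrix), dtype=bool)]
        assert off_diagonal.min() >= cfg.min_pairwise_mutations
        assert set(variable) == set(pool.variable_sites)
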