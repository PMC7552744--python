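# Methods

## Model and scope

`amplityper` genotypes a diploid, single-copy, highly polymorphic amplicon
locus (the motivating case is MHC class II *DRB* exon 2: a 236 bp insert
amplified with 24 bp primers, 284 bp total) from single-end reads with
Phred qualities. The core assumption is that each individual carries one or
two true alleles and that everything else in its amplicon is an artefact of
PCR or sequencing: near-neighbour error variants, chimeric recombinants of
the individual's own alleles, and low-frequency noise. The pipeline
separates these classes by read depth, platform error rates and sequence
structure rather than by any probabilistic model of the error process.

## Stage parameters

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| `min_mean_phred` | 30 | Phred | Mean-quality filter; per-base Q30 would discard nearly all reads on a homopolymer-error-prone platform. A per-base mode is available. |
| `min_len`–`max_len` | 279–289 | bp | Brackets the 284 bp primer-inclusive amplicon; applied after barcode/linker trimming, with both primers retained. |
| `max_reads_per_amplicon` | 5000 | reads | Depth cap; deeper amplicons are uniformly subsampled, seeded per run and per sample. |
| `substitution_rate` | 0.005 | per base | Ion Torrent substitution error rate used for cluster absorption. |
| `indel_rate` | 0.01 | per base | Ion Torrent indel error rate (homopolymer-driven). |
| `min_dominant_frequency` | 0.25 | fraction of top variant | A true second allele of a heterozygote cannot fall far below the first; measured against the amplicon's single most frequent variant (a running-dominant mode is available). |
| `min_variant_frequency` | 0.01 | PAF | Noise floor applied to clustered PAFs. |
| `paf_threshold` | 0.14 | PAF | Cut between the artefact band and true alleles; see threshold proposal below. |
| `max_alleles_per_individual` | 2 | alleles | Single-copy diploid locus. Extras are flagged `supernumerary`, never silently dropped. |
| `chimera_min_segment` | 20 | bp | Minimum exact parent segment on each side of a chimera breakpoint. |

## Numerical and design choices

**Alignment.** Pairwise edit summaries (substitutions / insertions /
deletions, unit costs) come from edlib's global alignment with extended
CIGARs. Where several alignments share the minimal total cost the engine's
canonical traceback decides the split; the test suite checks totals against
an independent quadratic DP on random pairs and exact splits on constructed
single-substitution and homopolymer-indel cases, where the optimum is
unique.

**Absorption ceilings.** A variant is absorbable into dominant *d* iff
substitutions ≤ max(1, round(sub_rate·L)) and indels ≤ max(1,
round(indel_rate·L)), L = len(d). The floor of one allowed error per class
keeps short amplicons from forbidding all absorption; `floor`/`ceil`
variants are selectable. Absorption ties go to the deeper dominant, then to
the lexicographically smaller sequence — the result is a deterministic
function of the variant multiset.

**Expected length.** When not supplied, the exact-length requirement for
dominants uses the modal variant length (ties to the shorter), which on
clean data is the primer-inclusive amplicon length.

**Threshold proposal.** All clustered PAFs in a run (chimera-flagged
clusters excluded) are sorted descending; within the sub-50% region
(augmented with a 0 sentinel) the widest gap between consecutive values is
taken as the artefact boundary and its midpoint proposed as the threshold.
If any flagged chimera sits at or above the proposal, the proposal is
raised to the chimera's PAF + 0.01 — one percentage point above the highest
known artefact. With fewer than two distinct PAFs the default 0.14 is
returned with a warning. The function only proposes; callers opt in via
`auto_threshold`.

**Filter order.** 1% floor → chimera flagging → PAF threshold → two-allele
cap. Chimera parents are the run-wide accepted alleles (strictly more
sensitive than per-amplicon parents, and a true allele can never be flagged
because parents are exempt). Every cluster lands in exactly one audit
category.

**Translation.** Standard code from a configurable frame offset (default
0). 236 bp is not a codon multiple; the trailing 1–2 nt are ignored with a
warning. Ambiguous codons translate to `X`.

**Median-joining network.** Bandelt-style: iterate {minimum spanning
network within ε; per-column majority medians of connected triples, ties
broken A<C<G<T<gap; add cost-minimal new medians (≤ λ + ε)} with medians
only accumulating, then iteratively prune median vectors of degree ≤ 2,
recomputing the MSN after each pass. Monotone growth guarantees a fixpoint;
a 20-iteration cap raises a loud error otherwise. Gaps count as a fifth
state in Hamming distances. Only ε = 0 is validated.

## What the simulator emulates — and what it does not

The generator reproduces the statistical structure the pipeline assumes:
8 stop-free alleles (pairwise distance ≥ 2, ~17 candidate variable sites in
236 bp), Hardy–Weinberg genotypes at the study's estimated allele
frequencies, uniform 656–5000× coverage, per-base substitutions at 0.5%,
±1 bp indels at homopolymer runs ≥ 3 bp (rate 0.005 per run per read — the
platform tendency is documented but unquantified, so a value of the same
order as the substitution rate was fixed once), chimeras as uniform-breakpoint
recombinants of the individual's two alleles (1% of a heterozygote's
reads), lognormal per-allele amplification weights (σ = 0.3, enough to skew
PAFs without routinely crossing the 14% threshold — the dropout mechanism
is exercised explicitly by widening σ in tests), 5% low-quality reads
(mean Q < 30) to exercise QC, and an SSCP emulator with dropout probability
0.28 per heterozygote (six false homozygotes among the ≈21.6 heterozygotes
expected under HWE in a 28-individual cohort) and a 1/28 false-positive
probability.

Not emulated: flowgram-level signal error (quality scores are uninformative
of error positions), correlated errors across reads, PCR-cycle dynamics of
chimera formation, barcode-region sequencing errors (barcodes are prepended
error-free, so demultiplexing losses are not part of the recovery
experiments), paired-end structure, and multi-locus co-amplification.
Passing recovery tests therefore demonstrate the calling logic under the
assumed error structure, not performance on real multi-copy MHC data.

## Test problem sizes

Worked examples (frequency arithmetic, concordance rates, threshold
narrative) are exact and instantaneous. Simulation-backed properties run at
the study's conditions — 28 individuals, coverage 656–5000 — with replicate
counts chosen to keep the default suite at a few minutes: the end-to-end
recovery property uses 12 replicate cohorts (≈340 amplicons, mean recovery
≥ 95%) plus one zero-noise cohort that must recover 100% exactly; the
clustering-direction property uses one full cohort and requires a strict
assigned-depth increase in all 28 amplicons. `scripts/acceptance.py` uses 4
replicate cohorts. Oracle equivalences run on 500 random alignment pairs,
2000-read tabulations and 20 random networks.

## Known limitations

- The absorption rule is a declared, deterministic reading of
  error-rate-based clustering; other tools' internal criteria may differ in
  tie cases.
- Chimera detection is exact-match only; a chimera carrying an additional
  sequencing error is not flagged (it is instead absorbed or dropped by the
  frequency filters).
- The threshold proposal assumes heterozygote allele PAFs stay above ~25%;
  extreme amplification bias would blur the gap it looks for.
- `allele_frequencies` treats every called individual as diploid; partial
  (single-allele) calls are counted as homozygous, as in the field's
  convention, which inflates frequencies under unrecognised dropout.
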