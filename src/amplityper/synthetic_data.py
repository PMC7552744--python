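"""Ground-truthed synthetic amplicon data for a single-copy diploid locus.

Emulates the statistical structure of an Ion Torrent MHC DRB exon 2
amplicon run: a pool of stop-codon-free 236 bp alleles separated by at
least two mutations, Hardy-Weinberg diploid genotypes over configurable
allele frequencies, per-amplicon coverage drawn uniformly from the
observed range (656-5000 reads), per-allele amplification bias
(lognormal weights), per-base substitution errors, homopolymer +/-1 bp
indels, PCR chimeras with uniform breakpoints, and a small fraction of
low-quality reads to exercise quality filtering. A per-read truth table
makes parameter-recovery testing possible. An SSCP/Sanger emulator
applies allelic dropout and occasional false positives to the true
genotypes.

Every draw comes from one seeded generator, so output is reproducible
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import (
    FORWARD_PRIMER,
    REVERSE_PRIMER,
    Amplicon,
    BarcodeScheme,
    Read,
    genotype_table,
)

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "DEFAULT_ALLELE_COUNTS",
    "SimConfig",
    "AllelePool",
    "make_allele_pool",
    "simulate_genotypes",
    "make_barcode_scheme",
    "simulate_amplicon",
    "simulate_reads",
    "emulate_sscp",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# gene-copy observation counts the NGS method reported for the eight
# alleles in 28 individuals; used (normalised) as the default truth
# frequencies of the simulated population
DEFAULT_ALLELE_COUNTS = (18, 17, 1, 6, 1, 2, 4, 7)

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation conditions.

    Defaults mirror the genotyped chamois cohort: 8 alleles of 236 bp at
    the NGS-estimated frequencies, 28 diploid individuals, coverage
    656-5000 reads per amplicon, platform error rates of 0.5%
    substitutions per base and homopolymer indels, and chimera/bias/
    dropout settings documented in the methods note.
    """

    n_alleles: int = 8
    allele_length: int = 236
    min_pairwise_mutations: int = 2
    n_variable_sites: int = 17
    allele_frequencies: tuple[float, ...] = tuple(
        c / sum(DEFAULT_ALLELE_COUNTS) for c in DEFAULT_ALLELE_COUNTS
    )
    n_individuals: int = 28
    coverage_range: tuple[int, int] = (656, 5000)
    substitution_rate: float = 0.005
    homopolymer_indel_rate: float = 0.005
    chimera_fraction: float = 0.01
    amplification_bias_sigma: float = 0.3
    low_quality_fraction: float = 0.05
    sscp_dropout_prob: float = 0.28
    sscp_false_positive_prob: float = 1 / 28
    frame_offset: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.allele_frequencies) != self.n_alleles:
            raise ValueError("allele_frequencies must have one entry per allele")
        if abs(sum(self.allele_frequencies) - 1.0) > 1e-9:
            raise ValueError("allele_frequencies must sum to 1")
        for rate in (
            self.substitution_rate,
            self.homopolymer_indel_rate,
            self.chimera_fraction,
            self.low_quality_fraction,
            self.sscp_dropout_prob,
            self.sscp_false_positive_prob,
        ):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if self.coverage_range[0] < 1 or self.coverage_range[0] > self.coverage_range[1]:
            raise ValueError("invalid coverage_range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass(frozen=True)
class AllelePool:
    """Named allele inserts with the realised variable-site summary."""

    sequences: dict[str, str]  # name -> 236 bp insert
    variable_sites: tuple[int, ...]  # 1-based positions
    variable_fraction: float

    def names(self) -> list[str]:
        return list(self.sequences)


def _has_stop(seq: str, frame_offset: int) -> bool:
    coding = seq[frame_offset:]
    return any(
        coding[i : i + 3] in STOP_CODONS for i in range(0, len(coding) - 2, 3)
    )


def _random_stop_free(length: int, frame_offset: int, rng: np.random.Generator) -> str:
    while True:
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if not _has_stop(seq, frame_offset):
            return seq


def make_allele_pool(
    cfg: SimConfig, rng: np.random.Generator | None = None, max_attempts: int = 10_000
) -> AllelePool:
    """Generate stop-free alleles differing at a small set of variable sites.

    An ancestral sequence is drawn, a set of candidate variable positions
    chosen, and each further allele derived by mutating 2-8 of those
    positions, rejecting candidates with a premature stop codon or closer
    than ``min_pairwise_mutations`` to any existing allele.
    """
    rng = cfg.rng() if rng is None else rng
    ancestor = _random_stop_free(cfg.allele_length, cfg.frame_offset, rng)
    site_pool = np.sort(
        rng.choice(cfg.allele_length, size=cfg.n_variable_sites, replace=False)
    )
    alleles = [ancestor]
    attempts = 0
    while len(alleles) < cfg.n_alleles:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not satisfy allele pool constraints "
                f"(n={cfg.n_alleles}, min distance {cfg.min_pairwise_mutations})"
            )
        k = int(rng.integers(2, min(9, cfg.n_variable_sites + 1)))
        positions = rng.choice(site_pool, size=k, replace=False)
        candidate = list(ancestor)
        for pos in positions:
            current = candidate[pos]
            candidate[pos] = rng.choice([b for b in BASES if b != current])
        candidate_seq = "".join(candidate)
        if _has_stop(candidate_seq, cfg.frame_offset):
            continue
        if any(
            _hamming(candidate_seq, existing) < cfg.min_pairwise_mutations
            for existing in alleles
        ):
            continue
        alleles.append(candidate_seq)
    names = [f"Sim-DRB*{i + 1:02d}" for i in range(cfg.n_alleles)]
    arr = np.frombuffer("".join(alleles).encode(), dtype="S1").reshape(len(alleles), -1)
    variable = tuple(int(i) + 1 for i in np.where((arr != arr[0]).any(axis=0))[0])
    return AllelePool(
        sequences=dict(zip(names, alleles)),
        variable_sites=variable,
        variable_fraction=len(variable) / cfg.allele_length,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def simulate_genotypes(
    cfg: SimConfig, pool: AllelePool, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw diploid genotypes under Hardy-Weinberg random mating."""
    rng = cfg.rng() if rng is None else rng
    names = pool.names()
    freqs = np.asarray(cfg.allele_frequencies)
    rows = []
    for i in range(cfg.n_individuals):
        copies = rng.choice(len(names), size=2, p=freqs)
        alleles = tuple(sorted({names[c] for c in copies}))
        rows.append((f"ind{i + 1:02d}", "truth", alleles))
    return genotype_table(rows)


def make_barcode_scheme(
    sample_ids: Sequence[str],
    rng: np.random.Generator | None = None,
    barcode_length: int = 10,
) -> BarcodeScheme:
    """Random unique barcodes in the IonXpress style, with the DRB primers."""
    rng = np.random.default_rng(0) if rng is None else rng
    barcodes: dict[str, str] = {}
    seen: set[str] = set()
    for sample in sample_ids:
        while True:
            code = "".join(BASES[i] for i in rng.integers(0, 4, size=barcode_length))
            if code not in seen:
                seen.add(code)
                barcodes[sample] = code
                break
    return BarcodeScheme(
        sample_barcodes=barcodes,
        forward_primer=FORWARD_PRIMER,
        reverse_primer=REVERSE_PRIMER,
    )


def _homopolymer_runs(seq: str, min_run: int = 3) -> list[tuple[int, int]]:
    """(start, length) of maximal single-base runs of length >= min_run."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_run:
                runs.append((start, i - start))
            start = i
    return runs


def _apply_errors(
    core: str,
    runs: list[tuple[int, int]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Inject homopolymer indels then substitutions into one read core."""
    n_indels = 0
    if runs and cfg.homopolymer_indel_rate > 0:
        hit = rng.random(len(runs)) < cfg.homopolymer_indel_rate
        if hit.any():
            chars = list(core)
            # apply right-to-left so earlier run coordinates stay valid
            for idx in np.where(hit)[0][::-1]:
                start, length = runs[idx]
                if length > 3 and rng.random() < 0.5:
                    del chars[start]  # contract the run by one base
                else:
                    chars.insert(start, core[start])  # expand by one base
                n_indels += 1
            core = "".join(chars)
    n_subs = int(rng.binomial(len(core), cfg.substitution_rate))
    if n_subs:
        core = _substitute(core, n_subs, rng)
    return core, n_subs, n_indels


def _substitute(core: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply n random substitutions at distinct positions."""
    positions = rng.choice(len(core), size=n_subs, replace=False)
    shifts = rng.integers(1, 4, size=n_subs)
    chars = list(core)
    for pos, shift in zip(positions.tolist(), shifts.tolist()):
        chars[pos] = BASES[(BASES.index(chars[pos]) + shift) % 4]
    return "".join(chars)


def simulate_amplicon(
    cfg: SimConfig,
    pool: AllelePool,
    individual_id: str,
    alleles: Sequence[str],
    rng: np.random.Generator,
    scheme: BarcodeScheme | None = None,
) -> tuple[Amplicon, pd.DataFrame]:
    """Simulate one individual's read set with a per-read truth table.

    Reads are the primer-inclusive 284 bp amplicon
    (forward primer + insert + reverse-complemented reverse primer);
    when a barcode scheme is given, barcode+linker are prepended
    error-free (the pipeline's demultiplexer removes them again).
    Sequencing errors hit the amplicon portion.
    """
    if not 1 <= len(alleles) <= 2:
        raise ValueError("an individual carries 1 or 2 alleles")
    rc_rev = _revcomp(REVERSE_PRIMER if scheme is None else scheme.reverse_primer)
    fwd = FORWARD_PRIMER if scheme is None else scheme.forward_primer
    prefix = ""
    if scheme is not None:
        prefix = scheme.sample_barcodes[individual_id] + scheme.linker
    cores = {name: fwd + pool.sequences[name] + rc_rev for name in alleles}
    runs = {name: _homopolymer_runs(core) for name, core in cores.items()}
    coverage = int(rng.integers(cfg.coverage_range[0], cfg.coverage_range[1] + 1))
    weights = np.ones(len(alleles))
    if len(alleles) == 2 and cfg.amplification_bias_sigma > 0:
        weights = rng.lognormal(0.0, cfg.amplification_bias_sigma, size=2)
    probs = weights / weights.sum()
    heterozygous = len(alleles) == 2
    insert_len = cfg.allele_length
    # per-amplicon batched draws (order matters for reproducibility)
    chimera_flags = (
        rng.random(coverage) < cfg.chimera_fraction
        if heterozygous
        else np.zeros(coverage, dtype=bool)
    )
    source_draws = rng.random(coverage)
    flip_draws = rng.random(coverage)
    breakpoints = rng.integers(1, insert_len, size=coverage)
    sequences: list[str] = []
    truth_rows = []
    for r in range(coverage):
        read_id = f"{individual_id}:r{r + 1}"
        if chimera_flags[r]:
            k = int(breakpoints[r])
            p, q = alleles if flip_draws[r] < 0.5 else list(alleles)[::-1]
            insert = pool.sequences[p][:k] + pool.sequences[q][k:]
            core = fwd + insert + rc_rev
            core_runs = _homopolymer_runs(core)
            source, parent_p, parent_q, breakpoint = "chimera", p, q, k
        else:
            source = alleles[0 if source_draws[r] < probs[0] else 1]
            core = cores[source]
            core_runs = runs[source]
            parent_p = parent_q = ""
            breakpoint = -1
        core, n_subs, n_indels = _apply_errors(core, core_runs, cfg, rng)
        sequences.append(prefix + core)
        truth_rows.append(
            (read_id, individual_id, source, parent_p, parent_q, breakpoint, n_subs, n_indels)
        )
    max_len = max(len(s) for s in sequences)
    low_quality = rng.random(coverage) < cfg.low_quality_fraction
    good_quals = rng.integers(30, 41, size=(coverage, max_len))
    low_quals = rng.integers(10, 30, size=(coverage, max_len))
    reads = [
        Read(
            row[0],
            seq,
            tuple(
                (low_quals if low_quality[i] else good_quals)[i, : len(seq)].tolist()
            ),
        )
        for i, (row, seq) in enumerate(zip(truth_rows, sequences))
    ]
    amplicon = Amplicon(sample_id=individual_id, reads=reads)
    amplicon.record("simulated", coverage)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "individual_id",
            "source",
            "chimera_parent_prefix",
            "chimera_parent_suffix",
            "chimera_breakpoint",
            "n_substitutions",
            "n_indels",
        ],
    )
    return amplicon, truth


def simulate_reads(
    cfg: SimConfig,
    pool: AllelePool,
    genotypes: pd.DataFrame,
    scheme: BarcodeScheme | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[tuple[Amplicon, pd.DataFrame]]:
    """Yield (amplicon, per-read truth) for every individual in turn.

    Streaming keeps memory at one amplicon; collect into a list for the
    full cohort.
    """
    rng = cfg.rng() if rng is None else rng
    for row in genotypes.itertuples(index=False):
        yield simulate_amplicon(
            cfg, pool, str(row.individual_id), list(row.alleles), rng, scheme
        )


def emulate_sscp(
    cfg: SimConfig,
    pool: AllelePool,
    truth_genotypes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Degrade true genotypes the way gel-based SSCP/Sanger typing does.

    Heterozygotes lose one allele (allelic dropout -> false homozygote)
    with ``sscp_dropout_prob``; with ``sscp_false_positive_prob`` an
    individual called with a single allele gains a spurious 1-mutation
    neighbour of a carried allele, respecting the two-allele cap.
    Returns the SSCP genotype table and the spurious alleles' sequences.
    """
    rng = cfg.rng() if rng is None else rng
    rows = []
    spurious: dict[str, str] = {}
    for row in truth_genotypes.itertuples(index=False):
        alleles = list(row.alleles)
        if len(alleles) == 2 and rng.random() < cfg.sscp_dropout_prob:
            drop = int(rng.integers(0, 2))
            alleles = [alleles[1 - drop]]
        if len(alleles) < 2 and rng.random() < cfg.sscp_false_positive_prob:
            template = pool.sequences[alleles[int(rng.integers(0, len(alleles)))]]
            pos = int(rng.integers(0, len(template)))
            base = BASES[(BASES.index(template[pos]) + int(rng.integers(1, 4))) % 4]
            name = f"fp-{row.individual_id}"
            spurious[name] = template[:pos] + base + template[pos + 1 :]
            alleles.append(name)
        rows.append((row.individual_id, "SSCP", tuple(sorted(alleles))))
    return genotype_table(rows), spurious
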