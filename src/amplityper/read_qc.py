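"""Quality/length filtering and the per-amplicon subsampling cap.

Mirrors the pre-clustering cleanup used for Ion Torrent amplicon runs:
reads below a mean Phred quality of 30 or outside the 279-289 bp window
are removed, and amplicons deeper than 5000 reads are randomly
subsampled to that cap. The length window brackets the primer-inclusive
284 bp amplicon (236 bp exon 2 insert + two 24 bp primers), so it is
applied to reads that still carry both primers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amplicon_io import Amplicon, Read

__all__ = ["QCParams", "filter_reads", "subsample"]


@dataclass(frozen=True)
class QCParams:
    """Filtering and subsampling knobs.

    ``min_mean_phred`` is compared against the read's MEAN quality by
    default (the convention of amplicon cleanup tools on this platform);
    set ``per_base_quality=True`` to require every base to reach it.
    """

    min_mean_phred: float = 30.0
    min_len: int = 279
    max_len: int = 289
    max_reads_per_amplicon: int = 5000
    rng_seed: int = 0
    per_base_quality: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("require 0 < min_len <= max_len")
        if self.max_reads_per_amplicon < 1:
            raise ValueError("max_reads_per_amplicon must be >= 1")


def _passes(read: Read, params: QCParams) -> bool:
    if not params.min_len <= len(read) <= params.max_len:
        return False
    if params.per_base_quality:
        return min(read.qualities) >= params.min_mean_phred
    return read.mean_quality >= params.min_mean_phred


def filter_reads(amplicon: Amplicon, params: QCParams) -> Amplicon:
    """Drop reads failing the quality or length predicate; order preserved.

    Idempotent; an empty survivor set is allowed and visible in provenance.
    """
    kept = [r for r in amplicon.reads if _passes(r, params)]
    out = Amplicon(sample_id=amplicon.sample_id, reads=kept, provenance=dict(amplicon.provenance))
    out.record("qc_seen", len(amplicon.reads))
    out.record("qc_kept", len(kept))
    out.record("qc_discarded", len(amplicon.reads) - len(kept))
    return out


def subsample(amplicon: Amplicon, params: QCParams) -> Amplicon:
    """Uniformly subsample to the cap, without replacement, reproducibly.

    Identity when depth <= cap. The draw is seeded from ``rng_seed`` and
    the amplicon's sample_id so that different amplicons of one run get
    independent but reproducible subsamples.
    """
    if len(amplicon) <= params.max_reads_per_amplicon:
        out = Amplicon(
            sample_id=amplicon.sample_id,
            reads=list(amplicon.reads),
            provenance=dict(amplicon.provenance),
        )
        out.record("subsample_kept", len(amplicon))
        return out
    salt = np.frombuffer(amplicon.sample_id.encode(), dtype=np.uint8).sum()
    rng = np.random.default_rng((params.rng_seed, int(salt)))
    idx = rng.choice(len(amplicon), size=params.max_reads_per_amplicon, replace=False)
    idx.sort()  # keep original read order
    kept = [amplicon.reads[i] for i in idx]
    out = Amplicon(
        sample_id=amplicon.sample_id, reads=kept, provenance=dict(amplicon.provenance)
    )
    out.record("subsample_seen", len(amplicon))
    out.record("subsample_kept", len(kept))
    out.record("subsample_seed", params.rng_seed)
    return out
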