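"""End-to-end processing of single records: profile -> decision -> sequence."""

from __future__ import annotations

from .consensus import DEFAULT_QUAL_CAP, merge_pair
from .io_formats import RecordOutcome
from .model import (
    DEFAULT_RATIO,
    Decision,
    decide,
    posterior_profile,
    single_end_profile,
)
from .prior import LengthPrior
from .records import AdaptorPair, ReadRecord


def process_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    adaptors: AdaptorPair,
    prior: LengthPrior,
    ratio_threshold: float = DEFAULT_RATIO,
    qual_cap: int = DEFAULT_QUAL_CAP,
) -> RecordOutcome:
    """Infer the MAP molecule length for a pair and reconstruct if merged."""
    profile = posterior_profile(r1, r2, adaptors, prior)
    result = decide(profile, ratio_threshold)
    if result.decision is Decision.MERGED:
        result.sequence = merge_pair(r1, r2, result.inferred_length, qual_cap)
    return RecordOutcome(r1, r2, result)


def process_single(
    read: ReadRecord,
    adaptor: str,
    prior: LengthPrior,
    ratio_threshold: float = DEFAULT_RATIO,
) -> RecordOutcome:
    """Infer the MAP trim point for a single-end read."""
    profile = single_end_profile(read, adaptor, prior)
    result = decide(profile, ratio_threshold, single_end=True)
    if result.decision is Decision.TRIMMED_SINGLE:
        result.sequence = read.slice(0, result.inferred_length)
    return RecordOutcome(read, None, result)
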