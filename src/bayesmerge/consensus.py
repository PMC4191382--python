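"""Consensus base calling for doubly covered molecule positions.

When both reads of a pair observe the same molecule position, the two
(base, quality) observations are combined with Bayes' rule under a uniform
1/4 nucleotide prior: ``p(n | b1, b2) ∝ p(b1 | n) · p(b2 | n)``. The call
is the argmax nucleotide; its quality is the PHRED scaling of the posterior
probability that the call is wrong,

    p(err) = Σ_{m ≠ n} p(b1, b2 | m) / Σ_m p(b1, b2 | m),

capped (default 60) so two agreeing high-quality bases stay encodable in
FASTQ. Positions covered by a single read keep their original base and
quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import QUAL_FLOOR, _pe
from .records import ReadRecord, reverse_complement

_NUCS = "ACGT"

DEFAULT_QUAL_CAP = 60


def obs_likelihood(b: str, q: int, n: str) -> float:
    """P(observing base ``b`` at quality ``q`` | true nucleotide ``n``)."""
    pe = _pe(q)
    return 1.0 - pe if b == n else pe / 3.0


@dataclass(frozen=True)
class ConsensusBase:
    base: str
    qual: int


def consensus_call(
    b1: str, q1: int, b2: str, q2: int, qual_cap: int = DEFAULT_QUAL_CAP
) -> ConsensusBase:
    """Call the consensus of two observations of one molecule position.

    Ties between conflicting bases of equal quality go to the read-1 base
    (the accompanying quality is then very low). If one observation is N the
    other is returned unchanged; two Ns give N at the floor quality.
    """
    if b1 == "N" and b2 == "N":
        return ConsensusBase("N", QUAL_FLOOR)
    if b1 == "N":
        return ConsensusBase(b2, int(q2))
    if b2 == "N":
        return ConsensusBase(b1, int(q1))

    joint = [obs_likelihood(b1, q1, n) * obs_likelihood(b2, q2, n) for n in _NUCS]
    total = sum(joint)
    best = max(range(4), key=lambda k: joint[k])
    # deterministic tie-break: prefer read 1's base on an exact tie
    if joint[_NUCS.index(b1)] == joint[best]:
        best = _NUCS.index(b1)
    p_err = (total - joint[best]) / total
    if p_err <= 0.0:
        qual = qual_cap
    else:
        qual = min(qual_cap, int(round(-10.0 * math.log10(p_err))))
    return ConsensusBase(_NUCS[best], max(qual, 0))


def merge_pair(
    r1: ReadRecord, r2: ReadRecord, i: int, qual_cap: int = DEFAULT_QUAL_CAP
) -> ReadRecord:
    """Reconstruct the molecule of length ``i`` from an overlapping pair.

    Read 1 covers molecule positions ``[0, min(l1, i))`` and the
    reverse-complemented read 2 covers ``[max(0, i - l2), i)``; singly
    covered positions copy the covering read, doubly covered ones are
    consensus-called.
    """
    l1, l2 = len(r1), len(r2)
    if not 0 <= i <= l1 + l2:
        raise ValueError(f"inferred length {i} inconsistent with read lengths {l1}+{l2}")
    rc2 = reverse_complement(r2)
    r2_off = i - l2  # molecule position of rc2's first base
    bases = []
    quals = []
    for m in range(i):
        in1 = m < l1
        in2 = m >= r2_off
        if in1 and in2:
            cb = consensus_call(
                r1.bases[m], int(r1.quals[m]),
                rc2.bases[m - r2_off], int(rc2.quals[m - r2_off]),
                qual_cap,
            )
            bases.append(cb.base)
            quals.append(cb.qual)
        elif in1:
            bases.append(r1.bases[m])
            quals.append(int(r1.quals[m]))
        else:
            bases.append(rc2.bases[m - r2_off])
            quals.append(int(rc2.quals[m - r2_off]))
    return ReadRecord(r1.id, "".join(bases), quals)
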