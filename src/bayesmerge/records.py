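"""Core sequence containers.

A :class:`ReadRecord` is one sequenced read: identifier, base string over
``{A,C,G,T,N}`` and a PHRED quality vector of the same length. An
:class:`AdaptorPair` holds the adaptor sequence expected at the 3' end of
read 1 (``a1``) and of read 2 (``a2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Illumina TruSeq-style adaptor defaults (overridable everywhere they are used).
DEFAULT_ADAPTOR1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
DEFAULT_ADAPTOR2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"


@dataclass(frozen=True, eq=False)
class ReadRecord:
    """One sequenced read with PHRED-scaled base qualities."""

    id: str
    bases: str
    quals: np.ndarray

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.bases == other.bases
            and np.array_equal(self.quals, other.quals)
        )

    def __post_init__(self) -> None:
        quals = np.asarray(self.quals, dtype=np.int64)
        object.__setattr__(self, "quals", quals)
        if len(self.bases) != quals.shape[0]:
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {quals.shape[0]} qualities"
            )
        if quals.size and quals.min() < 0:
            raise ValueError(f"read {self.id!r}: negative quality value")
        if not VALID_BASES.issuperset(self.bases):
            bad = sorted(set(self.bases) - VALID_BASES)
            raise ValueError(f"read {self.id!r}: invalid base(s) {bad}")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "ReadRecord":
        return ReadRecord(self.id, self.bases[start:stop], self.quals[start:stop])


@dataclass(frozen=True)
class AdaptorPair:
    """Adaptor sequences read into from the 3' end of each mate."""

    a1: str = DEFAULT_ADAPTOR1
    a2: str = DEFAULT_ADAPTOR2

    def __post_init__(self) -> None:
        for name, seq in (("a1", self.a1), ("a2", self.a2)):
            if not seq:
                raise ValueError(f"adaptor {name} must be non-empty")
            if not frozenset("ACGT").issuperset(seq):
                raise ValueError(f"adaptor {name} contains non-ACGT characters")


def reverse_complement(read: ReadRecord) -> ReadRecord:
    """Reverse-complement the bases (N stays N) and reverse the qualities."""
    return ReadRecord(
        read.id,
        read.bases.translate(_COMPLEMENT)[::-1],
        read.quals[::-1].copy(),
    )


def revcomp_str(seq: str) -> str:
    """Reverse-complement a plain base string."""
    if not VALID_BASES.issuperset(seq):
        raise ValueError("non-nucleotide character in sequence")
    return seq.translate(_COMPLEMENT)[::-1]
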