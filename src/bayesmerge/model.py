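"""Posterior over original molecule lengths for a read pair.

The model: a DNA molecule of unknown length ``i`` was sequenced from both
ends with reads of length ``l1`` and ``l2``. If ``i < l1`` (or ``l2``) the
read runs into the library adaptor; if ``i < l1 + l2`` the two reads overlap
over part of the molecule. For every candidate ``i`` in ``0..l1+l2`` the
likelihood of the observed pair is the product of

* the probability that the read tails match the known adaptor sequences
  (mismatches tolerated through the PHRED error probabilities, indels not
  modelled),
* the probability that the doubly covered molecule positions carry two
  observations of the same base (marginalised over the four nucleotides with
  a uniform base prior), and
* a factor of 1/4 per molecule position seen by exactly one read.

A further hypothesis — the molecule is longer than ``l1 + l2`` and the reads
cannot overlap — gets the prior tail mass times ``(1/4)^(l1+l2)``. The MAP
length is accepted only if the runner-up hypothesis is at least 20-fold less
likely (the ambiguity guard); otherwise the pair is left untouched.

All arithmetic is in log space. Qualities are floored at 2 before being
converted to error probabilities so that an observed match is always
evidence for a match; an ``N`` is scored as 1/4 against anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .prior import LengthPrior
from .records import AdaptorPair, ReadRecord, reverse_complement

QUAL_FLOOR = 2
LOG_QUARTER = math.log(0.25)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def error_prob(q: int) -> float:
    """PHRED error probability ``10^(-q/10)``."""
    if q < 0:
        raise ValueError("quality score must be >= 0")
    return 10.0 ** (-q / 10.0)


def _pe(q: int) -> float:
    """Error probability with the quality floored at ``QUAL_FLOOR``."""
    return error_prob(max(int(q), QUAL_FLOOR))


def match_prob(adaptor_base: str, read_base: str, q: int, beyond_adaptor: bool) -> float:
    """Probability of the read base given the adaptor base as template.

    Past the adaptor's end (``beyond_adaptor``) the template is unknown and
    every base has probability 1/4.
    """
    if beyond_adaptor:
        return 0.25
    if adaptor_base not in _BASE_INDEX or read_base not in _BASE_INDEX:
        raise ValueError("bases must be one of A,C,G,T,N")
    if adaptor_base == "N" or read_base == "N":
        return 0.25
    pe = _pe(q)
    return 1.0 - pe if adaptor_base == read_base else pe / 3.0


def adaptor_loglik(read: ReadRecord, adaptor: str, start: int) -> float:
    """Log probability of the read suffix ``read[start:]`` given the adaptor.

    Adaptor position 0 aligns to read position ``start``; read positions past
    the adaptor's end contribute 1/4 each. ``start == len(read)`` is the empty
    product, 0.0.
    """
    l = len(read)
    if not 0 <= start <= l:
        raise ValueError(f"start {start} out of range for read of length {l}")
    total = 0.0
    la = len(adaptor)
    for k in range(start, l):
        j = k - start
        if j < la:
            total += math.log(match_prob(adaptor[j], read.bases[k], int(read.quals[k]), False))
        else:
            total += LOG_QUARTER
    return total


def _obs_probs(b: str, q: int) -> np.ndarray:
    """P(observed base | true nucleotide n) for n in A,C,G,T. N is uninformative."""
    if b == "N":
        return np.full(4, 0.25)
    pe = _pe(q)
    v = np.full(4, pe / 3.0)
    v[_BASE_INDEX[b]] = 1.0 - pe
    return v


def overlap_base_loglik(b1: str, q1: int, b2: str, q2: int) -> float:
    """Log probability of two observations of the same (unknown) base.

    Marginalises over the four nucleotides with a uniform 1/4 base prior.
    """
    if b1 not in _BASE_INDEX or b2 not in _BASE_INDEX:
        raise ValueError("bases must be one of A,C,G,T,N")
    return math.log(0.25 * float(np.dot(_obs_probs(b1, q1), _obs_probs(b2, q2))))


# ---------------------------------------------------------------------------
# geometry helpers

def _overlap_bounds(i: int, l1: int, l2: int) -> tuple[int, int]:
    """Molecule positions covered by both reads for candidate length ``i``.

    Read 1 covers ``[0, min(l1, i))``; reverse-complemented read 2 covers
    ``[max(0, i - l2), i)``. Returns the (possibly empty) intersection.
    """
    lo = max(0, i - l2)
    hi = min(l1, i)
    return (lo, hi) if hi > lo else (0, 0)


def length_loglik(
    r1: ReadRecord,
    r2: ReadRecord,
    adaptors: AdaptorPair,
    i: int,
    prior: LengthPrior,
) -> float:
    """Unnormalised log posterior of molecule length ``i`` for a read pair.

    Scalar reference path; :func:`posterior_profile` evaluates the same
    quantity for all ``i`` at once.
    """
    l1, l2 = len(r1), len(r2)
    if not 0 <= i <= l1 + l2:
        raise ValueError(f"candidate length {i} out of range 0..{l1 + l2}")
    n_hyp = l1 + l2 + 2
    total = prior.log_prior(i, n_hyp)
    total += adaptor_loglik(r1, adaptors.a1, min(i, l1))
    total += adaptor_loglik(r2, adaptors.a2, min(i, l2))
    rc2 = reverse_complement(r2)
    lo, hi = _overlap_bounds(i, l1, l2)
    for m in range(lo, hi):
        j = m - i + l2  # index into the reverse-complemented read 2
        total += overlap_base_loglik(
            r1.bases[m], int(r1.quals[m]), rc2.bases[j], int(rc2.quals[j])
        )
    singles = i - (hi - lo)
    total += singles * LOG_QUARTER
    return total


def no_merge_loglik(r1: ReadRecord, r2: ReadRecord, prior: LengthPrior) -> float:
    """Log posterior of the molecule being longer than ``l1 + l2``."""
    L = len(r1) + len(r2)
    return prior.log_tail(L, L + 2) + L * LOG_QUARTER


# ---------------------------------------------------------------------------
# posterior profile (vectorised)

class Decision(str, Enum):
    MERGED = "merged"
    AMBIGUOUS = "ambiguous"
    KEPT_AS_PAIR = "kept_as_pair"
    TRIMMED_SINGLE = "trimmed_single"


@dataclass
class LengthPosterior:
    """Log posterior per candidate length plus the no-merge hypothesis.

    ``log_post[i]`` is the unnormalised log posterior of length ``i``;
    ``log_no_merge`` the no-merge (or, single-end, no-trim) hypothesis.
    ``best_i`` indexes the maximum over all hypotheses, with
    ``best_i == len(log_post)`` meaning no-merge wins. ``log_odds`` is the
    log ratio of best to second best.
    """

    log_post: np.ndarray
    log_no_merge: float
    best_i: int
    log_odds: float

    @property
    def no_merge_index(self) -> int:
        return len(self.log_post)

    @property
    def best_is_no_merge(self) -> bool:
        return self.best_i == self.no_merge_index

    def all_hypotheses(self) -> np.ndarray:
        return np.append(self.log_post, self.log_no_merge)

    def normalized(self) -> np.ndarray:
        """Posterior probabilities over all hypotheses, summing to 1."""
        logp = self.all_hypotheses()
        logp = logp - logp.max()
        p = np.exp(logp)
        return p / p.sum()


def _finish_profile(log_all: np.ndarray) -> LengthPosterior:
    order = np.argsort(log_all)
    best = int(order[-1])
    second = int(order[-2])
    # smallest index wins on an exact tie
    ties = np.flatnonzero(log_all == log_all[best])
    if ties.size > 1:
        best = int(ties[0])
        second = int(ties[1])
    return LengthPosterior(
        log_post=log_all[:-1],
        log_no_merge=float(log_all[-1]),
        best_i=best,
        log_odds=float(log_all[best] - log_all[second]),
    )


def _base_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_CODE_TO_IDX = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _CODE_TO_IDX[ord(_b)] = _i


def _obs_matrix(read: ReadRecord) -> np.ndarray:
    """Per-position observation probabilities, shape (len, 4)."""
    idx = _CODE_TO_IDX[_base_codes(read.bases)]
    pe = 10.0 ** (-np.maximum(read.quals, QUAL_FLOOR) / 10.0)
    n = len(read)
    out = np.repeat((pe / 3.0)[:, None], 4, axis=1)
    pos = np.arange(n)
    real = idx < 4
    out[pos[real], idx[real]] = 1.0 - pe[real]
    out[~real] = 0.25
    return out


def _adaptor_logliks(read: ReadRecord, adaptor: str) -> np.ndarray:
    """``adaptor_loglik(read, adaptor, s)`` for every start ``s`` in 0..len(read).

    Built as a (len+1, len) matrix of per-position log match probabilities and
    summed along rows; positions before the start contribute 0, positions past
    the adaptor's end contribute log(1/4).
    """
    l = len(read)
    la = len(adaptor)
    if l == 0:
        return np.zeros(1)
    obs = _obs_matrix(read)  # (l, 4), rows are P(read base | template)
    a_idx = _CODE_TO_IDX[_base_codes(adaptor)]
    K = np.arange(l)[None, :]
    S = np.arange(l + 1)[:, None]
    J = K - S
    within = (J >= 0) & (J < la)
    Jc = np.clip(J, 0, la - 1)
    logm = np.log(obs[K.repeat(l + 1, axis=0), a_idx[Jc]])
    cell = np.where(J < 0, 0.0, np.where(within, logm, LOG_QUARTER))
    return cell.sum(axis=1)


def posterior_profile(
    r1: ReadRecord,
    r2: ReadRecord,
    adaptors: AdaptorPair,
    prior: LengthPrior,
) -> LengthPosterior:
    """Evaluate every length hypothesis plus no-merge for a read pair."""
    l1, l2 = len(r1), len(r2)
    if l1 == 0 or l2 == 0:
        raise ValueError("both reads must be non-empty")
    n_hyp = l1 + l2 + 2
    rc2 = reverse_complement(r2)

    a1 = _adaptor_logliks(r1, adaptors.a1)  # indexed by start 0..l1
    a2 = _adaptor_logliks(r2, adaptors.a2)  # indexed by start 0..l2
    B = np.log(0.25 * (_obs_matrix(r1) @ _obs_matrix(rc2).T))  # (l1, l2)

    i_vals = np.arange(l1 + l2 + 1)
    log_all = np.empty(l1 + l2 + 2)
    for i in i_vals:
        lo, hi = _overlap_bounds(int(i), l1, l2)
        ov = np.trace(B, offset=l2 - int(i)) if hi > lo else 0.0
        log_all[i] = (
            prior.log_prior(int(i), n_hyp)
            + a1[min(i, l1)]
            + a2[min(i, l2)]
            + ov
            + (int(i) - (hi - lo)) * LOG_QUARTER
        )
    log_all[-1] = no_merge_loglik(r1, r2, prior)
    return _finish_profile(log_all)


def single_end_profile(read: ReadRecord, adaptor: str, prior: LengthPrior) -> LengthPosterior:
    """Posterior over trim points for a single read.

    Candidate ``i`` means the molecule occupies ``read[:i]`` (scored 1/4 per
    base) and the adaptor starts at position ``i``. The no-trim hypothesis
    (molecule longer than the read) takes the prior tail mass beyond the read
    length.
    """
    l = len(read)
    if l == 0:
        raise ValueError("read must be non-empty")
    n_hyp = l + 2
    a = _adaptor_logliks(read, adaptor)
    log_all = np.empty(l + 2)
    for i in range(l + 1):
        log_all[i] = prior.log_prior(i, n_hyp) + i * LOG_QUARTER + a[i]
    log_all[-1] = prior.log_tail(l, n_hyp) + l * LOG_QUARTER
    return _finish_profile(log_all)


# ---------------------------------------------------------------------------
# decision

DEFAULT_RATIO = 1.0 / 20.0


@dataclass
class MergeResult:
    """Outcome of the MAP decision for one input record (pair or single)."""

    decision: Decision
    inferred_length: int | None
    sequence: ReadRecord | None
    log_odds: float


def decide(
    profile: LengthPosterior,
    ratio_threshold: float = DEFAULT_RATIO,
    single_end: bool = False,
) -> MergeResult:
    """Apply the ambiguity guard and pick the MAP hypothesis.

    The pair is left untouched (``ambiguous``) when the second-best
    hypothesis is within ``ratio_threshold`` of the best, i.e. the
    likelihood ratio runner-up/best exceeds the threshold. Otherwise the
    winner is either the no-merge hypothesis (``kept_as_pair``) or a
    molecule length (``merged``; ``trimmed_single`` in single-end mode).
    The reconstructed sequence is filled in by the caller.
    """
    if not 0 < ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be in (0, 1]")
    # strict comparison: at threshold 1.0 the guard can never fire, since the
    # runner-up/best ratio never exceeds 1
    if profile.log_odds < -math.log(ratio_threshold):
        return MergeResult(Decision.AMBIGUOUS, None, None, profile.log_odds)
    if profile.best_is_no_merge:
        return MergeResult(Decision.KEPT_AS_PAIR, None, None, profile.log_odds)
    kind = Decision.TRIMMED_SINGLE if single_end else Decision.MERGED
    return MergeResult(kind, profile.best_i, None, profile.log_odds)
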