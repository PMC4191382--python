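"""Read-pair simulator with known ground truth, and reconstruction scoring.

The simulator emulates paired-end sequencing of a library whose molecule
lengths follow a log-normal distribution (or an explicit list of lengths).
Molecules come from a reference FASTA or from a random-sequence generator
with configurable GC fraction; fragments containing N are skipped and
redrawn. Read 1 is the molecule prefix; read 2 the reverse-complement
suffix; when the molecule is shorter than the read length the adaptor is
appended and, past the adaptor, random bases fill the remaining cycles.
Substitution errors are injected independently per base at a configured
rate, with emitted PHRED scores drawn from separate distributions for
correct and erroneous bases. All randomness comes from one seeded
``numpy.random.Generator`` (PCG64), so output is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .io_formats import RecordOutcome
from .model import Decision
from .records import AdaptorPair, ReadRecord, reverse_complement, revcomp_str

_NUCS = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class QualityProfile:
    """Distributions of emitted PHRED scores for correct and erroneous bases.

    Parametric by default (discrete normal, clipped to [qmin, qmax]); an
    empirical profile can be loaded from a TSV with columns
    ``quality  class(correct|error)  weight``.
    """

    correct_mean: float = 37.0
    correct_sd: float = 3.0
    error_mean: float = 22.0
    error_sd: float = 6.0
    qmin: int = 2
    qmax: int = 41
    empirical: dict | None = None  # {"correct": (quals, probs), "error": (...)}

    def sample(self, rng: np.random.Generator, is_error: np.ndarray) -> np.ndarray:
        n = is_error.shape[0]
        if self.empirical is not None:
            out = np.empty(n, dtype=np.int64)
            for key, mask in (("correct", ~is_error), ("error", is_error)):
                quals, probs = self.empirical[key]
                out[mask] = rng.choice(quals, size=int(mask.sum()), p=probs)
            return out
        mean = np.where(is_error, self.error_mean, self.correct_mean)
        sd = np.where(is_error, self.error_sd, self.correct_sd)
        q = np.rint(rng.normal(mean, sd)).astype(np.int64)
        return np.clip(q, self.qmin, self.qmax)

    @classmethod
    def from_tsv(cls, path) -> "QualityProfile":
        table: dict[str, dict[int, float]] = {"correct": {}, "error": {}}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                q, klass, w = line.split("\t")
                table[klass][int(q)] = table[klass].get(int(q), 0.0) + float(w)
        empirical = {}
        for klass, counts in table.items():
            if not counts:
                raise ValueError(f"profile TSV has no rows of class {klass!r}")
            quals = np.array(sorted(counts), dtype=np.int64)
            w = np.array([counts[q] for q in quals], dtype=float)
            empirical[klass] = (quals, w / w.sum())
        return cls(empirical=empirical)


@dataclass
class SimConfig:
    """Study conditions for one simulation run."""

    n_pairs: int = 1000
    read_length: int = 100
    adaptors: AdaptorPair = field(default_factory=AdaptorPair)
    error_rate: float = 0.0
    length_mu: float = 3.8
    length_sigma: float = 0.3
    lengths: Sequence[int] | None = None  # overrides the lognormal if given
    quality: QualityProfile = field(default_factory=QualityProfile)
    seed: int = 0
    reference_fasta: str | None = None
    gc_fraction: float = 0.5
    max_attempts: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must be in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read length must be positive")


@dataclass(frozen=True)
class TruthRecord:
    id: str
    sequence: str
    length: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("truth length does not match sequence")


class _ReferenceSampler:
    """Draw molecules of requested lengths from a FASTA or at random."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.rng = rng
        self.max_attempts = config.max_attempts
        self.gc = config.gc_fraction
        self.contigs: list[str] | None = None
        if config.reference_fasta is not None:
            import pysam

            with pysam.FastxFile(str(config.reference_fasta)) as fh:
                self.contigs = [rec.sequence.upper() for rec in fh]
            if not self.contigs:
                raise ValueError("reference FASTA contains no sequences")

    def _random_molecule(self, length: int) -> str:
        p = np.array([(1 - self.gc) / 2, self.gc / 2, self.gc / 2, (1 - self.gc) / 2])
        return self.rng.choice(_NUCS, size=length, p=p).tobytes().decode()

    def draw(self, length: int) -> str:
        if self.contigs is None:
            return self._random_molecule(length)
        for _ in range(self.max_attempts):
            contig = self.contigs[self.rng.integers(len(self.contigs))]
            if len(contig) < length:
                continue
            start = int(self.rng.integers(len(contig) - length + 1))
            frag = contig[start : start + length]
            if "N" not in frag:  # fragments with unresolved bases are skipped
                return frag
        raise ValueError(
            f"no N-free fragment of length {length} found in {self.max_attempts} attempts"
        )


def _draw_lengths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.lengths is not None:
        pool = np.asarray(config.lengths, dtype=np.int64)
        return rng.choice(pool, size=config.n_pairs)
    x = rng.lognormal(config.length_mu, config.length_sigma, size=config.n_pairs)
    return np.maximum(np.rint(x).astype(np.int64), 1)


def _sequence_read(
    template: str,
    adaptor: str,
    read_len: int,
    error_rate: float,
    profile: QualityProfile,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray]:
    """Emit one read: template, then adaptor, then random bases; add errors."""
    ideal = (template + adaptor)[:read_len]
    if len(ideal) < read_len:
        pad = rng.choice(_NUCS, size=read_len - len(ideal)).tobytes().decode()
        ideal += pad
    bases = np.frombuffer(ideal.encode(), dtype="S1").copy()
    is_err = rng.random(read_len) < error_rate
    for k in np.flatnonzero(is_err):
        alternatives = _NUCS[_NUCS != bases[k]]
        bases[k] = alternatives[rng.integers(3)]
    quals = profile.sample(rng, is_err)
    return bases.tobytes().decode(), quals


def simulate_pairs(config: SimConfig) -> Iterator[tuple[ReadRecord, ReadRecord, TruthRecord]]:
    """Yield (read 1, read 2, truth) triples under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    sampler = _ReferenceSampler(config, rng)
    lengths = _draw_lengths(config, rng)
    for k, length in enumerate(lengths):
        molecule = sampler.draw(int(length))
        name = f"sim_{k}"
        b1, q1 = _sequence_read(
            molecule, config.adaptors.a1, config.read_length,
            config.error_rate, config.quality, rng,
        )
        b2, q2 = _sequence_read(
            revcomp_str(molecule), config.adaptors.a2, config.read_length,
            config.error_rate, config.quality, rng,
        )
        yield (
            ReadRecord(name, b1, q1),
            ReadRecord(name, b2, q2),
            TruthRecord(name, molecule, int(length)),
        )


def simulate_singles(config: SimConfig) -> Iterator[tuple[ReadRecord, TruthRecord]]:
    """Single-end variant: only read 1 is emitted."""
    for r1, _r2, truth in simulate_pairs(config):
        yield r1, truth


def write_truth_tsv(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\ttrue_length\ttrue_sequence\n")
        for t in truths:
            fh.write(f"{t.id}\t{t.length}\t{t.sequence}\n")


def read_truth_tsv(path) -> dict[str, TruthRecord]:
    truths = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("truth table must start with an 'id' header line")
        for line in fh:
            name, length, seq = line.rstrip("\n").split("\t")
            truths[name] = TruthRecord(name, seq, int(length))
    return truths


# ---------------------------------------------------------------------------
# scoring

@dataclass
class ReconstructionScore:
    n: int
    merged: int
    ambiguous: int
    kept_as_pair: int
    perfect_fraction: float
    mismatch_fraction: float  # merged but with >= 1 mismatch to the truth
    correct_length_fraction: float
    false_merges: int  # merged although the true molecule exceeds l1+l2


def score_outcomes(
    truths: dict[str, TruthRecord], outcomes: Sequence[RecordOutcome]
) -> ReconstructionScore:
    """Score merged reconstructions against the simulation ground truth."""
    n = len(outcomes)
    merged = ambiguous = kept = perfect = mismatched = correct_len = false = 0
    for out in outcomes:
        name = out.r1.id
        if name not in truths:
            raise ValueError(f"output read {name!r} missing from the truth table")
        truth = truths[name]
        if out.result.decision is Decision.AMBIGUOUS:
            ambiguous += 1
            continue
        if out.result.decision is Decision.KEPT_AS_PAIR:
            kept += 1
            continue
        merged += 1
        max_i = len(out.r1) + (len(out.r2) if out.r2 is not None else 0)
        if truth.length > max_i:
            false += 1
        if out.result.inferred_length == truth.length:
            correct_len += 1
        if out.result.sequence is not None and out.result.sequence.bases == truth.sequence:
            perfect += 1
        else:
            mismatched += 1
    return ReconstructionScore(
        n=n,
        merged=merged,
        ambiguous=ambiguous,
        kept_as_pair=kept,
        perfect_fraction=perfect / n if n else 0.0,
        mismatch_fraction=mismatched / n if n else 0.0,
        correct_length_fraction=correct_len / n if n else 0.0,
        false_merges=false,
    )


def cross_correction_rates(
    truths: dict[str, TruthRecord], outcomes: Sequence[RecordOutcome]
) -> tuple[float, float]:
    """Per-base mismatch rate to the truth, merged consensus vs trimmed reads.

    Only the doubly covered (overlap) region of merged pairs is compared: the
    first rate scores the consensus bases there, the second scores the same
    positions as they appear in the two adaptor-trimmed but unmerged reads.
    """
    merged_mm = merged_bases = trimmed_mm = trimmed_bases = 0
    for out in outcomes:
        if out.result.decision is not Decision.MERGED or out.r2 is None:
            continue
        truth = truths[out.r1.id]
        i = out.result.inferred_length
        if i != truth.length:
            continue
        l1, l2 = len(out.r1), len(out.r2)
        rc2 = reverse_complement(out.r2)
        lo, hi = max(0, i - l2), min(l1, i)
        for m in range(lo, hi):
            true_b = truth.sequence[m]
            merged_bases += 1
            merged_mm += out.result.sequence.bases[m] != true_b
            trimmed_bases += 2
            trimmed_mm += out.r1.bases[m] != true_b
            trimmed_mm += rc2.bases[m - (i - l2)] != true_b
    return (
        merged_mm / merged_bases if merged_bases else 0.0,
        trimmed_mm / trimmed_bases if trimmed_bases else 0.0,
    )
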