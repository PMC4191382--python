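# Methods

## Model

A sequencing library molecule of unknown length *i* is read from both ends.
Three data regimes exist: (a) *i* < read length — each read contains the
whole molecule followed by adaptor sequence; (b) read length ≤ *i* <
*l₁*+*l₂* — no adaptor is visible but the reads overlap; (c) *i* ≥
*l₁*+*l₂* — the reads are disjoint observations. The method computes one
posterior over all of these at once.

### Geometry

All coordinates are 0-based, half-open. For candidate length *i*, read 1
covers molecule positions [0, min(*l₁*, *i*)) and the reverse complement of
read 2 covers [max(0, *i*−*l₂*), *i*). Their intersection is the overlap;
positions covered by exactly one read contribute a factor 1/4 (a single
observation of an a-priori uniform base), which makes hypotheses with
different data decompositions comparable. *i* = 0 is the adaptor-dimer
hypothesis: both reads are scored entirely against their adaptors. The
adaptor term aligns adaptor position 0 with read position min(*i*, *l*) and
runs to the end of the read; read positions beyond the adaptor's end score
1/4 (the downstream sequence is unspecified).

### Per-base probabilities

A PHRED score *q* encodes error probability p_e = 10^(−q/10). A sequencing
error is assumed equally likely to produce each of the three alternative
bases, so a template match scores 1 − p_e and a mismatch p_e/3. Overlap
positions marginalise the product of the two observation probabilities over
the four nucleotides with a uniform 1/4 base prior. Two regularisations:

* **Quality floor.** Qualities are floored at 2 before use. Without it,
  q = 0 gives p_e = 1 and an observed match becomes evidence *against*
  identity (1 − p_e < p_e/3); the floor guarantees 1 − p_e > p_e/3 always.
  The raw `error_prob` function is exact; the floor applies at the point of
  use.
* **N bases.** An N scores 1/4 against anything, everywhere — an
  uninformative observation that never counts as a match.

### Prior and the no-merge hypothesis

The fragment-length prior is uniform (each of the *l₁*+*l₂*+2 hypotheses —
all lengths plus no-merge — gets mass 1/(*l₁*+*l₂*+2)) or log-normal with
density (1/(iσ√2π))·exp(−(ln i − μ)²/2σ²). The log-normal density is
undefined at *i* = 0; the dimer hypothesis is evaluated at 0.5 as a
continuity correction. The no-merge hypothesis (molecule longer than
*l₁*+*l₂*) receives the survival mass 1 − cdf(*l₁*+*l₂*) times
(1/4)^(l₁+l₂), every base being a single observation. Density and cdf come
from `scipy.stats.lognorm`; the MLE fit is the closed form μ̂ = mean(ln x),
σ̂ = √(mean((ln x − μ̂)²)) with the 1/n variance (exact for the log-normal,
no optimiser needed). A fit with σ̂ = 0 (all lengths identical) is rejected.

### Decision rule

The MAP hypothesis is accepted only when the runner-up (searched over all
remaining hypotheses, no-merge included) is at least 20-fold less likely;
otherwise the record is left untouched (`ambiguous`). The ratio is exposed
as `--ratio` (default 1/20); at 1.0 the guard never fires, since the
runner-up/best ratio cannot exceed 1. Exact ties in the argmax go to the
smallest length; they also always trip the guard. When no-merge wins, pairs
are written through unchanged (`kept_as_pair`).

### Consensus calling

Doubly covered positions are called by Bayes' rule under the uniform base
prior: p(n|b₁,b₂) ∝ p(b₁|n)·p(b₂|n)·(1/4). The emitted quality is the PHRED
scaling of the posterior error Σ_{m≠n} p(b₁,b₂|m) / Σ_m p(b₁,b₂|m), rounded
to the nearest integer and capped at 60 (configurable) — two agreeing
high-quality bases would otherwise overflow common FASTQ encodings. A
conflict between equal-quality bases keeps the read-1 base (deterministic;
the accompanying quality is near 0). If one observation is N the other is
reported with its original quality; two Ns give N at quality 2.

### Numerical notes

All products are computed as sums of logs; no further underflow guards are
needed. The per-pair profile is vectorised: the adaptor term for every
start position is a row sum over a (l+1) × l log-match matrix, and the
overlap term for every *i* is a diagonal trace of the l₁ × l₂ matrix
log(¼ · P₁P₂ᵀ) of marginalised two-observation likelihoods. A scalar
reference path (`length_loglik`) computes the identical quantity base by
base; the test suite holds the two within 1e-9 and both against an
independent direct-probability-product oracle on short reads, where no
log-space is involved at all.

## Single-end mode

Candidate trim point *i* scores *i*·log(1/4) for the molecule bases plus
the adaptor term from *i*; the molecule-longer-than-read hypothesis takes
the prior tail beyond *l₁*. The same guard applies; an accepted trim cuts
the read at *i*.

## Simulator

The simulator generates the conditions the model targets: molecule lengths
drawn from a log-normal (defaults μ = 3.8, σ = 0.3 — median ≈ 45 bp, an
ancient-DNA-like library) or from an explicit length list; molecules taken
from a reference FASTA (fragments containing N are redrawn, with an attempt
cap) or from a random generator with configurable GC fraction, so no genome
is required. Read 1 is the molecule prefix, read 2 the reverse-complement
suffix; when the molecule is shorter than the read the adaptor is appended
and random bases fill any remaining cycles. Substitution errors are
injected independently per base at the configured rate, uniform over the
three alternatives. Emitted qualities are drawn from separate discrete
distributions for correct and erroneous bases — defaults: normal(37, 3) and
normal(22, 6), rounded and clipped to [2, 41], emulating the shape of an
Illumina profile parametrically; an empirical profile can be loaded from a
TSV (quality, class, weight). All randomness flows from a single seeded
`numpy.random.Generator` (PCG64), so output is reproducible byte for byte.

What the simulator does **not** emulate: indels, position-dependent error
rates, miscalibrated quality strings, deamination damage (C→T/G→A at
fragment ends), real genomic repeats, or chimeric molecules. Passing tests
therefore demonstrate correctness of the inference given its model
assumptions, not performance on every real instrument artefact; in
particular, false-merge counts on random sequence understate what genomic
repeats can produce.

## Problem sizes and test design

Statistical checks use 1000 simulated pairs per condition (100 bp reads,
molecules 20–80 bp for short-molecule conditions; log-normal μ = 6.0,
σ = 0.25 for long-molecule false-merge contrasts), sizes at which the
binomial noise on the reported fractions is a few tenths of a percent.
Exactness checks (posterior vs direct products) use reads ≤ 15 bp, where
naive probability products stay far from underflow. `scripts/acceptance.py`
re-derives every reported number from a fresh simulation at run time,
seeded from its `--seed` argument.

## Design choices where the design was open

* Uniform-prior mass is per-hypothesis, 1/(*l₁*+*l₂*+2), so the no-merge
  hypothesis is on an equal footing with each length.
* The no-merge hypothesis competes inside the second-best search of the
  ambiguity guard (not after it).
* FASTQ qualities are PHRED+33 by default (`--phred-offset` to override);
  written quality characters are clamped to the encodable range.
* The BAM decision tag is `dm:A:{M,A,K,T}`; unmerged mates keep paired +
  unmapped + mate-unmapped flags.
* Adaptor defaults are TruSeq-style strings; they are configuration, not
  inference — adaptor discovery is out of scope.

## Limitations

Indel-tolerant alignment, adapter inference, quality recalibration,
damage-aware substitution priors, CRAM, demultiplexing and multithreading
are deliberately out of scope. Merging quality gains assume well-calibrated
input qualities; with miscalibrated scores the consensus qualities inherit
the miscalibration.
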