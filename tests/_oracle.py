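"""Independent brute-force reference for the merging model.

Everything here is computed as direct probability products in plain Python
floats (no log space, no vectorisation) from the model definition: adaptor
match terms, overlap terms marginalised over the four nucleotides, per-read
1/4 factors for singly covered positions, and the no-merge tail. Kept
deliberately separate from the package internals so the two paths can
disagree.
"""

import math

NUCS = "ACGT"


def pe(q: int) -> float:
    return 10.0 ** (-max(q, 2) / 10.0)


def p_obs(b: str, q: int, n: str) -> float:
    """P(observed base b | true nucleotide n); N is uninformative (1/4)."""
    if b == "N":
        return 0.25
    return 1.0 - pe(q) if b == n else pe(q) / 3.0


def match(adaptor_base: str, read_base: str, q: int) -> float:
    if adaptor_base == "N" or read_base == "N":
        return 0.25
    return 1.0 - pe(q) if adaptor_base == read_base else pe(q) / 3.0


def adaptor_term(bases: str, quals, adaptor: str, start: int) -> float:
    p = 1.0
    for k in range(start, len(bases)):
        j = k - start
        p *= match(adaptor[j], bases[k], quals[k]) if j < len(adaptor) else 0.25
    return p


def overlap_term(b1: str, q1: int, b2: str, q2: int) -> float:
    return sum(0.25 * p_obs(b1, q1, n) * p_obs(b2, q2, n) for n in NUCS)


def revcomp(bases: str, quals):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(bases)), list(reversed(list(quals)))


def pair_likelihood(r1, q1, r2, q2, a1, a2, i: int, prior_mass: float) -> float:
    """P(data | molecule length i) * prior, as a plain probability product.

    Read 1 covers molecule positions [0, min(l1, i)); the reverse complement
    of read 2 covers [max(0, i - l2), i); singly covered positions give 1/4.
    """
    l1, l2 = len(r1), len(r2)
    rc2, rcq2 = revcomp(r2, q2)
    p = prior_mass
    p *= adaptor_term(r1, q1, a1, min(i, l1))
    p *= adaptor_term(r2, q2, a2, min(i, l2))
    lo, hi = max(0, i - l2), min(l1, i)
    doubly = 0
    for m in range(max(lo, 0), max(hi, 0)):
        j = m - i + l2
        p *= overlap_term(r1[m], q1[m], rc2[j], rcq2[j])
        doubly += 1
    p *= 0.25 ** (i - doubly)
    return p


def no_merge_likelihood(l1: int, l2: int, tail_mass: float) -> float:
    return tail_mass * 0.25 ** (l1 + l2)


# -- consensus ---------------------------------------------------------------

def consensus_posterior(b1: str, q1: int, b2: str, q2: int):
    """p(n | b1, b2) over the four nucleotides, uniform 1/4 base prior."""
    joint = {n: p_obs(b1, q1, n) * p_obs(b2, q2, n) * 0.25 for n in NUCS}
    total = sum(joint.values())
    return {n: v / total for n, v in joint.items()}


def consensus_error(b1: str, q1: int, b2: str, q2: int, n: str) -> float:
    """p(-n | b1, b2): probability the called base n is wrong."""
    joint = {m: p_obs(b1, q1, m) * p_obs(b2, q2, m) for m in NUCS}
    return sum(v for m, v in joint.items() if m != n) / sum(joint.values())


def phred(p: float) -> float:
    return -10.0 * math.log10(p)
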