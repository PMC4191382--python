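"""Unit and property tests for the length-posterior model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracle as oracle
from bayesmerge.model import (
    Decision,
    LengthPosterior,
    adaptor_loglik,
    decide,
    error_prob,
    length_loglik,
    match_prob,
    no_merge_loglik,
    overlap_base_loglik,
    posterior_profile,
    single_end_profile,
)
from bayesmerge.prior import LengthPrior
from bayesmerge.records import AdaptorPair, ReadRecord, reverse_complement
from conftest import make_noiseless_pair, random_read

UNIFORM = LengthPrior("uniform")


# ---------------------------------------------------------------------------
# per-base probabilities

@pytest.mark.parametrize("q,expected", [(0, 1.0), (10, 0.1), (20, 0.01), (30, 0.001)])
def test_error_prob_is_phred_scale(q, expected):
    assert error_prob(q) == pytest.approx(expected)


def test_error_prob_rejects_negative_quality():
    with pytest.raises(ValueError):
        error_prob(-1)


@pytest.mark.parametrize(
    "a,b,q,beyond,expected",
    [
        ("A", "A", 20, False, 0.99),
        ("A", "C", 20, False, 0.01 / 3),
        ("G", "T", 30, False, 0.001 / 3),
        ("A", "C", 20, True, 0.25),  # past the adaptor's end: unknown template
        ("T", "T", 40, True, 0.25),
        ("N", "A", 20, False, 0.25),  # N is uninformative, never a match
        ("A", "N", 20, False, 0.25),
    ],
)
def test_match_prob_cases(a, b, q, beyond, expected):
    assert match_prob(a, b, q, beyond) == pytest.approx(expected)


def test_match_prob_quality_floor_keeps_match_informative():
    # q=0 would give p_e=1 and make a "match" evidence against itself;
    # the floor at q=2 keeps 1-p_e > p_e/3
    assert match_prob("A", "A", 0, False) > match_prob("A", "C", 0, False)


# ---------------------------------------------------------------------------
# adaptor term

def test_adaptor_loglik_empty_suffix_is_zero(rng):
    read = random_read(rng, 10)
    assert adaptor_loglik(read, "ACGT", 10) == 0.0


def test_adaptor_loglik_exact_suffix_match():
    read = ReadRecord("r", "TTTTTACGTC", np.full(10, 20))
    assert adaptor_loglik(read, "ACGTC", 5) == pytest.approx(5 * math.log(0.99))


def test_adaptor_loglik_mismatch_and_beyond():
    read = ReadRecord("r", "ACGT", np.full(4, 20))
    expected = math.log(0.99) + math.log(0.01 / 3) + 2 * math.log(0.25)
    assert adaptor_loglik(read, "AG", 0) == pytest.approx(expected)


def test_adaptor_loglik_start_out_of_range(rng):
    read = random_read(rng, 8)
    with pytest.raises(ValueError):
        adaptor_loglik(read, "ACGT", 9)


# ---------------------------------------------------------------------------
# overlap term

def test_overlap_base_agreeing():
    expected = math.log(0.25 * (0.99**2 + 3 * (0.01 / 3) ** 2))
    assert overlap_base_loglik("A", 20, "A", 20) == pytest.approx(expected)


def test_overlap_base_conflicting():
    expected = math.log(0.25 * (2 * 0.99 * (0.01 / 3) + 2 * (0.01 / 3) ** 2))
    assert overlap_base_loglik("A", 20, "C", 20) == pytest.approx(expected)


@given(
    b1=st.sampled_from("ACGTN"),
    b2=st.sampled_from("ACGTN"),
    q1=st.integers(0, 41),
    q2=st.integers(0, 41),
)
@settings(derandomize=True, max_examples=60)
def test_overlap_base_symmetric(b1, b2, q1, q2):
    assert overlap_base_loglik(b1, q1, b2, q2) == pytest.approx(
        overlap_base_loglik(b2, q2, b1, q1)
    )


# ---------------------------------------------------------------------------
# profile vs brute-force oracle

def _oracle_profile(r1, r2, adaptors, prior):
    l1, l2 = len(r1), len(r2)
    n_hyp = l1 + l2 + 2
    if prior.kind == "uniform":
        masses = [1.0 / n_hyp] * (l1 + l2 + 1)
        tail = 1.0 / n_hyp
    else:
        masses = [
            math.exp(prior.log_prior(i, n_hyp)) for i in range(l1 + l2 + 1)
        ]
        from scipy import stats

        tail = float(stats.lognorm.sf(l1 + l2, s=prior.sigma, scale=math.exp(prior.mu)))
    vals = [
        oracle.pair_likelihood(
            r1.bases, list(r1.quals), r2.bases, list(r2.quals),
            adaptors.a1, adaptors.a2, i, masses[i],
        )
        for i in range(l1 + l2 + 1)
    ]
    vals.append(oracle.no_merge_likelihood(l1, l2, tail))
    return np.array(vals)


@pytest.mark.parametrize("prior", [UNIFORM, LengthPrior("lognormal", 2.5, 0.5)])
def test_posterior_profile_matches_direct_products(rng, adaptors, prior):
    """Vectorised log-space profile == naive probability products, reads <= 15 bp."""
    for _ in range(25):
        r1 = random_read(rng, int(rng.integers(3, 16)), alphabet="ACGTN", qmin=0)
        r2 = random_read(rng, int(rng.integers(3, 16)), alphabet="ACGTN", qmin=0)
        prof = posterior_profile(r1, r2, adaptors, prior)
        expected = _oracle_profile(r1, r2, adaptors, prior)
        got = np.exp(prof.all_hypotheses())
        np.testing.assert_allclose(got, expected, rtol=1e-9)


def test_scalar_length_loglik_agrees_with_profile(rng, adaptors):
    r1 = random_read(rng, 12, alphabet="ACGTN", qmin=0)
    r2 = random_read(rng, 9, alphabet="ACGTN", qmin=0)
    prof = posterior_profile(r1, r2, adaptors, UNIFORM)
    for i in range(len(r1) + len(r2) + 1):
        assert length_loglik(r1, r2, adaptors, i, UNIFORM) == pytest.approx(
            prof.log_post[i], abs=1e-9
        )
    assert no_merge_loglik(r1, r2, UNIFORM) == pytest.approx(prof.log_no_merge)


# ---------------------------------------------------------------------------
# geometry boundary cases

def test_abutting_hypothesis_is_pure_quarter_terms(rng, adaptors):
    r1, r2 = random_read(rng, 7), random_read(rng, 5)
    L = 12
    expected = UNIFORM.log_prior(L, L + 2) + L * math.log(0.25)
    assert length_loglik(r1, r2, adaptors, L, UNIFORM) == pytest.approx(expected)


def test_adaptor_dimer_hypothesis(rng):
    # reads exactly equal to adaptor prefixes: i=0 scores near-pure matches
    adaptors = AdaptorPair("ACGTACGTACGT", "TGCATGCATGCA")
    r1 = ReadRecord("d", adaptors.a1[:8], np.full(8, 40))
    r2 = ReadRecord("d", adaptors.a2[:8], np.full(8, 40))
    ll = length_loglik(r1, r2, adaptors, 0, UNIFORM)
    expected = UNIFORM.log_prior(0, 18) + 16 * math.log(1 - 1e-4)
    assert ll == pytest.approx(expected)
    prof = posterior_profile(r1, r2, adaptors, UNIFORM)
    assert prof.best_i == 0


def test_candidate_length_out_of_range(rng, adaptors):
    r1, r2 = random_read(rng, 5), random_read(rng, 5)
    with pytest.raises(ValueError):
        length_loglik(r1, r2, adaptors, 11, UNIFORM)


# ---------------------------------------------------------------------------
# profile-level properties

def test_noiseless_pair_map_recovers_length(rng, adaptors):
    r1, r2, molecule = make_noiseless_pair(rng, 30, 50, adaptors)
    prof = posterior_profile(r1, r2, adaptors, UNIFORM)
    assert prof.best_i == 30
    assert prof.log_odds > math.log(20)


def test_normalized_posterior_sums_to_one(rng, adaptors):
    r1 = random_read(rng, 20)
    r2 = random_read(rng, 18)
    prof = posterior_profile(r1, r2, adaptors, UNIFORM)
    assert len(prof.log_post) == 20 + 18 + 1
    assert prof.normalized().sum() == pytest.approx(1.0, abs=1e-9)
    assert prof.log_odds >= 0


def test_profile_symmetric_under_mate_swap(rng, adaptors):
    """Swapping (r1, a1) with (r2, a2) describes the same molecule read from
    the other strand and must give an identical profile."""
    r1, r2, _ = make_noiseless_pair(rng, 35, 60, adaptors)
    swapped = AdaptorPair(adaptors.a2, adaptors.a1)
    p = posterior_profile(r1, r2, adaptors, UNIFORM)
    q = posterior_profile(r2, r1, swapped, UNIFORM)
    np.testing.assert_allclose(p.all_hypotheses(), q.all_hypotheses(), rtol=1e-12)
    assert p.best_i == q.best_i


# ---------------------------------------------------------------------------
# decision logic

def _profile(values, no_merge):
    arr = np.array(values, dtype=float)
    allv = np.append(arr, no_merge)
    order = np.argsort(allv)
    best, second = int(order[-1]), int(order[-2])
    return LengthPosterior(arr, float(no_merge), best, float(allv[best] - allv[second]))


def test_decide_clear_winner_merges():
    prof = _profile([-10.0, -1.0, -10.0], -12.0)
    res = decide(prof)
    assert res.decision is Decision.MERGED and res.inferred_length == 1


def test_decide_tie_is_ambiguous():
    prof = _profile([-1.0, -1.0, -9.0], -12.0)
    assert decide(prof).decision is Decision.AMBIGUOUS


def test_decide_no_merge_winner_keeps_pair():
    prof = _profile([-10.0, -9.0], -1.0)
    prof.best_i = 2
    assert decide(prof).decision is Decision.KEPT_AS_PAIR


def test_decide_threshold_edge():
    # runner-up exactly 20x weaker: ratio == threshold, guard must not fire
    prof = _profile([-math.log(20), 0.0], -50.0)
    assert decide(prof, 1 / 20).decision is Decision.MERGED
    # just inside the guard
    prof2 = _profile([-math.log(19), 0.0], -50.0)
    assert decide(prof2, 1 / 20).decision is Decision.AMBIGUOUS


def test_decide_rejects_bad_threshold():
    prof = _profile([-1.0, -5.0], -9.0)
    with pytest.raises(ValueError):
        decide(prof, 1.5)


# ---------------------------------------------------------------------------
# single-end

def test_single_end_map_trim_point(rng):
    adaptor = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACTTTTTTTTTTTTTTTTTTTT"
    molecule = "".join(rng.choice(list("ACGT"), size=60))
    ideal = (molecule + adaptor)[:100]
    read = ReadRecord("s", ideal, np.full(100, 40))
    prof = single_end_profile(read, adaptor, UNIFORM)
    res = decide(prof, single_end=True)
    assert res.decision is Decision.TRIMMED_SINGLE
    assert res.inferred_length == 60


def test_single_end_no_adaptor_content(rng):
    read = random_read(rng, 80, qmin=35)
    prof = single_end_profile(read, "AGATCGGAAGAGCACACGTC", UNIFORM)
    res = decide(prof, single_end=True)
    # nothing supports an internal trim point strongly
    assert res.decision in (Decision.AMBIGUOUS, Decision.KEPT_AS_PAIR) or (
        res.inferred_length >= 80 - 3
    )


def test_single_end_full_length_entry_matches_general_formula(rng):
    read = random_read(rng, 15)
    adaptor = "ACGTACGT"
    prof = single_end_profile(read, adaptor, UNIFORM)
    l = len(read)
    expected = UNIFORM.log_prior(l, l + 2) + l * math.log(0.25)
    assert prof.log_post[l] == pytest.approx(expected)
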