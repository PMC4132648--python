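from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebm.exceptions import DataValidationError
from ebm.sequence_inference import (
    EventSequence,
    exhaustive_ml_sequence,
    log_likelihood_sequence,
    mcmc_sample,
    most_likely_sequence,
    positional_variance_from_samples,
)

from conftest import make_tables


def brute_force_loglik(lt, order):
    """Literal nested-loop evaluation of the sequence likelihood in linear space."""
    le, ln = lt.like_event, lt.like_noevent
    j, n = le.shape
    total = 0.0
    for subj in range(j):
        s = 0.0
        for k in range(n + 1):
            prod = 1.0
            for pos, ev in enumerate(order):
                prod *= le[subj, ev] if pos < k else ln[subj, ev]
            s += prod / (n + 1)
        total += np.log(s)
    return total


def test_single_event_single_subject_closed_form():
    lt = make_tables(np.random.default_rng(0), 1, 1)
    a = lt.like_event[0, 0]
    b = lt.like_noevent[0, 0]
    assert log_likelihood_sequence(lt, EventSequence((0,))) == pytest.approx(
        np.log((a + b) / 2), abs=1e-12
    )


def test_equal_tables_permutation_symmetry():
    rng = np.random.default_rng(1)
    lt = make_tables(rng, 8, 4)
    lt.like_noevent[:] = lt.like_event
    lt.log_like_noevent[:] = lt.log_like_event
    lls = {
        log_likelihood_sequence(lt, EventSequence(p)) for p in permutations(range(4))
    }
    assert max(lls) - min(lls) < 1e-9


@pytest.mark.parametrize("seed", range(5))
def test_log_domain_matches_linear_nested_loop(seed):
    rng = np.random.default_rng(seed)
    lt = make_tables(rng, 5, 3)
    for p in permutations(range(3)):
        ours = log_likelihood_sequence(lt, EventSequence(p))
        oracle = brute_force_loglik(lt, p)
        assert ours == pytest.approx(oracle, rel=1e-10)


def test_greedy_matches_exhaustive_argmax():
    """Greedy + restarts finds the global optimum on small problems."""
    for seed in range(25):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(3, 6))
        lt = make_tables(rng, 30, n)
        greedy = most_likely_sequence(lt, n_starts=8, seed=seed)
        exact, exact_ll = exhaustive_ml_sequence(lt)
        assert log_likelihood_sequence(lt, greedy) == pytest.approx(exact_ll, abs=1e-9)


def test_two_events_strong_preference():
    # Subjects in which event 1 (index 1) is abnormal but event 0 is not:
    # the ordering must put event 1 first.
    le = np.tile([0.01, 2.0], (20, 1))
    ln = np.tile([2.0, 0.01], (20, 1))
    lt = make_tables(np.random.default_rng(0), 20, 2)
    lt.like_event, lt.like_noevent = le, ln
    lt.log_like_event, lt.log_like_noevent = np.log(le), np.log(ln)
    best = most_likely_sequence(lt, n_starts=2, seed=0)
    assert best.order == (1, 0)


def test_degenerate_tables_warn():
    lt = make_tables(np.random.default_rng(2), 5, 3)
    lt.like_noevent[:] = lt.like_event
    lt.log_like_noevent[:] = lt.log_like_event
    with pytest.warns(UserWarning, match="degenerate"):
        most_likely_sequence(lt, n_starts=2, seed=0)


def test_invalid_permutation_rejected():
    lt = make_tables(np.random.default_rng(3), 4, 3)
    with pytest.raises(DataValidationError):
        log_likelihood_sequence(lt, np.array([0, 0, 2]))
    with pytest.raises(DataValidationError):
        EventSequence((0, 2))


def test_subject_order_invariance():
    rng = np.random.default_rng(4)
    lt = make_tables(rng, 12, 4)
    perm = rng.permutation(12)
    shuffled = make_tables(rng, 12, 4)
    shuffled.like_event = lt.like_event[perm]
    shuffled.like_noevent = lt.like_noevent[perm]
    shuffled.log_like_event = lt.log_like_event[perm]
    shuffled.log_like_noevent = lt.log_like_noevent[perm]
    seq = EventSequence((2, 0, 3, 1))
    assert log_likelihood_sequence(lt, seq) == pytest.approx(
        log_likelihood_sequence(shuffled, seq), rel=1e-12
    )


class TestMCMC:
    def test_positional_variance_doubly_stochastic(self):
        rng = np.random.default_rng(6)
        lt = make_tables(rng, 10, 5)
        init = most_likely_sequence(lt, n_starts=3, seed=1)
        post = mcmc_sample(lt, init, n_samples=2000, burn_in=200, seed=2)
        np.testing.assert_allclose(post.positional_variance.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(post.positional_variance.sum(axis=1), 1.0, atol=1e-9)
        assert post.ml_log_likelihood >= post.log_likelihoods.max()

    def test_uniform_limit_on_flat_likelihood(self):
        lt = make_tables(np.random.default_rng(7), 6, 4)
        lt.like_noevent[:] = lt.like_event
        lt.log_like_noevent[:] = lt.log_like_event
        post = mcmc_sample(lt, EventSequence((0, 1, 2, 3)), n_samples=50_000, seed=3)
        assert post.acceptance_rate == pytest.approx(1.0)
        assert np.max(np.abs(post.positional_variance - 0.25)) < 0.05

    def test_frequencies_match_normalized_likelihoods(self):
        """Empirical permutation frequencies on a 3-event problem agree with the
        normalized sequence likelihoods within 3 batch-means Monte-Carlo SEs."""
        rng = np.random.default_rng(8)
        lt = make_tables(rng, 6, 3)
        perms = list(permutations(range(3)))
        lls = np.array([log_likelihood_sequence(lt, EventSequence(p)) for p in perms])
        target = np.exp(lls - lls.max())
        target /= target.sum()
        post = mcmc_sample(lt, EventSequence(perms[0]), n_samples=60_000, burn_in=2_000, seed=9)
        keys = [tuple(s) for s in post.samples]
        for p, prob in zip(perms, target):
            ind = np.array([k == p for k in keys], dtype=float)
            emp = ind.mean()
            batches = ind.reshape(50, -1).mean(axis=1)
            se = batches.std(ddof=1) / np.sqrt(len(batches))
            assert abs(emp - prob) <= 3 * max(se, 1e-4), (p, emp, prob, se)

    def test_reproducible_given_seed(self):
        lt = make_tables(np.random.default_rng(10), 8, 4)
        init = EventSequence((0, 1, 2, 3))
        a = mcmc_sample(lt, init, n_samples=500, burn_in=50, seed=5)
        b = mcmc_sample(lt, init, n_samples=500, burn_in=50, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    n=st.integers(min_value=1, max_value=5),
    j=st.integers(min_value=1, max_value=8),
)
def test_likelihood_matches_oracle_for_any_shape(seed, n, j):
    """Property: the log-domain sequence likelihood equals the literal
    linear-space evaluation for arbitrary table shapes and permutations."""
    rng = np.random.default_rng(seed)
    lt = make_tables(rng, j, n)
    order = tuple(rng.permutation(n))
    assert log_likelihood_sequence(lt, EventSequence(order)) == pytest.approx(
        brute_force_loglik(lt, order), rel=1e-10
    )


def test_positional_variance_counting():
    samples = np.array([[0, 1, 2], [0, 1, 2], [1, 0, 2], [2, 1, 0]])
    pv = positional_variance_from_samples(samples, 3)
    assert pv[0, 0] == pytest.approx(0.5)
    assert pv[2, 2] == pytest.approx(0.75)
    np.testing.assert_allclose(pv.sum(axis=0), 1.0)
    np.testing.assert_allclose(pv.sum(axis=1), 1.0)
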