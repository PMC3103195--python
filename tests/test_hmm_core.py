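import numpy as np
import pytest
from hypothesis import given, strategies as st

from pedphase import hmm_core as hc
from pedphase.hmm_core import (ContextEngine, InconsistentDataError,
                               apply_factored_transition, brute_force_likelihood,
                               build_state_space, emission_oracle,
                               emission_probability, forward_backward, haldane,
                               interval_kernels, marginalize_shifts,
                               state_count, transition_matrix)
from .conftest import random_context


# ---------------------------------------------------------------------------
# map function and state space
# ---------------------------------------------------------------------------

def test_haldane_known_values():
    assert haldane(0.0) == 0.0
    assert haldane(50.0) == pytest.approx(0.5)
    assert haldane(0.01) == pytest.approx(0.00990066, abs=1e-8)
    # small-distance series: r ~ d - d^2
    assert haldane(0.01) == pytest.approx(0.01 - 0.01 ** 2, rel=1e-2)


@given(st.floats(0, 10), st.floats(0, 10))
def test_haldane_monotone_and_bounded(d1, d2):
    r1, r2 = haldane(d1), haldane(d2)
    assert 0 <= r1 <= 0.5 and 0 <= r2 <= 0.5
    if d1 < d2:
        assert r1 <= r2


def test_haldane_rejects_negative():
    with pytest.raises(ValueError):
        haldane(-0.1)


def test_state_counts():
    assert build_state_space(2).n_states == 4
    assert build_state_space(3).n_states == 64
    assert state_count(4) == 16384
    with pytest.raises(ValueError):
        build_state_space(4)  # enumeration intractable, count-only


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_meioses", [2, 6])
def test_factorized_equals_dense_transition(n_meioses):
    rng = np.random.default_rng(0)
    kernels = interval_kernels(rng.random(5) * 0.2, [True] * n_meioses,
                               n_meioses)
    for j in range(5):
        dense = transition_matrix(kernels[j])
        assert np.allclose(dense.sum(axis=1), 1.0)
        x = rng.random((3, 2 ** n_meioses))
        np.testing.assert_allclose(
            apply_factored_transition(x, kernels[j]), x @ dense, atol=1e-12)


def test_untracked_meiosis_is_memoryless():
    k = interval_kernels([0.02], [True, False], 2)
    assert k[0, 1, 0, 0] == 0.5  # untracked bit flips half the time
    assert k[0, 0, 0, 1] == pytest.approx(haldane(0.02))


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def test_all_homozygous_emission_is_one():
    geno = np.tile(np.array([1, 1], np.uint8), (7, 2, 1))
    eng = ContextEngine(geno, np.ones(7, bool), [0.01], depth=3)
    E, _ = eng.emissions(np.full((7, 2), 0.5))
    np.testing.assert_allclose(E, 1.0)


def test_skewness_zero_forbids_ba_order():
    # focus het {1,2}; parents homozygous opposite, so state+shift imply the
    # ordered realisation directly; with skewness 0 and eps 0, the shift
    # putting the dam allele on strand 0 (BA order: strand0 = allele 2)
    # has zero emission weight
    geno = np.zeros((7, 1, 2), np.uint8)
    geno[0] = [(1, 2)]
    geno[1] = [(1, 1)]
    geno[2] = [(2, 2)]
    present = np.array([1, 1, 1, 0, 0, 0, 0], bool)
    skew = np.zeros((7, 1))
    p_ab = emission_probability(geno, skew, state=0, shift=0, marker=0,
                                present=present, eps=0.0)
    p_ba = emission_probability(geno, skew, state=0, shift=1, marker=0,
                                present=present, eps=0.0)
    assert p_ab == 1.0 and p_ba == 0.0


@pytest.mark.parametrize("depth", [2, 3])
@pytest.mark.parametrize("seed", range(4))
def test_emission_matches_enumeration_oracle(depth, seed):
    rng = np.random.default_rng(seed)
    geno, present, skew = random_context(rng, depth=depth, n_markers=3)
    eng = ContextEngine(geno, present, rng.random(2) * 0.05, depth=depth,
                        eps=1e-6)
    E, _ = eng.emissions(skew)
    for shift in range(eng.n_shifts):
        for state in range(eng.n_states):
            for j in range(3):
                want = emission_oracle(geno, skew, state, shift, j, present,
                                       depth, 1e-6)
                assert E[shift, j, state] == pytest.approx(want, rel=1e-12,
                                                           abs=1e-300)


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------

def test_single_marker_uniform_posterior():
    geno = np.zeros((7, 1, 2), np.uint8)  # everyone missing: emission 1
    present = np.array([1, 1, 1, 0, 0, 0, 0], bool)
    eng = ContextEngine(geno, present, [], depth=2)
    post = forward_backward(eng, np.full((7, 1), 0.5), shift=0)
    np.testing.assert_allclose(post.state_posterior[0], 0.25)
    assert post.log_likelihood_per_shift[0] == pytest.approx(0.0)


@pytest.mark.parametrize("depth", [2, 3])
def test_forward_matches_brute_force(depth):
    rng = np.random.default_rng(11)
    geno, present, skew = random_context(rng, depth=depth, n_markers=3)
    eng = ContextEngine(geno, present, rng.random(2) * 0.1, depth=depth)
    E, _ = eng.emissions(skew)
    prior = np.full(eng.n_states, 1.0 / eng.n_states)
    Ts = [transition_matrix(eng.kernels[j]) for j in range(2)]
    for shift in range(eng.n_shifts):
        want = np.log(brute_force_likelihood(prior, Ts, E[shift]))
        got = forward_backward(eng, skew, shift).log_likelihood_per_shift[shift]
        assert got == pytest.approx(want, rel=1e-9)


def test_posterior_normalized_at_every_locus():
    rng = np.random.default_rng(3)
    geno, present, skew = random_context(rng, depth=3, n_markers=8)
    eng = ContextEngine(geno, present, rng.random(7) * 0.05)
    post = marginalize_shifts(eng, skew)
    np.testing.assert_allclose(post.state_posterior.sum(axis=1), 1.0,
                               atol=1e-9)
    q = post.order_posterior
    assert np.all((q[np.isfinite(q)] >= 0) & (q[np.isfinite(q)] <= 1))


def test_depth3_evaluates_exactly_eight_shifts():
    rng = np.random.default_rng(5)
    geno, present, skew = random_context(rng, depth=3, n_markers=4)
    present[:] = True
    eng = ContextEngine(geno, present, rng.random(3) * 0.05)
    post = marginalize_shifts(eng, skew, beam_threshold=None)
    assert post.n_shifts_evaluated == 8


def test_uninformative_data_gives_symmetric_shifts_and_prior_q():
    geno = np.zeros((7, 3, 2), np.uint8)  # everything missing
    present = np.ones(7, bool)
    eng = ContextEngine(geno, present, [0.01, 0.01])
    skew = np.full((7, 3), 0.5)
    post = marginalize_shifts(eng, skew)
    lls = post.log_likelihood_per_shift
    np.testing.assert_allclose(lls, lls[0], atol=1e-12)
    assert np.all(np.isnan(post.order_posterior))  # no heterozygous site


def test_beam_on_off_agree_on_informative_fixture(small_trained):
    from pedphase.trainer import _prepare_contexts, TrainerConfig
    from pedphase.pedio import build_analysis_contexts
    from pedphase.hmm_core import N_MEMBERS

    ped, geno, truth, mmap, res = small_trained
    cols = mmap.chrom_indices("1")
    ctx = build_analysis_contexts(ped)[0]
    cd = _prepare_contexts([ctx], geno, cols,
                           mmap.interval_distances("1"), TrainerConfig())[0]
    skew7 = np.full((N_MEMBERS, len(cols)), 0.5)
    for k in range(N_MEMBERS):
        if cd.rows[k] >= 0:
            skew7[k] = res.skewness.p[cd.rows[k], cols]
    exact = cd.engine.posterior(skew7, beam_threshold=None)
    beamed = cd.engine.posterior(skew7, beam_threshold=1e-8)
    m = np.isfinite(exact.order_posterior)
    np.testing.assert_allclose(beamed.order_posterior[m],
                               exact.order_posterior[m], atol=1e-9)
    assert beamed.log_likelihood == pytest.approx(exact.log_likelihood,
                                                  abs=1e-9)


def test_global_skewness_flip_leaves_likelihood_unchanged():
    rng = np.random.default_rng(17)
    for depth in (2, 3):
        geno, present, skew = random_context(rng, depth=depth, n_markers=6)
        eng = ContextEngine(geno, present, rng.random(5) * 0.05, depth=depth)
        l1 = marginalize_shifts(eng, skew).log_likelihood
        l2 = marginalize_shifts(eng, 1.0 - skew).log_likelihood
        assert l2 == pytest.approx(l1, abs=1e-9)


def test_inversion_delta_equals_recompute():
    rng = np.random.default_rng(23)
    for depth in (2, 3):
        geno, present, skew = random_context(rng, depth=depth, n_markers=5,
                                             missing_prob=0.1)
        eng = ContextEngine(geno, present, rng.random(4) * 0.05, depth=depth)
        post = eng.posterior(skew, want_inversion=True)
        n_memb = 3 if depth == 2 else 7
        for k in range(n_memb):
            if not present[k]:
                continue
            for j in range(5):
                skew2 = skew.copy()
                skew2[k, j + 1:] = 1 - skew2[k, j + 1:]
                want = (eng.posterior(skew2).log_likelihood
                        - post.log_likelihood)
                assert post.inversion_delta[k, j] == pytest.approx(
                    want, abs=1e-8)
        # flipping nothing after the last marker is the identity
        for k in range(n_memb):
            if present[k]:
                assert post.inversion_delta[k, 4] == pytest.approx(0, abs=1e-9)


def test_zero_likelihood_with_eps_zero_raises():
    # kid carries an allele neither parent has anywhere
    geno = np.zeros((7, 2, 2), np.uint8)
    geno[0] = [(2, 2), (2, 2)]
    geno[1] = [(1, 1), (1, 1)]
    geno[2] = [(1, 1), (1, 1)]
    present = np.array([1, 1, 1, 0, 0, 0, 0], bool)
    eng = ContextEngine(geno, present, [0.01], depth=2, eps=0.0)
    with pytest.raises(InconsistentDataError):
        marginalize_shifts(eng, np.full((7, 2), 0.5))
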