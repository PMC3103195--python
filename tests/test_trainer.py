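import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pedphase import trainer as tr
from pedphase.pedio import Pedigree, GenotypeMatrix, MarkerMap, \
    build_analysis_contexts
from pedphase.trainer import (SkewnessTable, TrainerConfig, VoteLedger,
                              accumulate_votes, apply_inversion, clamp_bound,
                              clamp_update, context_weights, harden_phase,
                              initialize_skewness, inversion_scan, train)
from pedphase.simulator import simulate_cross
from pedphase.evaluation import phase_accuracy
from .conftest import small_cfg


# ---------------------------------------------------------------------------
# clamping
# ---------------------------------------------------------------------------

def test_clamp_known_values():
    assert clamp_update(0.5, 1.0) == pytest.approx(0.75)
    assert clamp_update(0.5, 0.6) == pytest.approx(0.6)  # within bound
    # bound(0.25) = 0.25*0.75/1.25 = 0.15 -> floor at 0.10
    assert clamp_update(0.25, 0.0) == pytest.approx(0.10)


@given(st.floats(0.01, 0.99), st.floats(-0.5, 1.5))
def test_clamp_respects_printed_bound(p, p_raw):
    p_new = clamp_update(p, p_raw)
    assert 0.0 <= p_new <= 1.0
    assert abs(p_new - p) <= clamp_bound(p) + 1e-12


def test_clamp_odds_factor_three_at_half():
    p_new = clamp_update(0.5, 1.0)
    assert p_new / (1 - p_new) == pytest.approx(3.0, abs=1e-9)
    p_new = clamp_update(0.5, 0.0)
    assert (p_new / (1 - p_new)) ** -1 == pytest.approx(3.0, abs=1e-9)


# ---------------------------------------------------------------------------
# initialisation and anchors
# ---------------------------------------------------------------------------

def _mini_inputs(genos):
    """One individual, one chromosome, given genotype pairs."""
    ped = Pedigree.from_records([("x", None, None)])
    g = GenotypeMatrix(ids=["x"], data=[genos])
    mmap = MarkerMap.from_positions({"1": np.arange(len(genos), dtype=float)})
    return ped, g, mmap


def test_initialize_all_homozygous_leaves_no_anchor():
    ped, g, mmap = _mini_inputs([(1, 1), (2, 2), (1, 1)])
    with pytest.warns(UserWarning, match="no heterozygous"):
        skew = initialize_skewness(ped, g, mmap)
    assert not skew.anchor.any()
    np.testing.assert_allclose(skew.p, 0.5)


def test_initialize_anchors_first_heterozygote():
    genos = [(1, 1)] * 3 + [(1, 2)] + [(1, 1)] * 3 + [(1, 2)] + [(1, 1)]
    ped, g, mmap = _mini_inputs(genos)
    skew = initialize_skewness(ped, g, mmap)
    assert skew.p[0, 3] == 0.0 and skew.anchor[0, 3]
    assert skew.p[0, 7] == 0.5 and not skew.anchor[0, 7]


def test_anchors_remain_zero_after_training(small_trained):
    _, _, _, _, res = small_trained
    skew = res.skewness
    assert np.all(skew.p[skew.anchor] == 0.0)


# ---------------------------------------------------------------------------
# votes
# ---------------------------------------------------------------------------

class _FakePosterior:
    def __init__(self, q, inv=None):
        self.order_posterior = q
        self.inversion_delta = inv


def _ctx(sib=(1, 1)):
    from pedphase.pedio import AnalysisContext

    return AnalysisContext(focus_id="f", parent_ids=("s", "d"),
                           grandparent_ids=("a", "b", "c", "e"),
                           meiosis_count=6, sibling_counts=sib)


def test_agnostic_posterior_contributes_zero():
    ledger = VoteLedger.empty(["f", "s", "d", "a", "b", "c", "e"], 4)
    skew7 = np.full((7, 4), 0.37)
    q = skew7.copy()  # posterior equals prior everywhere
    rows = np.arange(7)
    cols = np.arange(4)
    accumulate_votes(ledger, _ctx(), _FakePosterior(q), skew7, rows, cols)
    np.testing.assert_allclose(ledger.votes, 0.0, atol=1e-12)


def test_grandparent_votes_scaled_by_sibling_count():
    w = context_weights(_ctx(sib=(10, 4)))
    np.testing.assert_allclose(w, [1, 1, 1, 0.1, 0.1, 0.25, 0.25])


def test_opposite_votes_cancel():
    ledger = VoteLedger.empty(["f"], 1)
    skew7 = np.full((7, 1), 0.5)
    rows = np.full(7, -1)
    rows[0] = 0
    cols = np.array([0])
    up = np.full((7, 1), np.nan)
    up[0] = 0.6
    down = np.full((7, 1), np.nan)
    down[0] = 0.4
    accumulate_votes(ledger, _ctx(), _FakePosterior(up), skew7, rows, cols)
    accumulate_votes(ledger, _ctx(), _FakePosterior(down), skew7, rows, cols)
    assert ledger.votes[0, 0] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# inversions
# ---------------------------------------------------------------------------

def test_inversion_is_an_involution():
    skew = SkewnessTable(["x"], np.array([[0.1, 0.9, 0.5, 0.2]]),
                         np.zeros((1, 4), bool), np.ones((1, 4), bool))
    cols = np.arange(4)
    before = skew.p.copy()
    apply_inversion(skew, "x", cols, 0)
    assert not np.allclose(skew.p, before)
    apply_inversion(skew, "x", cols, 0)
    np.testing.assert_allclose(skew.p, before)


def test_inversion_fixed_point_at_half():
    skew = SkewnessTable(["x"], np.full((1, 5), 0.5),
                         np.zeros((1, 5), bool), np.ones((1, 5), bool))
    apply_inversion(skew, "x", np.arange(5), 1)
    np.testing.assert_allclose(skew.p, 0.5)


def test_inversion_re_complements_when_anchor_downstream():
    anchor = np.zeros((1, 5), bool)
    anchor[0, 2] = True
    skew = SkewnessTable(["x"], np.array([[0.9, 0.8, 0.0, 0.9, 0.1]]),
                         anchor, np.ones((1, 5), bool))
    apply_inversion(skew, "x", np.arange(5), 0)
    # anchor stays 0; net effect is complementing markers <= position
    np.testing.assert_allclose(skew.p[0], [0.1, 0.8, 0.0, 0.9, 0.1])
    assert skew.p[0, 2] == 0.0


def test_inversion_scan_flags_flipped_block(small_trained):
    ped, geno, truth, mmap, res = small_trained
    contexts = build_analysis_contexts(ped)
    iid = ped.founders[0]
    skew = res.skewness
    i = skew.index[iid]
    cols = mmap.chrom_indices("1")
    hets = np.flatnonzero(skew.het[i, cols])
    assert len(hets) > 6
    cut = int(hets[len(hets) // 2])

    base = dict(inversion_scan(iid, "1", contexts, geno, mmap, skew))
    # converged phase: no downstream flip should clearly help
    assert max(base.values()) < 1.0

    flipped = skew.copy()
    down = cols[cut + 1:]
    flipped.p[i, down] = 1 - flipped.p[i, down]
    scores = dict(inversion_scan(iid, "1", contexts, geno, mmap, flipped))
    best = max(scores, key=scores.get)
    # restoring the block is strongly favoured, at the cut point
    assert scores[best] > 2.0
    assert abs(best - cut) <= 1
    # and the cached-pass score equals a from-scratch recompute
    restored = flipped.copy()
    restored.p[i, cols[best + 1:]] = 1 - restored.p[i, cols[best + 1:]]
    delta = (_total_ll(iid, contexts, geno, mmap, restored)
             - _total_ll(iid, contexts, geno, mmap, flipped))
    assert scores[best] == pytest.approx(delta, abs=1e-6)


def _total_ll(iid, contexts, geno, mmap, skew):
    from pedphase.trainer import _prepare_contexts
    from pedphase.hmm_core import N_MEMBERS

    cols = mmap.chrom_indices("1")
    rel = [c for c in contexts if iid in c.member_ids]
    tot = 0.0
    for cd in tr._prepare_contexts(rel, geno, cols,
                                   mmap.interval_distances("1"),
                                   TrainerConfig()):
        s7 = np.full((N_MEMBERS, len(cols)), 0.5)
        for k in range(N_MEMBERS):
            if cd.rows[k] >= 0:
                s7[k] = skew.p[cd.rows[k], cols]
        tot += cd.engine.posterior(s7).log_likelihood
    return tot


# ---------------------------------------------------------------------------
# hardening
# ---------------------------------------------------------------------------

def test_harden_orders_extreme_sites():
    g = GenotypeMatrix(ids=["x"], data=[[(1, 2), (1, 2), (1, 2), (1, 1),
                                         (0, 0)]])
    skew = SkewnessTable(["x"], np.array([[0.0, 1.0, 0.5, 0.5, 0.5]]),
                         np.zeros((1, 5), bool), g.is_het())
    h = harden_phase(skew, g, threshold=0.1)
    assert tuple(h.strands[0, 0]) == (1, 2)   # AB
    assert tuple(h.strands[0, 1]) == (2, 1)   # BA
    assert not h.phased[0, 2]                 # undecided het
    assert h.phased[0, 3]                     # homozygote trivially phased
    assert not h.phased[0, 4]                 # missing
    # threshold semantics: p = 0.005 is phased at threshold 0.01
    skew.p[0, 2] = 0.005
    assert harden_phase(skew, g, threshold=0.01).phased[0, 2]


def test_harden_default_rounds_everything_decided():
    g = GenotypeMatrix(ids=["x"], data=[[(1, 2), (1, 2), (1, 2)]])
    skew = SkewnessTable(["x"], np.array([[0.4, 0.6, 0.5]]),
                         np.zeros((1, 3), bool), g.is_het())
    h = harden_phase(skew, g)
    assert h.phased[0, 0] and h.phased[0, 1]
    assert tuple(h.strands[0, 0]) == (1, 2)
    assert tuple(h.strands[0, 1]) == (2, 1)
    assert not h.phased[0, 2]  # exact tie stays open


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def test_training_recovers_phase_on_small_cross(small_trained):
    # two of the eight founders in this tiny design never breed, so they
    # appear in no analysis pedigree and stay unphased; score the rest
    ped, geno, truth, mmap, res = small_trained
    phased = harden_phase(res.skewness, geno)
    rep = phase_accuracy(phased, truth, ped, mmap)
    g = rep.per_generation.set_index("generation")
    assert g.loc["2", "het_accuracy"] > 0.97
    assert g.loc["3", "het_accuracy"] > 0.97


def test_training_is_deterministic():
    ped, geno, truth, mmap = simulate_cross(small_cfg(seed=3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = train(ped, geno, mmap, TrainerConfig(max_iterations=4))
        r2 = train(ped, geno, mmap, TrainerConfig(max_iterations=4))
    np.testing.assert_array_equal(r1.skewness.p, r2.skewness.p)


def test_context_order_does_not_matter():
    ped, geno, truth, mmap = simulate_cross(small_cfg(seed=5))
    contexts = build_analysis_contexts(ped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = train(ped, geno, mmap, TrainerConfig(max_iterations=3),
                   contexts=contexts)
        r2 = train(ped, geno, mmap, TrainerConfig(max_iterations=3),
                   contexts=contexts[::-1])
    np.testing.assert_allclose(r1.skewness.p, r2.skewness.p, atol=1e-12)


def test_serial_and_parallel_runs_agree():
    ped, geno, truth, mmap = simulate_cross(
        small_cfg(seed=9, chromosomes=2, markers_per_chromosome=20))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = train(ped, geno, mmap, TrainerConfig(max_iterations=3,
                                                  n_workers=1))
        r2 = train(ped, geno, mmap, TrainerConfig(max_iterations=3,
                                                  n_workers=2))
    np.testing.assert_array_equal(r1.skewness.p, r2.skewness.p)


def test_single_chromosome_run_equals_joint_slice():
    ped, geno, truth, mmap = simulate_cross(
        small_cfg(seed=9, chromosomes=2, markers_per_chromosome=20))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        joint = train(ped, geno, mmap, TrainerConfig(max_iterations=3))
        # chromosome 1 alone
        cols = mmap.chrom_indices("1")
        sub_map = MarkerMap(mmap.table.iloc[cols].reset_index(drop=True))
        sub_geno = GenotypeMatrix(ids=list(geno.ids),
                                  data=geno.data[:, cols])
        alone = train(ped, sub_geno, sub_map,
                      TrainerConfig(max_iterations=3))
    np.testing.assert_allclose(alone.skewness.p, joint.skewness.p[:, cols],
                               atol=1e-12)


def test_total_loglik_rises_after_early_iterations(small_trained):
    # the objective is a composite likelihood (each analysis conditions on
    # relatives' point estimates), so small transient dips are possible,
    # but from iteration 2 on the trend must be upward
    _, _, _, _, res = small_trained
    ll = res.diagnostics.sort_values("iteration")["total_loglik"].to_numpy()
    slack = 0.02 * np.abs(ll[1:-1])
    assert np.all(ll[2:] >= ll[1:-1] - slack)
    assert ll[-1] > ll[0]


def test_diagnostics_shape(small_trained):
    _, _, _, _, res = small_trained
    d = res.diagnostics
    assert {"chrom", "iteration", "total_loglik", "n_inversions",
            "sum_abs_dp"} <= set(d.columns)
    assert (d.groupby("chrom")["iteration"].min() == 1).all()
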