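"""Inheritance-vector HMM for local-pedigree haplotype phasing.

Model summary
-------------
One analysis centres on a *focus* individual together with its parents and
grandparents.  The hidden state at a locus is an inheritance vector: one bit
per tracked meiosis, giving the grandparental origin (strand 0 or strand 1 of
the transmitting ancestor) of the allele passed down at that locus.  Two
meioses are tracked in the two-generation model (4 states), six in the
three-generation model (64 states); a four-generation model would need 14
meioses (16,384 states) and is supported only as a count query.

Transitions between adjacent markers are independent per meiosis: each bit
flips with the recombination fraction given by the Haldane map function of
the interval's map distance, so the full transition matrix is the n-fold
Kronecker product of 2x2 kernels ``[[1-r, r], [r, 1-r]]``.

Emissions connect the hidden inheritance vector to the observed *unordered*
genotypes through per-individual, per-marker skewness parameters
``s in [0, 1]``: the probability that the true ordered realisation of the
unordered pair {A, B} (A <= B) is BA, i.e. that strand 0 carries the larger
allele.  ``s = 0.5`` is order-neutral, ``0.0`` permits only AB, ``1.0`` only
BA.  The emission probability for a state is the sum over ordered strand
realisations of every member (weighted by their skewness) of the product of
allele-consistency factors along the six meioses; a contradiction contributes
the mismatch floor ``eps`` instead of zero, and missing genotypes contribute
a factor of exactly 1 (wildcard).

Because the strand labelling of the focus individual and its parents is not
tied to parental origin, the model is evaluated under all 8 *shift*
combinations (strand-to-parental-origin assignments for focus, sire and dam)
and marginalised; shifts with negligible running likelihood can be truncated
beam-style.

All forward/backward passes are rescaled per locus; the factorized
transition kernel is applied per meiosis rather than as a dense matrix, with
the dense Kronecker construction kept as a cross-check
(:func:`transition_matrix`).  :func:`brute_force_likelihood` and
:func:`emission_oracle` are slow, enumeration-based oracles used by the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EPS_DEFAULT = 1e-6

# member slots of an analysis pedigree, in role order
ROLE_FOCUS, ROLE_SIRE, ROLE_DAM, ROLE_SS, ROLE_SD, ROLE_DS, ROLE_DD = range(7)
N_MEMBERS = 7

# meiosis bits of the 64-state model:
# 0: sire -> focus, 1: dam -> focus, 2: SS -> sire, 3: SD -> sire,
# 4: DS -> dam, 5: DD -> dam
# shift bits: 0: focus, 1: sire, 2: dam

# flipping the skewness of one member downstream of a marker is equivalent to
# relabelling that member's strands there, i.e. to complementing the state
# bits / shift bits that reference those strands:
_INV_D3 = {
    ROLE_FOCUS: ((), 0b001),
    ROLE_SIRE: ((0,), 0b010),
    ROLE_DAM: ((1,), 0b100),
    ROLE_SS: ((2,), 0),
    ROLE_SD: ((3,), 0),
    ROLE_DS: ((4,), 0),
    ROLE_DD: ((5,), 0),
}
_INV_D2 = {
    ROLE_FOCUS: ((), 0b1),
    ROLE_SIRE: ((0,), 0),
    ROLE_DAM: ((1,), 0),
}


class InconsistentDataError(ValueError):
    """All state paths have zero likelihood (only possible with eps = 0)."""


# ---------------------------------------------------------------------------
# map function and state space
# ---------------------------------------------------------------------------

def haldane(d):
    """Haldane map function: recombination fraction r = (1 - exp(-2 d)) / 2
    for map distance ``d`` in Morgans (no crossover interference)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def n_meioses_for_depth(n_generations: int) -> int:
    """Number of tracked meioses for an analysis ``n_generations`` deep
    (2 -> 2, 3 -> 6, 4 -> 14): each added ancestor generation doubles the
    untransmitted-phase bookkeeping."""
    if n_generations < 2:
        raise ValueError("at least two generations are required")
    return 2 ** n_generations - 2


def state_count(n_generations: int) -> int:
    """Size of the inheritance-vector state space (count-only; any depth)."""
    return 2 ** n_meioses_for_depth(n_generations)


@dataclass(frozen=True)
class StateSpace:
    """Enumerated inheritance vectors for a supported analysis depth."""

    n_meioses: int
    states: np.ndarray  # (n_states, n_meioses) uint8 bit vectors

    @property
    def n_states(self) -> int:
        return self.states.shape[0]


def build_state_space(n_generations: int) -> StateSpace:
    """Enumerated state space for depth 2 (4 states) or 3 (64 states);
    deeper models are intractable and only countable via :func:`state_count`."""
    if n_generations not in (2, 3):
        raise ValueError(
            f"depth {n_generations} not supported for enumeration; "
            "use state_count() for a count-only query"
        )
    nm = n_meioses_for_depth(n_generations)
    v = np.arange(2 ** nm)
    states = ((v[:, None] >> np.arange(nm)[None, :]) & 1).astype(np.uint8)
    return StateSpace(n_meioses=nm, states=states)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def interval_kernels(distances, tracked, n_meioses: int) -> np.ndarray:
    """Per-interval, per-meiosis 2x2 transition kernels.

    ``distances``: (n_intervals,) map distances in Morgans.
    ``tracked``: (n_meioses,) bool; untracked meioses (into absent ancestors)
    get a memoryless r = 0.5 kernel.
    Returns (n_intervals, n_meioses, 2, 2).
    """
    r = haldane(np.asarray(distances, dtype=float))
    out = np.empty((len(r), n_meioses, 2, 2))
    for k in range(n_meioses):
        rk = r if tracked[k] else np.full_like(r, 0.5)
        out[:, k, 0, 0] = out[:, k, 1, 1] = 1.0 - rk
        out[:, k, 0, 1] = out[:, k, 1, 0] = rk
    return out


def apply_factored_transition(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Apply one interval's transition to ``x`` (..., n_states) using the
    per-meiosis 2x2 kernels (n_meioses, 2, 2) -- never forming the dense
    matrix.  Bit k of the state index is the k-th meiosis."""
    nm = kernels.shape[0]
    lead = x.shape[:-1]
    y = x.reshape(lead + (2,) * nm)
    for k in range(nm):
        ax = y.ndim - 1 - k  # bit k varies fastest in the flat index
        y = np.moveaxis(np.tensordot(y, kernels[k], axes=([ax], [0])), -1, ax)
    return y.reshape(lead + (2 ** nm,))


def transition_matrix(kernels: np.ndarray) -> np.ndarray:
    """Dense (n_states, n_states) transition matrix as the Kronecker product
    of one interval's 2x2 kernels; cross-check for the factorized path."""
    from functools import reduce

    # bit 0 varies fastest -> it must be the rightmost Kronecker factor
    return reduce(np.kron, kernels[::-1])


_TRANS_CACHE: dict = {}


def _transition_stack(distances, tracked, n_meioses: int) -> np.ndarray:
    """(n_intervals, S, S) dense transition matrices, assembled once per
    (chromosome, tracking pattern) from the factorized kernels and shared by
    every context with the same pattern."""
    key = (np.asarray(distances, float).tobytes(), tuple(bool(t) for t in tracked),
           n_meioses)
    hit = _TRANS_CACHE.get(key)
    if hit is not None:
        return hit
    kernels = interval_kernels(distances, tracked, n_meioses)
    S = 2 ** n_meioses
    if kernels.shape[0] == 0:
        stack = np.zeros((0, S, S))
    else:
        stack = np.stack([transition_matrix(kernels[j])
                          for j in range(kernels.shape[0])])
    _TRANS_CACHE[key] = stack
    return stack


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def _eq_table(eps: float) -> np.ndarray:
    """EQ[x, c] for allele codes {0, 1} and 2 = wildcard: 1 on agreement or
    wildcard, eps on contradiction."""
    eq = np.full((3, 3), eps)
    eq[0, 0] = eq[1, 1] = 1.0
    eq[2, :] = eq[:, 2] = 1.0
    return eq


def _strand_alleles(geno: np.ndarray) -> np.ndarray:
    """Per-member strand/realisation allele codes.

    ``geno``: (M, 2) sorted unordered pairs in file coding (0 missing,
    alleles 1/2).  Returns SA (M, 2 strands, 2 realisations) with internal
    codes 0/1 and 2 = wildcard.  Realisation 0 = AB (strand 0 carries the
    smaller allele), realisation 1 = BA.
    """
    M = geno.shape[0]
    lo = geno[:, 0].astype(np.int8) - 1
    hi = geno[:, 1].astype(np.int8) - 1
    sa = np.empty((M, 2, 2), dtype=np.int8)
    sa[:, 0, 0] = lo
    sa[:, 0, 1] = hi
    sa[:, 1, 0] = hi
    sa[:, 1, 1] = lo
    sa[geno[:, 0] == 0] = 2  # missing genotype -> wildcard strands
    return sa


def _realization_weights(skew: np.ndarray, het: np.ndarray) -> np.ndarray:
    """(M, 2) weights of the AB/BA realisations: [1-s, s] at heterozygous
    sites, [1, 0] elsewhere (single realisation)."""
    w = np.zeros((skew.shape[0], 2))
    w[:, 0] = np.where(het, 1.0 - skew, 1.0)
    w[:, 1] = np.where(het, skew, 0.0)
    return w


def _gp_message(w: np.ndarray, sa: np.ndarray, eq: np.ndarray) -> np.ndarray:
    """Grandparent message T[j, bit, c]: weight that the grandparent
    transmits allele ``c`` via the strand selected by ``bit``."""
    return np.einsum("mr,mbrc->mbc", w, eq[sa])


def _parent_message(w, sa, t_a, t_b, eq, restrict_ba=False) -> np.ndarray:
    """Parent message P[j, m, sg, a, b, c]: weight that the parent transmits
    allele ``c`` via its strand ``m``, given its own origin shift ``sg`` and
    the grandparent meiosis bits ``a`` (paternal side) and ``b``."""
    M = sa.shape[0]
    P = np.zeros((M, 2, 2, 2, 2, 3))
    reals = (1,) if restrict_ba else (0, 1)
    for r in reals:
        ec = eq[sa[:, :, r]]  # (M, strand m, c)
        for sg in range(2):
            ta = np.take_along_axis(
                t_a, sa[:, sg, r][:, None, None].astype(np.intp), axis=2
            )[:, :, 0]  # (M, bit a)
            tb = np.take_along_axis(
                t_b, sa[:, 1 - sg, r][:, None, None].astype(np.intp), axis=2
            )[:, :, 0]
            P[:, :, sg] += (
                w[:, r, None, None, None, None]
                * ec[:, :, None, None, :]
                * ta[:, None, :, None, None]
                * tb[:, None, None, :, None]
            )
    return P


def _pair_message(w, sa, eq, restrict_ba=False) -> np.ndarray:
    """Two-generation parent message P2[j, m, c] (no grandparent links)."""
    if restrict_ba:
        w = np.stack([np.zeros_like(w[:, 1]), w[:, 1]], axis=1)
    return np.einsum("mr,mbrc->mbc", w, eq[sa])


def _assemble_d3(wf, saf, PS, PD) -> np.ndarray:
    """Combine focus realisation weights with the two parent messages into
    the full emission array, shape (8 shifts, M, 64 states)."""
    M = saf.shape[0]
    # axes: (M, sigD, sigS, sigF, mDD, mDS, mSD, mSS, mD, mS)
    E10 = np.zeros((M, 2, 2, 2, 2, 2, 2, 2, 2, 2))
    for r in range(2):
        for sf in range(2):
            c_s = saf[:, sf, r].astype(np.intp)
            c_d = saf[:, 1 - sf, r].astype(np.intp)
            idx = c_s[:, None, None, None, None, None]
            PSr = np.take_along_axis(PS, idx, axis=5)[..., 0]  # (M,mS,sgS,a,b)
            idx = c_d[:, None, None, None, None, None]
            PDr = np.take_along_axis(PD, idx, axis=5)[..., 0]  # (M,mD,sgD,a,b)
            sire = PSr.transpose(0, 2, 4, 3, 1)[
                :, None, :, None, None, :, :, None, :
            ]  # (M,1,sgS,1,1,mSD,mSS,1,mS)
            dam = PDr.transpose(0, 2, 4, 3, 1)[
                :, :, None, :, :, None, None, :, None
            ]  # (M,sgD,1,mDD,mDS,1,1,mD,1)
            E10[:, :, :, sf] += wf[:, r].reshape(M, 1, 1, 1, 1, 1, 1, 1, 1) * sire * dam
    return E10.reshape(M, 8, 64).transpose(1, 0, 2)


def _assemble_d2(wf, saf, PS2, PD2) -> np.ndarray:
    """Two-generation emission array, shape (2 shifts, M, 4 states)."""
    M = saf.shape[0]
    E4 = np.zeros((M, 2, 2, 2))  # (M, sigF, mD, mS)
    for r in range(2):
        for sf in range(2):
            c_s = saf[:, sf, r].astype(np.intp)
            c_d = saf[:, 1 - sf, r].astype(np.intp)
            ps = np.take_along_axis(PS2, c_s[:, None, None], axis=2)[:, :, 0]
            pd_ = np.take_along_axis(PD2, c_d[:, None, None], axis=2)[:, :, 0]
            E4[:, sf] += wf[:, r, None, None] * pd_[:, :, None] * ps[:, None, :]
    return E4.reshape(M, 2, 4).transpose(1, 0, 2)


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Forward-backward output for one analysis context on one chromosome.

    ``order_posterior[k, j]`` is the posterior probability that member ``k``'s
    true ordering at marker ``j`` is BA (NaN where the member is absent,
    homozygous or ungenotyped).  ``inversion_delta[k, j]`` is the change in
    total log-likelihood if all of member ``k``'s skewness values strictly
    downstream of ``j`` were complemented.
    """

    log_likelihood: float
    log_likelihood_per_shift: np.ndarray  # (n_shifts,), -inf where truncated
    n_shifts_evaluated: int
    state_posterior: np.ndarray  # (M, n_states), shift-marginalised
    order_posterior: np.ndarray  # (N_MEMBERS, M)
    inversion_delta: Optional[np.ndarray] = None  # (N_MEMBERS, M)
    # internals cached for tests
    _alpha: Optional[np.ndarray] = field(default=None, repr=False)
    _beta: Optional[np.ndarray] = field(default=None, repr=False)
    _log_a: Optional[np.ndarray] = field(default=None, repr=False)
    _log_b: Optional[np.ndarray] = field(default=None, repr=False)


def _logsumexp(a, axis=None):
    a = np.asarray(a, dtype=float)
    hi = np.max(a, axis=axis, keepdims=True)
    hi = np.where(np.isfinite(hi), hi, 0.0)
    out = np.log(np.sum(np.exp(a - hi), axis=axis)) + np.squeeze(hi, axis=axis)
    return out


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class ContextEngine:
    """HMM engine for one analysis context on one chromosome.

    Static per-context data (strand-allele tables, transition kernels) is
    prepared once; :meth:`posterior` is then called each training iteration
    with the current skewness rows.

    Parameters
    ----------
    geno7 : (7, M, 2) uint8
        Sorted unordered genotype pairs of the members in role order
        (focus, sire, dam, SS, SD, DS, DD); absent members all-zero.
    present : (7,) bool
        Which members exist in the pedigree.
    distances : (M-1,) float
        Map distances between adjacent markers, Morgans.
    depth : {2, 3}
        Two- or three-generation analysis (4 or 64 states).
    eps : float
        Mismatch floor for state/genotype contradictions; ``0`` only for
        guaranteed error-free data.
    """

    def __init__(self, geno7, present, distances, depth=3, eps=EPS_DEFAULT):
        if depth not in (2, 3):
            raise ValueError(f"unsupported depth {depth}")
        self.depth = depth
        self.n_meioses = 2 if depth == 2 else 6
        self.n_states = 2 ** self.n_meioses
        self.n_shifts = 2 if depth == 2 else 8
        self.n_members = 3 if depth == 2 else 7
        self.eps = float(eps)
        self.eq = _eq_table(self.eps)

        geno7 = np.asarray(geno7, dtype=np.uint8)
        self.M = geno7.shape[1]
        self.present = np.asarray(present, dtype=bool).copy()
        geno7 = geno7.copy()
        geno7[~self.present] = 0  # absent member == fully missing
        self.het = (geno7[:, :, 0] != geno7[:, :, 1]) & (geno7[:, :, 0] != 0)
        self.sa = np.stack([_strand_alleles(geno7[k]) for k in range(N_MEMBERS)])

        if depth == 3:
            tracked = self.present[1:7]
        else:
            tracked = self.present[1:3]
        self.kernels = interval_kernels(distances, tracked, self.n_meioses)
        # hot loop uses the dense per-interval matrices pre-assembled from
        # the factorized kernels (identical results, one matmul per step)
        self.trans = _transition_stack(distances, tracked, self.n_meioses)
        self._inv_map = _INV_D3 if depth == 3 else _INV_D2
        # state-index permutations for single-bit flips
        v = np.arange(self.n_states)
        self._bitflip = {k: v ^ (1 << k) for k in range(self.n_meioses)}

    # -- emissions ----------------------------------------------------------

    def emissions(self, skew7, with_ratios=True):
        """Emission array E (n_shifts, M, n_states) for the given skewness
        rows, and per-member BA-restricted ratios (None where undefined)."""
        skew7 = np.asarray(skew7, dtype=float)
        w = [
            _realization_weights(skew7[k], self.het[k]) for k in range(N_MEMBERS)
        ]
        eq = self.eq
        if self.depth == 3:
            T = {k: _gp_message(w[k], self.sa[k], eq) for k in (3, 4, 5, 6)}
            PS = _parent_message(w[1], self.sa[1], T[3], T[4], eq)
            PD = _parent_message(w[2], self.sa[2], T[5], T[6], eq)
            E = _assemble_d3(w[0], self.sa[0], PS, PD)
            if not with_ratios:
                return E, None
            wf_ba = np.stack([np.zeros(self.M), w[0][:, 1]], axis=1)
            eba = [
                _assemble_d3(wf_ba, self.sa[0], PS, PD),
                _assemble_d3(
                    w[0], self.sa[0],
                    _parent_message(w[1], self.sa[1], T[3], T[4], eq, True), PD
                ),
                _assemble_d3(
                    w[0], self.sa[0], PS,
                    _parent_message(w[2], self.sa[2], T[5], T[6], eq, True)
                ),
                _assemble_d3(
                    w[0], self.sa[0],
                    _parent_message(
                        w[1], self.sa[1],
                        _gp_message(
                            np.stack([np.zeros(self.M), w[3][:, 1]], axis=1),
                            self.sa[3], eq),
                        T[4], eq),
                    PD),
                _assemble_d3(
                    w[0], self.sa[0],
                    _parent_message(
                        w[1], self.sa[1], T[3],
                        _gp_message(
                            np.stack([np.zeros(self.M), w[4][:, 1]], axis=1),
                            self.sa[4], eq),
                        eq),
                    PD),
                _assemble_d3(
                    w[0], self.sa[0], PS,
                    _parent_message(
                        w[2], self.sa[2],
                        _gp_message(
                            np.stack([np.zeros(self.M), w[5][:, 1]], axis=1),
                            self.sa[5], eq),
                        T[6], eq)),
                _assemble_d3(
                    w[0], self.sa[0], PS,
                    _parent_message(
                        w[2], self.sa[2], T[5],
                        _gp_message(
                            np.stack([np.zeros(self.M), w[6][:, 1]], axis=1),
                            self.sa[6], eq),
                        eq)),
            ]
        else:
            PS2 = _pair_message(w[1], self.sa[1], eq)
            PD2 = _pair_message(w[2], self.sa[2], eq)
            E = _assemble_d2(w[0], self.sa[0], PS2, PD2)
            if not with_ratios:
                return E, None
            wf_ba = np.stack([np.zeros(self.M), w[0][:, 1]], axis=1)
            eba = [
                _assemble_d2(wf_ba, self.sa[0], PS2, PD2),
                _assemble_d2(w[0], self.sa[0],
                             _pair_message(w[1], self.sa[1], eq, True), PD2),
                _assemble_d2(w[0], self.sa[0], PS2,
                             _pair_message(w[2], self.sa[2], eq, True)),
            ]
        ratios = np.full((N_MEMBERS,) + E.shape, np.nan)
        for k, eb in enumerate(eba):
            if not (self.present[k] and self.het[k].any()):
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios[k] = np.where(E > 0, eb / np.where(E > 0, E, 1.0), 0.0)
        return E, ratios

    def emission_probability(self, skew7, state: int, shift: int,
                             marker: int) -> float:
        """Single-cell emission probability (convenience/testing surface)."""
        E, _ = self.emissions(skew7, with_ratios=False)
        return float(E[shift, marker, state])

    # -- forward/backward ---------------------------------------------------

    def posterior(
        self,
        skew7,
        shifts: Optional[Sequence[int]] = None,
        beam_threshold: Optional[float] = None,
        beam_warmup: float = 0.1,
        want_inversion: bool = True,
    ) -> PosteriorResult:
        """Rescaled forward-backward over the requested shifts (default all),
        marginalising order posteriors and, optionally, the downstream-
        inversion log-likelihood deltas for every member."""
        E, ratios = self.emissions(skew7, with_ratios=True)
        S, M = self.n_states, self.M
        all_shifts = np.arange(self.n_shifts)
        active = np.array(sorted(shifts), dtype=int) if shifts is not None else all_shifts
        ns = len(active)

        alpha = np.zeros((ns, M, S))
        log_a = np.full((ns, M), -np.inf)
        x = np.full((ns, S), 1.0 / S) * E[active, 0, :]
        warm = int(np.ceil(beam_warmup * M)) if beam_threshold else M + 1
        keep = np.ones(ns, dtype=bool)
        log_beam = np.log(beam_threshold) if beam_threshold else -np.inf
        cur = np.zeros(ns)
        for j in range(M):
            if j > 0:
                x = (alpha[:, j - 1, :] @ self.trans[j - 1]) * E[active, j, :]
                x[~keep] = alpha[~keep, j - 1, :]
            c = x.sum(axis=1)
            bad = keep & (c <= 0.0)
            if bad.any():
                if self.eps == 0.0 and not (keep & (c > 0)).any():
                    raise InconsistentDataError(
                        f"zero likelihood at marker {j} for all shifts (eps=0)"
                    )
                keep &= ~bad
                c = np.where(c > 0, c, 1.0)
            alpha[:, j, :] = x / c[:, None]
            cur = np.where(keep, cur + np.log(np.where(c > 0, c, 1.0)), cur)
            log_a[:, j] = np.where(keep, cur, -np.inf)
            if j >= warm and keep.sum() > 1:
                keep &= cur >= cur[keep].max() + log_beam
        if not keep.any():
            raise InconsistentDataError("all shifts truncated or inconsistent")

        # drop truncated shifts from likelihood/posterior bookkeeping
        act_idx = np.flatnonzero(keep)
        alpha = alpha[act_idx]
        log_a = log_a[act_idx]
        requested = active
        active = active[act_idx]
        ns = len(active)

        # the inversion scan recombines each shift with its strand-relabel
        # partner, whose *backward* tables are needed even when its forward
        # likelihood was truncated -- so run the backward pass over every
        # requested shift in that case
        bwd = requested if want_inversion else active
        nb = len(bwd)
        beta = np.zeros((nb, M, S))
        log_b = np.zeros((nb, M))
        beta[:, M - 1, :] = 1.0 / S
        log_b[:, M - 1] = np.log(S)
        for j in range(M - 2, -1, -1):
            x = (E[bwd, j + 1, :] * beta[:, j + 1, :]) @ self.trans[j].T
            c = x.sum(axis=1)
            c = np.where(c > 0, c, 1.0)
            beta[:, j, :] = x / c[:, None]
            log_b[:, j] = log_b[:, j + 1] + np.log(c)
        bwd_pos = {s: i for i, s in enumerate(bwd)}
        beta_act = beta[[bwd_pos[s] for s in active]]

        ll_shift = log_a[:, M - 1].copy()
        ll_total = _logsumexp(ll_shift) - np.log(self.n_shifts)
        shift_post = np.exp(ll_shift - _logsumexp(ll_shift))

        ab = alpha * beta_act
        norm = ab.sum(axis=2, keepdims=True)
        gamma = ab / np.where(norm > 0, norm, 1.0)  # (ns, M, S)
        state_post = np.einsum("s,smv->mv", shift_post, gamma)

        order_post = np.full((N_MEMBERS, M), np.nan)
        for k in range(self.n_members):
            if not (self.present[k] and self.het[k].any()):
                continue
            qk = np.einsum("smv,smv->sm", gamma, ratios[k][active])
            q = shift_post @ qk
            order_post[k, self.het[k]] = q[self.het[k]]

        inv = None
        if want_inversion:
            inv = self._inversion_deltas(alpha, log_a, active, beta, log_b,
                                         bwd_pos, ll_shift)

        full_ll = np.full(self.n_shifts, -np.inf)
        full_ll[active] = ll_shift
        return PosteriorResult(
            log_likelihood=float(ll_total),
            log_likelihood_per_shift=full_ll,
            n_shifts_evaluated=ns,
            state_posterior=state_post,
            order_posterior=order_post,
            inversion_delta=inv,
            _alpha=alpha,
            _beta=beta_act,
            _log_a=log_a,
            _log_b=log_b,
        )

    def _inversion_deltas(self, alpha, log_a, active, beta, log_b, bwd_pos,
                          ll_shift):
        """Log-likelihood change for complementing each member's skewness
        strictly downstream of each marker, by recombining the cached forward
        pass with the bit-flip/shift-permuted backward pass."""
        ns, M, S = alpha.shape
        ll_cur = _logsumexp(ll_shift)
        out = np.full((N_MEMBERS, M), -np.inf)
        for k in range(self.n_members):
            if not self.present[k]:
                continue
            bits, sxor = self._inv_map[k]
            perm = np.arange(S)
            for b in bits:
                perm = self._bitflip[b][perm]
            ia = np.arange(ns)
            ib = np.array([bwd_pos[s ^ sxor] for s in active])
            inner = np.einsum("smv,smv->sm", alpha[ia], beta[ib][:, :, perm])
            with np.errstate(divide="ignore"):
                terms = np.log(inner) + log_a[ia] + log_b[ib]
            out[k] = _logsumexp(terms, axis=0) - ll_cur
        return out


# ---------------------------------------------------------------------------
# functional convenience surface
# ---------------------------------------------------------------------------

def emission_probability(geno7, skew7, state, shift, marker, present=None,
                         depth=3, eps=EPS_DEFAULT):
    """Emission probability for one (state, shift, marker) cell of an
    analysis context; ``geno7`` (7, M, 2) role-ordered genotypes."""
    geno7 = np.asarray(geno7, dtype=np.uint8)
    if present is None:
        present = (geno7 != 0).any(axis=(1, 2))
    eng = ContextEngine(geno7, present, np.zeros(max(geno7.shape[1] - 1, 0)),
                        depth=depth, eps=eps)
    return eng.emission_probability(np.asarray(skew7, float), state, shift, marker)


def forward_backward(engine: ContextEngine, skew7, shift: int) -> PosteriorResult:
    """Forward-backward under one fixed shift (no marginalisation)."""
    return engine.posterior(skew7, shifts=[shift], want_inversion=False)


def marginalize_shifts(engine: ContextEngine, skew7,
                       beam_threshold: Optional[float] = None,
                       beam_warmup: float = 0.1,
                       want_inversion: bool = False) -> PosteriorResult:
    """Shift-marginalised posterior; exact when ``beam_threshold`` is None."""
    return engine.posterior(skew7, beam_threshold=beam_threshold,
                            beam_warmup=beam_warmup,
                            want_inversion=want_inversion)


# ---------------------------------------------------------------------------
# enumeration oracles (test-only, deliberately slow and simple)
# ---------------------------------------------------------------------------

def brute_force_likelihood(prior, transitions, emissions) -> float:
    """Total probability as an explicit sum over *all* state paths.

    ``prior``: (S,); ``transitions``: list of (S, S) dense matrices;
    ``emissions``: (M, S).  Materialises the full path tensor -- use only for
    tiny instances."""
    emissions = np.asarray(emissions, dtype=float)
    M, S = emissions.shape
    prob = np.asarray(prior, dtype=float) * emissions[0]
    for j in range(1, M):
        step = np.asarray(transitions[j - 1]) * emissions[j][None, :]
        prob = prob[..., :, None] * step  # grow one path axis per marker
    return float(prob.sum())


def emission_oracle(geno7, skew7, state, shift, marker, present=None,
                    depth=3, eps=EPS_DEFAULT) -> float:
    """Loop-based emission enumeration over all members' ordered strand
    realisations, with explicit per-meiosis consistency checks."""
    geno7 = np.asarray(geno7)
    if present is None:
        present = (geno7 != 0).any(axis=(1, 2))
    nm = 2 if depth == 2 else 6
    n_memb = 3 if depth == 2 else 7
    bits = [(state >> k) & 1 for k in range(nm)]
    sf = shift & 1
    ss = (shift >> 1) & 1 if depth == 3 else 0
    sd = (shift >> 2) & 1 if depth == 3 else 0

    def realizations(k):
        if not present[k]:
            return [((None, None), 1.0)]
        lo, hi = int(geno7[k, marker, 0]), int(geno7[k, marker, 1])
        if lo == 0:
            return [((None, None), 1.0)]
        if lo == hi:
            return [((lo, lo), 1.0)]
        s = float(skew7[k][marker])
        return [((lo, hi), 1.0 - s), ((hi, lo), s)]

    def eq(x, y):
        if x is None or y is None:
            return 1.0
        return 1.0 if x == y else eps

    total = 0.0
    from itertools import product

    for combo in product(*[realizations(k) for k in range(n_memb)]):
        strands = [c[0] for c in combo]
        weight = 1.0
        for _, w in combo:
            weight *= w
        if weight == 0.0:
            continue
        f, s_, d = strands[0], strands[1], strands[2]
        factor = eq(f[sf], s_[bits[0]]) * eq(f[1 - sf], d[bits[1]])
        if depth == 3:
            gss, gsd, gds, gdd = strands[3], strands[4], strands[5], strands[6]
            factor *= eq(s_[ss], gss[bits[2]]) * eq(s_[1 - ss], gsd[bits[3]])
            factor *= eq(d[sd], gds[bits[4]]) * eq(d[1 - sd], gdd[bits[5]])
        total += weight * factor
    return total
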