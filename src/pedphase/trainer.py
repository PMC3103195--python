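"""Skewness training: a modified Baum-Welch loop with voting, clamped
updates, anchor handling and a downstream-inversion scan.

One iteration, per chromosome:

1. *Analysis phase* -- every focus individual's local-pedigree HMM is
   evaluated with the current skewness table.  Each member of the analysis
   pedigree receives a vote equal to the deviation between its posterior
   BA-order probability and its current skewness at every heterozygous
   marker; votes to grandparents are divided by the number of (half-)
   siblings sharing the connecting parent, because all those siblings only
   re-observe the single meiosis that formed that parent.  The scan for
   favourable downstream inversions (complementing all skewness values past
   a marker) is accumulated in the same pass from the cached
   forward/backward tables.
2. *Update phase* -- votes are summed onto the prior values, clipped to
   [0, 1], and clamped so the odds ratio p/(1-p) changes by at most a factor
   of 3 per iteration: |p - p'| <= p(1-p) min(1/(0.5+(1-p)), 1/(0.5+p)).
   Anchored markers (the first heterozygote per individual per chromosome,
   fixed at 0.0 to break the strand-labelling symmetry) never move.  Then at
   most one inversion per individual-chromosome is accepted if its summed
   log-likelihood gain exceeds a threshold, with a short cooldown against
   oscillation.

Training stops when the per-individual sum of absolute skewness changes
falls below a tolerance on every individual, or at ``max_iterations``.
Because votes are accumulated first and applied second, results do not
depend on the order in which contexts are evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .pedio import (
    AnalysisContext,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    PhasedHaplotypes,
    build_analysis_contexts,
)
from . import hmm_core
from .hmm_core import ContextEngine, N_MEMBERS


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class TrainerConfig:
    """Training controls.

    ``tolerance`` applies to the per-individual, per-chromosome sum of
    absolute skewness changes in one iteration.  ``inversion_threshold`` is
    in log-likelihood units; accepted inversions are serialised greedily by
    score within an iteration -- an individual sharing an analysis pedigree
    with an already-accepted inversion waits for the next iteration, and an
    accepted inversion blocks that individual for ``inversion_cooldown``
    further iterations.  Inversion scores are computed with every other
    individual's skewness held fixed, so simultaneous flips of coupled
    relatives would cancel each other and oscillate; serialising keeps each
    accepted flip an actual improvement.  ``beam_threshold`` is the relative
    likelihood below which a strand-shift alternative is truncated (after
    the first ``beam_warmup`` fraction of markers).  ``epsilon`` is the
    emission mismatch floor (0 only for guaranteed error-free data).
    """

    max_iterations: int = 25
    tolerance: float = 1e-3
    inversion_enabled: bool = True
    inversion_threshold: float = 0.5
    inversion_cooldown: int = 1
    vote_aggregation: str = "logit"  # log-odds evidence; or "sum"/"mean"
                                     # deviations on the probability scale
    beam_enabled: bool = True
    beam_threshold: float = 1e-8
    beam_warmup: float = 0.1
    epsilon: float = 1e-6
    depth: int = 3
    harden_threshold: float = 0.5
    reanchor_iteration: int = 5
    reanchor_band: float = 0.05
    n_workers: int = 1
    seed: int = 0

    def validate(self):
        if self.max_iterations < 1 or self.tolerance < 0:
            raise ValueError("max_iterations >= 1 and tolerance >= 0 required")
        if not 0 < self.beam_threshold < 1 or not 0 <= self.beam_warmup < 1:
            raise ValueError("beam settings out of range")
        if self.inversion_threshold <= 0:
            raise ValueError("inversion threshold must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SkewnessTable:
    """Trained phase parameters p[i, j] = P(order BA) per individual/marker,
    with the anchor mask (entries held at exactly 0.0) and the heterozygosity
    mask they were trained on."""

    ids: list
    p: np.ndarray        # (n, M) float
    anchor: np.ndarray   # (n, M) bool
    het: np.ndarray      # (n, M) bool

    def __post_init__(self):
        self.index = {iid: k for k, iid in enumerate(self.ids)}

    def copy(self) -> "SkewnessTable":
        return SkewnessTable(list(self.ids), self.p.copy(),
                             self.anchor.copy(), self.het.copy())


@dataclass
class VoteLedger:
    """Accumulated weighted skewness deviations and inversion scores.
    ``weight`` tracks the summed vote weights per cell so the update can use
    either the plain deviation sum or the weighted mean deviation."""

    ids: list
    votes: np.ndarray       # (n, M) float, sum of w * (q - p)
    inversion: np.ndarray   # (n, M) float, summed log-likelihood deltas
    weight: np.ndarray      # (n, M) float, sum of w where q was defined

    @classmethod
    def empty(cls, ids, n_markers: int) -> "VoteLedger":
        return cls(list(ids), np.zeros((len(ids), n_markers)),
                   np.zeros((len(ids), n_markers)),
                   np.zeros((len(ids), n_markers)))


@dataclass
class TrainResult:
    skewness: SkewnessTable
    diagnostics: pd.DataFrame  # chrom, iteration, total_loglik, n_inversions,
                               # sum_abs_dp, max_individual_dp
    iterations: dict           # chrom -> iterations run
    converged: dict            # chrom -> bool
    final_delta: pd.DataFrame  # chrom, id, sum_abs_dp at the last iteration
    inversions: pd.DataFrame = None  # chrom, iteration, id, position, score


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def initialize_skewness(ped: Pedigree, genotypes: GenotypeMatrix,
                        mmap: MarkerMap) -> SkewnessTable:
    """All 0.5, except the first heterozygous marker of every individual on
    every chromosome, which is anchored at exactly 0.0."""
    n, M = genotypes.n_individuals, genotypes.n_markers
    p = np.full((n, M), 0.5)
    anchor = np.zeros((n, M), dtype=bool)
    het = genotypes.is_het()
    unanchorable = 0
    for chrom in mmap.chromosomes:
        cols = mmap.chrom_indices(chrom)
        sub = het[:, cols]
        for i in range(n):
            hets = np.flatnonzero(sub[i])
            if len(hets) == 0:
                unanchorable += 1
                continue
            j = cols[hets[0]]
            p[i, j] = 0.0
            anchor[i, j] = True
    if unanchorable:
        warnings.warn(
            f"{unanchorable} individual-chromosome(s) have no heterozygous "
            "marker; left unanchored (trivially phased)"
        )
    return SkewnessTable(ids=list(genotypes.ids), p=p, anchor=anchor, het=het)


def clamp_bound(p):
    """Maximum allowed |p - p'| per iteration:
    p(1-p) * min(1/(0.5+(1-p)), 1/(0.5+p))."""
    p = np.asarray(p, dtype=float)
    return p * (1.0 - p) / (0.5 + np.maximum(p, 1.0 - p))


def clamp_update(p, p_raw):
    """Clamped update: move from ``p`` toward ``p_raw`` (clipped to [0, 1])
    by at most :func:`clamp_bound`, limiting the per-iteration change of the
    odds ratio p/(1-p) to a factor of 3."""
    p = np.asarray(p, dtype=float)
    p_raw = np.clip(np.asarray(p_raw, dtype=float), 0.0, 1.0)
    delta = np.clip(p_raw - p, -clamp_bound(p), clamp_bound(p))
    out = p + delta
    if out.ndim == 0:
        return float(out)
    return out


MEMBER_WEIGHT_SLOTS = (
    (0, None), (1, None), (2, None),
    (3, 0), (4, 0), (5, 1), (6, 1),  # grandparents scale by parent slot
)


def context_weights(ctx: AnalysisContext) -> np.ndarray:
    """Vote weights per member slot: 1 for focus and parents, 1/n for
    grandparents where n = offspring count of the connecting parent."""
    w = np.ones(N_MEMBERS)
    w[3] = w[4] = 1.0 / ctx.sibling_counts[0]
    w[5] = w[6] = 1.0 / ctx.sibling_counts[1]
    return w


_LOGIT_CLIP = 1e-9


def _logit(p):
    p = np.clip(p, _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
    return np.log(p) - np.log1p(-p)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def accumulate_votes(ledger: VoteLedger, ctx: AnalysisContext,
                     posterior: hmm_core.PosteriorResult,
                     skew7: np.ndarray, rows: np.ndarray,
                     cols: np.ndarray, scale: str = "logit") -> VoteLedger:
    """Add one context's weighted deviations between the posterior order
    probability q and the prior p, plus its inversion deltas, to the ledger.

    ``scale='logit'`` (default) records deviations on the log-odds scale,
    so independent analyses combine like likelihood evidence (a cell seen
    confidently by seven meioses and contradicted by one resolves to the
    joint answer rather than the 7:1 average); ``scale='probability'`` is
    the plain q - p deviation.  Either way a skewness-agnostic posterior
    (q == p) contributes exactly zero.  ``rows`` maps member slots to ledger
    rows (-1 = absent); ``cols`` are the chromosome's marker columns."""
    w = context_weights(ctx)
    q = posterior.order_posterior
    for k in range(N_MEMBERS):
        if rows[k] < 0:
            continue
        mask = np.isfinite(q[k])
        if mask.any():
            if scale == "logit":
                dev = _logit(q[k, mask]) - _logit(skew7[k, mask])
            else:
                dev = q[k, mask] - skew7[k, mask]
            ledger.votes[rows[k], cols[mask]] += w[k] * dev
            ledger.weight[rows[k], cols[mask]] += w[k]
        if posterior.inversion_delta is not None:
            # grandparent contributions carry the same 1/n scaling as votes:
            # every grandchild context re-tracks the one meiosis that formed
            # the connecting parent, so unweighted sums double-count it
            d = posterior.inversion_delta[k]
            ledger.inversion[rows[k], cols] += w[k] * np.where(
                np.isfinite(d), d, 0.0)
    return ledger


def apply_inversion(skew: SkewnessTable, iid: str, cols: np.ndarray,
                    position: int) -> np.ndarray:
    """Complement all skewness values strictly downstream of ``position``
    (a local index into ``cols``) for one individual on one chromosome.

    If the individual's anchor lies downstream, the plain complement would
    pin it at 1.0; the whole chromosome is then re-complemented (a global
    strand relabelling, likelihood-invariant), returning the anchor to 0.0.

    Returns the global column indices whose value was complemented (an even
    number of complements cancels), so pending per-cell votes can be
    re-expressed in the new strand labelling (a complement negates them).
    """
    i = skew.index[iid]
    down = cols[position + 1:]
    skew.p[i, down] = 1.0 - skew.p[i, down]
    anchors_here = np.flatnonzero(skew.anchor[i, cols])
    if len(anchors_here) and anchors_here[0] > position:
        skew.p[i, cols] = 1.0 - skew.p[i, cols]
        return cols[: position + 1]
    return down


def harden_phase(skew: SkewnessTable, genotypes: GenotypeMatrix,
                 threshold: float = 0.5) -> PhasedHaplotypes:
    """Turn trained skewness into two ordered strands.

    Heterozygous sites with p <= threshold are ordered AB (strand 0 carries
    the smaller allele), p >= 1 - threshold are ordered BA; anything in
    between stays unphased (canonical order, phased flag off).  The default
    threshold 0.5 phases every site the training leaned on at all (the
    method converges in all positions, so this is the intended protocol;
    only exact ties stay unphased); lower it, e.g. to 0.1, to demand 9:1
    posterior odds and leave uncertain sites open."""
    g = genotypes.data
    lo, hi = g[:, :, 0], g[:, :, 1]
    het = genotypes.is_het()
    miss = genotypes.is_missing()
    ba = het & (skew.p >= 1.0 - threshold) & (skew.p > 0.5)
    ab = het & (skew.p <= threshold) & (skew.p < 0.5)
    strands = np.stack([np.where(ba, hi, lo), np.where(ba, lo, hi)], axis=-1)
    phased = ~miss & (~het | ab | ba)
    return PhasedHaplotypes(ids=list(genotypes.ids),
                            strands=strands.astype(np.uint8), phased=phased)


# ---------------------------------------------------------------------------
# per-chromosome training
# ---------------------------------------------------------------------------

@dataclass
class _CtxData:
    ctx: AnalysisContext
    engine: ContextEngine
    rows: np.ndarray     # (7,) genotype/skewness row per member, -1 absent


def _prepare_contexts(contexts, genotypes: GenotypeMatrix, cols, distances,
                      cfg: TrainerConfig):
    out = []
    for ctx in contexts:
        rows = np.full(N_MEMBERS, -1, dtype=int)
        geno7 = np.zeros((N_MEMBERS, len(cols), 2), dtype=np.uint8)
        for k, mid in enumerate(ctx.member_ids):
            if mid is None:
                continue
            r = genotypes.index[mid]
            rows[k] = r
            geno7[k] = genotypes.data[r][cols]
        present = rows >= 0
        # a context without any grandparent collapses exactly to the
        # two-generation model: the extra meiosis bits carry unit emissions
        # and uniform transitions and marginalise out to a factor of 1
        depth = cfg.depth
        if depth == 3 and not present[3:7].any():
            depth = 2
        engine = ContextEngine(geno7, present, distances,
                               depth=depth, eps=cfg.epsilon)
        out.append(_CtxData(ctx=ctx, engine=engine, rows=rows))
    return out


def _train_chromosome(chrom, contexts, genotypes, skew: SkewnessTable,
                      cols, distances, cfg: TrainerConfig):
    """Train one chromosome in place on ``skew``; returns diagnostics rows
    and the per-individual delta of the final iteration."""
    ctx_data = _prepare_contexts(contexts, genotypes, cols, distances, cfg)
    n = skew.p.shape[0]
    beam = cfg.beam_threshold if cfg.beam_enabled else None
    last_inversion: dict = {}  # row -> iteration of last accepted inversion
    inversion_count: dict = {}  # row -> accepted inversions so far
    # rows that co-occur in some analysis pedigree (their inversion scores
    # are computed assuming the other's table is fixed)
    neighbours: dict = {i: set() for i in range(n)}
    for cd in ctx_data:
        members = [r for r in cd.rows if r >= 0]
        for a in members:
            neighbours[a].update(m for m in members if m != a)
    diag_rows = []
    events = []  # accepted inversions: (iteration, id, position, score)
    per_ind_dp = np.zeros(n)
    converged = False
    iters_run = 0

    for it in range(1, cfg.max_iterations + 1):
        iters_run = it
        ledger = VoteLedger.empty(skew.ids, skew.p.shape[1])
        total_ll = 0.0
        for cd in ctx_data:
            skew7 = np.full((N_MEMBERS, len(cols)), 0.5)
            for k in range(N_MEMBERS):
                if cd.rows[k] >= 0:
                    skew7[k] = skew.p[cd.rows[k], cols]
            post = cd.engine.posterior(
                skew7,
                beam_threshold=beam,
                beam_warmup=cfg.beam_warmup,
                want_inversion=cfg.inversion_enabled,
            )
            total_ll += post.log_likelihood
            accumulate_votes(ledger, cd.ctx, post, skew7, cd.rows, cols,
                             scale=("logit" if cfg.vote_aggregation == "logit"
                                    else "probability"))

        p_old = skew.p[:, cols].copy()

        # inversions first, on the table the scores were computed for:
        # greedy by score, at most one per individual, never two coupled
        # individuals in the same iteration, with a cooldown.  Pending votes
        # for complemented cells are re-expressed in the new labelling
        # (deviations change sign under a strand relabel).
        n_inv = 0
        if cfg.inversion_enabled:
            inv = ledger.inversion[:, cols]
            best_j = np.argmax(inv, axis=1)
            best_s = inv[np.arange(n), best_j]
            order = np.argsort(-best_s, kind="stable")
            blocked: set = set()
            for i in order:
                if best_s[i] <= cfg.inversion_threshold:
                    break
                if i in blocked:
                    continue
                prev = last_inversion.get(i)
                # the cooldown doubles with every accepted inversion of the
                # same individual-chromosome: a repeatedly re-inverted region
                # signals two near-equal optima, and relatives need several
                # clamp-limited iterations to adapt before the score is
                # trustworthy again
                cool = cfg.inversion_cooldown * 2 ** max(
                    0, inversion_count.get(i, 0) - 1)
                if prev is not None and it - prev <= cool:
                    continue
                flipped = apply_inversion(skew, skew.ids[i], cols,
                                          int(best_j[i]))
                ledger.votes[i, flipped] *= -1.0
                last_inversion[i] = it
                inversion_count[i] = inversion_count.get(i, 0) + 1
                events.append((it, skew.ids[i], int(best_j[i]),
                               float(best_s[i])))
                blocked.add(i)
                blocked.update(neighbours[i])
                n_inv += 1

        # clamped update (anchors bypass)
        p_prior = skew.p[:, cols]
        delta = ledger.votes[:, cols]
        if cfg.vote_aggregation == "logit":
            # combine independent analyses as likelihood evidence
            p_raw = _sigmoid(_logit(p_prior) + delta)
        elif cfg.vote_aggregation == "mean":
            wsum = ledger.weight[:, cols]
            p_raw = p_prior + delta / np.where(wsum > 0, wsum, 1.0)
        else:  # plain deviation sum
            p_raw = p_prior + delta
        p_new = clamp_update(p_prior, p_raw)
        anchor_sub = skew.anchor[:, cols]
        p_new[anchor_sub] = 0.0
        skew.p[:, cols] = p_new

        # symmetric-anchor rescue: an individual whose whole chromosome is
        # still near 0.5 is stuck on an uninformative anchor; move it
        if it == cfg.reanchor_iteration:
            _reanchor(skew, cols, cfg.reanchor_band)

        per_ind_dp = np.abs(skew.p[:, cols] - p_old).sum(axis=1)
        worst = int(np.argmax(per_ind_dp))
        diag_rows.append(
            dict(chrom=chrom, iteration=it, total_loglik=total_ll,
                 n_inversions=n_inv, sum_abs_dp=float(per_ind_dp.sum()),
                 max_individual_dp=float(per_ind_dp.max()),
                 max_dp_id=skew.ids[worst])
        )
        if per_ind_dp.max() < cfg.tolerance:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"chromosome {chrom}: no convergence within "
            f"{cfg.max_iterations} iterations "
            f"(max individual sum|dp| = {per_ind_dp.max():.4g})"
        )
    return diag_rows, per_ind_dp, iters_run, converged, events


def _reanchor(skew: SkewnessTable, cols, band: float):
    for i in range(skew.p.shape[0]):
        hets = np.flatnonzero(skew.het[i, cols])
        if len(hets) < 2:
            continue
        anchors = np.flatnonzero(skew.anchor[i, cols])
        if len(anchors) == 0:
            continue
        a = anchors[0]
        others = cols[hets[hets != a]]
        if np.all(np.abs(skew.p[i, others] - 0.5) <= band):
            nxt = hets[hets > a]
            if len(nxt) == 0:
                continue
            skew.anchor[i, cols[a]] = False
            skew.p[i, cols[a]] = 0.5
            skew.anchor[i, cols[nxt[0]]] = True
            skew.p[i, cols[nxt[0]]] = 0.0


# ---------------------------------------------------------------------------
# inversion scan as a standalone query (testing surface)
# ---------------------------------------------------------------------------

def inversion_scan(iid: str, chrom: str, contexts, genotypes: GenotypeMatrix,
                   mmap: MarkerMap, skew: SkewnessTable,
                   cfg: Optional[TrainerConfig] = None):
    """Score every position on ``chrom`` for inverting ``iid``'s downstream
    skewness: summed log-likelihood delta over all analysis pedigrees that
    contain the individual.  Returns list of (position, score)."""
    cfg = cfg or TrainerConfig()
    cols = mmap.chrom_indices(chrom)
    distances = mmap.interval_distances(chrom)
    relevant = [c for c in contexts if iid in c.member_ids]
    scores = np.zeros(len(cols))
    for cd in _prepare_contexts(relevant, genotypes, cols, distances, cfg):
        skew7 = np.full((N_MEMBERS, len(cols)), 0.5)
        for k in range(N_MEMBERS):
            if cd.rows[k] >= 0:
                skew7[k] = skew.p[cd.rows[k], cols]
        post = cd.engine.posterior(skew7, want_inversion=True)
        for k, mid in enumerate(cd.ctx.member_ids):
            if mid == iid:
                d = post.inversion_delta[k]
                scores += np.where(np.isfinite(d), d, 0.0)
    return list(enumerate(scores))


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def train(ped: Pedigree, genotypes: GenotypeMatrix, mmap: MarkerMap,
          cfg: Optional[TrainerConfig] = None,
          contexts=None) -> TrainResult:
    """Run the whole training loop over all chromosomes.

    Chromosomes are linkage-independent and trained separately (in parallel
    when ``cfg.n_workers > 1``; results are identical to the serial run)."""
    cfg = cfg or TrainerConfig()
    cfg.validate()
    if contexts is None:
        contexts = build_analysis_contexts(
            ped, depth=cfg.depth if cfg.depth in (2, 3) else 3
        )
    skew = initialize_skewness(ped, genotypes, mmap)

    chroms = mmap.chromosomes
    jobs = [
        (chrom, mmap.chrom_indices(chrom), mmap.interval_distances(chrom))
        for chrom in chroms
    ]

    def run_one(chrom, cols, distances):
        local = skew.copy()
        out = _train_chromosome(chrom, contexts, genotypes, local, cols,
                                distances, cfg)
        return chrom, cols, local.p[:, cols], local.anchor[:, cols], out

    if cfg.n_workers > 1 and len(jobs) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=cfg.n_workers)(
            delayed(run_one)(*job) for job in jobs
        )
    else:
        results = [run_one(*job) for job in jobs]

    diag_rows, final_rows, inv_rows = [], [], []
    iterations, converged = {}, {}
    for chrom, cols, p_sub, anchor_sub, out in results:
        skew.p[:, cols] = p_sub
        skew.anchor[:, cols] = anchor_sub
        rows, per_ind_dp, iters_run, conv, events = out
        diag_rows.extend(rows)
        iterations[chrom] = iters_run
        converged[chrom] = conv
        for it, iid, pos, score in events:
            inv_rows.append(dict(chrom=chrom, iteration=it, id=iid,
                                 position=pos, score=score))
        for i, iid in enumerate(skew.ids):
            final_rows.append(
                dict(chrom=chrom, id=iid, sum_abs_dp=float(per_ind_dp[i]))
            )

    return TrainResult(
        skewness=skew,
        diagnostics=pd.DataFrame(diag_rows),
        iterations=iterations,
        converged=converged,
        final_delta=pd.DataFrame(final_rows),
        inversions=pd.DataFrame(
            inv_rows, columns=["chrom", "iteration", "id", "position", "score"]
        ),
    )
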