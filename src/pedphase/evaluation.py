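"""Accuracy of inferred haplotypes against simulated truth.

The strand labelling of inferred haplotypes is arbitrary per
individual-chromosome (it is only defined relative to the anchor marker), so
every individual-chromosome is scored under the better of the two global
strand orientations.  A heterozygous marker is *correctly phased* if its
ordered pair matches truth under that orientation; unphased sites count as
incorrect.  An individual is *perfectly phased* iff all its heterozygous
markers on all chromosomes are correct.

Homozygous and missing loci have no phase, so the headline marker accuracy
is over heterozygous loci only; an all-marker variant (homozygous loci in
the denominator, correct when the unordered genotype matches truth) is also
reported, as published per-marker accuracies are often quoted that way.
Switch errors (adjacent phased heterozygote pairs whose relative phase
disagrees with truth) are reported as a supplementary diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .pedio import InputError, MarkerMap, Pedigree, PhasedHaplotypes


@dataclass
class AccuracyReport:
    per_generation: pd.DataFrame   # generation, n_individuals, perfect_frac,
                                   # het_accuracy, all_accuracy, n_het
    per_individual: pd.DataFrame   # id, generation, n_het, n_correct, perfect
    switch_errors: pd.DataFrame    # id, chrom, n_switch
    error_positions: Dict[str, List[int]]

    @property
    def overall(self) -> pd.Series:
        return self.per_generation.set_index("generation").loc["all"]

    def to_table(self) -> str:
        """Human-readable per-generation accuracy table."""
        lines = ["Generation  Perfectly phased individuals  "
                 "Correctly phased markers (het)  (all)"]
        for _, r in self.per_generation.iterrows():
            lines.append(
                f"{str(r['generation']):>10}  "
                f"{100 * r['perfect_frac']:27.2f}%  "
                f"{100 * r['het_accuracy']:29.2f}%  "
                f"{100 * r['all_accuracy']:5.2f}%"
            )
        return "\n".join(lines)


def _strands_of(obj) -> tuple:
    """Accept PhasedHaplotypes or TruthSet-like (ids/strands) objects."""
    phased = getattr(obj, "phased", None)
    if phased is None:
        phased = np.ones(obj.strands.shape[:2], dtype=bool)
    return list(obj.ids), np.asarray(obj.strands), np.asarray(phased)


def phase_accuracy(inferred, truth, ped: Pedigree,
                   mmap: MarkerMap) -> AccuracyReport:
    """Score inferred haplotypes against truth, per generation."""
    ids_i, st_i, ph_i = _strands_of(inferred)
    ids_t, st_t, _ = _strands_of(truth)
    if st_i.shape[1] != st_t.shape[1]:
        raise InputError(
            f"marker sets differ: {st_i.shape[1]} inferred vs "
            f"{st_t.shape[1]} truth markers"
        )
    if st_i.shape[1] != mmap.n_markers:
        raise InputError("marker map does not match haplotype matrices")
    t_index = {iid: k for k, iid in enumerate(ids_t)}

    chrom_cols = [mmap.chrom_indices(c) for c in mmap.chromosomes]
    rows = []
    err_pos: Dict[str, List[int]] = {}
    sw_rows = []
    for i, iid in enumerate(ids_i):
        t = t_index[iid]
        het = st_t[t, :, 0] != st_t[t, :, 1]
        geno_ok = np.sort(st_i[i], axis=1) == np.sort(st_t[t], axis=1)
        geno_ok = geno_ok.all(axis=1)
        n_het = n_correct = 0
        n_all = n_all_correct = 0
        wrong: List[int] = []
        for chrom, cols in zip(mmap.chromosomes, chrom_cols):
            same = (st_i[i, cols] == st_t[t, cols]).all(axis=1)
            swap = (st_i[i, cols] == st_t[t, cols][:, ::-1]).all(axis=1)
            h = het[cols]
            ok_same = same & ph_i[i, cols]
            ok_swap = swap & ph_i[i, cols]
            # orientation freedom: pick the better global strand labelling
            if (ok_same & h).sum() >= (ok_swap & h).sum():
                ok = ok_same
            else:
                ok = ok_swap
            n_het += int(h.sum())
            n_correct += int((ok & h).sum())
            n_all += int(geno_ok[cols].sum())
            n_all_correct += int(((ok & h) | (~h & geno_ok[cols])).sum())
            wrong.extend(int(c) for c in cols[h & ~ok])
            sw_rows.append(
                dict(id=iid, chrom=chrom,
                     n_switch=_switch_count(
                         st_i[i, cols], st_t[t, cols],
                         h & ph_i[i, cols]))
            )
        rows.append(
            dict(id=iid, generation=ped.generation_of(iid), n_het=n_het,
                 n_correct=n_correct, n_all=n_all,
                 n_all_correct=n_all_correct,
                 perfect=n_correct == n_het)
        )
        if wrong:
            err_pos[iid] = wrong

    per_ind = pd.DataFrame(rows)
    gen_rows = []
    groups = list(per_ind.groupby("generation")) + [("all", per_ind)]
    for gen, sub in groups:
        n_het = int(sub["n_het"].sum())
        n_all = int(sub["n_all"].sum())
        gen_rows.append(
            dict(
                generation=str(gen),
                n_individuals=len(sub),
                perfect_frac=float(sub["perfect"].mean()),
                het_accuracy=(
                    float(sub["n_correct"].sum()) / n_het if n_het else 1.0
                ),
                all_accuracy=(
                    float(sub["n_all_correct"].sum()) / n_all if n_all else 1.0
                ),
                n_het=n_het,
            )
        )
    return AccuracyReport(
        per_generation=pd.DataFrame(gen_rows),
        per_individual=per_ind.drop(columns=["n_all", "n_all_correct"]),
        switch_errors=pd.DataFrame(sw_rows),
        error_positions=err_pos,
    )


def _switch_count(inf: np.ndarray, tru: np.ndarray,
                  usable: np.ndarray) -> int:
    """Switch errors on one individual-chromosome: adjacent usable
    (phased heterozygous) sites whose relative phase flips versus truth."""
    sites = np.flatnonzero(usable)
    if len(sites) < 2:
        return 0
    agree = (inf[sites] == tru[sites]).all(axis=1)
    return int((agree[1:] != agree[:-1]).sum())


def switch_errors(inferred, truth, mmap: MarkerMap) -> pd.DataFrame:
    """Standalone switch-error counts per (individual, chromosome)."""
    ids_i, st_i, ph_i = _strands_of(inferred)
    ids_t, st_t, _ = _strands_of(truth)
    t_index = {iid: k for k, iid in enumerate(ids_t)}
    rows = []
    for i, iid in enumerate(ids_i):
        t = t_index[iid]
        het = st_t[t, :, 0] != st_t[t, :, 1]
        for chrom in mmap.chromosomes:
            cols = mmap.chrom_indices(chrom)
            rows.append(
                dict(id=iid, chrom=chrom,
                     n_switch=_switch_count(st_i[i, cols], st_t[t, cols],
                                            (het & ph_i[i])[cols]))
            )
    return pd.DataFrame(rows)
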