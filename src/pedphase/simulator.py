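"""Synthetic multi-generational cross with known truth haplotypes.

The generator emulates the structure of a dense livestock-style mapping
population: a small founder set (default 20 founders, 5 sires each mated to
3 dams), five generations, and an evenly spaced SNP map (default 1 cM
spacing at a uniform 1 cM/Mbp rate).  Founder haplotypes are i.i.d.
Bernoulli draws -- linkage disequilibrium among founders is irrelevant to
the linkage-driven phasing mechanism under test, and a hook accepts
externally supplied founder haplotypes instead.

Meioses follow Haldane's no-interference model: an independent crossover
indicator per marker interval with probability ``haldane(d)``, matching the
transition model of the phasing HMM.  Each offspring strand is therefore a
mosaic of the corresponding parent's two strands; the full mosaic (and every
breakpoint) is recorded as ground truth.

Breeding individuals for generations 3+ are chosen from distinct broods with
disjoint parents, so no local analysis pedigree contains the same ancestor
twice (the emission model treats the members of a local pedigree as
distinct).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .pedio import (
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    PhasedHaplotypes,
    write_genotypes,
    write_marker_map,
    write_pedigree,
    write_phased,
)
from .hmm_core import haldane


class ConfigError(ValueError):
    """Infeasible simulation design."""


@dataclass
class SimConfig:
    """Simulation design parameters.

    The defaults are the reduced-scale study conditions used throughout the
    test suite: a 5-generation cross with 20 founders (5 sires x 3 dams
    each), 8 offspring per mating, and 2 chromosomes x 100 markers at 1 cM
    spacing with founder allele frequency 0.5 and clean genotypes.
    """

    n_founders: int = 20
    founder_sires: int = 5
    generations: int = 5
    matings_per_sire: int = 3        # founder sires
    breeding_sires: int = 4          # generations 3+
    breeding_matings_per_sire: int = 2
    offspring_per_mating: int = 8
    chromosomes: int = 2
    markers_per_chromosome: int = 100
    spacing_cm: float = 1.0
    founder_allele_freq: float = 0.5
    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def validate(self):
        counts = (
            self.n_founders, self.founder_sires, self.generations,
            self.matings_per_sire, self.breeding_sires,
            self.breeding_matings_per_sire, self.offspring_per_mating,
            self.chromosomes, self.markers_per_chromosome,
        )
        if any(c < 1 for c in counts):
            raise ConfigError("all design counts must be >= 1")
        for r in (self.founder_allele_freq, self.missing_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.spacing_cm <= 0:
            raise ConfigError("marker spacing must be > 0")
        if self.founder_sires * self.matings_per_sire > self.n_founders - self.founder_sires:
            raise ConfigError(
                "founder design needs "
                f"{self.founder_sires * self.matings_per_sire} dams but only "
                f"{self.n_founders - self.founder_sires} non-sire founders exist"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Ground-truth haplotypes: ``strands[i, j, 0]`` is the paternal (from
    sire) and ``strands[i, j, 1]`` the maternal strand allele of individual
    ``i`` at marker ``j`` (founders: arbitrary labelling as drawn).
    ``breakpoints[(child_id, 'pat'|'mat')]`` lists global marker-interval
    indices where the transmitting meiosis crossed over."""

    ids: list
    strands: np.ndarray  # (n, M, 2) uint8
    breakpoints: dict = field(default_factory=dict)

    def __post_init__(self):
        self.index = {iid: k for k, iid in enumerate(self.ids)}

    def to_phased(self) -> PhasedHaplotypes:
        n, m, _ = self.strands.shape
        return PhasedHaplotypes(
            ids=list(self.ids),
            strands=self.strands.copy(),
            phased=np.ones((n, m), dtype=bool),
        )


def build_map(cfg: SimConfig) -> MarkerMap:
    """Evenly spaced map: chromosomes '1'..'C', positions k * spacing_cm."""
    pos = {
        str(c + 1): np.arange(cfg.markers_per_chromosome) * cfg.spacing_cm
        for c in range(cfg.chromosomes)
    }
    return MarkerMap.from_positions(pos, unit="cM")


def simulate_founders(cfg: SimConfig, rng: np.random.Generator,
                      n_markers: int) -> np.ndarray:
    """Founder strands (n_founders, M, 2): allele 2 with probability
    ``founder_allele_freq``, else allele 1, i.i.d. per strand and marker."""
    draws = rng.random((cfg.n_founders, n_markers, 2))
    return np.where(draws < cfg.founder_allele_freq, 2, 1).astype(np.uint8)


def simulate_meiosis(parent_strands: np.ndarray, mmap: MarkerMap,
                     rng: np.random.Generator):
    """One gamete from a parent's two strands.

    Per chromosome: the starting strand is uniform, and the source strand
    switches at each marker interval independently with probability
    ``haldane(d)``.  Returns (gamete (M,), breakpoint interval indices).
    """
    M = parent_strands.shape[0]
    gamete = np.empty(M, dtype=np.uint8)
    breaks = []
    for chrom in mmap.chromosomes:
        idx = mmap.chrom_indices(chrom)
        r = haldane(mmap.interval_distances(chrom))
        start = rng.integers(2)
        xo = rng.random(len(r)) < r
        src = (start + np.concatenate([[0], np.cumsum(xo)])) % 2
        gamete[idx] = parent_strands[idx, src]
        breaks.extend(int(idx[k]) for k in np.flatnonzero(xo))
    return gamete, breaks


def simulate_cross(cfg: SimConfig,
                   founder_strands: Optional[np.ndarray] = None):
    """Gene-drop a full cross.

    Returns ``(pedigree, genotypes, truth, marker_map)``.  ``founder_strands``
    optionally overrides the i.i.d. founder draw (shape (n_founders, M, 2),
    alleles 1/2).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mmap = build_map(cfg)
    M = mmap.n_markers

    if founder_strands is None:
        founder_strands = simulate_founders(cfg, rng, M)
    elif founder_strands.shape != (cfg.n_founders, M, 2):
        raise ConfigError(
            f"founder_strands shape {founder_strands.shape} != "
            f"{(cfg.n_founders, M, 2)}"
        )

    ids: list = []
    records: list = []  # (id, sire, dam)
    strands: list = []
    breakpoints: dict = {}
    parents_of: dict = {}  # id -> (sire, dam) for brood bookkeeping

    def add(iid, sire, dam, st):
        ids.append(iid)
        records.append((iid, sire, dam))
        strands.append(st)
        parents_of[iid] = (sire, dam)

    for k in range(cfg.n_founders):
        add(f"G1_{k:03d}", None, None, founder_strands[k])

    def drop_child(iid, sire, dam):
        pat, b_pat = simulate_meiosis(strands[ids.index(sire)], mmap, rng)
        mat, b_mat = simulate_meiosis(strands[ids.index(dam)], mmap, rng)
        breakpoints[(iid, "pat")] = b_pat
        breakpoints[(iid, "mat")] = b_mat
        add(iid, sire, dam, np.stack([pat, mat], axis=-1))

    prev = list(ids)  # founder generation
    for g in range(2, cfg.generations + 1):
        if g == 2:
            sires = prev[: cfg.founder_sires]
            dams = prev[cfg.founder_sires:
                        cfg.founder_sires * (1 + cfg.matings_per_sire)]
            matings = [
                (s, dams[i * cfg.matings_per_sire + j])
                for i, s in enumerate(sires)
                for j in range(cfg.matings_per_sire)
            ]
        else:
            matings = _select_matings(prev, parents_of, cfg)
        offspring = []
        for mk, (sire, dam) in enumerate(matings):
            for c in range(cfg.offspring_per_mating):
                iid = f"G{g}_{mk:03d}_{c:03d}"
                drop_child(iid, sire, dam)
                offspring.append(iid)
        prev = offspring

    truth = TruthSet(ids=list(ids), strands=np.stack(strands),
                     breakpoints=breakpoints)
    ped = Pedigree.from_records(records)

    geno = np.sort(truth.strands, axis=2).astype(np.uint8)
    if cfg.error_rate > 0:
        flip = rng.random(geno.shape) < cfg.error_rate
        geno = np.where(flip, 3 - geno, geno).astype(np.uint8)
        geno = np.sort(geno, axis=2)
    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape[:2]) < cfg.missing_rate
        geno[miss] = 0
    genotypes = GenotypeMatrix(ids=list(ids), data=geno)
    return ped, genotypes, truth, mmap


def _select_matings(prev, parents_of, cfg: SimConfig):
    """Choose breeding sires/dams from distinct broods with disjoint parents."""
    n_s = cfg.breeding_sires
    n_d_each = cfg.breeding_matings_per_sire
    by_brood: dict = {}
    for iid in prev:
        by_brood.setdefault(parents_of[iid], []).append(iid)
    broods = list(by_brood.items())
    if len(broods) < 2:
        raise ConfigError("need at least two broods to avoid sib matings")
    sires = []
    used = set()
    for b in range(min(n_s, len(broods))):
        cand = broods[b][1][0]
        sires.append(cand)
        used.add(cand)
    while len(sires) < n_s:  # more sires than broods: reuse broods
        for b in range(len(broods)):
            for cand in by_brood[broods[b][0]]:
                if cand not in used:
                    sires.append(cand)
                    used.add(cand)
                    break
            if len(sires) == n_s:
                break
    matings = []
    for sire in sires:
        sp = set(parents_of[sire])
        taken = 0
        for brood_parents, members in broods:
            if taken == n_d_each:
                break
            if sp & set(brood_parents):
                continue  # full or half sibs of the sire
            for cand in members:
                if cand in used:
                    continue
                used.add(cand)
                matings.append((sire, cand))
                taken += 1
                break
        if taken < n_d_each:
            raise ConfigError(
                f"cannot find {n_d_each} unrelated dams for sire {sire}"
            )
    return matings


# ---------------------------------------------------------------------------
# file output (same formats pedio reads)
# ---------------------------------------------------------------------------

def write_simulation(out_dir, ped: Pedigree, genotypes: GenotypeMatrix,
                     truth: TruthSet, mmap: MarkerMap) -> dict:
    """Write pedigree/map/genotypes/truth under ``out_dir``; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.tsv",
        "map": out / "markers.tsv",
        "genotypes": out / "genotypes.tsv",
        "truth": out / "truth.tsv",
    }
    write_pedigree(ped, paths["pedigree"])
    write_marker_map(mmap, paths["map"])
    write_genotypes(genotypes, paths["genotypes"], marker_ids=mmap.marker_ids)
    write_phased(truth.to_phased(), paths["truth"], fmt="tsv", marker_map=mmap)
    return paths
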