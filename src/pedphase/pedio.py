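"""Data model and I/O for pedigrees, marker maps, genotypes and phased output.

The containers here are deliberately thin wrappers around pandas/numpy
structures:

* :class:`Pedigree` -- individuals with sire/dam links and derived generation
  numbers (longest ancestor chain, founders = generation 1).
* :class:`MarkerMap` -- per-chromosome ordered marker positions, stored in
  Morgans internally.
* :class:`GenotypeMatrix` -- unordered biallelic genotypes, alleles coded
  1/2 with 0 as the missing sentinel.
* :class:`AnalysisContext` -- the local pedigree around one focus individual
  (parents + grandparents), the unit of one HMM analysis.
* :class:`PhasedHaplotypes` -- hardened two-strand output plus a per-site
  phased mask.

File dialects are plain-text: a documented TSV for each object, plus classic
whitespace PED for pedigrees/genotypes and VCF v4.2 (via pysam) for phased
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING_CODES = {"0", "NA", "", ".", "-", "nan"}

#: role order of the (up to) seven members of a depth-3 analysis pedigree:
#: focus, sire, dam, sire's sire, sire's dam, dam's sire, dam's dam
MEMBER_ROLES = ("focus", "sire", "dam", "ss", "sd", "ds", "dd")


class InputError(ValueError):
    """Malformed input file or inconsistent dimensions."""


class PedigreeError(ValueError):
    """Structural pedigree problem (cycle, duplicate id)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Pedigree with derived generation numbers.

    ``table`` has columns ``id``, ``sire``, ``dam`` (``None`` = unknown) and
    ``generation`` (int, founders = 1, otherwise 1 + max over known parents,
    i.e. longest ancestor chain -- so a founder x generation-2 mating yields a
    generation-3 offspring).
    """

    table: pd.DataFrame
    index: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "Pedigree":
        ids, sires, dams = [], [], []
        seen = set()
        for rec in records:
            iid, sire, dam = rec
            iid = str(iid)
            if iid in seen:
                raise PedigreeError(f"duplicate individual id {iid!r}")
            seen.add(iid)
            ids.append(iid)
            sires.append(_norm_parent(sire))
            dams.append(_norm_parent(dam))
        # referenced parents without their own record are unknown founders:
        # treat the link as missing but warn once
        dangling = {p for p in sires + dams if p is not None and p not in seen}
        if dangling:
            warnings.warn(
                f"{len(dangling)} referenced parent id(s) have no pedigree "
                f"record; treated as unknown founders: {sorted(dangling)[:5]}"
            )
            sires = [None if s in dangling else s for s in sires]
            dams = [None if d in dangling else d for d in dams]
        generation = _assign_generations(ids, sires, dams)
        table = pd.DataFrame(
            {"id": ids, "sire": sires, "dam": dams, "generation": generation}
        )
        return cls(table=table, index={iid: k for k, iid in enumerate(ids)})

    # -- queries ------------------------------------------------------------

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    @property
    def n(self) -> int:
        return len(self.table)

    def parents_of(self, iid: str) -> tuple:
        row = self.table.iloc[self.index[iid]]
        return row["sire"], row["dam"]

    def generation_of(self, iid: str) -> int:
        return int(self.table.iloc[self.index[iid]]["generation"])

    @property
    def founders(self) -> list:
        t = self.table
        return list(t.loc[t["sire"].isna() & t["dam"].isna(), "id"])

    def offspring_count(self, iid: str) -> int:
        """Number of pedigree offspring of ``iid`` (as sire or dam)."""
        t = self.table
        return int(((t["sire"] == iid) | (t["dam"] == iid)).sum())


def _norm_parent(p) -> Optional[str]:
    if p is None:
        return None
    p = str(p).strip()
    return None if p in MISSING_CODES else p


def _assign_generations(ids, sires, dams) -> list:
    """Longest-ancestor-chain depth; founders (no known parent) = 1."""
    parent = {i: (s, d) for i, s, d in zip(ids, sires, dams)}
    gen: dict = {}
    state: dict = {}  # 1 = on stack, 2 = done

    def visit(i, chain):
        if i in gen:
            return gen[i]
        if state.get(i) == 1:
            raise PedigreeError(
                f"pedigree cycle detected involving {i!r} (chain {chain})"
            )
        state[i] = 1
        s, d = parent[i]
        g = 1 + max(
            (visit(p, chain + [i]) for p in (s, d) if p is not None), default=0
        )
        state[i] = 2
        gen[i] = g
        return g

    return [visit(i, []) for i in ids]


def read_pedigree(path, dialect: str = "tsv") -> Pedigree:
    """Read a pedigree file.

    ``tsv``: header with columns id, sire, dam (extra columns ignored).
    ``ped``: classic whitespace PED; columns fam, id, sire, dam, ...
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"id", "sire", "dam"} - set(df.columns)
        if missing:
            raise InputError(f"pedigree file {path} lacks columns {missing}")
        recs = list(df[["id", "sire", "dam"]].itertuples(index=False, name=None))
    elif dialect == "ped":
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        if df.shape[1] < 4:
            raise InputError(f"PED file {path} has fewer than 4 columns")
        recs = list(df[[1, 2, 3]].itertuples(index=False, name=None))
    else:
        raise InputError(f"unknown pedigree dialect {dialect!r}")
    return Pedigree.from_records(recs)


def write_pedigree(ped: Pedigree, path, dialect: str = "tsv") -> None:
    path = Path(path)
    t = ped.table
    if dialect == "tsv":
        out = t[["id", "sire", "dam"]].fillna("0")
        out.to_csv(path, sep="\t", index=False)
    elif dialect == "ped":
        out = pd.DataFrame(
            {
                "fam": "FAM1",
                "id": t["id"],
                "sire": t["sire"].fillna("0"),
                "dam": t["dam"].fillna("0"),
                "sex": 0,
                "pheno": -9,
            }
        )
        out.to_csv(path, sep=" ", index=False, header=False)
    else:
        raise InputError(f"unknown pedigree dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Ordered marker positions per chromosome, positions in Morgans.

    ``table`` columns: chrom (str), marker (str), pos_m (float, Morgans),
    bp (float, may be NaN). Row order is the global marker order; all markers
    of one chromosome are contiguous and non-decreasing in position.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if not np.all(np.isfinite(t["pos_m"])) or (t["pos_m"] < 0).any():
            raise InputError("marker positions must be finite and >= 0")
        for chrom, sub in t.groupby("chrom", sort=False):
            d = np.diff(sub["pos_m"].to_numpy())
            if (d < 0).any():
                raise InputError(f"non-monotonic positions on chromosome {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def marker_ids(self) -> list:
        return list(self.table["marker"])

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Global row indices of the markers on ``chrom``."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def interval_distances(self, chrom: str) -> np.ndarray:
        """Map distances (Morgans) between adjacent markers on ``chrom``."""
        pos = self.table["pos_m"].to_numpy()[self.chrom_indices(chrom)]
        return np.diff(pos)

    @classmethod
    def from_positions(cls, chrom_positions: dict, unit: str = "cM") -> "MarkerMap":
        """Build a map from ``{chrom: array of positions}`` (cM or Morgans)."""
        scale = 0.01 if unit == "cM" else 1.0
        rows = []
        for chrom, pos in chrom_positions.items():
            for k, p in enumerate(np.asarray(pos, dtype=float)):
                rows.append((str(chrom), f"{chrom}_m{k}", p * scale, np.nan))
        return cls(pd.DataFrame(rows, columns=["chrom", "marker", "pos_m", "bp"]))


def read_marker_map(path, units: str = "cM", cm_per_mbp: float = 1.0) -> MarkerMap:
    """Read a marker map TSV (columns chrom, marker, pos).

    ``units='cM'`` reads pos in centimorgans; ``units='Mbp'`` reads physical
    megabase positions and converts at ``cm_per_mbp`` (default 1, a uniform
    1 cM/Mbp genome).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "marker": str})
    missing = {"chrom", "marker", "pos"} - set(df.columns)
    if missing:
        raise InputError(f"marker map {path} lacks columns {missing}")
    pos = df["pos"].astype(float)
    if units == "cM":
        pos_m = pos / 100.0
        bp = df["bp"].astype(float) if "bp" in df.columns else np.nan
    elif units == "Mbp":
        pos_m = pos * cm_per_mbp / 100.0
        bp = pos * 1e6
    else:
        raise InputError(f"unknown map units {units!r}")
    return MarkerMap(
        pd.DataFrame(
            {"chrom": df["chrom"], "marker": df["marker"], "pos_m": pos_m, "bp": bp}
        )
    )


def write_marker_map(mmap: MarkerMap, path, units: str = "cM") -> None:
    t = mmap.table
    if units == "cM":
        pos = t["pos_m"] * 100.0
    elif units == "Mbp":
        pos = t["bp"] / 1e6
    else:
        raise InputError(f"unknown map units {units!r}")
    out = pd.DataFrame({"chrom": t["chrom"], "marker": t["marker"], "pos": pos})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Unordered biallelic genotypes: ``data[i, j] = (lo, hi)`` with alleles
    in {1, 2} and (0, 0) for missing; rows follow a pedigree, columns a map."""

    ids: list
    data: np.ndarray  # (n_individuals, n_markers, 2) uint8, sorted pairs

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise InputError("genotype data must have shape (n, m, 2)")
        bad = ~np.isin(self.data, (0, 1, 2))
        if bad.any():
            i, j, _ = np.argwhere(bad)[0]
            raise InputError(
                f"unknown allele symbol at individual {self.ids[i]!r}, "
                f"marker column {j}: {self.data[i, j]}"
            )
        # any missing allele makes the pair missing; store sorted
        miss = (self.data == 0).any(axis=2)
        self.data = np.sort(self.data, axis=2)
        self.data[miss] = 0
        self.index = {iid: k for k, iid in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    def row(self, iid: str) -> np.ndarray:
        return self.data[self.index[iid]]

    def is_het(self) -> np.ndarray:
        """(n, m) bool: genotype present and heterozygous."""
        return (self.data[:, :, 0] != self.data[:, :, 1]) & (
            self.data[:, :, 0] != 0
        )

    def is_missing(self) -> np.ndarray:
        return (self.data == 0).any(axis=2)


def read_genotypes(
    path,
    dialect: str = "tsv",
    pedigree: Optional[Pedigree] = None,
    marker_map: Optional[MarkerMap] = None,
) -> GenotypeMatrix:
    """Read genotypes; ``tsv`` = id column then two allele columns per marker,
    ``ped`` = 6 leading PED columns then allele pairs. Rows are re-ordered to
    the pedigree and must cover exactly its individuals."""
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        ids = df.iloc[:, 0].astype(str).tolist()
        alleles = df.iloc[:, 1:]
    elif dialect == "ped":
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        ids = df.iloc[:, 1].astype(str).tolist()
        alleles = df.iloc[:, 6:]
    else:
        raise InputError(f"unknown genotype dialect {dialect!r}")
    if alleles.shape[1] % 2:
        raise InputError(f"odd number of allele columns in {path}")
    try:
        arr = alleles.to_numpy(dtype=float).astype(np.int64)
    except ValueError as exc:
        raise InputError(f"non-numeric allele symbol in {path}: {exc}") from None
    arr = arr.reshape(len(ids), -1, 2)
    if marker_map is not None and arr.shape[1] != marker_map.n_markers:
        raise InputError(
            f"{arr.shape[1]} marker columns but map has {marker_map.n_markers}"
        )
    if pedigree is not None:
        if sorted(ids) != sorted(pedigree.ids):
            raise InputError(
                f"genotype rows ({len(ids)}) do not match pedigree "
                f"({pedigree.n} individuals)"
            )
        order = [ids.index(i) for i in pedigree.ids]
        arr = arr[order]
        ids = pedigree.ids
    return GenotypeMatrix(ids=ids, data=arr)


def write_genotypes(g: GenotypeMatrix, path, dialect: str = "tsv",
                    marker_ids: Optional[Sequence[str]] = None) -> None:
    flat = g.data.reshape(g.n_individuals, -1)
    if dialect == "tsv":
        if marker_ids is None:
            marker_ids = [f"m{j}" for j in range(g.n_markers)]
        cols = [f"{m}_{a}" for m in marker_ids for a in (1, 2)]
        df = pd.DataFrame(flat, columns=cols)
        df.insert(0, "id", g.ids)
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "ped":
        df = pd.DataFrame(flat)
        for col, val in (("pheno", -9), ("sex", 0), ("dam", "0"), ("sire", "0")):
            df.insert(0, col, val)
        df.insert(0, "id", g.ids)
        df.insert(0, "fam", "FAM1")
        df.to_csv(path, sep=" ", index=False, header=False)
    else:
        raise InputError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Analysis contexts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisContext:
    """Local analysis pedigree around one focus individual.

    ``parent_ids`` = (sire, dam); ``grandparent_ids`` = (sire's sire,
    sire's dam, dam's sire, dam's dam); missing members are ``None``.
    ``sibling_counts`` = number of pedigree offspring of each parent (the
    focus itself counts), used to scale grandparent votes. A missing parent
    hides its own parents (missing subtree)."""

    focus_id: str
    parent_ids: tuple
    grandparent_ids: tuple
    meiosis_count: int
    sibling_counts: tuple

    @property
    def member_ids(self) -> tuple:
        """Ids in :data:`MEMBER_ROLES` order (None where absent)."""
        return (self.focus_id,) + self.parent_ids + self.grandparent_ids


def build_analysis_contexts(
    ped: Pedigree,
    focus_policy: str = "all_nonfounders",
    focus_ids: Optional[Sequence[str]] = None,
    depth: int = 3,
) -> list:
    """One :class:`AnalysisContext` per focus individual.

    ``focus_policy='all_nonfounders'`` uses every individual with at least one
    known parent; ``'explicit'`` uses ``focus_ids``.
    """
    if depth not in (2, 3):
        raise InputError(f"unsupported analysis depth {depth}")
    if focus_policy == "all_nonfounders":
        founders = set(ped.founders)
        chosen = [i for i in ped.ids if i not in founders]
    elif focus_policy == "explicit":
        if focus_ids is None:
            raise InputError("explicit focus policy requires focus_ids")
        chosen = [str(i) for i in focus_ids]
    else:
        raise InputError(f"unknown focus policy {focus_policy!r}")

    # offspring counts computed once
    t = ped.table
    counts = t["sire"].value_counts().add(t["dam"].value_counts(), fill_value=0)

    contexts = []
    for iid in chosen:
        sire, dam = ped.parents_of(iid)
        gps: list = [None, None, None, None]
        if depth == 3:
            if sire is not None:
                gps[0], gps[1] = ped.parents_of(sire)
            if dam is not None:
                gps[2], gps[3] = ped.parents_of(dam)
        sib = tuple(
            max(1, int(counts.get(p, 0))) if p is not None else 1
            for p in (sire, dam)
        )
        contexts.append(
            AnalysisContext(
                focus_id=iid,
                parent_ids=(sire, dam),
                grandparent_ids=tuple(gps),
                meiosis_count=2 if depth == 2 else 6,
                sibling_counts=sib,
            )
        )
    return contexts


# ---------------------------------------------------------------------------
# Phased haplotypes
# ---------------------------------------------------------------------------

@dataclass
class PhasedHaplotypes:
    """Two ordered allele strands per individual; ``phased[i, j]`` marks sites
    where the order is resolved (homozygous sites are trivially resolved).
    Strand labelling is arbitrary per individual-chromosome (anchor
    convention); comparisons must allow a global swap."""

    ids: list
    strands: np.ndarray  # (n, m, 2) uint8
    phased: np.ndarray   # (n, m) bool

    def __post_init__(self):
        self.strands = np.asarray(self.strands, dtype=np.uint8)
        self.phased = np.asarray(self.phased, dtype=bool)
        self.index = {iid: k for k, iid in enumerate(self.ids)}

    def unordered(self) -> np.ndarray:
        """Recover the unordered genotype pairs (sorted, missing -> 0)."""
        out = np.sort(self.strands, axis=2)
        out[(self.strands == 0).any(axis=2)] = 0
        return out


def write_phased(
    h: PhasedHaplotypes,
    path,
    fmt: str = "tsv",
    marker_map: Optional[MarkerMap] = None,
) -> None:
    """Write phased haplotypes as long TSV or VCF v4.2 (phased GT ``|`` where
    hardened, ``/`` where not; allele 1 -> REF, 2 -> ALT)."""
    path = Path(path)
    if fmt == "tsv":
        if marker_map is None:
            chroms = np.array(["1"] * h.strands.shape[1])
            markers = np.array([f"m{j}" for j in range(h.strands.shape[1])])
        else:
            chroms = marker_map.table["chrom"].to_numpy()
            markers = np.asarray(marker_map.marker_ids)
        n, m, _ = h.strands.shape
        df = pd.DataFrame(
            {
                "id": np.repeat(h.ids, m),
                "chrom": np.tile(chroms, n),
                "marker": np.tile(markers, n),
                "a0": h.strands[:, :, 0].ravel(),
                "a1": h.strands[:, :, 1].ravel(),
                "phased": h.phased.astype(int).ravel(),
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "vcf":
        if marker_map is None:
            raise InputError("VCF output requires a marker map")
        _write_vcf(h, path, marker_map)
    else:
        raise InputError(f"unknown phased output format {fmt!r}")


def _write_vcf(h: PhasedHaplotypes, path, mmap: MarkerMap) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "pedphase")
    t = mmap.table
    for chrom in mmap.chromosomes:
        idx = mmap.chrom_indices(chrom)
        length = int(_vcf_pos(t, idx[-1])) + 1
        header.contigs.add(str(chrom), length=length)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for iid in h.ids:
        header.add_sample(str(iid))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(mmap.n_markers):
            rec = vcf.new_record(
                contig=str(t["chrom"].iloc[j]),
                start=int(_vcf_pos(t, j)) - 1,
                alleles=("A", "C"),  # synthetic bases: 1 -> REF(A), 2 -> ALT(C)
                id=str(t["marker"].iloc[j]),
            )
            for k, iid in enumerate(h.ids):
                a0, a1 = h.strands[k, j]
                gt = (
                    None if a0 == 0 else int(a0) - 1,
                    None if a1 == 0 else int(a1) - 1,
                )
                rec.samples[str(iid)]["GT"] = gt
                rec.samples[str(iid)].phased = bool(h.phased[k, j])
            vcf.write(rec)


def _vcf_pos(t: pd.DataFrame, j: int) -> float:
    bp = t["bp"].iloc[j]
    if np.isfinite(bp):
        return bp
    # fall back to cM expressed as bp at 1 cM/Mbp
    return t["pos_m"].iloc[j] * 1e8 + 1


def read_phased(path, fmt: str = "tsv",
                marker_map: Optional[MarkerMap] = None) -> PhasedHaplotypes:
    """Read phased haplotypes written by :func:`write_phased`."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
        ids = list(dict.fromkeys(df["id"]))
        m = len(df) // len(ids)
        strands = np.stack(
            [df["a0"].to_numpy(), df["a1"].to_numpy()], axis=-1
        ).reshape(len(ids), m, 2)
        phased = df["phased"].to_numpy(bool).reshape(len(ids), m)
        return PhasedHaplotypes(ids=ids, strands=strands, phased=phased)
    if fmt == "vcf":
        import pysam

        with pysam.VariantFile(str(path)) as vcf:
            ids = list(vcf.header.samples)
            rows = []
            phased_rows = []
            for rec in vcf:
                alle = []
                ph = []
                for iid in ids:
                    gt = rec.samples[iid]["GT"]
                    alle.append(
                        [0 if a is None else a + 1 for a in gt]
                    )
                    ph.append(bool(rec.samples[iid].phased))
                rows.append(alle)
                phased_rows.append(ph)
        strands = np.array(rows, dtype=np.uint8).transpose(1, 0, 2)
        phased = np.array(phased_rows, dtype=bool).T
        return PhasedHaplotypes(ids=ids, strands=strands, phased=phased)
    raise InputError(f"unknown phased input format {fmt!r}")
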