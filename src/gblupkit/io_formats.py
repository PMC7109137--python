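"""Pedigree, phenotype and genotype containers plus readers, writers,
marker filters, mean imputation and per-individual marker summaries.

Dosages are stored as a dense ``float64`` matrix with entries in
``{0, 1, 2, nan}`` (``nan`` = missing) until imputation, after which they
may be real-valued. Positions are 1-based, chromosomes are opaque string
tokens compared for equality only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FilterError, GenotypeIOError, PedigreeError, PhenotypeIOError

logger = logging.getLogger(__name__)

#: Sentinel parent token meaning "parent not recorded".
UNKNOWN = ""

_UNKNOWN_TOKENS = {"", "0", "NA", ".", "unknown", "UNKNOWN"}


class Site(NamedTuple):
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "B"


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeTable:
    """Topologically ordered trio records (individual, sire, dam).

    Parents are either earlier individuals or :data:`UNKNOWN`. Construction
    validates uniqueness, resolvability of parents and acyclicity, and sorts
    parents-first if the input order violates that.
    """

    records: tuple[tuple[str, str, str], ...]
    generation: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", _toposort_records(self.records))

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def parents(self, individual: str) -> tuple[str, str]:
        return self._index()[individual]

    def _index(self) -> dict[str, tuple[str, str]]:
        idx = self.__dict__.get("_parent_index")
        if idx is None:
            idx = {i: (s, d) for i, s, d in self.records}
            self.__dict__["_parent_index"] = idx
        return idx

    @property
    def founders(self) -> list[str]:
        return [i for i, s, d in self.records if s == UNKNOWN and d == UNKNOWN]

    @property
    def nonfounders(self) -> list[str]:
        return [i for i, s, d in self.records if s != UNKNOWN or d != UNKNOWN]

    def subset_founders(self) -> "PedigreeTable":
        """Pedigree restricted to founders (all-unknown parents)."""
        return PedigreeTable(tuple((i, UNKNOWN, UNKNOWN) for i in self.founders))

    def subset_ancestors(self, ids: Sequence[str]) -> "PedigreeTable":
        """Pedigree restricted to ``ids`` and all of their ancestors."""
        index = self._index()
        keep: set[str] = set()
        stack = [i for i in ids]
        while stack:
            i = stack.pop()
            if i in keep or i == UNKNOWN:
                continue
            if i not in index:
                raise PedigreeError(f"id {i!r} not in pedigree")
            keep.add(i)
            stack.extend(index[i])
        return PedigreeTable(tuple(r for r in self.records if r[0] in keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["individual", "sire", "dam"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _normalize_parent(token: str) -> str:
    token = token.strip()
    return UNKNOWN if token in _UNKNOWN_TOKENS else token


def _toposort_records(
    records: Iterable[tuple[str, str, str]],
) -> tuple[tuple[str, str, str], ...]:
    recs = [(i.strip(), _normalize_parent(s), _normalize_parent(d)) for i, s, d in records]
    seen: set[str] = set()
    for i, _, _ in recs:
        if i in seen:
            raise PedigreeError(f"duplicate individual id: {i!r}")
        if not i:
            raise PedigreeError("empty individual id")
        seen.add(i)
    by_id = {i: (s, d) for i, s, d in recs}
    for i, (s, d) in by_id.items():
        for p in (s, d):
            if p != UNKNOWN and p not in by_id:
                raise PedigreeError(f"parent {p!r} of {i!r} never appears as an individual")
    # Kahn's algorithm, preserving input order among ready nodes.
    n_parents = {
        i: sum(1 for p in (s, d) if p != UNKNOWN) for i, (s, d) in by_id.items()
    }
    children: dict[str, list[str]] = {i: [] for i in by_id}
    for i, (s, d) in by_id.items():
        for p in {s, d} - {UNKNOWN}:
            children[p].append(i)
    ready = [i for i, _, _ in recs if n_parents[i] == 0]
    order: list[str] = []
    head = 0
    while head < len(ready):
        i = ready[head]
        head += 1
        order.append(i)
        for c in children[i]:
            # a child with identical sire and dam must have both satisfied
            n_parents[c] -= sum(1 for p in by_id[c] if p == i)
            if n_parents[c] == 0:
                ready.append(c)
    if len(order) != len(recs):
        on_cycle = next(i for i in by_id if i not in set(order))
        raise PedigreeError(f"pedigree contains a cycle involving {on_cycle!r}")
    return tuple((i, *by_id[i]) for i in order)


def read_pedigree(path) -> PedigreeTable:
    """Read a ``individual,sire,dam`` CSV; unknown parents are empty or "0"."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["individual", "sire", "dam"]
    if list(df.columns[:3]) != expected:
        raise PedigreeError(
            f"pedigree header must start with {','.join(expected)}; got {list(df.columns)}"
        )
    return PedigreeTable(tuple(df[expected].itertuples(index=False, name=None)))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeRecords:
    """Long-format repeated measurements: one row per (individual, year, trait)."""

    frame: pd.DataFrame  # columns: individual(str), year(int), trait(str), value(float)

    def __post_init__(self) -> None:
        df = self.frame
        dup = df.duplicated(subset=["individual", "year", "trait"])
        if dup.any():
            row = df[dup].iloc[0]
            raise PhenotypeIOError(
                "duplicate phenotype record for "
                f"({row['individual']}, {row['year']}, {row['trait']})"
            )

    @property
    def traits(self) -> list[str]:
        return sorted(self.frame["trait"].unique())

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.frame["individual"]))

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.frame[self.frame["trait"] == trait].reset_index(drop=True)

    def subset_individuals(self, ids: Sequence[str]) -> "PhenotypeRecords":
        keep = self.frame["individual"].isin(set(ids))
        return PhenotypeRecords(self.frame[keep].reset_index(drop=True))

    def write_csv(self, path) -> None:
        out = self.frame.copy()
        out["value"] = out["value"].map(lambda v: "%.10g" % v)
        out.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeRecords:
    """Read ``individual,year,trait,value`` CSV.

    "NA"/empty values are skipped (count logged); any other non-numeric value
    is rejected with its row number. Duplicate (individual, year, trait) keys
    raise :class:`PhenotypeIOError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["individual", "year", "trait", "value"]
    if list(df.columns[:4]) != expected:
        raise PhenotypeIOError(
            f"phenotype header must start with {','.join(expected)}; got {list(df.columns)}"
        )
    values = []
    keep_rows = []
    n_skipped = 0
    for rownum, raw in enumerate(df["value"], start=2):  # 1-based + header line
        token = raw.strip()
        if token in {"", "NA", "NaN", "nan"}:
            n_skipped += 1
            continue
        try:
            values.append(float(token))
        except ValueError:
            raise PhenotypeIOError(f"non-numeric value {raw!r} at row {rownum}") from None
        keep_rows.append(rownum - 2)
    if n_skipped:
        logger.info("read_phenotypes: skipped %d rows with missing values", n_skipped)
    out = df.iloc[keep_rows][["individual", "trait"]].reset_index(drop=True)
    try:
        out["year"] = df.iloc[keep_rows]["year"].astype(int).to_numpy()
    except ValueError as exc:
        raise PhenotypeIOError(f"non-integer year: {exc}") from None
    out["value"] = values
    return PhenotypeRecords(out[["individual", "year", "trait", "value"]])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x sites alt-allele dosage matrix with site metadata.

    ``dosage[i, k]`` counts alt alleles of individual ``i`` at site ``k``
    (0, 1, 2 or ``nan`` for missing; real-valued after imputation).
    """

    individual_ids: list[str]
    sites: list[Site]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individual_ids), len(self.sites)):
            raise GenotypeIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.sites)} sites"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise GenotypeIOError("duplicate individual ids in genotype matrix")
        order = sorted(range(len(self.sites)), key=lambda k: (self.sites[k].chrom, self.sites[k].pos))
        if order != list(range(len(self.sites))):
            self.sites = [self.sites[k] for k in order]
            self.dosage = self.dosage[:, order]
        prev: Site | None = None
        for s in self.sites:
            if prev is not None and s.chrom == prev.chrom and s.pos <= prev.pos:
                raise GenotypeIOError(
                    f"duplicate/non-increasing position {s.chrom}:{s.pos}"
                )
            prev = s

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def m(self) -> int:
        return len(self.sites)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def allele_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing dosages."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset(self, *, individuals: np.ndarray | None = None, sites: np.ndarray | None = None) -> "GenotypeMatrix":
        ids = self.individual_ids
        sts = self.sites
        dose = self.dosage
        if sites is not None:
            sites = np.asarray(sites)
            sts = [self.sites[k] for k in np.flatnonzero(sites)] if sites.dtype == bool else [self.sites[k] for k in sites]
            dose = dose[:, sites]
        if individuals is not None:
            individuals = np.asarray(individuals)
            keep = np.flatnonzero(individuals) if individuals.dtype == bool else individuals
            ids = [self.individual_ids[i] for i in keep]
            dose = dose[keep, :]
        return GenotypeMatrix(list(ids), list(sts), dose.copy())

    # -- writers ------------------------------------------------------------

    def write_dosage_tsv(self, path) -> None:
        """TSV dialect: rows = individuals, header columns are ``chrom:pos``,
        missing written as ``NA``."""
        with open(path, "w") as fh:
            fh.write("individual\t" + "\t".join(f"{s.chrom}:{s.pos}" for s in self.sites) + "\n")
            for i, iid in enumerate(self.individual_ids):
                cells = [
                    "NA" if np.isnan(v) else ("%d" % v if float(v).is_integer() else "%.10g" % v)
                    for v in self.dosage[i]
                ]
                fh.write(iid + "\t" + "\t".join(cells) + "\n")

    def write_vcf(self, path) -> None:
        """Plain-text VCF 4.2 with GT-only genotypes (dosages must be integral)."""
        if np.any(~np.isnan(self.dosage) & (self.dosage != np.round(self.dosage))):
            raise GenotypeIOError("cannot write non-integer dosages to VCF")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(s.chrom for s in self.sites):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.individual_ids)
                + "\n"
            )
            for k, s in enumerate(self.sites):
                col = self.dosage[:, k]
                gts = ["./." if np.isnan(v) else gt_map[int(v)] for v in col]
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.chrom}_{s.pos}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        ids = list(vcf.samples)
    except Exception as exc:  # cyvcf2 raises bare Exception on bad headers
        raise GenotypeIOError(f"malformed VCF {path}: {exc}") from None
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array([g[:2] for g in v.genotypes], dtype=float)
        dose = gts.sum(axis=1)
        dose[(gts < 0).any(axis=1)] = np.nan
        sites.append(Site(str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
        rows.append(dose)
    if n_multi:
        logger.info("read_genotypes: skipped %d multiallelic records", n_multi)
    if not sites:
        raise GenotypeIOError(f"no biallelic sites parsed from {path}")
    return GenotypeMatrix(ids, sites, np.column_stack(rows))


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "individual":
        raise GenotypeIOError("dosage TSV must have 'individual' as first column")
    sites = []
    for col in df.columns[1:]:
        try:
            chrom, pos = col.rsplit(":", 1)
            sites.append(Site(chrom, int(pos)))
        except ValueError:
            raise GenotypeIOError(f"bad dosage TSV site header {col!r}") from None
    if not sites:
        raise GenotypeIOError(f"no sites in dosage TSV {path}")
    body = df.iloc[:, 1:].replace({"NA": "nan", "": "nan"}).to_numpy(dtype=float)
    return GenotypeMatrix(list(df["individual"]), sites, body)


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field, biallelic) or the dosage-TSV dialect."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise GenotypeIOError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    rule_counts: dict[str, int]
    n_sites_in: int
    n_sites_out: int
    n_individuals_in: int
    n_individuals_out: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule_counts": self.rule_counts,
                "sites": {"in": self.n_sites_in, "out": self.n_sites_out},
                "individuals": {"in": self.n_individuals_in, "out": self.n_individuals_out},
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"sites: {self.n_sites_in} -> {self.n_sites_out}"]
        if self.n_individuals_in != self.n_individuals_out:
            lines.append(f"individuals: {self.n_individuals_in} -> {self.n_individuals_out}")
        lines += [f"  removed by {rule}: {c}" for rule, c in self.rule_counts.items()]
        return "\n".join(lines)


def _adjacency_keep(sites: Sequence[Site], keep: np.ndarray) -> np.ndarray:
    """Greedy left-to-right sweep: drop a kept site within 1 bp of the
    previously kept site on the same chromosome (lower position wins)."""
    out = keep.copy()
    last: dict[str, int] = {}
    for k, s in enumerate(sites):
        if not out[k]:
            continue
        prev = last.get(s.chrom)
        if prev is not None and s.pos - prev <= 1:
            out[k] = False
        else:
            last[s.chrom] = s.pos
    return out


def filter_sites(
    g: GenotypeMatrix,
    max_missing_frac: float = 0.10,
    min_maf: float = 0.05,
    remove_adjacent: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Site filters in order: missingness > ``max_missing_frac``,
    MAF < ``min_maf`` (non-missing dosages), then 1-bp adjacency."""
    if g.m == 0:
        raise FilterError("empty genotype matrix")
    miss_frac = g.missing_mask.mean(axis=0)
    keep = miss_frac <= max_missing_frac
    n_miss = int((~keep).sum())

    maf = np.full(g.m, np.nan)
    nonmiss_counts = (~g.missing_mask).sum(axis=0)
    ok = keep & (nonmiss_counts > 0)
    with np.errstate(invalid="ignore"):
        maf[ok] = np.minimum(g.allele_freq()[ok], 1 - g.allele_freq()[ok])
    fail_maf = keep & ((nonmiss_counts == 0) | (maf < min_maf))
    keep = keep & ~fail_maf
    n_maf = int(fail_maf.sum())

    n_adj = 0
    if remove_adjacent:
        kept2 = _adjacency_keep(g.sites, keep)
        n_adj = int(keep.sum() - kept2.sum())
        keep = kept2

    if not keep.any():
        raise FilterError(
            "all sites removed; relax max_missing_frac/min_maf or disable remove_adjacent"
        )
    report = FilterReport(
        {"missingness": n_miss, "maf": n_maf, "adjacency": n_adj},
        g.m, int(keep.sum()), g.n, g.n,
    )
    return g.subset(sites=keep), report


def filter_coverage(
    g: GenotypeMatrix,
    min_site_cov: float = 0.9,
    min_taxa_cov: float = 0.8,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Coverage-style filter: sites with call rate < ``min_site_cov``, then
    individuals with call rate < ``min_taxa_cov`` over retained sites, then
    sites with MAF < ``min_maf``."""
    if g.m == 0:
        raise FilterError("empty genotype matrix")
    called = ~g.missing_mask
    site_keep = called.mean(axis=0) >= min_site_cov
    n_site = int((~site_keep).sum())
    if not site_keep.any():
        raise FilterError("all sites removed by site-coverage filter")
    g2 = g.subset(sites=site_keep)

    taxa_keep = (~g2.missing_mask).mean(axis=1) >= min_taxa_cov
    n_taxa = int((~taxa_keep).sum())
    if not taxa_keep.any():
        raise FilterError("all individuals removed by taxa-coverage filter")
    g3 = g2.subset(individuals=taxa_keep)

    nonmiss = (~g3.missing_mask).sum(axis=0)
    maf = np.where(nonmiss > 0, g3.maf(), -1.0)
    maf_keep = maf >= min_maf
    n_maf = int((~maf_keep).sum())
    if not maf_keep.any():
        raise FilterError("all sites removed by MAF filter")
    g4 = g3.subset(sites=maf_keep)

    report = FilterReport(
        {"site_coverage": n_site, "taxa_coverage": n_taxa, "maf": n_maf},
        g.m, g4.m, g.n, g4.n,
    )
    return g4, report


def impute_mean(g: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Replace missing dosages by the per-site mean of observed dosages.

    Deterministic; ``seed`` is reserved for pluggable stochastic imputers and
    only logged. Errors on a fully missing site.
    """
    miss = g.missing_mask
    if not miss.any():
        return GenotypeMatrix(list(g.individual_ids), list(g.sites), g.dosage.copy())
    fully = miss.all(axis=0)
    if fully.any():
        k = int(np.flatnonzero(fully)[0])
        raise GenotypeIOError(
            f"site {g.sites[k].chrom}:{g.sites[k].pos} is fully missing; filter it first"
        )
    logger.info("impute_mean: seed=%d (unused by the deterministic mean imputer)", seed)
    means = np.nanmean(g.dosage, axis=0)
    dose = g.dosage.copy()
    rows, cols = np.nonzero(miss)
    dose[rows, cols] = means[cols]
    return GenotypeMatrix(list(g.individual_ids), list(g.sites), dose)


def heterozygosity(g: GenotypeMatrix) -> pd.Series:
    """Per-individual fraction of non-missing loci with dosage exactly 1."""
    nonmiss = (~g.missing_mask).sum(axis=1)
    if (nonmiss == 0).any():
        bad = g.individual_ids[int(np.flatnonzero(nonmiss == 0)[0])]
        raise GenotypeIOError(f"individual {bad!r} has no non-missing genotypes")
    het = np.nansum(g.dosage == 1, axis=1) / nonmiss
    return pd.Series(het, index=pd.Index(g.individual_ids, name="individual"), name="heterozygosity")
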