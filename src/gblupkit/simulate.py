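"""Synthetic two-generation breeding populations with known truth.

Founder haplotypes are drawn site-wise independent (HWE, linkage
equilibrium); progeny genotypes are gene-dropped through the pedigree with
Poisson-count crossovers (Haldane, no interference); phenotypes follow an
additive + permanent-environment + year + residual model with polygenic
QTL architectures, so every downstream estimate can be checked against
truth. All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SimulationError
from .io_formats import UNKNOWN, GenotypeMatrix, PedigreeTable, PhenotypeRecords, Site


@dataclass(frozen=True)
class TraitConfig:
    name: str
    h2: float
    pe_fraction: float = 0.10
    mean: float = 0.0
    phenotypic_variance: float = 1.0
    n_qtl: int = 200
    year_effects: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise SimulationError(f"trait {self.name}: h2 must be in [0,1]")
        if self.h2 + self.pe_fraction > 1.0 + 1e-12:
            raise SimulationError(f"trait {self.name}: h2 + pe_fraction exceeds 1")


# Eight traits echoing a fruit-quality panel: names, heritabilities spanning
# 0.15-0.50, and means/SDs on familiar scales.
DEFAULT_TRAITS: tuple[TraitConfig, ...] = (
    TraitConfig("AVFW", 0.50, mean=136.0, phenotypic_variance=90.0**2),
    TraitConfig("FIRM", 0.41, mean=7.8, phenotypic_variance=2.5**2),
    TraitConfig("ASTR", 0.26, mean=0.9, phenotypic_variance=1.1**2),
    TraitConfig("RUSS", 0.21, mean=2.5, phenotypic_variance=0.99**2),
    TraitConfig("SSC", 0.18, mean=15.4, phenotypic_variance=1.8**2),
    TraitConfig("TA", 0.17, mean=0.83, phenotypic_variance=0.37**2),
    TraitConfig("CRISP", 0.15, mean=3.5, phenotypic_variance=1.0**2),
    TraitConfig("JUIC", 0.15, mean=2.6, phenotypic_variance=1.2**2),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic study.

    When ``n_base_founders`` is set, an extra *unrecorded* base generation is
    simulated and the ``n_founders`` accessions are drawn as children of
    random base pairs: the panel then carries realistic genomic family
    structure (half/full sibs) while its recorded pedigree still shows
    unknown parents — the common situation for germplasm collections without
    passport data. The accessions remain the parents of the progeny
    generation, whose pedigree is recorded.
    """

    n_founders: int = 274
    n_chromosomes: int = 17
    n_snps: int = 6400
    maf_range: tuple[float, float] = (0.05, 0.5)
    chromosome_length_morgans: float = 1.0
    chromosome_length_bp: int = 30_000_000
    mean_crosses_per_parent: float = 2.0
    progeny_per_cross: int = 18
    traits: tuple[TraitConfig, ...] = DEFAULT_TRAITS
    n_years: int = 2
    progeny_years: int = 1
    n_base_founders: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.traits:
            if t.n_qtl > self.n_snps:
                raise SimulationError(f"trait {t.name}: n_qtl exceeds n_snps")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulationTruth:
    """Generative truth recorded alongside the synthetic data."""

    qtl: dict[str, pd.DataFrame]  # trait -> (site_index, chrom, pos, effect)
    true_bv: pd.DataFrame  # individuals x traits
    true_pe: pd.DataFrame
    year_effects: dict[str, list[float]]
    realized_components: pd.DataFrame  # trait x (var_a, var_pe, var_e, h2, pe_fraction)

    def write(self, prefix) -> None:
        self.true_bv.to_csv(f"{prefix}_true_bv.csv", float_format="%.10g")
        self.true_pe.to_csv(f"{prefix}_true_pe.csv", float_format="%.10g")
        self.realized_components.to_csv(f"{prefix}_components.csv", float_format="%.10g")
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(
                {
                    "year_effects": self.year_effects,
                    "qtl": {t: df.to_dict(orient="list") for t, df in self.qtl.items()},
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


def _site_layout(cfg: SimulationConfig, rng: np.random.Generator) -> list[Site]:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    half = cfg.chromosome_length_bp // 2
    sites: list[Site] = []
    for c in range(cfg.n_chromosomes):
        m = int(per_chrom[c])
        if m > half:
            raise SimulationError(
                f"cannot place {m} SNPs with >=2 bp spacing on a "
                f"{cfg.chromosome_length_bp} bp chromosome"
            )
        # positions 2*j guarantee >=2 bp spacing
        pos = 2 * np.sort(rng.choice(np.arange(1, half + 1), size=m, replace=False))
        sites.extend(Site(f"chr{c + 1:02d}", int(p)) for p in pos)
    return sites


def simulate_founders(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    prefix: str = "P",
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """HWE founder genotypes; returns (GenotypeMatrix, id -> 2 x m haplotypes)."""
    if cfg.n_snps <= 0:
        raise SimulationError("n_snps must be positive")
    n = cfg.n_founders if n is None else n
    if n <= 0:
        raise SimulationError("number of founders must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sites = _site_layout(cfg, rng)
    m = len(sites)
    lo, hi = cfg.maf_range
    p = rng.uniform(lo, hi, size=m)
    haps = rng.random((n, 2, m)) < p  # site-wise independent
    ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    dosage = haps.sum(axis=1).astype(float)
    gm = GenotypeMatrix(ids, sites, dosage)
    return gm, {iid: haps[i].astype(np.int8) for i, iid in enumerate(ids)}


# ---------------------------------------------------------------------------
# Pedigree and gene drop
# ---------------------------------------------------------------------------


def _cross_layer(
    rng: np.random.Generator,
    parent_ids: list[str],
    n_crosses: int,
    progeny_per_cross: int,
    prefix: str,
) -> list[tuple[str, str, str]]:
    records = []
    child = 1
    for _ in range(max(n_crosses, 1)):
        sire, dam = rng.choice(len(parent_ids), size=2, replace=False)
        for _ in range(progeny_per_cross):
            records.append((f"{prefix}{child:05d}", parent_ids[sire], parent_ids[dam]))
            child += 1
    return records


def simulate_pedigree(
    cfg: SimulationConfig,
    founder_ids: list[str],
    rng: np.random.Generator | None = None,
) -> PedigreeTable:
    """Random non-selfing crosses; expected crosses per parent equals
    ``mean_crosses_per_parent``, each yielding ``progeny_per_cross`` offspring."""
    if len(founder_ids) < 2:
        raise SimulationError("need at least two founders to cross")
    if cfg.mean_crosses_per_parent <= 0:
        raise SimulationError("mean_crosses_per_parent must be positive")
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n_crosses = int(round(len(founder_ids) * cfg.mean_crosses_per_parent / 2.0))
    records = [(f, UNKNOWN, UNKNOWN) for f in founder_ids]
    records += _cross_layer(rng, founder_ids, n_crosses, cfg.progeny_per_cross, "O")
    return PedigreeTable(tuple(records))


def _gamete(
    haps: np.ndarray,
    chrom_slices: list[slice],
    positions: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty(haps.shape[1], dtype=np.int8)
    for sl in chrom_slices:
        n_co = rng.poisson(cfg.chromosome_length_morgans)
        start = rng.integers(2)
        if n_co == 0:
            out[sl] = haps[start, sl]
            continue
        co_pos = np.sort(rng.uniform(0, cfg.chromosome_length_bp, size=n_co))
        # number of crossovers to the left of each site decides the source strand
        n_left = np.searchsorted(co_pos, positions[sl])
        src = (start + n_left) % 2
        seg = haps[:, sl]
        out[sl] = seg[src, np.arange(seg.shape[1])]
    return out


def gene_drop(
    haplotypes: dict[str, np.ndarray],
    ped: PedigreeTable,
    cfg: SimulationConfig,
    founder_sites: list[Site],
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree (Poisson crossovers,
    uniform positions); returns dosages for every pedigree individual."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    positions = np.array([s.pos for s in founder_sites], dtype=float)
    chroms = [s.chrom for s in founder_sites]
    chrom_slices = []
    start = 0
    for k in range(1, len(chroms) + 1):
        if k == len(chroms) or chroms[k] != chroms[k - 1]:
            chrom_slices.append(slice(start, k))
            start = k
    haps = dict(haplotypes)
    for iid, sire, dam in ped.records:
        if sire == UNKNOWN and dam == UNKNOWN:
            if iid not in haps:
                raise SimulationError(f"founder {iid!r} has no haplotypes")
            continue
        if sire not in haps or dam not in haps:
            raise SimulationError(f"individual {iid!r} has un-haplotyped parents")
        g1 = _gamete(haps[sire], chrom_slices, positions, cfg, rng)
        g2 = _gamete(haps[dam], chrom_slices, positions, cfg, rng)
        haps[iid] = np.stack([g1, g2])
    ids = ped.ids
    dosage = np.stack([haps[i].sum(axis=0) for i in ids]).astype(float)
    return GenotypeMatrix(list(ids), list(founder_sites), dosage)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    g: GenotypeMatrix,
    ped: PedigreeTable,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    records_per_individual: dict[str, int] | None = None,
) -> tuple[PhenotypeRecords, SimulationTruth]:
    """Additive QTL + permanent environment + year + residual records.

    True breeding values are QTL dosages times effects, centered and rescaled
    so their realised variance is exactly h2 * phenotypic_variance. By default
    founders receive ``n_years`` records and progeny ``progeny_years`` (one);
    ``records_per_individual`` overrides the per-individual record counts
    (ids absent from the mapping get none).
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    ids = ped.ids
    if set(ids) - set(g.individual_ids):
        raise SimulationError("genotype matrix does not cover all pedigree individuals")
    gidx = {iid: i for i, iid in enumerate(g.individual_ids)}
    order = np.array([gidx[i] for i in ids], dtype=int)
    founders = set(ped.founders)
    if records_per_individual is None:
        records_per_individual = {
            i: (cfg.n_years if i in founders else cfg.progeny_years) for i in ids
        }

    qtl_frames: dict[str, pd.DataFrame] = {}
    bv_cols: dict[str, np.ndarray] = {}
    pe_cols: dict[str, np.ndarray] = {}
    year_effects: dict[str, list[float]] = {}
    comp_rows = []
    rows: list[tuple[str, int, str, float]] = []

    n_years_max = max(
        cfg.n_years, cfg.progeny_years, max(records_per_individual.values(), default=0)
    )
    for trait in cfg.traits:
        var_p = trait.phenotypic_variance
        var_e = (1.0 - trait.h2 - trait.pe_fraction) * var_p
        if var_e < -1e-12:
            raise SimulationError(f"trait {trait.name}: negative residual variance")
        var_e = max(var_e, 0.0)
        qtl_idx = np.sort(rng.choice(g.m, size=trait.n_qtl, replace=False))
        effects = rng.standard_normal(trait.n_qtl)
        bv = g.dosage[np.ix_(order, qtl_idx)] @ effects
        bv -= bv.mean()
        sd = bv.std()
        if trait.h2 > 0:
            if sd == 0:
                raise SimulationError(f"trait {trait.name}: QTL carry no variance")
            scale = np.sqrt(trait.h2 * var_p) / sd
            bv *= scale
            effects = effects * scale
        else:
            bv[:] = 0.0
            effects = effects * 0.0
        pe = rng.normal(0.0, np.sqrt(trait.pe_fraction * var_p), size=len(ids))
        ye = list(trait.year_effects) or [0.0] * n_years_max
        if len(ye) < n_years_max:
            ye = ye + [0.0] * (n_years_max - len(ye))

        for i, iid in enumerate(ids):
            n_rec = records_per_individual.get(iid, 0)
            noise = rng.normal(0.0, np.sqrt(var_e), size=n_rec) if var_e > 0 else np.zeros(n_rec)
            for t in range(n_rec):
                rows.append(
                    (iid, t + 1, trait.name, trait.mean + ye[t] + bv[i] + pe[i] + noise[t])
                )

        qtl_frames[trait.name] = pd.DataFrame(
            {
                "site_index": qtl_idx,
                "chrom": [g.sites[j].chrom for j in qtl_idx],
                "pos": [g.sites[j].pos for j in qtl_idx],
                "effect": effects,
            }
        )
        bv_cols[trait.name] = bv
        pe_cols[trait.name] = pe
        year_effects[trait.name] = [float(v) for v in ye]
        comp_rows.append(
            {
                "trait": trait.name,
                "var_a": float(np.var(bv)),
                "var_pe": float(np.var(pe)),
                "var_e": var_e,
                "h2_target": trait.h2,
                "pe_fraction": trait.pe_fraction,
            }
        )

    idx = pd.Index(ids, name="individual")
    truth = SimulationTruth(
        qtl=qtl_frames,
        true_bv=pd.DataFrame(bv_cols, index=idx),
        true_pe=pd.DataFrame(pe_cols, index=idx),
        year_effects=year_effects,
        realized_components=pd.DataFrame(comp_rows).set_index("trait"),
    )
    frame = pd.DataFrame(rows, columns=["individual", "year", "trait", "value"])
    return PhenotypeRecords(frame), truth


# ---------------------------------------------------------------------------
# Whole-study builder
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """In-memory bundle of one simulated breeding study.

    ``parent_ids`` is the own-phenotyped accession panel (the parents of the
    progeny generation); ``parent_pedigree`` covers the panel plus any base
    ancestors, for own-phenotype animal-model fits.
    """

    config: SimulationConfig
    pedigree: PedigreeTable  # recorded pedigree (what the analyses see)
    genotypes: GenotypeMatrix  # all recorded individuals
    founder_genotypes: GenotypeMatrix
    phenotypes: PhenotypeRecords
    truth: SimulationTruth
    parent_ids: list[str] = field(default_factory=list)
    progeny_ids: list[str] = field(default_factory=list)
    parent_pedigree: PedigreeTable | None = None
    true_pedigree: PedigreeTable | None = None  # includes unrecorded ancestry

    def parent_phenotypes(self) -> PhenotypeRecords:
        return self.phenotypes.subset_individuals(self.parent_ids)

    def progeny_phenotypes(self) -> PhenotypeRecords:
        return self.phenotypes.subset_individuals(self.progeny_ids)

    def write(self, out_dir) -> dict[str, str]:
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "pedigree": os.path.join(out_dir, "pedigree.csv"),
            "phenotypes": os.path.join(out_dir, "phenotypes.csv"),
            "genotypes_vcf": os.path.join(out_dir, "genotypes.vcf"),
            "genotypes_tsv": os.path.join(out_dir, "genotypes.tsv"),
        }
        self.pedigree.write_csv(paths["pedigree"])
        self.phenotypes.write_csv(paths["phenotypes"])
        self.genotypes.write_vcf(paths["genotypes_vcf"])
        self.genotypes.write_dosage_tsv(paths["genotypes_tsv"])
        self.truth.write(os.path.join(out_dir, "truth"))
        return paths


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Run founders -> (optional base crosses) -> pedigree -> gene drop ->
    phenotypes under one seed."""
    if cfg.n_base_founders is None:
        founders, haps = simulate_founders(cfg)
        parent_ids = list(founders.individual_ids)
        true_ped = simulate_pedigree(cfg, parent_ids)
        ped = true_ped
        parent_ped = ped.subset_founders()
    else:
        # Base generation exists genetically but is unrecorded: accessions
        # appear as founders in the pedigree handed to the analyses.
        founders, haps = simulate_founders(cfg, n=cfg.n_base_founders, prefix="B")
        rng = np.random.default_rng(cfg.seed + 1)
        base_ids = list(founders.individual_ids)
        acc_records = _cross_layer(rng, base_ids, cfg.n_founders, 1, "P")
        parent_ids = [r[0] for r in acc_records]
        n_crosses = int(round(len(parent_ids) * cfg.mean_crosses_per_parent / 2.0))
        prog_records = _cross_layer(rng, parent_ids, n_crosses, cfg.progeny_per_cross, "O")
        base_records = [(b, UNKNOWN, UNKNOWN) for b in base_ids]
        true_ped = PedigreeTable(tuple(base_records + acc_records + prog_records))
        acc_as_founders = [(p, UNKNOWN, UNKNOWN) for p in parent_ids]
        ped = PedigreeTable(tuple(acc_as_founders + prog_records))
        parent_ped = PedigreeTable(tuple(acc_as_founders))
    geno_all = gene_drop(haps, true_ped, cfg, founders.sites)
    progeny_ids = [i for i in ped.ids if i not in set(parent_ids)]
    phenotyped = {i: cfg.n_years for i in parent_ids}
    phenotyped.update({i: cfg.progeny_years for i in progeny_ids})
    phen, truth = simulate_phenotypes(geno_all, true_ped, cfg, records_per_individual=phenotyped)
    recorded = np.array([geno_all.individual_ids.index(i) for i in ped.ids], dtype=int)
    geno = geno_all.subset(individuals=recorded)
    return SyntheticStudy(
        config=cfg,
        pedigree=ped,
        genotypes=geno,
        founder_genotypes=founders,
        phenotypes=phen,
        truth=truth,
        parent_ids=parent_ids,
        progeny_ids=progeny_ids,
        parent_pedigree=parent_ped,
        true_pedigree=true_ped,
    )


def default_study(seed: int, out_dir=None, **overrides) -> SyntheticStudy:
    """The full-scale default dataset: 274 founders, ~5000 progeny from ~274
    crosses, 6400 SNPs over 17 chromosomes, 8 traits with h2 0.15-0.50 and two
    harvest years for parents. Keyword overrides rescale it for tests."""
    if "traits" not in overrides:
        # keep the default trait panel usable on downscaled marker sets
        n_snps = int(overrides.get("n_snps", SimulationConfig.n_snps))
        overrides["traits"] = tuple(
            replace(t, n_qtl=min(t.n_qtl, n_snps)) for t in DEFAULT_TRAITS
        )
    cfg = SimulationConfig(seed=seed, **overrides)
    study = simulate_study(cfg)
    if out_dir is not None:
        study.write(out_dir)
    return study
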