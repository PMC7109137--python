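"""End-to-end analysis: own-phenotype BLUP breeding values, progeny-based
GCA, heritability, own-vs-GCA correlations, and replicated k-fold
cross-validated genomic prediction.
"""

from __future__ import annotations

import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import GblupkitError, ModelError
from .io_formats import (
    PedigreeTable,
    PhenotypeRecords,
    filter_sites,
    impute_mean,
    heterozygosity,
    read_genotypes,
    read_pedigree,
    read_phenotypes,
)
from .mixed_model import (
    DesignBundle,
    VarianceEstimates,
    build_design,
    heritability,
    reml_fit,
)
from .relmat import RelationshipMatrix, amat, gmat_vanraden, make_invertible

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Own-phenotype and progeny analyses
# ---------------------------------------------------------------------------


def own_phenotype_blup(
    phen: PhenotypeRecords, ped: PedigreeTable, trait: str
) -> pd.Series:
    """Additive BLUPs from an accession's own repeated records.

    Fits the repeatability model (year fixed, permanent-environment random,
    additive covariance from the pedigree A-matrix) and returns the additive
    BLUP for every accession that has records.
    """
    k = make_invertible(amat(ped))
    d = build_design(phen, trait, k.individual_ids, fixed_year=True)
    include_pe = d.has_repeated_records()
    fit = reml_fit(d, k, include_pe=include_pe)
    pos = {iid: i for i, iid in enumerate(k.individual_ids)}
    with_records = sorted(set(d.record_ids), key=pos.__getitem__)
    return fit.ebv.loc[with_records].rename("blup_bv")


@dataclass
class GcaResult:
    gca: pd.Series  # per-parent additive BLUP from the progeny fit
    variances: VarianceEstimates
    low_info_parents: list[str] = field(default_factory=list)

    @property
    def h2(self) -> float:
        return heritability(self.variances)


def progeny_gca(
    phen_progeny: PhenotypeRecords,
    ped: PedigreeTable,
    trait: str,
    parent_ids: list[str],
) -> GcaResult:
    """Per-parent GCA from progeny phenotypes.

    Fits the animal model on progeny records with pedigree relationships over
    parents and progeny jointly; a parent's GCA is its additive BLUP from this
    fit. Parents without phenotyped progeny are flagged low-information.
    """
    k = make_invertible(amat(ped))
    d = build_design(phen_progeny, trait, k.individual_ids, fixed_year=True)
    include_pe = d.has_repeated_records()
    fit = reml_fit(d, k, include_pe=include_pe)
    recorded = set(d.record_ids)
    has_recorded_progeny: set[str] = set()
    for child, sire, dam in ped.records:
        if child in recorded:
            has_recorded_progeny.update((sire, dam))
    low_info = [p for p in parent_ids if p not in has_recorded_progeny]
    if low_info:
        logger.warning(
            "progeny_gca(%s): %d parents have no phenotyped progeny (low information)",
            trait, len(low_info),
        )
    return GcaResult(
        gca=fit.ebv.loc[list(parent_ids)].rename("gca"),
        variances=fit.variances,
        low_info_parents=low_info,
    )


def corr_own_vs_gca(blupbv: pd.Series, gca: pd.Series) -> float:
    """Product-moment correlation over the shared accessions."""
    shared = blupbv.index.intersection(gca.index)
    if len(shared) < 3:
        raise GblupkitError("need at least 3 shared accessions to correlate")
    a = blupbv.loc[shared].to_numpy(dtype=float)
    b = gca.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise GblupkitError("zero variance in one of the vectors; correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def make_folds(n: int, k: int, seed: int, min_size: int = 1) -> list[np.ndarray]:
    """Seeded random partition of ``range(n)`` into ``k`` disjoint folds with
    sizes differing by at most one, larger folds first."""
    if not 2 <= k <= n:
        raise GblupkitError(f"need 2 <= k <= n, got k={k}, n={n}")
    if n // k < min_size:
        raise GblupkitError(
            f"folds of {n} records into {k} subsets would have fewer than "
            f"{min_size} records"
        )
    perm = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, k)
    folds = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return folds


@dataclass
class CVResult:
    """Per-fold prediction accuracies from replicated k-fold cross-validation."""

    trait: str
    n_folds: int
    n_repeats: int
    seed: int
    fold_assignments: list[list[np.ndarray]]  # [repeat][fold] -> indices
    records: pd.DataFrame  # repeat, fold, n_validation, accuracy, corr_gca

    @property
    def accuracies(self) -> np.ndarray:
        return self.records["accuracy"].to_numpy()

    def summary(self) -> dict[str, float]:
        acc = self.accuracies
        out = {
            "mean_accuracy": float(np.mean(acc)),
            "q1_accuracy": float(np.quantile(acc, 0.25)),
            "median_accuracy": float(np.median(acc)),
            "q3_accuracy": float(np.quantile(acc, 0.75)),
            "mean_of_repeat_means": float(
                self.records.groupby("repeat")["accuracy"].mean().mean()
            ),
        }
        if self.records["corr_gca"].notna().any():
            out["mean_corr_gca"] = float(self.records["corr_gca"].mean())
        return out


def _design_from_values(values: np.ndarray, train_idx: np.ndarray, ids: list[str]) -> DesignBundle:
    return DesignBundle(
        y=values[train_idx],
        X=np.ones((len(train_idx), 1)),
        individual_ids=list(ids),
        record_indiv=np.asarray(train_idx, dtype=int),
        record_ids=[ids[i] for i in train_idx],
        year_levels=[],
    )


def cv_genomic_prediction(
    blupbv: pd.Series,
    g: RelationshipMatrix,
    k: int = 11,
    repeats: int = 20,
    seed: int = 0,
    gca: pd.Series | None = None,
) -> CVResult:
    """Replicated k-fold cross-validation of genomic prediction.

    Per repeat and fold: an intercept-only GBLUP model is refitted (variance
    components included) on the training accessions' BLUP-BVs; held-out
    accessions get GEBVs through the genomic relationship matrix, and the
    fold's accuracy is corr(GEBV, BLUP-BV) in the validation set (plus
    corr(GEBV, GCA) when GCA is supplied). Per-repeat seeds are
    ``seed + repeat``.
    """
    # canonical accession order: summaries independent of input ordering
    blupbv = blupbv.sort_index()
    ids = list(blupbv.index)
    n = len(ids)
    g.index_of(ids)  # fail fast on coverage
    gpd = make_invertible(g)
    if list(gpd.individual_ids) != ids:
        sub = gpd.submatrix(ids)
        gpd = RelationshipMatrix(ids, sub, gpd.kind)
    values = blupbv.to_numpy(dtype=float)
    gca_values = gca.loc[ids].to_numpy(dtype=float) if gca is not None else None

    assignments: list[list[np.ndarray]] = []
    rows = []
    for rep in range(repeats):
        folds = make_folds(n, k, seed + rep, min_size=3)
        assignments.append(folds)
        for fold_i, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), val_idx)
            d = _design_from_values(values, train_idx, ids)
            fit = reml_fit(d, gpd, include_pe=False)
            gebv = fit.ebv.to_numpy()[val_idx]
            acc = float(stats.pearsonr(gebv, values[val_idx]).statistic)
            cg = (
                float(stats.pearsonr(gebv, gca_values[val_idx]).statistic)
                if gca_values is not None
                else np.nan
            )
            rows.append((rep, fold_i, len(val_idx), acc, cg))
    records = pd.DataFrame(
        rows, columns=["repeat", "fold", "n_validation", "accuracy", "corr_gca"]
    )
    return CVResult(
        trait=str(blupbv.name or "trait"),
        n_folds=k,
        n_repeats=repeats,
        seed=seed,
        fold_assignments=assignments,
        records=records,
    )


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


@dataclass
class TraitSummary:
    trait: str
    h2_progeny: float
    corr_blupbv_gca: float
    mean_cv_accuracy: float
    corr_gebv_gca_mean: float


@dataclass
class StudyReport:
    summaries: list[TraitSummary]
    cv_results: dict[str, CVResult]
    settings: dict

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.summaries])


_DEFAULT_CONFIG = {
    "seed": 1,
    "cv": {"folds": 11, "repeats": 20},
    "filters": {"max_missing_frac": 0.10, "min_maf": 0.05, "remove_adjacent": True},
    "traits": None,
    "simulation": {},
}


def _load_config(config) -> dict:
    if isinstance(config, dict):
        cfg = dict(config)
    else:
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = {**_DEFAULT_CONFIG, **cfg}
    for key in ("cv", "filters"):
        merged[key] = {**_DEFAULT_CONFIG[key], **(cfg.get(key) or {})}
    return merged


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise GblupkitError(f"[stage: {name}] {exc}") from exc


def run_study(config, out_dir=None) -> StudyReport:
    """Execute the whole analysis from a YAML config (path or dict).

    The config either names input files (``inputs: {pedigree, phenotypes,
    genotypes, genotype_format}``) or simulation overrides (``simulation:``,
    the default). Per trait: own-phenotype BLUP-BV, progeny GCA + h2, their
    correlation, then replicated k-fold genomic-prediction CV. Outputs (when
    ``out_dir`` given): trait_summary.csv, cv_<trait>.csv, report.txt,
    settings.json.
    """
    cfg = _load_config(config)
    seed = int(cfg["seed"])

    if cfg.get("inputs"):
        inputs = cfg["inputs"]
        ped = _stage("read_pedigree", read_pedigree, inputs["pedigree"])
        phen = _stage("read_phenotypes", read_phenotypes, inputs["phenotypes"])
        geno = _stage(
            "read_genotypes",
            read_genotypes,
            inputs["genotypes"],
            inputs.get("genotype_format", "vcf"),
        )
        parent_ids = inputs.get("parent_ids") or ped.founders
        source = {"mode": "files", **{k: str(v) for k, v in inputs.items()}}
    else:
        from .simulate import default_study

        study = _stage("simulate", default_study, seed, **(cfg.get("simulation") or {}))
        ped, phen, geno = study.pedigree, study.phenotypes, study.genotypes
        parent_ids = study.parent_ids
        progeny_override = study.progeny_ids
        source = {"mode": "simulation", **{k: str(v) for k, v in (cfg.get("simulation") or {}).items()}}

    traits = cfg.get("traits") or phen.traits
    unknown = set(traits) - set(phen.traits)
    if unknown:
        raise GblupkitError(f"[stage: config] unknown traits {sorted(unknown)}")

    own_phen = phen.subset_individuals(parent_ids)
    if cfg.get("inputs"):
        progeny_ids = [i for i in ped.ids if i not in set(parent_ids)]
    else:
        progeny_ids = progeny_override
    prog_phen = phen.subset_individuals(progeny_ids)
    own_ped = ped.subset_ancestors(parent_ids)

    fcfg = cfg["filters"]
    geno_f, freport = _stage("filter_sites", filter_sites, geno, **fcfg)
    geno_i = _stage("impute", impute_mean, geno_f, seed)
    gsub = geno_i.subset(
        individuals=np.array([geno_i.individual_ids.index(p) for p in parent_ids])
    )
    g = _stage("gmat", gmat_vanraden, gsub)
    het = _stage("heterozygosity", heterozygosity, geno_f)

    summaries = []
    cv_results: dict[str, CVResult] = {}
    for trait in traits:
        blupbv = _stage(f"own_blup:{trait}", own_phenotype_blup, own_phen, own_ped, trait)
        gres = _stage(f"gca:{trait}", progeny_gca, prog_phen, ped, trait, list(parent_ids))
        r_own_gca = _stage(f"corr:{trait}", corr_own_vs_gca, blupbv, gres.gca)
        cv = _stage(
            f"cv:{trait}",
            cv_genomic_prediction,
            blupbv.rename(trait),
            g,
            cfg["cv"]["folds"],
            cfg["cv"]["repeats"],
            seed,
            gres.gca,
        )
        cv_results[trait] = cv
        s = cv.summary()
        summaries.append(
            TraitSummary(
                trait=trait,
                h2_progeny=gres.h2,
                corr_blupbv_gca=r_own_gca,
                mean_cv_accuracy=s["mean_accuracy"],
                corr_gebv_gca_mean=s.get("mean_corr_gca", float("nan")),
            )
        )

    offdiag = g.values[~np.eye(g.n, dtype=bool)]
    settings = {
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "source": source,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_parents": len(parent_ids),
        "n_progeny": len(progeny_ids),
        "snp_filter": json.loads(freport.to_json()),
        "mean_heterozygosity": float(het.mean()),
        "mean_genomic_relationship_offdiag": float(offdiag.mean()),
    }
    report = StudyReport(summaries=summaries, cv_results=cv_results, settings=settings)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        sf = report.summary_frame().copy()
        for col in sf.columns[1:]:
            sf[col] = sf[col].map(lambda v: "%.10g" % v)
        sf.to_csv(os.path.join(out_dir, "trait_summary.csv"), index=False)
        for trait, cv in cv_results.items():
            out = cv.records.copy()
            out["accuracy"] = out["accuracy"].map(lambda v: "%.10g" % v)
            out["corr_gca"] = out["corr_gca"].map(lambda v: "%.10g" % v)
            out.to_csv(os.path.join(out_dir, f"cv_{trait}.csv"), index=False)
        with open(os.path.join(out_dir, "settings.json"), "w") as fh:
            json.dump(settings, fh, indent=2, sort_keys=True)
        with open(os.path.join(out_dir, "report.txt"), "w") as fh:
            fh.write(_text_report(report))
    return report


def _text_report(report: StudyReport) -> str:
    lines = [
        "Genome-assisted parental selection study",
        "=" * 44,
        "",
        f"seed: {report.settings['seed']}",
        f"parents: {report.settings['n_parents']}, progeny: {report.settings['n_progeny']}",
        f"mean heterozygosity: {report.settings['mean_heterozygosity']:.3f}",
        "mean genomic relationship (off-diagonal): "
        f"{report.settings['mean_genomic_relationship_offdiag']:.3f}",
        "",
        "trait      h2(prog)  r(BLUP-BV,GCA)  CV accuracy  r(GEBV,GCA)",
    ]
    for s in report.summaries:
        lines.append(
            f"{s.trait:<10} {s.h2_progeny:8.3f} {s.corr_blupbv_gca:15.3f} "
            f"{s.mean_cv_accuracy:12.3f} {s.corr_gebv_gca_mean:12.3f}"
        )
    lines.append("")
    return "\n".join(lines)
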