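"""Shared fixtures.

The two session-scoped simulated studies back both the acceptance suite and
the heavier property tests; everything else is generated per-test at toy
scale. REML non-convergence warnings on tiny folds are tolerated inside
fixtures (boundary fits on 15-record training sets).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gblupkit as gk


def _quiet(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


@pytest.fixture(scope="session")
def toy_pedigree() -> gk.PedigreeTable:
    # A,B founders; C,D full sibs; E = C x D (inbred, F = 0.25)
    return gk.PedigreeTable(
        (
            ("A", "", ""),
            ("B", "", ""),
            ("C", "A", "B"),
            ("D", "A", "B"),
            ("E", "C", "D"),
        )
    )


# ---------------------------------------------------------------------------
# Study fixtures (acceptance criteria 5-7 share these)
# ---------------------------------------------------------------------------

H2_BY_TRAIT = {t.name: t.h2 for t in gk.DEFAULT_TRAITS}


@pytest.fixture(scope="session")
def study_sqrt_h2() -> gk.SyntheticStudy:
    """8-trait study at 200 parents / ~2000 progeny (heritability-
    correspondence scale); accession panel genomically related through an
    unrecorded base generation."""
    traits = tuple(
        gk.TraitConfig(t.name, t.h2, pe_fraction=t.pe_fraction, mean=t.mean,
                       phenotypic_variance=t.phenotypic_variance, n_qtl=80)
        for t in gk.DEFAULT_TRAITS
    )
    cfg = gk.SimulationConfig(
        n_founders=200, n_chromosomes=17, n_snps=1190, progeny_per_cross=10,
        n_base_founders=30, seed=20, traits=traits,
    )
    return gk.simulate_study(cfg)


@pytest.fixture(scope="session")
def sqrt_h2_results(study_sqrt_h2) -> dict:
    """Per-trait BLUP-BV, GCA, progeny-h2 and their correlation."""
    study = study_sqrt_h2
    own = study.parent_phenotypes()
    prog = study.progeny_phenotypes()
    out = {}
    for t in study.config.traits:
        bv = _quiet(gk.own_phenotype_blup, own, study.parent_pedigree, t.name)
        gca = _quiet(gk.progeny_gca, prog, study.pedigree, t.name, study.parent_ids)
        out[t.name] = {
            "blupbv": bv,
            "gca": gca.gca,
            "h2_hat": gca.h2,
            "corr_own_gca": gk.corr_own_vs_gca(bv, gca.gca),
        }
    return out


@pytest.fixture(scope="session")
def study_cv() -> gk.SyntheticStudy:
    """CV-scale study: 274 accessions, ~2000 SNPs, ~1900 progeny, plus a
    pure-noise ninth trait for the null-accuracy check."""
    traits = tuple(
        gk.TraitConfig(t.name, t.h2, pe_fraction=t.pe_fraction, mean=t.mean,
                       phenotypic_variance=t.phenotypic_variance, n_qtl=100)
        for t in gk.DEFAULT_TRAITS
    ) + (gk.TraitConfig("NOISE", 0.0, pe_fraction=0.0),)
    cfg = gk.SimulationConfig(
        n_founders=274, n_chromosomes=17, n_snps=2040, progeny_per_cross=7,
        n_base_founders=30, seed=1, traits=traits,
    )
    return gk.simulate_study(cfg)


@pytest.fixture(scope="session")
def cv_grm(study_cv) -> gk.RelationshipMatrix:
    geno = study_cv.genotypes
    rows = np.array([geno.individual_ids.index(p) for p in study_cv.parent_ids])
    gpar, _ = gk.filter_sites(geno.subset(individuals=rows))
    return gk.gmat_vanraden(gk.impute_mean(gpar))


@pytest.fixture(scope="session")
def cv_trait_results(study_cv) -> dict:
    study = study_cv
    own = study.parent_phenotypes()
    prog = study.progeny_phenotypes()
    out = {}
    for t in study.config.traits:
        bv = _quiet(gk.own_phenotype_blup, own, study.parent_pedigree, t.name)
        gca = _quiet(gk.progeny_gca, prog, study.pedigree, t.name, study.parent_ids)
        out[t.name] = {
            "blupbv": bv,
            "gca": gca.gca,
            "corr_own_gca": gk.corr_own_vs_gca(bv, gca.gca),
        }
    return out


@pytest.fixture(scope="session")
def cv_results(study_cv, cv_trait_results, cv_grm) -> dict:
    """20-repeat 11-fold CV per trait (including the noise trait)."""
    out = {}
    for t in study_cv.config.traits:
        r = cv_trait_results[t.name]
        out[t.name] = _quiet(
            gk.cv_genomic_prediction,
            r["blupbv"].rename(t.name), cv_grm,
            11, 20, 42, r["gca"],
        )
    return out


@pytest.fixture(scope="session")
def h2_recovery() -> list[tuple[float, float]]:
    """(true h2, REML h2-hat) on >=1500 phenotyped progeny; fixed seed."""
    traits = tuple(
        gk.TraitConfig(f"T{h2:.2f}", h2, pe_fraction=0.0, n_qtl=120)
        for h2 in (0.15, 0.30, 0.50)
    )
    cfg = gk.SimulationConfig(
        n_founders=160, n_chromosomes=17, n_snps=850, progeny_per_cross=9,
        mean_crosses_per_parent=3.0, seed=2, traits=traits,
    )
    study = gk.simulate_study(cfg)
    prog = study.progeny_phenotypes()
    assert len(study.progeny_ids) >= 1500
    pairs = []
    for t in traits:
        res = _quiet(gk.progeny_gca, prog, study.pedigree, t.name, study.parent_ids)
        pairs.append((t.h2, res.h2))
    return pairs
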