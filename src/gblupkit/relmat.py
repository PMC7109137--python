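"""Additive relationship matrices: pedigree (tabular method) and genomic
(VanRaden method 1), plus positive-definiteness repair for mixed-model use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .errors import GblupkitError
from .io_formats import UNKNOWN, GenotypeMatrix, PedigreeTable

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Labeled symmetric additive-relationship matrix.

    kind is "pedigree" (expected additive relationships from the pedigree;
    diagonal 1+F) or "genomic" (realised relationships from centered SNP
    dosages; rows sum to zero when sample allele frequencies are used).
    """

    individual_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise GblupkitError(f"relationship matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0.0):
            raise GblupkitError("relationship matrix is not symmetric (tol 1e-12)")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise GblupkitError(f"id {exc.args[0]!r} not in relationship matrix") from None

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index_of(ids)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.individual_ids, columns=self.individual_ids)

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "individual"
        df.to_csv(path, float_format="%.12g")

    @classmethod
    def read_csv(cls, path, kind: str) -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), kind)

    def write_npz(self, path) -> None:
        np.savez(path, ids=np.array(self.individual_ids), values=self.values, kind=self.kind)

    @classmethod
    def read_npz(cls, path) -> "RelationshipMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls([str(i) for i in z["ids"]], z["values"], str(z["kind"]))


def amat(ped: PedigreeTable) -> RelationshipMatrix:
    """Pedigree additive (numerator) relationship matrix by the tabular method.

    With individuals in parents-first order: a(i,i) = 1 + 0.5*a(s_i, d_i) and
    a(i,j) = 0.5*(a(j, s_i) + a(j, d_i)) for earlier j; unknown parents
    contribute 0.
    """
    ids = ped.ids
    pos = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    for i, (iid, sire, dam) in enumerate(ped.records):
        si = pos[sire] if sire != UNKNOWN else -1
        di = pos[dam] if dam != UNKNOWN else -1
        row = np.zeros(i)
        if si >= 0:
            row += a[si, :i]
        if di >= 0:
            row += a[di, :i]
        row *= 0.5
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(ids, a, "pedigree")


def inbreeding(ped: PedigreeTable) -> pd.Series:
    """Per-individual inbreeding coefficient F = a(i,i) - 1."""
    rel = amat(ped)
    return pd.Series(
        np.diag(rel.values) - 1.0,
        index=pd.Index(rel.individual_ids, name="individual"),
        name="inbreeding",
    )


def gmat_vanraden(g: GenotypeMatrix) -> RelationshipMatrix:
    """Realised genomic relationship matrix (VanRaden method 1).

    With p_k the sample alt-allele frequency at site k and W the dosage matrix
    column-centered by 2*p_k: G = W W' / (2 * sum_k p_k (1 - p_k)). Requires a
    fully observed (imputed) matrix and no monomorphic sites.
    """
    if np.isnan(g.dosage).any():
        raise GblupkitError("genotype matrix has missing entries; run impute_mean first")
    p = g.dosage.mean(axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        k = int(np.flatnonzero(mono)[0])
        raise GblupkitError(
            f"monomorphic site {g.sites[k].chrom}:{g.sites[k].pos}; apply filter_sites first"
        )
    w = g.dosage - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    values = (w @ w.T) / denom
    values = (values + values.T) / 2.0  # sweep numerical asymmetry
    return RelationshipMatrix(list(g.individual_ids), values, "genomic")


def is_positive_definite(values: np.ndarray) -> bool:
    try:
        cholesky(values, lower=True)
        return True
    except np.linalg.LinAlgError:
        return False
    except Exception:
        return False


def make_invertible(k: RelationshipMatrix, epsilon: float = 1e-4) -> RelationshipMatrix:
    """Return ``k`` unchanged if Cholesky succeeds; otherwise blend towards the
    identity, (1-eps)*K + eps*I, repeating (at most 10 times) until positive
    definite. Each blend is logged."""
    if epsilon <= 0:
        raise GblupkitError(f"epsilon must be positive, got {epsilon}")
    values = k.values
    for attempt in range(10):
        if is_positive_definite(values):
            if attempt == 0:
                return k
            return RelationshipMatrix(list(k.individual_ids), values, k.kind)
        logger.warning(
            "make_invertible: %s matrix not positive definite; blending with identity (epsilon=%g, pass %d)",
            k.kind, epsilon, attempt + 1,
        )
        values = (1.0 - epsilon) * values + epsilon * np.eye(k.n)
    raise GblupkitError("matrix still not positive definite after 10 identity blends")
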