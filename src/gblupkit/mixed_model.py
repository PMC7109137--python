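"""Individual-level mixed models fitted by REML.

Two model shapes are supported, both with an additive genetic effect whose
covariance is a supplied relationship matrix K (pedigree or genomic):

* the repeatability model ``y = Xb + Z a + Z p + e`` with a permanent-
  environment effect for repeated records, and
* the plain additive model ``y = Xb + Z a + e`` (intercept-only X for
  genomic prediction of accession-level responses).

Variance components are estimated by average-information REML in the
V-parameterisation with EM fallback steps; BLUPs for *all* individuals in K
(including recordless ones) follow from a-hat = sigma2_a * K Z' P y.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .errors import ModelError
from .io_formats import PhenotypeRecords
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

#: Variance lower bound, as a fraction of the sample phenotypic variance.
VARIANCE_FLOOR_FRACTION = 1e-6


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignBundle:
    """Response and incidence information for one trait.

    ``record_indiv[r]`` is the index (into ``individual_ids``) of the
    individual owning record ``r``; it plays the role of the Z incidence
    matrix (one 1 per row) for both the additive and permanent-environment
    effects. ``individual_ids`` may include individuals without records.
    """

    y: np.ndarray
    X: np.ndarray
    individual_ids: list[str]
    record_indiv: np.ndarray
    record_ids: list[str]
    year_levels: list[int]

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def z_dense(self) -> np.ndarray:
        """Dense Z incidence matrix (records x individuals); for oracles/tests."""
        z = np.zeros((self.n_records, self.n_individuals))
        z[np.arange(self.n_records), self.record_indiv] = 1.0
        return z

    def has_repeated_records(self) -> bool:
        return np.bincount(self.record_indiv).max() > 1 if self.n_records else False


def build_design(
    phen: PhenotypeRecords,
    trait: str,
    ids: list[str],
    fixed_year: bool = True,
) -> DesignBundle:
    """One row per record of ``trait``; X = intercept (+ harvest-year factor
    with the earliest year as reference when ``fixed_year``)."""
    df = phen.for_trait(trait)
    if df.empty:
        raise ModelError(f"trait {trait!r} has no phenotype records")
    if df["individual"].nunique() < 2:
        raise ModelError(f"trait {trait!r} has records for fewer than 2 individuals")
    pos = {iid: i for i, iid in enumerate(ids)}
    missing = set(df["individual"]) - set(pos)
    if missing:
        raise ModelError(
            f"individuals with records absent from the id list: {sorted(missing)[:5]}"
        )
    y = df["value"].to_numpy(dtype=float)
    record_indiv = np.array([pos[i] for i in df["individual"]], dtype=int)
    years = sorted(df["year"].unique())
    cols = [np.ones(len(df))]
    if fixed_year:
        for yr in years[1:]:  # earliest year = reference level
            cols.append((df["year"] == yr).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelError("fixed-effects design is rank deficient after reference drop")
    return DesignBundle(
        y=y,
        X=X,
        individual_ids=list(ids),
        record_indiv=record_indiv,
        record_ids=list(df["individual"]),
        year_levels=[int(v) for v in years],
    )


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------


@dataclass
class VarianceEstimates:
    sigma2_a: float
    sigma2_p: float | None
    sigma2_e: float
    log_likelihood: float
    converged: bool
    n_iterations: int

    def total(self) -> float:
        return self.sigma2_a + (self.sigma2_p or 0.0) + self.sigma2_e


@dataclass
class MixedModelFit:
    beta_hat: np.ndarray
    ebv: pd.Series
    pe_hat: pd.Series | None
    variances: VarianceEstimates
    relationship_kind: str
    log_likelihood_path: list[float]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"ebv": self.ebv})
        if self.pe_hat is not None:
            out["pe"] = self.pe_hat
        return out

    def settings_json(self) -> dict:
        v = self.variances
        return {
            "sigma2_a": v.sigma2_a,
            "sigma2_p": v.sigma2_p,
            "sigma2_e": v.sigma2_e,
            "log_likelihood": v.log_likelihood,
            "converged": v.converged,
            "n_iterations": v.n_iterations,
            "relationship_kind": self.relationship_kind,
        }


class _DenseEvaluator:
    """REML quantities via explicit V inversion (any number of structures)."""

    def __init__(self, y, X, structures):
        self.y, self.X, self.structures = y, X, structures
        self.n = len(y)

    def __call__(self, sigma):
        n = self.n
        V = sigma[-1] * np.eye(n)
        for s2, S in zip(sigma[:-1], self.structures):
            V += s2 * S
        c, low = cho_factor(V, lower=True)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = cho_solve((c, low), np.eye(n))
        VinvX = Vinv @ self.X
        XtVinvX = self.X.T @ VinvX
        cb = cho_factor(XtVinvX)
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cb[0]))))
        P = Vinv - VinvX @ cho_solve(cb, VinvX.T)
        Py = P @ self.y
        logL = -0.5 * (logdet_v + logdet_x + float(self.y @ Py))
        mats = list(self.structures) + [None]  # None = identity (residual)
        us, quads, trs = [], [], []
        for S in mats:
            u = Py if S is None else S @ Py
            us.append(u)
            quads.append(float(Py @ u))
            trs.append(float(np.trace(P)) if S is None else float(np.sum(P * S)))
        k = len(mats)
        ai = np.empty((k, k))
        Pus = [P @ u for u in us]
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(us[i] @ Pus[j])
        beta = cho_solve(cb, VinvX.T @ self.y)
        return {
            "logL": logL, "quad": np.array(quads), "tr": np.array(trs),
            "ai": ai, "Py": Py, "beta": beta,
        }


class _EigenEvaluator:
    """Fast path for V = s1 * S + se * I via a one-off eigendecomposition of S.

    All per-iteration work is O(n p^2); exact, not an approximation.
    """

    def __init__(self, y, X, structure):
        d, U = eigh(structure)
        self.d = np.clip(d, 0.0, None)  # S is PSD up to roundoff
        self.U = U
        self.yt = U.T @ y
        self.Xt = U.T @ X

    def _papply(self, winv, A, cb, v):
        return winv * v - A @ cho_solve(cb, A.T @ v)

    def __call__(self, sigma):
        s1, se = sigma
        w = s1 * self.d + se
        winv = 1.0 / w
        A = self.Xt * winv[:, None]
        M = self.Xt.T @ A
        cb = cho_factor(M)
        logdet_x = 2.0 * float(np.sum(np.log(np.diag(cb[0]))))
        Pty = self._papply(winv, A, cb, self.yt)
        AM = A @ cho_solve(cb, np.eye(M.shape[0]))
        diag_p = winv - np.einsum("ij,ij->i", AM, A)
        logL = -0.5 * (float(np.sum(np.log(w))) + logdet_x + float(self.yt @ Pty))
        u1 = self.d * Pty
        quads = np.array([float(Pty @ u1), float(Pty @ Pty)])
        trs = np.array([float(self.d @ diag_p), float(np.sum(diag_p))])
        Pu1 = self._papply(winv, A, cb, u1)
        Pue = self._papply(winv, A, cb, Pty)
        ai = 0.5 * np.array(
            [[float(u1 @ Pu1), float(u1 @ Pue)], [float(u1 @ Pue), float(Pty @ Pue)]]
        )
        beta = cho_solve(cb, A.T @ self.yt)
        return {
            "logL": logL, "quad": quads, "tr": trs, "ai": ai,
            "Py": self.U @ Pty, "beta": beta,
        }


def _em_step(sigma, state, q_levels):
    quad, tr = state["quad"], state["tr"]
    return sigma + sigma**2 * (quad - tr) / q_levels


def _reml_maximize(evaluate, sigma0, q_levels, floor, max_iter, tol, method):
    sigma = np.asarray(sigma0, dtype=float)
    state = evaluate(sigma)
    path = [state["logL"]]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if method == "em":
            proposal = np.maximum(_em_step(sigma, state, q_levels), floor)
        else:
            score = -0.5 * (state["tr"] - state["quad"])
            try:
                delta = np.linalg.solve(state["ai"], score)
            except np.linalg.LinAlgError:
                delta = np.linalg.pinv(state["ai"]) @ score
            if not np.all(np.isfinite(delta)):
                delta = np.zeros_like(sigma)
            proposal = sigma + delta
            shrink = 0
            while np.any(proposal < floor) and shrink < 12:
                delta *= 0.5  # shorten the AI step until it stays in bounds
                proposal = sigma + delta
                shrink += 1
            if np.any(proposal < floor):
                proposal = _em_step(sigma, state, q_levels)
            proposal = np.maximum(proposal, floor)
        new_state = evaluate(proposal)
        if method != "em":
            halvings = 0
            while new_state["logL"] < state["logL"] - 1e-10 and halvings < 8:
                proposal = np.maximum(0.5 * (proposal + sigma), floor)
                new_state = evaluate(proposal)
                halvings += 1
            if new_state["logL"] < state["logL"] - 1e-10:
                proposal = np.maximum(_em_step(sigma, state, q_levels), floor)
                new_state = evaluate(proposal)
        rel_change = abs(new_state["logL"] - state["logL"]) / (abs(state["logL"]) + 1.0)
        sigma, state = proposal, new_state
        path.append(state["logL"])
        if rel_change < tol:
            converged = True
            break
    return sigma, state, converged, it, path


def reml_fit(
    d: DesignBundle,
    k: RelationshipMatrix,
    include_pe: bool,
    method: str = "ai",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MixedModelFit:
    """REML variance components and MME BLUPs/BLUEs for the design ``d``
    under additive covariance ``k`` (positive definite; see make_invertible).

    ``method`` is "ai" (average information with EM fallback, default) or
    "em" (pure EM, guaranteed monotone log-likelihood). EBVs are returned for
    every individual in ``k``, recordless ones predicted through K.
    """
    if method not in ("ai", "em"):
        raise ModelError(f"unknown REML method {method!r}")
    if include_pe and not d.has_repeated_records():
        raise ModelError(
            "permanent-environment effect is not identifiable without repeated "
            "records; call with include_pe=False"
        )
    ri = d.record_indiv
    idx = k.index_of(d.individual_ids)
    kmat = k.values[np.ix_(idx, idx)]
    s_a = kmat[np.ix_(ri, ri)]  # Z K Z'
    y, X = d.y, d.X
    n, q = d.n_records, d.n_individuals
    vary = float(np.var(y))
    if vary <= 0.0:
        vary = 1.0
    floor = VARIANCE_FLOOR_FRACTION * vary
    n_terms = 3 if include_pe else 2
    sigma0 = np.full(n_terms, vary / n_terms)

    if include_pe:
        s_p = (ri[:, None] == ri[None, :]).astype(float)
        evaluate = _DenseEvaluator(y, X, [s_a, s_p])
        q_levels = np.array([q, q, n], dtype=float)
    else:
        evaluate = _EigenEvaluator(y, X, s_a)
        q_levels = np.array([q, n], dtype=float)

    sigma, state, converged, n_iter, path = _reml_maximize(
        evaluate, sigma0, q_levels, floor, max_iter, tol, method
    )
    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations "
            f"(last logL {state['logL']:.6f})",
            stacklevel=2,
        )

    Py = state["Py"]
    zt_py = np.bincount(ri, weights=Py, minlength=q)
    ebv_full = sigma[0] * (k.values @ np.bincount(idx[ri], weights=Py, minlength=k.n))
    ebv = pd.Series(ebv_full, index=pd.Index(k.individual_ids, name="individual"), name="ebv")
    pe_hat = None
    sigma2_p = None
    if include_pe:
        sigma2_p = float(sigma[1])
        pe_hat = pd.Series(
            sigma[1] * zt_py,
            index=pd.Index(d.individual_ids, name="individual"),
            name="pe",
        )
    variances = VarianceEstimates(
        sigma2_a=float(sigma[0]),
        sigma2_p=sigma2_p,
        sigma2_e=float(sigma[-1]),
        log_likelihood=float(state["logL"]),
        converged=converged,
        n_iterations=n_iter,
    )
    return MixedModelFit(
        beta_hat=np.asarray(state["beta"], dtype=float),
        ebv=ebv,
        pe_hat=pe_hat,
        variances=variances,
        relationship_kind=k.kind,
        log_likelihood_path=path,
    )


# ---------------------------------------------------------------------------
# Variance-ratio summaries
# ---------------------------------------------------------------------------


def heritability(v: VarianceEstimates) -> float:
    """Narrow-sense heritability: sigma2_a / (sigma2_a + sigma2_p + sigma2_e)."""
    total = v.total()
    if total <= 0:
        raise ModelError("all variance components are zero; heritability undefined")
    return v.sigma2_a / total


def repeatability(v: VarianceEstimates) -> float:
    """(sigma2_a + sigma2_p) / total phenotypic variance."""
    total = v.total()
    if total <= 0:
        raise ModelError("all variance components are zero; repeatability undefined")
    return (v.sigma2_a + (v.sigma2_p or 0.0)) / total
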