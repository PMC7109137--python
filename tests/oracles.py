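"""Independent reference implementations used to check the package.

Everything here is deliberately naive (recursion, dense algebra, closed
forms) and shares no code with the package under test.
"""

from __future__ import annotations

import numpy as np


def kinship_amat(records):
    """Additive relationships as 2x coefficient-of-coancestry, computed by
    the classic recursion f(i,j) = (f(sire_i, j) + f(dam_i, j)) / 2 with
    f(i,i) = (1 + f(sire_i, dam_i)) / 2; unknown parents contribute 0.

    ``records`` is a parents-first list of (id, sire, dam) with "" unknown.
    """
    order = {iid: n for n, (iid, _, _) in enumerate(records)}
    parents = {iid: (s, d) for iid, s, d in records}
    cache = {}

    def f(i, j):
        if i == "" or j == "":
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        si, di = parents[i]
        if i == j:
            val = 0.5 * (1.0 + f(si, di))
        else:
            val = 0.5 * (f(si, j) + f(di, j))
        cache[key] = val
        return val

    ids = [r[0] for r in records]
    n = len(ids)
    a = np.empty((n, n))
    for x in range(n):
        for y in range(x, n):
            a[x, y] = a[y, x] = 2.0 * f(ids[x], ids[y])
    return ids, a


def random_pedigree(rng, max_n=40):
    """Random acyclic parents-first pedigree with unknown-parent gaps."""
    n = int(rng.integers(3, max_n + 1))
    records = []
    for i in range(n):
        iid = f"I{i}"
        if i < 2 or rng.random() < 0.25:
            records.append((iid, "", ""))
            continue
        sire, dam = rng.choice(i, size=2, replace=False)
        if rng.random() < 0.1:  # one known parent only
            records.append((iid, f"I{sire}", ""))
        else:
            records.append((iid, f"I{sire}", f"I{dam}"))
    return records


def anova_oneway(y, groups):
    """Balanced one-way random-effects ANOVA estimators.

    Returns (sigma2_between, sigma2_within) from mean squares:
    sigma2_within = MSW, sigma2_between = (MSB - MSW) / m for common group
    size m. Matches REML exactly on balanced data when MSB >= MSW.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    m = len(y) // len(labels)
    means = np.array([y[groups == g].mean() for g in labels])
    msb = m * np.sum((means - y.mean()) ** 2) / (len(labels) - 1)
    ssw = sum(np.sum((y[groups == g] - y[groups == g].mean()) ** 2) for g in labels)
    msw = ssw / (len(y) - len(labels))
    return (msb - msw) / m, msw


def gls_beta(y, X, V):
    """Generalised least squares (X' V^-1 X)^-1 X' V^-1 y via dense solves."""
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    return np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)


def mme_solve(y, X, Za, K, sigma2_a, sigma2_e, Zp=None, sigma2_p=None):
    """Henderson's mixed-model equations, built dense and solved directly.

    Returns (beta, a_hat, p_hat) with a_hat covering every column of Za
    (i.e. every individual in K, recordless ones included).
    """
    Kinv = np.linalg.inv(K)
    lam_a = sigma2_e / sigma2_a
    blocks = [
        [X.T @ X, X.T @ Za],
        [Za.T @ X, Za.T @ Za + Kinv * lam_a],
    ]
    rhs = [X.T @ y, Za.T @ y]
    if Zp is not None:
        lam_p = sigma2_e / sigma2_p
        blocks[0].append(X.T @ Zp)
        blocks[1].append(Za.T @ Zp)
        blocks.append([Zp.T @ X, Zp.T @ Za, Zp.T @ Zp + np.eye(Zp.shape[1]) * lam_p])
        rhs.append(Zp.T @ y)
    C = np.block(blocks)
    sol = np.linalg.solve(C, np.concatenate(rhs))
    p = X.shape[1]
    q = Za.shape[1]
    beta = sol[:p]
    a_hat = sol[p : p + q]
    p_hat = sol[p + q :] if Zp is not None else None
    return beta, a_hat, p_hat


def reml_loglik(y, X, V):
    """Direct REML log-likelihood (up to the usual constant)."""
    n, p = X.shape
    sign, logdet_v = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    sign2, logdet_x = np.linalg.slogdet(XtVinvX)
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVinvX) @ X.T @ Vinv
    return -0.5 * (logdet_v + logdet_x + float(y @ P @ y))
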