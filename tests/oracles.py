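"""Independent brute-force reference implementations.

Everything here is written as plain double loops directly from the
definitions — no shared code with the package's vectorised paths — so
it can serve as the oracle the fast implementations are checked
against on small instances.
"""

from __future__ import annotations

import numpy as np


def naive_transform(T: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Column-wise inner product, elementwise loops."""
    n = X.shape[0]
    return np.array([float(np.dot(X[j, :], T[:, j])) for j in range(n)])


def naive_tensor(matrices: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.stack([naive_transform(T, X) for T in matrices])


def naive_predict(matrices, alpha, beta, X) -> float:
    R = naive_tensor(matrices, X)
    total = 0.0
    for k in range(len(alpha)):
        for j in range(len(beta)):
            total += alpha[k] * R[k, j] * beta[j]
    return total


def naive_objective(matrices, alpha, beta, X, y, X1, X2, l1, l2, l3) -> float:
    """The full loss, every sum as an explicit loop.

    Within-class clustering sums run over unordered pairs p < q; the
    cross-class sums (clustering and ranking) over the full N1 x N2 grid.
    """
    sq = sum(
        (y[l] - naive_predict(matrices, alpha, beta, X[l])) ** 2
        for l in range(len(y))
    )
    reg = l1 * float(np.sum(np.asarray(alpha) ** 2) * np.sum(np.asarray(beta) ** 2))
    rank = 0.0
    for Xp in X1:
        for Xq in X2:
            Rq = naive_tensor(matrices, Xq)
            Rp = naive_tensor(matrices, Xp)
            rank += float(np.asarray(alpha) @ (Rq - Rp) @ np.asarray(beta))
    rank *= 2.0 * l2
    clus = 0.0
    for T in matrices:
        for group, sign in ((X1, 1.0), (X2, 1.0)):
            m = len(group)
            for p in range(m):
                for q in range(p + 1, m):
                    d = naive_transform(T, group[p]) - naive_transform(T, group[q])
                    clus += sign * float(np.dot(d, d))
        for Xp in X1:
            for Xq in X2:
                d = naive_transform(T, Xp) - naive_transform(T, Xq)
                clus -= float(np.dot(d, d))
    clus *= l3
    return float(sq + reg + rank + clus)


def naive_S(k, j, matrices, alpha, beta, X, X1, X2, l3) -> np.ndarray:
    S = np.zeros((4, 4))
    for group, sign in ((X1, 1.0), (X2, 1.0)):
        m = len(group)
        for p in range(m):
            for q in range(p + 1, m):
                z = group[p][j, :] - group[q][j, :]
                S += sign * l3 * np.outer(z, z)
    for Xp in X1:
        for Xq in X2:
            z = Xp[j, :] - Xq[j, :]
            S -= l3 * np.outer(z, z)
    for Xl in X:
        S += alpha[k] ** 2 * beta[j] ** 2 * np.outer(Xl[j, :], Xl[j, :])
    return S


def naive_B(k, j, matrices, alpha, beta, X, y, X1, X2, l2) -> np.ndarray:
    vec = np.zeros(4)
    for l in range(len(y)):
        f = naive_predict(matrices, alpha, beta, X[l])
        loo = f - alpha[k] * beta[j] * float(np.dot(X[l][j, :], matrices[k][:, j]))
        vec += (y[l] - loo) * X[l][j, :]
    for Xp in X1:
        for Xq in X2:
            vec += l2 * (Xp[j, :] - Xq[j, :])
    return alpha[k] * beta[j] * vec


def naive_alpha(matrices, beta, X, y, X1, X2, l1, l2) -> np.ndarray:
    K = len(matrices)
    M = np.zeros((K, K))
    rhs = np.zeros(K)
    beta = np.asarray(beta)
    for l in range(len(y)):
        u = naive_tensor(matrices, X[l]) @ beta
        M += np.outer(u, u)
        rhs += y[l] * u
    M += l1 * float(np.dot(beta, beta)) * np.eye(K)
    for Xp in X1:
        for Xq in X2:
            rhs += l2 * (naive_tensor(matrices, Xp) - naive_tensor(matrices, Xq)) @ beta
    return np.linalg.solve(M, rhs)


def naive_beta(matrices, alpha, X, y, X1, X2, l1, l2) -> np.ndarray:
    alpha = np.asarray(alpha)
    n = matrices.shape[2]
    M = np.zeros((n, n))
    rhs = np.zeros(n)
    for l in range(len(y)):
        v = alpha @ naive_tensor(matrices, X[l])
        M += np.outer(v, v)
        rhs += y[l] * v
    M += l1 * float(np.dot(alpha, alpha)) * np.eye(n)
    for Xp in X1:
        for Xq in X2:
            rhs += l2 * alpha @ (naive_tensor(matrices, Xp) - naive_tensor(matrices, Xq))
    return np.linalg.solve(M, rhs)
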