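"""Independent reference solvers used to certify the production code.

Deliberately share no code with costdrivers.sgl: the full-vector proximal
gradient oracle recomputes its own soft-threshold/group-shrinkage inline and
iterates without blockwise decomposition; the plain-lasso oracle is a
textbook cyclic coordinate descent.
"""

import numpy as np


def sgl_objective(X, y, beta, groups, lam, alpha, n=None):
    """(1/2n)||y - Xb||^2 + lam[(1-a) sum ||b_j|| + a sum |b_i|], unit weights."""
    n = X.shape[0] if n is None else n
    r = y - X @ beta
    pen = 0.0
    for idx in groups:
        pen += (1 - alpha) * np.sqrt(np.sum(beta[idx] ** 2))
    pen += alpha * np.sum(np.abs(beta))
    return 0.5 * r @ r / n + lam * pen


def sgl_prox_gradient_oracle(X, y, groups, lam, alpha, max_iter=200000,
                             tol=1e-14):
    """Full-vector ISTA with the exact prox of the mixed penalty.

    For every group the prox of t*(a*lam*l1 + (1-a)*lam*l2) is the group
    shrinkage applied to the soft-thresholded vector.  Step size 1/L with
    L the largest eigenvalue of X'X/n.  Small problems only.
    """
    n, p = X.shape
    L = float(np.linalg.eigvalsh(X.T @ X / n)[-1])
    step = 1.0 / max(L, 1e-12)
    b = np.zeros(p)
    for _ in range(max_iter):
        grad = X.T @ (X @ b - y) / n
        v = b - step * grad
        new = np.empty_like(b)
        t1 = step * alpha * lam
        t2 = step * (1 - alpha) * lam
        for idx in groups:
            z = v[idx]
            s = np.sign(z) * np.maximum(np.abs(z) - t1, 0.0)
            nrm = np.sqrt(np.sum(s ** 2))
            new[idx] = 0.0 if nrm <= t2 else (1 - t2 / nrm) * s
        if np.max(np.abs(new - b)) < tol:
            b = new
            break
        b = new
    return b


def lasso_cd_oracle(X, y, lam, max_iter=100000, tol=1e-14):
    """Plain lasso via cyclic coordinate descent on standardized columns.

    Solves (1/2n)||y - Xb||^2 + lam * sum |b_i| assuming X'X/n has unit
    diagonal.
    """
    n, p = X.shape
    b = np.zeros(p)
    r = y.copy()
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            old = b[j]
            rho = X[:, j] @ r / n + old
            new = np.sign(rho) * max(abs(rho) - lam, 0.0)
            if new != old:
                r -= X[:, j] * (new - old)
                b[j] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return b


def pca_eig_oracle(B):
    """PCA of a column block by direct eigendecomposition of the covariance.

    Returns (centered block, eigenvalues descending, eigenvectors as columns).
    """
    Bc = B - B.mean(axis=0)
    cov = Bc.T @ Bc / B.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return Bc, evals[order], evecs[:, order]
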