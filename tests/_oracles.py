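"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written from first principles with the most
explicit possible linear algebra (pseudo-inverses, dense
eigendecompositions, elementwise loops) and share no code with the
package internals they verify.
"""

import numpy as np


def brute_force_cca_inertia(y, x, z=None):
    """Chi-square constrained-ordination inertia by explicit steps.

    y : sites x species counts; x : sites x p constraints; z : optional
    covariables.  Returns (total, conditioned, constrained, eigenvalues).
    """
    y = np.asarray(y, float)
    keep = y.sum(axis=1) > 0
    y = y[keep][:, y[keep].sum(axis=0) > 0]
    f = y.sum()
    n, m = y.shape
    p = y / f
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    q = np.empty_like(p)
    for i in range(n):
        for j in range(m):
            q[i, j] = (p[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    total = np.sum(q * q)

    def weighted_fit(design, target):
        # weighted-center columns, scale rows by sqrt(r), project via pinv
        d = np.asarray(design, float)
        if d.ndim == 1:
            d = d[:, None]
        d = d - np.sum(r[:, None] * d, axis=0)
        dw = np.sqrt(r)[:, None] * d
        beta = np.linalg.pinv(dw) @ target
        return dw @ beta

    conditioned = 0.0
    if z is not None:
        zk = np.asarray(z, float)[keep]
        fit_z = weighted_fit(zk, q)
        conditioned = float(np.sum(fit_z * fit_z))
        q = q - fit_z
        xk = np.asarray(x, float)[keep]
        if xk.ndim == 1:
            xk = xk[:, None]
        xk_c = xk - np.sum(r[:, None] * xk, axis=0)
        xw = np.sqrt(r)[:, None] * xk_c
        xw_fit = weighted_fit(zk, xw)
        fit = _pinv_project(xw - xw_fit, q)
    else:
        xk = np.asarray(x, float)[keep]
        fit = weighted_fit(xk, q)
    constrained = float(np.sum(fit * fit))
    # eigenvalues of the fitted part by dense eigendecomposition
    eigval = np.linalg.eigvalsh(fit @ fit.T)
    eigval = np.sort(eigval)[::-1]
    eigval = eigval[eigval > 1e-9 * max(eigval[0], 1e-30)]
    return float(total), conditioned, constrained, eigval


def _pinv_project(design, target):
    return design @ (np.linalg.pinv(design) @ target)


def partial_correlation_by_residuals(a, b, c):
    """Partial Pearson correlation of a and b given c via OLS residuals."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    design = np.column_stack([np.ones_like(c), c])
    ra = a - design @ np.linalg.lstsq(design, a, rcond=None)[0]
    rb = b - design @ np.linalg.lstsq(design, b, rcond=None)[0]
    return float(np.corrcoef(ra, rb)[0, 1])


def enumerate_fixed_margin_matrices(row_sums, col_sums):
    """All binary matrices with the given margins, by exhaustive search."""
    n, m = len(row_sums), len(col_sums)
    out = []

    def rec(i, cols_left, rows):
        if i == n:
            if all(c == 0 for c in cols_left):
                out.append(np.array(rows))
            return
        from itertools import combinations
        for cols in combinations(range(m), row_sums[i]):
            if all(cols_left[j] > 0 for j in cols):
                row = [1 if j in cols else 0 for j in range(m)]
                rec(i + 1,
                    [c - (1 if j in cols else 0)
                     for j, c in enumerate(cols_left)],
                    rows + [row])

    rec(0, list(col_sums), [])
    return out
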