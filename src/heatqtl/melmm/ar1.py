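"""Separable AR1 x AR1 residual correlation over field rows and columns.

The residual of environment j is N(0, sigma2_j * AR1(rho_col) (x)
AR1(rho_row)): plots at column-lag a and row-lag b correlate as
rho_col^a * rho_row^b. For a complete column x row grid the operator applies
solves and log-determinants through the small per-axis factors (never
materialising the plot x plot matrix); an incomplete grid falls back to a
dense principal submatrix.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["ar1_corr", "ar1_inv", "ar1_logdet", "ar1_dcorr", "ar1_kron_correlation",
           "AR1KronResidual"]


def ar1_corr(rho: float, n: int) -> np.ndarray:
    """Dense AR1 correlation matrix rho^|i-j|."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_inv(rho: float, n: int) -> np.ndarray:
    """Closed-form tridiagonal inverse of the AR1 correlation matrix."""
    if n == 1:
        return np.array([[1.0]])
    out = np.zeros((n, n))
    f = 1.0 / (1.0 - rho ** 2)
    d = np.full(n, (1.0 + rho ** 2) * f)
    d[0] = d[-1] = f
    np.fill_diagonal(out, d)
    off = -rho * f
    idx = np.arange(n - 1)
    out[idx, idx + 1] = off
    out[idx + 1, idx] = off
    return out


def ar1_logdet(rho: float, n: int) -> float:
    """log-determinant of the AR1 correlation matrix: (n-1) log(1 - rho^2)."""
    return (n - 1) * float(np.log1p(-rho ** 2))


def ar1_dcorr(rho: float, n: int) -> np.ndarray:
    """Elementwise derivative of rho^|i-j| with respect to rho."""
    idx = np.arange(n)
    lag = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        d = lag * np.where(lag > 0, rho ** (lag - 1.0), 0.0)
    return d


def ar1_kron_correlation(rho_row: float, rho_col: float, n_rows: int, n_cols: int
                         ) -> "AR1KronResidual":
    """Structured AR1(row) x AR1(col) correlation over a complete grid.

    Plots are ordered column-major (rows fastest). The returned operator
    supports matvec, solve and logdet without forming the dense matrix.
    """
    cols = np.repeat(np.arange(n_cols), n_rows)
    rows = np.tile(np.arange(n_rows), n_cols)
    op = AR1KronResidual(cols, rows)
    op.set_params(1.0, rho_row, rho_col)
    return op


class AR1KronResidual:
    """sigma2 * AR1(rho_col) (x) AR1(rho_row) over one environment's plots.

    ``cols``/``rows`` give each plot's grid address in plot order. A complete
    grid uses the factorised fast path; otherwise dense submatrices are used.
    """

    def __init__(self, cols, rows):
        cols = np.asarray(cols)
        rows = np.asarray(rows)
        self.n = len(cols)
        self.ucols, ci = np.unique(cols, return_inverse=True)
        self.urows, ri = np.unique(rows, return_inverse=True)
        self.nc, self.nr = len(self.ucols), len(self.urows)
        # plot -> (col index, row index); column-major grid linear index
        self.grid_index = ci * self.nr + ri
        self.full = self.n == self.nc * self.nr
        if self.full:
            # permutation grid order -> plot order
            self.perm = np.argsort(self.grid_index)
        self.sigma2 = None

    # -- parameterisation -------------------------------------------------
    def set_params(self, sigma2: float, rho_row: float, rho_col: float) -> None:
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not (abs(rho_row) < 1 and abs(rho_col) < 1):
            raise ValueError("|rho| must be < 1")
        self.sigma2, self.rho_row, self.rho_col = sigma2, rho_row, rho_col
        self.Ar = ar1_corr(rho_row, self.nr)
        self.Ac = ar1_corr(rho_col, self.nc)
        self.Ar_inv = ar1_inv(rho_row, self.nr)
        self.Ac_inv = ar1_inv(rho_col, self.nc)
        self.dAr = ar1_dcorr(rho_row, self.nr)
        self.dAc = ar1_dcorr(rho_col, self.nc)
        if not self.full:
            dense = np.kron(self.Ac, self.Ar)[np.ix_(self.grid_index, self.grid_index)]
            self._dense_corr = dense
            self._dense_cho = cho_factor(dense, lower=True)
            self._dense_inv = cho_solve(self._dense_cho, np.eye(self.n))

    # -- structured application -------------------------------------------
    def _apply_factors(self, M: np.ndarray, Fc: np.ndarray, Fr: np.ndarray) -> np.ndarray:
        """(Fc (x) Fr) M for plot-ordered M, via the grid fast path."""
        one_d = M.ndim == 1
        M2 = M[:, None] if one_d else M
        m = M2.shape[1]
        if self.full:
            grid = np.empty((self.n, m))
            grid[self.grid_index] = M2  # plot -> grid order
            g = grid.reshape(self.nc, self.nr, m)
            g = np.tensordot(Fc, g, axes=(1, 0))          # cols
            g = np.tensordot(Fr, g, axes=(1, 1)).transpose(1, 0, 2)  # rows
            out = g.reshape(self.n, m)[self.grid_index]
        else:
            dense = np.kron(Fc, Fr)[np.ix_(self.grid_index, self.grid_index)]
            out = dense @ M2
        return out[:, 0] if one_d else out

    def matvec(self, M: np.ndarray) -> np.ndarray:
        return self.sigma2 * self._apply_factors(M, self.Ac, self.Ar)

    def solve(self, M: np.ndarray) -> np.ndarray:
        if self.full:
            return self._apply_factors(M, self.Ac_inv, self.Ar_inv) / self.sigma2
        one_d = M.ndim == 1
        M2 = M[:, None] if one_d else M
        out = cho_solve(self._dense_cho, M2) / self.sigma2
        return out[:, 0] if one_d else out

    def logdet(self) -> float:
        base = self.n * float(np.log(self.sigma2))
        if self.full:
            return base + self.nr * ar1_logdet(self.rho_col, self.nc) \
                + self.nc * ar1_logdet(self.rho_row, self.nr)
        sign, ld = np.linalg.slogdet(self._dense_corr)
        return base + ld

    def dense(self) -> np.ndarray:
        """Dense covariance (tests and small problems only)."""
        if self.full:
            full = self.sigma2 * np.kron(self.Ac, self.Ar)
            return full[np.ix_(self.grid_index, self.grid_index)]
        return self.sigma2 * self._dense_corr

    # -- derivatives -------------------------------------------------------
    def dmatvec(self, M: np.ndarray, wrt: str) -> np.ndarray:
        """(dR / d theta) M for theta in {sigma2, rho_row, rho_col}."""
        if wrt == "sigma2":
            return self._apply_factors(M, self.Ac, self.Ar)
        if wrt == "rho_row":
            return self.sigma2 * self._apply_factors(M, self.Ac, self.dAr)
        if wrt == "rho_col":
            return self.sigma2 * self._apply_factors(M, self.dAc, self.Ar)
        raise ValueError(wrt)

    def trace_rinv_dr(self, wrt: str) -> float:
        """tr(R^{-1} dR/dtheta)."""
        if self.full:
            if wrt == "sigma2":
                return self.n / self.sigma2
            if wrt == "rho_row":
                return self.nc * float(np.sum(self.Ar_inv * self.dAr))
            if wrt == "rho_col":
                return self.nr * float(np.sum(self.Ac_inv * self.dAc))
            raise ValueError(wrt)
        if wrt == "sigma2":
            return self.n / self.sigma2
        if wrt == "rho_row":
            dsub = np.kron(self.Ac, self.dAr)[np.ix_(self.grid_index, self.grid_index)]
        elif wrt == "rho_col":
            dsub = np.kron(self.dAc, self.Ar)[np.ix_(self.grid_index, self.grid_index)]
        else:
            raise ValueError(wrt)
        return float(np.sum(self._dense_inv * dsub))
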