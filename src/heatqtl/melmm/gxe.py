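"""Environment-by-environment genetic covariance structures.

The genotype-by-environment effects u_g (stacked environment-major: all
lines of environment 1, then environment 2, ...) have covariance

    Sigma = sum_m Delta_m (x) K_m

where each Delta_m is a t x t across-environment covariance model (factor
analytic Lambda Lambda^T + Psi, diagonal, or unstructured) and K_m is an
r x r line-relationship kernel (identity, or a genomic relationship matrix).
One term covers the baseline model (Delta (x) I); the scan's pair
(Delta_a (x) G_{-i}) + (Delta_p (x) I) is handled jointly through the
eigenbasis of G, which keeps inverses and log-determinants at t x t cost per
line eigenvalue.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FADelta", "DiagDelta", "UnstructuredDelta", "GxECov", "default_delta"]


class FADelta:
    """Factor-analytic Delta = Lambda Lambda^T + diag(Psi), order k.

    Free parameters: the lower-trapezoid of Lambda (entries with row >= col;
    the upper triangle of the first k rows is pinned at zero for rotational
    identifiability) followed by the t specific variances.
    """

    def __init__(self, t: int, k: int):
        if not (1 <= k < max(t, 2)):
            raise ValueError("FA order k must satisfy 1 <= k < t")
        self.t, self.k = t, k
        self.free = [(j, l) for l in range(k) for j in range(t) if j >= l]
        self.n_params = len(self.free) + t

    def _lambda(self, theta: np.ndarray) -> np.ndarray:
        lam = np.zeros((self.t, self.k))
        for idx, (j, l) in enumerate(self.free):
            lam[j, l] = theta[idx]
        return lam

    def delta(self, theta: np.ndarray) -> np.ndarray:
        lam = self._lambda(theta)
        return lam @ lam.T + np.diag(theta[len(self.free):])

    def ddelta(self, theta: np.ndarray) -> list[np.ndarray]:
        lam = self._lambda(theta)
        out = []
        for j, l in self.free:
            d = np.zeros((self.t, self.t))
            d[j, :] += lam[:, l]
            d[:, j] += lam[:, l]
            out.append(d)
        for j in range(self.t):
            d = np.zeros((self.t, self.t))
            d[j, j] = 1.0
            out.append(d)
        return out

    def init_params(self, gvar: np.ndarray) -> np.ndarray:
        gvar = np.broadcast_to(np.asarray(gvar, float), (self.t,))
        theta = np.empty(self.n_params)
        for idx, (j, l) in enumerate(self.free):
            # first factor carries most structure; later ones start small
            theta[idx] = np.sqrt(0.5 * gvar[j]) * (1.0 if l == 0 else 0.3 / (l + 1))
        theta[len(self.free):] = 0.4 * gvar
        return theta

    def init_from_cov(self, cov: np.ndarray) -> np.ndarray:
        """Start Lambda/Psi from a moment estimate of Delta (leading PCs)."""
        cov = (cov + cov.T) / 2.0
        w, V = np.linalg.eigh(cov)
        w = np.maximum(w[::-1], 1e-8 * max(w.max(), 1e-12))
        V = V[:, ::-1]
        lam = np.zeros((self.t, self.k))
        for l in range(min(self.k, self.t)):
            scale = 1.0 if l == 0 else 0.7
            lam[:, l] = np.sqrt(w[l]) * V[:, l] * scale
        # rotate towards the identifiability pattern: just zero the pinned cells
        theta = np.empty(self.n_params)
        for idx, (j, l) in enumerate(self.free):
            theta[idx] = lam[j, l]
        resid = np.diag(cov) - np.sum(lam ** 2, axis=1)
        theta[len(self.free):] = np.maximum(resid, 0.1 * np.maximum(np.diag(cov), 1e-12))
        return theta

    def clamp(self, theta: np.ndarray, floor: float) -> np.ndarray:
        out = theta.copy()
        out[len(self.free):] = np.maximum(out[len(self.free):], floor)
        return out

    def bounds(self, floor: float) -> tuple[np.ndarray, np.ndarray]:
        lb = np.full(self.n_params, -np.inf)
        lb[len(self.free):] = floor
        return lb, np.full(self.n_params, np.inf)

    def param_names(self) -> list[str]:
        return [f"lambda[{j + 1},{l + 1}]" for j, l in self.free] + \
               [f"psi[{j + 1}]" for j in range(self.t)]


class DiagDelta:
    """Independent environments: Delta = diag(variances)."""

    def __init__(self, t: int):
        self.t = t
        self.n_params = t

    def delta(self, theta: np.ndarray) -> np.ndarray:
        return np.diag(theta)

    def ddelta(self, theta: np.ndarray) -> list[np.ndarray]:
        out = []
        for j in range(self.t):
            d = np.zeros((self.t, self.t))
            d[j, j] = 1.0
            out.append(d)
        return out

    def init_params(self, gvar: np.ndarray) -> np.ndarray:
        return np.broadcast_to(np.asarray(gvar, float), (self.t,)).copy()

    def init_from_cov(self, cov: np.ndarray) -> np.ndarray:
        return np.maximum(np.diag(cov).copy(), 1e-12)

    def clamp(self, theta: np.ndarray, floor: float) -> np.ndarray:
        return np.maximum(theta, floor)

    def bounds(self, floor: float) -> tuple[np.ndarray, np.ndarray]:
        return np.full(self.t, floor), np.full(self.t, np.inf)

    def param_names(self) -> list[str]:
        return [f"var[{j + 1}]" for j in range(self.t)]


class UnstructuredDelta:
    """Unstructured PSD Delta through its Cholesky factor L (Delta = L L^T)."""

    def __init__(self, t: int):
        self.t = t
        self.free = [(i, j) for j in range(t) for i in range(j, t)]
        self.n_params = len(self.free)

    def _chol(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.t, self.t))
        for idx, (i, j) in enumerate(self.free):
            L[i, j] = theta[idx]
        return L

    def delta(self, theta: np.ndarray) -> np.ndarray:
        L = self._chol(theta)
        return L @ L.T

    def ddelta(self, theta: np.ndarray) -> list[np.ndarray]:
        L = self._chol(theta)
        out = []
        for i, j in self.free:
            d = np.zeros((self.t, self.t))
            d[i, :] += L[:, j]
            d[:, i] += L[:, j]
            out.append(d)
        return out

    def init_params(self, gvar: np.ndarray) -> np.ndarray:
        gvar = np.broadcast_to(np.asarray(gvar, float), (self.t,))
        theta = np.zeros(self.n_params)
        for idx, (i, j) in enumerate(self.free):
            if i == j:
                theta[idx] = np.sqrt(0.8 * gvar[i])
            elif j == 0:
                theta[idx] = 0.3 * np.sqrt(gvar[i])
        return theta

    def init_from_cov(self, cov: np.ndarray) -> np.ndarray:
        cov = (cov + cov.T) / 2.0
        w, V = np.linalg.eigh(cov)
        w = np.maximum(w, 1e-6 * max(w.max(), 1e-12))
        L = np.linalg.cholesky((V * w) @ V.T)
        theta = np.empty(self.n_params)
        for idx, (i, j) in enumerate(self.free):
            theta[idx] = L[i, j]
        return theta

    def clamp(self, theta: np.ndarray, floor: float) -> np.ndarray:
        out = theta.copy()
        root = np.sqrt(floor)
        for idx, (i, j) in enumerate(self.free):
            if i == j and abs(out[idx]) < root:
                out[idx] = root
        return out

    def bounds(self, floor: float) -> tuple[np.ndarray, np.ndarray]:
        lb = np.full(self.n_params, -np.inf)
        for idx, (i, j) in enumerate(self.free):
            if i == j:
                lb[idx] = np.sqrt(floor)
        return lb, np.full(self.n_params, np.inf)

    def param_names(self) -> list[str]:
        return [f"chol[{i + 1},{j + 1}]" for i, j in self.free]


def default_delta(t: int, k: int | None = None):
    """The package's FA-order rule: k = 1 for t <= 4, k = 2 for t >= 5.

    t = 1 degenerates to a plain genetic variance (diagonal model); an
    explicit ``k`` overrides the rule.
    """
    if t == 1:
        return DiagDelta(1)
    if k is None:
        k = 1 if t <= 4 else 2
    return FADelta(t, k)


class GxECov:
    """Sum of Delta (x) K terms over environment-major G x E effects.

    ``terms`` is a list of (name, delta_model, K) with K an r x r kernel or
    None for the identity. Supported: a single term, or exactly two terms
    whose second kernel is the identity (the scan's additive + polygenic
    pair).
    """

    def __init__(self, terms, n_lines: int, ridge: float = 1e-8):
        self.terms = []
        self.n_lines = n_lines
        for name, delta, K in terms:
            if K is not None:
                K = np.asarray(K, float)
                if K.shape != (n_lines, n_lines):
                    raise ValueError(f"kernel of term {name!r} has wrong shape")
                # small ridge keeps a rank-deficient GRM invertible
                K = K + ridge * (np.trace(K) / n_lines + 1.0) * np.eye(n_lines)
            self.terms.append((name, delta, K))
        kinds = [K is not None for _, _, K in self.terms]
        if len(self.terms) == 2:
            if kinds[1]:
                raise ValueError("with two terms the second kernel must be identity")
            name, delta, K = self.terms[0]
            if K is not None:
                w, U = np.linalg.eigh(K)
                self._eig = (np.maximum(w, 0.0), U)
            else:
                self._eig = (np.ones(n_lines), None)
        elif len(self.terms) == 1:
            name, delta, K = self.terms[0]
            if K is not None:
                self._K_inv = np.linalg.inv(K)
                self._K_logdet = float(np.linalg.slogdet(K)[1])
        else:
            raise ValueError("GxECov supports one or two terms")
        self.t = self.terms[0][1].t
        self.n_params = sum(d.n_params for _, d, _ in self.terms)
        self.q = self.t * n_lines

    def split(self, theta: np.ndarray) -> list[np.ndarray]:
        out, at = [], 0
        for _, d, _ in self.terms:
            out.append(theta[at:at + d.n_params])
            at += d.n_params
        return out

    def init_params(self, gvar) -> np.ndarray:
        parts = []
        for i, (_, d, K) in enumerate(self.terms):
            g = np.broadcast_to(np.asarray(gvar, float), (self.t,)) / len(self.terms)
            if K is not None:
                g = g / (np.trace(K) / self.n_lines)  # kernel carries scale
            parts.append(d.init_params(g))
        return np.concatenate(parts)

    def init_from_cov(self, cov: np.ndarray) -> np.ndarray:
        """Start from a moment estimate of the total G x E covariance.

        With a kernel term present, most of the moment covariance seeds the
        identity-kernel term; the kernel term starts small (its truth may
        well be zero) and scaled by the kernel's mean diagonal.
        """
        parts = []
        if len(self.terms) == 1:
            _, d, K = self.terms[0]
            scale = np.trace(K) / self.n_lines if K is not None else 1.0
            parts.append(d.init_from_cov(cov / scale))
        else:
            (_, da, Ka), (_, dp, _) = self.terms
            scale = np.trace(Ka) / self.n_lines
            parts.append(da.init_from_cov(0.05 * cov / scale))
            parts.append(dp.init_from_cov(0.95 * cov))
        return np.concatenate(parts)

    def clamp(self, theta: np.ndarray, floor: float) -> np.ndarray:
        parts = []
        for th, (_, d, K) in zip(self.split(theta), self.terms):
            f = floor / (np.trace(K) / self.n_lines) if K is not None else floor
            parts.append(d.clamp(th, f))
        return np.concatenate(parts)

    def bounds(self, floor: float) -> tuple[np.ndarray, np.ndarray]:
        lbs, ubs = [], []
        for _, d, K in self.terms:
            f = floor / (np.trace(K) / self.n_lines) if K is not None else floor
            lb, ub = d.bounds(f)
            lbs.append(lb)
            ubs.append(ub)
        return np.concatenate(lbs), np.concatenate(ubs)

    def param_names(self) -> list[str]:
        out = []
        for name, d, _ in self.terms:
            out += [f"{name}:{p}" for p in d.param_names()]
        return out

    def deltas(self, theta: np.ndarray) -> dict:
        return {name: d.delta(th)
                for th, (name, d, _) in zip(self.split(theta), self.terms)}

    def inv_and_logdet(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        """Dense q x q Sigma^{-1} and log|Sigma|."""
        r = self.n_lines
        thetas = self.split(theta)
        if len(self.terms) == 1:
            name, dmod, K = self.terms[0]
            delta = dmod.delta(thetas[0])
            sign, ld_delta = np.linalg.slogdet(delta)
            if sign <= 0:
                raise np.linalg.LinAlgError("Delta not positive definite")
            dinv = np.linalg.inv(delta)
            if K is None:
                sinv = np.kron(dinv, np.eye(r))
                logdet = r * ld_delta
            else:
                sinv = np.kron(dinv, self._K_inv)
                logdet = r * ld_delta + self.t * self._K_logdet
            return sinv, float(logdet)
        # two terms: Delta_a (x) K + Delta_p (x) I via the eigenbasis of K
        (na, da, Ka), (np_, dp, _) = self.terms
        delta_a = da.delta(thetas[0])
        delta_p = dp.delta(thetas[1])
        w, U = self._eig
        # per-eigenvalue t x t blocks
        B = delta_a[None, :, :] * w[:, None, None] + delta_p[None, :, :]
        sign, ld = np.linalg.slogdet(B)
        if (sign <= 0).any():
            raise np.linalg.LinAlgError("G x E covariance not positive definite")
        Binv = np.linalg.inv(B)  # (r, t, t)
        t = self.t
        sinv = np.empty((self.q, self.q))
        for a in range(t):
            for b in range(a, t):
                if U is None:
                    block = np.diag(Binv[:, a, b])
                else:
                    block = (U * Binv[:, a, b]) @ U.T
                sinv[a * r:(a + 1) * r, b * r:(b + 1) * r] = block
                if b != a:
                    sinv[b * r:(b + 1) * r, a * r:(a + 1) * r] = block.T
        return sinv, float(ld.sum())
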