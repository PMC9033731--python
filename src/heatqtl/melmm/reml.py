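"""Average-information REML for the multi-environment linear mixed model.

Model: y = X beta + Z_g u_g + sum_k Z_k u_k + e, with

* u_g ~ N(0, Sigma_g), Sigma_g a :class:`~heatqtl.melmm.gxe.GxECov`
  (factor-analytic Delta (x) kernel terms, environment-major);
* u_k iid random design terms (blocks, rows, columns), one variance each;
* e independent across environments, within environment
  N(0, sigma2_j AR1(rho_col) (x) AR1(rho_row)).

Estimation maximises the residual log-likelihood by damped average-
information (AI) updates: the AI step is solved from (AI + lambda diag AI),
the damping growing until the step both stays in the parameter domain and
does not decrease the likelihood (a Levenberg-style fallback that replaces
explicit EM steps). Residual solves use the Woodbury identity through the
random-effect system C = Sigma^{-1} + Z' R^{-1} Z, so the per-iteration cost
is a Cholesky of C plus two triangular-solve sweeps; the AR1 (x) AR1 blocks
never materialise.

Variance parameters are floored at ``floor_frac * var(y)`` rather than
allowed to hit zero, keeping every covariance invertible; autocorrelations
are clipped to |rho| <= 0.98.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ..types import FAParams, SpatialParams
from .ar1 import AR1KronResidual
from .design import ModelSpec
from .gxe import FADelta, GxECov, default_delta

__all__ = ["REMLOptions", "FitResult", "MixedModel", "reml_fit", "genetic_correlations"]


@dataclass
class REMLOptions:
    """Convergence and model-structure controls for the REML fit."""

    max_iter: int = 100
    tol: float = 1e-8
    estimate_spatial_corr: bool = True
    floor_frac: float = 1e-8
    verbose: bool = False
    max_inner: int = 12


@dataclass
class FitResult:
    """REML estimates, fixed effects, and convergence diagnostics."""

    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    beta: pd.Series
    beta_se: pd.Series
    deltas: dict
    spatial: SpatialParams
    extra_variances: dict
    theta: np.ndarray
    param_names: list
    theta_se: np.ndarray
    iter_log: list = field(default_factory=list, repr=False)
    model: "MixedModel | None" = field(default=None, repr=False)

    def fa_params(self, term: str = "g") -> FAParams:
        model = self.model.gxe
        for (name, dmod, _), th in zip(model.terms, model.split(self._gxe_theta())):
            if name == term and isinstance(dmod, FADelta):
                lam = dmod._lambda(th)
                psi = th[len(dmod.free):]
                return FAParams(lam, psi)
        raise ValueError(f"term {term!r} is not factor-analytic")

    def _gxe_theta(self) -> np.ndarray:
        return self.theta[: self.model.gxe.n_params]

    def genetic_blups(self) -> pd.DataFrame:
        """Genotype-by-environment predictions (lines x environments)."""
        st = self.model.state
        spec = self.model.spec
        r, t = spec.n_lines, spec.n_env
        g = st.g[: r * t].reshape(t, r)
        out = np.zeros((t, r))
        for (name, dmod, K), th in zip(self.model.gxe.terms,
                                       self.model.gxe.split(self._gxe_theta())):
            delta = dmod.delta(th)
            gk = g @ K if K is not None else g
            out += delta @ gk
        return pd.DataFrame(out.T, index=spec.lines, columns=spec.envs)


class _State:
    """Caches for one evaluation of the residual log-likelihood."""

    __slots__ = (
        "theta", "loglik", "ops", "C_L", "B", "Sinv", "Vy", "VX", "Phi",
        "XtVX_L", "beta", "Py", "yPy", "g", "Xg", "logdet_parts",
    )


class MixedModel:
    """One trait's ME-LMM: design + G x E structure + REML machinery."""

    def __init__(self, spec: ModelSpec, gxe: GxECov, options: REMLOptions | None = None):
        if gxe.n_lines != spec.n_lines or gxe.t != spec.n_env:
            raise ValueError("G x E structure disagrees with the design")
        self.spec = spec
        self.gxe = gxe
        self.opt = options or REMLOptions()
        self._check_fixed_rank()
        self._assemble()
        self.state: _State | None = None

    # ------------------------------------------------------------------
    def _check_fixed_rank(self) -> None:
        X = self.spec.X
        q, rmat = np.linalg.qr(X)
        diag = np.abs(np.diag(rmat))
        bad = diag < 1e-10 * max(diag.max(), 1.0)
        if bad.any():
            names = [self.spec.fixed_names[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"aliased fixed-effect levels: {', '.join(names)}")

    def _assemble(self) -> None:
        spec = self.spec
        self.qg = spec.n_lines * spec.n_env
        mats = [spec.Zg] + [term.Z for term in spec.extra_terms]
        self.Z = sparse.hstack(mats, format="csr")
        self.q = self.Z.shape[1]
        self.extra_ranges = []
        at = self.qg
        for term in spec.extra_terms:
            self.extra_ranges.append((term.name, at, at + term.n_levels))
            at += term.n_levels
        # per-environment locals
        self.env_rows = [spec.env_rows(e) for e in range(spec.n_env)]
        self.ops = []
        self.Zloc = []
        self.act = []
        for e, env in enumerate(spec.envs):
            cols, rows = spec.layout[env]
            self.ops.append(AR1KronResidual(cols, rows))
            Zs = self.Z[self.env_rows[e]].tocsc()
            nnz = np.diff(Zs.indptr) > 0
            act = np.flatnonzero(nnz)
            self.act.append(act)
            self.Zloc.append(Zs[:, act].tocsr())
        self.var_y = float(np.var(spec.y))
        self.floor = self.opt.floor_frac * self.var_y
        self.lb, self.ub = self._param_bounds()

    # -- parameter vector ----------------------------------------------
    @property
    def n_resid_params(self) -> int:
        per = 3 if self.opt.estimate_spatial_corr else 1
        return per * self.spec.n_env

    def param_names(self) -> list:
        names = list(self.gxe.param_names())
        names += [f"var:{name}" for name, _, _ in self.extra_ranges]
        for env in self.spec.envs:
            names.append(f"sigma2({env})")
            if self.opt.estimate_spatial_corr:
                names += [f"rho_row({env})", f"rho_col({env})"]
        return names

    def _moment_estimates(self) -> tuple[np.ndarray, np.ndarray]:
        """Crude per-env residual variances and G x E covariance from the data.

        Residual variance comes from within-environment duplicate-plot
        differences of the p-rep design (Var(y1 - y2) = 2 sigma2 under weak
        spatial correlation); the across-environment genetic covariance from
        line-by-environment means. Used only to start the optimiser.
        """
        spec = self.spec
        r, t = spec.n_lines, spec.n_env
        line_of = {}
        rows, cols = spec.Zg.nonzero()
        sums = np.zeros((t, r))
        cnts = np.zeros((t, r))
        for i, j in zip(rows, cols):
            sums[j // r, j % r] += spec.y[i]
            cnts[j // r, j % r] += 1
        sig2 = np.empty(t)
        for e in range(t):
            env_rows = self.env_rows[e]
            # duplicate-pair differences within this environment
            diffs = []
            first = {}
            for i, j in zip(rows, cols):
                if j // r != e:
                    continue
                key = j % r
                if key in first:
                    diffs.append(spec.y[i] - first[key])
                else:
                    first[key] = spec.y[i]
            if len(diffs) >= 10:
                sig2[e] = 0.5 * float(np.var(diffs))
            else:
                sig2[e] = 0.5 * float(np.var(spec.y[env_rows]))
            sig2[e] = max(sig2[e], 10 * self.floor)
        with np.errstate(invalid="ignore"):
            means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        dm = pd.DataFrame(means.T)  # lines x envs
        cov = dm.cov(min_periods=2).to_numpy()
        cov = np.where(np.isfinite(cov), cov, 0.0)
        # remove the residual share of the means' variance
        mean_reps = np.where(cnts.sum(axis=1) > 0, cnts.mean(axis=1), 1.0)
        np.fill_diagonal(cov, np.maximum(np.diag(cov) - sig2 / np.maximum(mean_reps, 1.0),
                                         0.05 * np.maximum(np.diag(cov), 10 * self.floor)))
        return sig2, cov

    def init_theta(self) -> np.ndarray:
        try:
            sig2, cov = self._moment_estimates()
            parts = [self.gxe.init_from_cov(cov)]
        except Exception:
            v = self.var_y
            sig2 = np.full(self.spec.n_env, 0.5 * v)
            parts = [self.gxe.init_params(0.4 * v)]
        parts.append(np.full(len(self.extra_ranges), 0.05 * self.var_y))
        res = []
        for e in range(self.spec.n_env):
            res.append(sig2[e])
            if self.opt.estimate_spatial_corr:
                res += [0.1, 0.1]
        parts.append(np.array(res))
        return self.clamp(np.concatenate(parts))

    def _split_resid(self, theta: np.ndarray):
        nres = self.n_resid_params
        res = theta[len(theta) - nres:]
        per = 3 if self.opt.estimate_spatial_corr else 1
        out = []
        for e in range(self.spec.n_env):
            chunk = res[e * per:(e + 1) * per]
            if self.opt.estimate_spatial_corr:
                out.append((chunk[0], chunk[1], chunk[2]))
            else:
                out.append((chunk[0], 0.0, 0.0))
        return out

    def _param_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb_g, ub_g = self.gxe.bounds(self.floor)
        ne = len(self.extra_ranges)
        lb = [lb_g, np.full(ne, self.floor)]
        ub = [ub_g, np.full(ne, np.inf)]
        per = 3 if self.opt.estimate_spatial_corr else 1
        for _ in self.spec.envs:
            lb.append(np.array([self.floor] + [-0.98] * (per - 1)))
            ub.append(np.array([np.inf] + [0.98] * (per - 1)))
        return np.concatenate(lb), np.concatenate(ub)

    def clamp(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lb, self.ub)

    # -- core linear algebra --------------------------------------------
    def _rsolve(self, M: np.ndarray) -> np.ndarray:
        out = np.empty_like(M)
        for e, rows in enumerate(self.env_rows):
            out[rows] = self.ops[e].solve(M[rows])
        return out

    def _zt(self, M: np.ndarray) -> np.ndarray:
        """Z^T M for dense M."""
        one_d = M.ndim == 1
        M2 = M[:, None] if one_d else M
        out = np.zeros((self.q, M2.shape[1]))
        for e, rows in enumerate(self.env_rows):
            out[self.act[e]] += self.Zloc[e].T @ M2[rows]
        return out[:, 0] if one_d else out

    def _evaluate(self, theta: np.ndarray) -> _State:
        spec = self.spec
        st = _State()
        st.theta = theta
        ng = self.gxe.n_params
        ne = len(self.extra_ranges)
        for e, (s2, rr, rc) in enumerate(self._split_resid(theta)):
            self.ops[e].set_params(s2, rr, rc)
        st.ops = self._split_resid(theta)
        logdet_R = sum(op.logdet() for op in self.ops)

        Sinv_g, logdet_Sg = self.gxe.inv_and_logdet(theta[:ng])
        Sinv = np.zeros((self.q, self.q))
        Sinv[: self.qg, : self.qg] = Sinv_g
        logdet_S = logdet_Sg
        for (name, lo, hi), v in zip(self.extra_ranges, theta[ng:ng + ne]):
            idx = np.arange(lo, hi)
            Sinv[idx, idx] = 1.0 / v
            logdet_S += (hi - lo) * np.log(v)
        st.Sinv = Sinv

        # F_e = R_e^{-1} Z_e  (per-env local dense)
        self._FR = []
        B = np.zeros((self.q, self.q))
        for e, rows in enumerate(self.env_rows):
            Zd = np.asarray(self.Zloc[e].todense())
            FRe = self.ops[e].solve(Zd)
            self._FR.append(FRe)
            act = self.act[e]
            B[np.ix_(act, act)] += self.Zloc[e].T @ FRe
        st.B = B
        C = Sinv + B
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("random-effect system not PD") from err
        st.C_L = L
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))

        def vinv(M: np.ndarray) -> np.ndarray:
            one_d = M.ndim == 1
            M2 = M[:, None] if one_d else M
            RM = self._rsolve(M2)
            tZ = self._zt(RM)
            w = cho_solve((L, True), tZ)
            out = RM.copy()
            for e, rows in enumerate(self.env_rows):
                out[rows] -= self._FR[e] @ w[self.act[e]]
            return out[:, 0] if one_d else out

        self._vinv = vinv
        y, X = spec.y, spec.X
        st.Vy = vinv(y)
        st.VX = vinv(X)
        XtVX = X.T @ st.VX
        XtVX = (XtVX + XtVX.T) / 2.0
        try:
            XL = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("X' V^{-1} X not PD") from err
        st.XtVX_L = XL
        logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(XL))))
        st.Phi = cho_solve((XL, True), np.eye(X.shape[1]))
        xty = X.T @ st.Vy
        st.beta = cho_solve((XL, True), xty)
        st.Py = st.Vy - st.VX @ st.beta
        st.yPy = float(y @ st.Py)
        st.g = self._zt(st.Py)
        st.Xg = self._zt(st.VX)
        st.logdet_parts = (logdet_R, logdet_S, logdet_C, logdet_XtVX)
        st.loglik = -0.5 * (logdet_R + logdet_S + logdet_C + logdet_XtVX + st.yPy)
        return st

    # -- derivatives ------------------------------------------------------
    def _derivatives(self, st: _State):
        spec = self.spec
        r, t = spec.n_lines, spec.n_env
        theta = st.theta
        ng = self.gxe.n_params
        ne = len(self.extra_ranges)
        L = st.C_L
        # Traces against W = Z' V^{-1} Z = B - E'E (E = L^{-1} B) are taken
        # blockwise below without materialising W.
        E = solve_triangular(L, st.B, lower=True)
        E_colsq = np.einsum("ij,ij->j", E, E)
        Phi = st.Phi
        VXPhi = st.VX @ Phi

        scores = np.empty(len(theta))
        H = np.empty((spec.n_plots, len(theta)))

        gmat = st.g[: r * t].reshape(t, r)
        Xgm = st.Xg[: r * t].reshape(t, r, -1)
        p = Xgm.shape[2]
        at = 0
        for (name, dmod, K), th in zip(self.gxe.terms, self.gxe.split(theta[:ng])):
            if K is not None:
                Kg = gmat @ K             # t x r
                KX = np.tensordot(K, Xgm, axes=(1, 1)).transpose(1, 0, 2)
            else:
                Kg = gmat
                KX = Xgm
            Gamma = gmat @ Kg.T          # quadratic frame
            # trace frames: tr(K W_ab) with W = B - E'E; B genetic blocks are
            # env-diagonal, so only the E'E part couples environments
            Eg = [E[:, a * r:(a + 1) * r] for a in range(t)]
            EK = [eg @ K for eg in Eg] if K is not None else Eg
            T = np.empty((t, t))
            for a in range(t):
                Baa = st.B[a * r:(a + 1) * r, a * r:(a + 1) * r]
                diag_part = float(np.sum(K * Baa)) if K is not None \
                    else float(np.trace(Baa))
                for b in range(a, t):
                    ee = float(np.sum(Eg[a] * EK[b]))
                    T[a, b] = T[b, a] = (diag_part if a == b else 0.0) - ee
            XgPhi = np.einsum("arp,pq->arq", Xgm, Phi)
            U = np.einsum("arp,brp->ab", XgPhi, KX)
            U = (U + U.T) / 2.0
            for i, ddel in enumerate(dmod.ddelta(th)):
                tr_part = float(np.sum(ddel * (T - U)))
                quad = float(np.sum(ddel * Gamma))
                scores[at + i] = -0.5 * (tr_part - quad)
                svec = np.zeros(self.q)
                svec[: r * t] = (ddel @ Kg).ravel()
                H[:, at + i] = self.Z @ svec
            at += dmod.n_params

        for (name, lo, hi), v in zip(self.extra_ranges, theta[ng:ng + ne]):
            idx = np.arange(lo, hi)
            tr_vinv = float(np.sum(np.diag(st.B)[idx] - E_colsq[idx]))
            tr_q = float(np.sum((st.Xg[idx] @ Phi) * st.Xg[idx]))
            quad = float(st.g[idx] @ st.g[idx])
            scores[at] = -0.5 * (tr_vinv - tr_q - quad)
            svec = np.zeros(self.q)
            svec[idx] = st.g[idx]
            H[:, at] = self.Z @ svec
            at += 1

        per = 3 if self.opt.estimate_spatial_corr else 1
        wrts = ("sigma2", "rho_row", "rho_col")[:per]
        for e, rows in enumerate(self.env_rows):
            op = self.ops[e]
            act = self.act[e]
            # E_j = L^{-1} F_j' expanded to all q rows
            Fq = np.zeros((self.q, len(rows)))
            Fq[act] = self._FR[e].T
            Ej = solve_triangular(L, Fq, lower=True)
            Py_j = st.Py[rows]
            VX_j = st.VX[rows]
            VXPhi_j = VXPhi[rows]
            for w_i, wrt in enumerate(wrts):
                dPy = op.dmatvec(Py_j, wrt)
                quad = float(Py_j @ dPy)
                tr1 = op.trace_rinv_dr(wrt)
                tr2 = float(np.sum(Ej.T * op.dmatvec(Ej.T, wrt)))
                trq = float(np.sum(VXPhi_j * op.dmatvec(VX_j, wrt)))
                scores[at] = -0.5 * ((tr1 - tr2 - trq) - quad)
                h = np.zeros(spec.n_plots)
                h[rows] = dPy
                H[:, at] = h
                at += 1

        PH = self._vinv(H)
        PH -= st.VX @ (Phi @ (spec.X.T @ PH))
        AI = 0.5 * (H.T @ PH)
        AI = (AI + AI.T) / 2.0
        return scores, AI

    # -- optimisation -----------------------------------------------------
    def fit(self, start: np.ndarray | None = None) -> FitResult:
        theta = self.clamp(start.copy() if start is not None else self.init_theta())
        st = self._evaluate(theta)
        lam = 1e-3
        iter_log = []
        converged = False
        grad_norm = np.inf
        n_iter = 0
        btol = 1e-6 * (1.0 + np.abs(np.where(np.isfinite(self.lb), self.lb, 0.0)))
        for n_iter in range(1, self.opt.max_iter + 1):
            scores, AI = self._derivatives(st)
            # active set: parameters pinned at a bound whose gradient points
            # outward are frozen out of the AI system this iteration
            at_lo = (st.theta <= self.lb + btol) & (scores < 0)
            at_hi = (st.theta >= self.ub - btol) & (scores > 0)
            free = ~(at_lo | at_hi)
            grad_norm = float(np.max(np.abs(scores[free]))) if free.any() else 0.0
            if not free.any():
                converged = True
                iter_log.append((n_iter, st.loglik, "all at bounds"))
                break
            idx = np.flatnonzero(free)
            sc_f = scores[idx]
            AI_f = AI[np.ix_(idx, idx)]
            accepted = False
            for _ in range(self.opt.max_inner):
                M = AI_f + lam * np.diag(np.maximum(np.diag(AI_f), 1e-12)) \
                    + 1e-12 * np.eye(len(idx))
                try:
                    step_f = np.linalg.solve(M, sc_f)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = st.theta.copy()
                cand[idx] += step_f
                cand = self.clamp(cand)
                try:
                    st_new = self._evaluate(cand)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                if st_new.loglik >= st.loglik - 1e-10 * (1.0 + abs(st.loglik)):
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                iter_log.append((n_iter, st.loglik, "stalled"))
                break
            delta_ll = st_new.loglik - st.loglik
            rel_step = float(np.max(np.abs(st_new.theta[idx] - st.theta[idx])
                                    / (1.0 + np.abs(st.theta[idx]))))
            st = st_new
            lam = max(lam / 3.0, 1e-8)
            iter_log.append((n_iter, st.loglik, f"AI lam={lam:.1e}"))
            if self.opt.verbose:
                print(f"iter {n_iter}: loglik {st.loglik:.6f} ({iter_log[-1][2]})")
            if abs(delta_ll) < self.opt.tol * (1.0 + abs(st.loglik)) \
                    and rel_step < np.sqrt(self.opt.tol):
                converged = True
                break
        self.state = st
        return self._result(st, converged, n_iter, grad_norm, iter_log)

    def _result(self, st, converged, n_iter, grad_norm, iter_log) -> FitResult:
        spec = self.spec
        ng = self.gxe.n_params
        ne = len(self.extra_ranges)
        beta = pd.Series(st.beta, index=spec.fixed_names)
        beta_se = pd.Series(np.sqrt(np.diag(st.Phi)), index=spec.fixed_names)
        deltas = self.gxe.deltas(st.theta[:ng])
        spatial = SpatialParams({
            env: tuple(map(float, prm))
            for env, prm in zip(spec.envs, self._split_resid(st.theta))
        })
        extra = {name: float(v) for (name, _, _), v in
                 zip(self.extra_ranges, st.theta[ng:ng + ne])}
        # observed-information style SEs from the AI matrix at the optimum
        try:
            _, AI = self._derivatives(st)
            theta_se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
        except np.linalg.LinAlgError:
            theta_se = np.full(len(st.theta), np.nan)
        return FitResult(
            loglik=float(st.loglik), converged=converged, n_iter=n_iter,
            grad_norm=grad_norm, beta=beta, beta_se=beta_se, deltas=deltas,
            spatial=spatial, extra_variances=extra, theta=st.theta.copy(),
            param_names=self.param_names(), theta_se=theta_se,
            iter_log=iter_log, model=self,
        )

    # -- scan support -----------------------------------------------------
    def p_apply(self, M: np.ndarray) -> np.ndarray:
        """P M at the current estimates (P the REML projection matrix)."""
        if self.state is None:
            raise RuntimeError("fit the model first")
        st = self.state
        VM = self._vinv(M)
        return VM - st.VX @ (st.Phi @ (self.spec.X.T @ VM))


def reml_fit(
    spec: ModelSpec,
    gxe: GxECov | None = None,
    options: REMLOptions | None = None,
    start: np.ndarray | None = None,
    fa_order: int | None = None,
) -> FitResult:
    """Fit the baseline ME-LMM (one genetic term Delta (x) I) by REML."""
    if gxe is None:
        gxe = GxECov([("g", default_delta(spec.n_env, fa_order), None)], spec.n_lines)
    model = MixedModel(spec, gxe, options)
    return model.fit(start=start)


def genetic_correlations(fit: FitResult, term: str = "g") -> pd.DataFrame:
    """Between-environment genetic correlation matrix from the fitted Delta."""
    if not fit.converged:
        raise ValueError("fit did not converge; correlations not reported")
    delta = fit.deltas[term]
    sd = np.sqrt(np.diag(delta))
    if (sd <= 0).any():
        bad = [fit.model.spec.envs[i] for i in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero genetic variance in {bad}: correlations undefined")
    corr = delta / np.outer(sd, sd)
    envs = fit.model.spec.envs
    return pd.DataFrame(corr, index=envs, columns=envs)
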