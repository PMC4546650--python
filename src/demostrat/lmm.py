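"""Restricted-maximum-likelihood fitting of nested random-intercept models.

The models handled here are linear mixed models with one or two levels of
nested random intercepts on top of the residual:

    two-level:    y = X b + u_family + e
    three-level:  y = X b + u_family + u_subject + e

with ``u_subject`` nested within ``u_family`` (repeated measurements of the
same person within a family).  Because every random effect is a scalar
intercept over a nested grouping, the marginal covariance of each family
block is

    V_i = sigma2_e * ( I + lam_s * blockdiag_j(J_subject_j) + lam_f * J )

where ``lam_f`` and ``lam_s`` are the family and subject variance ratios
relative to the residual and ``J`` is the all-ones matrix.  ``V_i^{-1}`` and
``log|V_i|`` then have closed forms via two Woodbury steps (first absorb the
subject blocks, then the rank-one family intercept), so the REML criterion
profiled over the fixed effects and the residual variance can be evaluated
in O(n * p) with vectorised grouped sums and optimised over the one or two
variance ratios only.  This makes a fit cost a fraction of a millisecond,
which the Monte-Carlo calibration machinery in this package depends on.

Estimates agree with general-purpose mixed-model software (statsmodels
``MixedLM``, lme4) to numerical tolerance; the test-suite cross-checks this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .exceptions import ConvergenceError, DegeneratePredictorError

__all__ = ["LMMResult", "fit_nested_lmm"]

#: Variance-ratio below which a component is treated as on the zero boundary
#: and the model is refitted without it.
BOUNDARY_RATIO = 1e-6

#: Convergence tolerance on the profiled REML objective.
OBJECTIVE_TOL = 1e-8


@dataclass
class LMMResult:
    """Fitted fixed effects and variance components of a nested LMM."""

    params: np.ndarray          # fixed-effect estimates, one per column of X
    bse: np.ndarray             # standard errors
    pvalues: np.ndarray         # two-sided Wald p (normal reference)
    names: list[str]            # column names of X
    sigma2_residual: float
    sigma2_family: float
    sigma2_subject: float       # 0.0 for two-level fits
    n_obs: int
    n_groups: int
    converged: bool
    reml_criterion: float
    dropped_components: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        """(estimate, se, p) for a named fixed effect."""
        i = self.names.index(name)
        return float(self.params[i]), float(self.bse[i]), float(self.pvalues[i])


def _group_codes(values: np.ndarray) -> np.ndarray:
    _, codes = np.unique(values, return_inverse=True)
    return codes


class _Profile:
    """Profiled REML/ML objective for fixed group structure and data."""

    def __init__(self, X, y, family, subject, reml):
        n, p = X.shape
        self.n, self.p = n, p
        self.reml = reml
        self.has_subject = subject is not None

        fam = _group_codes(np.asarray(family))
        if self.has_subject:
            subj = _group_codes(np.asarray(subject))
            order = np.lexsort((subj, fam))
        else:
            subj = None
            order = np.argsort(fam, kind="stable")
        self.order = order
        fam = fam[order]
        self.M = np.column_stack([np.asarray(X, float), np.asarray(y, float)])[order]

        self.fam_starts = np.flatnonzero(np.r_[True, fam[1:] != fam[:-1]])
        self.n_fam = len(self.fam_starts)
        fam_ids = np.cumsum(np.r_[True, fam[1:] != fam[:-1]]) - 1
        self.fam_of_row = fam_ids

        if self.has_subject:
            subj = subj[order]
            new_subj = np.r_[True, (subj[1:] != subj[:-1]) | (fam[1:] != fam[:-1])]
            self.subj_starts = np.flatnonzero(new_subj)
            subj_ids = np.cumsum(new_subj) - 1
            self.subj_of_row = subj_ids
            self.n_per_subj = np.bincount(subj_ids).astype(float)
            self.fam_of_subj = fam_ids[self.subj_starts]
        self.fam_sizes = np.bincount(fam_ids).astype(float)

    def whiten(self, lam, internals=False):
        """Return (V0^{-1} M, log|V0|) for the current variance ratios."""
        M = self.M
        if self.has_subject:
            lam_f, lam_s = lam
            a = 1.0 / (1.0 + lam_s * self.n_per_subj)          # per subject
            S = np.add.reduceat(M, self.subj_starts, axis=0)    # subject sums
            AinvM = M - (lam_s * a)[self.subj_of_row, None] * S[self.subj_of_row]
            u = a[self.subj_of_row]                             # A^{-1} 1 rows
            c = np.bincount(self.fam_of_subj, self.n_per_subj * a,
                            minlength=self.n_fam)
            logdet = float(np.sum(np.log1p(lam_s * self.n_per_subj)))
        else:
            (lam_f,) = lam
            a = None
            AinvM = M
            u = np.ones(self.n)
            c = self.fam_sizes
            logdet = 0.0
        T = np.add.reduceat(AinvM, self.fam_starts, axis=0)     # family sums
        g = lam_f / (1.0 + lam_f * c)
        VinvM = AinvM - g[self.fam_of_row, None] * u[:, None] * T[self.fam_of_row]
        logdet += float(np.sum(np.log1p(lam_f * c)))
        if internals:
            return VinvM, logdet, a, c
        return VinvM, logdet

    def value_and_grad(self, lam):
        """REML criterion and its gradient in the variance ratios.

        Uses the standard profiled-REML score: for each component with
        incidence matrix Z,

            dC/dlam = tr(W Z Z') - tr((X'WX)^{-1} X'W Z Z' W X)
                      - (n - p) * ||Z' W r||^2 / (r' W r)

        with W = V0^{-1} and r the GLS residual; every trace reduces to
        grouped sums already available from the whitening pass.
        """
        lam = np.asarray(lam, float)
        try:
            WM, logdet, a, c = self.whiten(lam, internals=True)
        except FloatingPointError:      # pragma: no cover
            return np.inf, np.zeros_like(lam)
        M, p, n = self.M, self.p, self.n
        G = M.T @ WM
        G = 0.5 * (G + G.T)
        XtWX, XtWy, ytWy = G[:p, :p], G[:p, p], G[p, p]
        try:
            cho = linalg.cho_factor(XtWX, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(lam)
        beta = linalg.cho_solve(cho, XtWy)
        rss = float(ytWy - XtWy @ beta)
        dof = n - p if self.reml else n
        sigma2 = max(rss / dof, np.finfo(float).tiny)
        crit = dof * np.log(sigma2) + logdet
        if self.reml:
            crit += 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

        Wr = WM[:, p] - WM[:, :p] @ beta
        WX = WM[:, :p]
        lam_f = lam[0]

        def component_grad(tr_wzz, U, zWr):
            term = tr_wzz
            if self.reml:
                term -= float(np.sum(linalg.cho_solve(cho, U.T).T * U))
            term -= dof * float(zWr @ zWr) / rss
            return term

        grads = []
        # family component
        na = c  # = 1' A^{-1} 1 per family
        tr_f = float(np.sum(na / (1.0 + lam_f * na)))
        U_f = np.add.reduceat(WX, self.fam_starts, axis=0)
        zWr_f = np.add.reduceat(Wr, self.fam_starts)
        grads.append(component_grad(tr_f, U_f, zWr_f))
        if self.has_subject:
            nj_aj = self.n_per_subj * a
            denom = 1.0 + lam_f * c
            tr_s = float(np.sum(nj_aj
                                - lam_f * nj_aj ** 2 / denom[self.fam_of_subj]))
            U_s = np.add.reduceat(WX, self.subj_starts, axis=0)
            zWr_s = np.add.reduceat(Wr, self.subj_starts)
            grads.append(component_grad(tr_s, U_s, zWr_s))
        return crit, np.array(grads)

    def gls(self, lam, need_cov=False):
        """GLS solve at the given ratios.

        Returns (beta, cov_unscaled, sigma2, logdet_V0, logdet_XtViX) where
        ``cov_unscaled`` is only computed when ``need_cov`` is set.
        """
        VinvM, logdet = self.whiten(lam)
        G = self.M.T @ VinvM
        G = 0.5 * (G + G.T)
        p = self.p
        XtViX, XtViy, ytViy = G[:p, :p], G[:p, p], G[p, p]
        try:
            cho = np.linalg.cholesky(XtViX)
        except np.linalg.LinAlgError:
            raise DegeneratePredictorError(
                "design matrix is rank deficient under the current weighting")
        beta = np.linalg.solve(XtViX, XtViy)
        rss = float(ytViy - XtViy @ beta)
        dof = self.n - p if self.reml else self.n
        sigma2 = max(rss / dof, np.finfo(float).tiny)
        logdet_XtViX = 2.0 * float(np.sum(np.log(np.diag(cho))))
        cov_unscaled = np.linalg.inv(XtViX) if need_cov else None
        return beta, cov_unscaled, sigma2, logdet, logdet_XtViX

    def objective(self, lam):
        try:
            _, _, sigma2, logdet, logdet_XtViX = self.gls(lam)
        except DegeneratePredictorError:
            return np.inf
        dof = self.n - self.p if self.reml else self.n
        crit = dof * np.log(sigma2) + logdet
        if self.reml:
            crit += logdet_XtViX
        return crit


def fit_nested_lmm(
    X,
    y,
    family,
    subject=None,
    *,
    names: list[str] | None = None,
    reml: bool = True,
    _dropped: tuple[str, ...] = (),
) -> LMMResult:
    """Fit a nested random-intercept LMM by profiled REML.

    Parameters
    ----------
    X
        Fixed-effect design matrix including the intercept column, (n, p).
    y
        Response vector, length n.
    family
        Outer grouping labels (one random intercept per distinct value).
    subject
        Optional inner grouping labels nested in ``family``; supplying them
        adds the subject-level random intercept (three-level model).
    names
        Column names of ``X`` used to address estimates in the result.
    reml
        Use restricted ML (default) rather than ML.

    Notes
    -----
    When an estimated variance ratio lands on the zero boundary the model is
    refitted with that component removed, so reported variance components
    are exactly zero rather than numerically tiny.  With no random
    components left the fit degenerates to ordinary least squares.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if len(y) != n:
        raise DegeneratePredictorError("X and y have incompatible shapes")
    if n <= p:
        raise DegeneratePredictorError("more parameters than observations")
    if np.linalg.matrix_rank(X) < p:
        raise DegeneratePredictorError("design matrix is rank deficient")

    if family is None:
        return _ols(X, y, names, _dropped)

    if subject is not None:
        # One record per subject leaves the subject variance confounded
        # with the residual; collapse to the two-level model.
        _, counts = np.unique(np.asarray(subject), return_counts=True)
        if counts.max() == 1:
            return fit_nested_lmm(X, y, family, None, names=names, reml=reml,
                                  _dropped=_dropped + ("subject",))

    prof = _Profile(X, y, family, subject, reml)
    if subject is not None:
        res = optimize.minimize(
            prof.value_and_grad, np.array([0.5, 0.5]), jac=True,
            method="L-BFGS-B", bounds=[(0.0, 1e8)] * 2,
            options={"ftol": OBJECTIVE_TOL, "gtol": 1e-10, "maxiter": 500},
        )
        lam, fun, success, message = res.x, res.fun, res.success, res.message
    else:
        # One variance ratio: coarse log-spaced grid to bracket the optimum,
        # then bounded Brent inside the bracket.  The grid keeps the Brent
        # interval tight, which holds the evaluation count low for the
        # Monte-Carlo workloads.
        grid = np.r_[0.0, np.logspace(-2.5, 2.5, 9), 1e6]
        vals = np.array([prof.objective((v,)) for v in grid])
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda v: prof.objective((v,)), bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6 * max(1.0, grid[i])})
        if vals[i] < res.fun:        # grid point (e.g. the 0 boundary) wins
            lam, fun = np.array([grid[i]]), vals[i]
        else:
            lam, fun = np.array([res.x]), res.fun
        success, message = True, ""
    if not np.isfinite(fun):
        raise ConvergenceError(
            "REML optimisation failed", {"message": message, "lam": lam})

    # Boundary handling: refit without components whose ratio collapsed to 0.
    if subject is not None and lam[1] < BOUNDARY_RATIO:
        return fit_nested_lmm(X, y, family, None, names=names, reml=reml,
                              _dropped=_dropped + ("subject",))
    if lam[0] < BOUNDARY_RATIO:
        if subject is not None:
            return fit_nested_lmm(X, y, subject, None, names=names, reml=reml,
                                  _dropped=_dropped + ("family",))
        return _ols(X, y, names, _dropped + ("family",))

    beta, cov_unscaled, sigma2, _, _ = prof.gls(lam, need_cov=True)
    cov = sigma2 * cov_unscaled
    bse = np.sqrt(np.diag(cov))
    z = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    lam_f = float(lam[0])
    lam_s = float(lam[1]) if subject is not None else 0.0
    return LMMResult(
        params=beta, bse=bse, pvalues=pvals, names=list(names),
        sigma2_residual=float(sigma2),
        sigma2_family=lam_f * float(sigma2) if "family" not in _dropped else 0.0,
        sigma2_subject=lam_s * float(sigma2),
        n_obs=n, n_groups=prof.n_fam, converged=bool(success),
        reml_criterion=float(fun), dropped_components=_dropped,
    )


def _ols(X, y, names, dropped) -> LMMResult:
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    z = beta / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LMMResult(
        params=beta, bse=bse, pvalues=pvals, names=list(names),
        sigma2_residual=sigma2, sigma2_family=0.0, sigma2_subject=0.0,
        n_obs=n, n_groups=n, converged=True,
        reml_criterion=float(n - p) * np.log(sigma2),
        dropped_components=tuple(dropped),
    )
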