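"""Linear mixed model with a kinship-structured random effect.

The stage-one model of the analysis is

    y = X b + u + e,    u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with y a log metabolite concentration, X the fixed-effect covariate design
and K the expected relationship matrix (2 x kinship).  `KinshipLMM.fit()`
maximizes the restricted likelihood over the variance components by
profiling: K is eigendecomposed once, the model is rotated to independent
observations with variances sigma^2 * (h * d_i + 1 - h) where h is the
heritability ratio sigma_g^2 / (sigma_g^2 + sigma_e^2), and the scalar h
is optimized on [0, 1) with the scale sigma^2 profiled in closed form.

`KinshipLMMResults.scan()` then tests SNP dosages one at a time by
generalized least squares with the heritability ratio held fixed at the
null-model estimate (the residual scale is re-profiled per SNP, so the
scan reduces exactly to ordinary least squares when K = I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import KinshipMatrix

__all__ = ["KinshipLMM", "KinshipLMMResults", "LmmError"]

_H_MAX = 1.0 - 1e-6


class LmmError(ValueError):
    pass


class KinshipLMM:
    """Mixed model y = Xb + u + e with Cov(u) = sigma_g^2 K.

    Parameters
    ----------
    endog : (n,) array
        Response (log metabolite concentration).
    exog : (n, p) array
        Fixed-effect design; must be full column rank.
    kinship : (n, n) array or KinshipMatrix
        Expected relationship matrix aligned with ``endog``.
    exog_names, subjects : optional labels carried through to results.
    """

    def __init__(self, endog, exog, kinship, exog_names=None, subjects=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.shape[0]:
            raise LmmError("endog and exog have different numbers of rows")
        if np.isnan(y).any() or np.isnan(X).any():
            raise LmmError("endog/exog contain NaN; listwise-delete first")
        K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
        if K.shape != (y.shape[0],) * 2:
            raise LmmError("kinship matrix does not match sample size")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise LmmError("exog is rank deficient; drop collinear columns")
        self.endog = y
        self.exog = X
        self.kinship = K
        self.nobs = y.shape[0]
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
        self.subjects = subjects
        self._eig = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       covariates: list[str], kinship: KinshipMatrix) -> "KinshipLMM":
        """Build from a subjects-indexed frame, listwise-deleting incomplete
        rows and aligning the kinship matrix; an intercept is prepended and
        constant covariate columns are dropped."""
        cols = [response] + list(covariates)
        sub = data.loc[:, cols].dropna()
        sub = sub.loc[sub.index.intersection(kinship.subjects)]
        keep = [c for c in covariates if sub[c].nunique() > 1]
        X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in keep])
        Ksub = kinship.subset(sub.index)
        return cls(sub[response].to_numpy(float), X, Ksub,
                   exog_names=["const"] + keep, subjects=sub.index)

    def set_kinship_eigen(self, d: np.ndarray, U: np.ndarray) -> None:
        """Inject a precomputed eigendecomposition of the kinship matrix
        (K = U diag(d) U'); lets callers fitting many responses on the same
        subject set pay for the decomposition once."""
        d = np.clip(np.asarray(d, float), 0.0, None)
        U = np.asarray(U, float)
        if d.shape != (self.nobs,) or U.shape != (self.nobs, self.nobs):
            raise LmmError("eigendecomposition does not match sample size")
        self._eig = (d, U, U.T @ self.endog, U.T @ self.exog)

    # -- restricted likelihood ------------------------------------------
    def _eigen(self):
        if self._eig is None:
            d, U = np.linalg.eigh(self.kinship)
            d = np.clip(d, 0.0, None)
            self._eig = (d, U, U.T @ self.endog, U.T @ self.exog)
        return self._eig

    def _profile(self, h: float):
        """GLS at heritability ratio h; returns (neg2_restricted_ll,
        sigma2_hat, beta, XtWiX_inv)."""
        d, _, ys, Xs = self._eigen()
        n, p = Xs.shape
        w = h * d + (1.0 - h)
        sw = np.sqrt(w)
        Xt, yt = Xs / sw[:, None], ys / sw
        XtX = Xt.T @ Xt
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            return np.inf, np.nan, None, None
        beta = XtX_inv @ (Xt.T @ yt)
        rss = float(np.sum((yt - Xt @ beta) ** 2))
        if rss <= 0:
            return np.inf, 0.0, beta, XtX_inv
        sigma2 = rss / (n - p)
        sign, logdet_xx = np.linalg.slogdet(XtX)
        if sign <= 0:
            return np.inf, sigma2, beta, XtX_inv
        neg2 = (n - p) * np.log(sigma2) + float(np.sum(np.log(w))) + logdet_xx + (n - p)
        return neg2, sigma2, beta, XtX_inv

    def fit(self, n_grid: int = 40) -> "KinshipLMMResults":
        """REML fit: coarse grid over the heritability ratio followed by a
        bounded scalar refinement; boundary estimates (h = 0) permitted."""
        grid = np.linspace(0.0, _H_MAX, n_grid)
        vals = np.array([self._profile(h)[0] for h in grid])
        if not np.isfinite(vals).any():
            return KinshipLMMResults(self, h=np.nan, sigma2=np.nan, beta=None,
                                     cov_beta=None, neg2ll=np.inf, converged=False)
        i = int(np.nanargmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
        res = optimize.minimize_scalar(lambda h: self._profile(h)[0],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        h = float(res.x) if res.fun <= vals[i] else float(grid[i])
        neg2, sigma2, beta, XtX_inv = self._profile(h)
        converged = np.isfinite(neg2) and beta is not None
        if h < 1e-8:
            h = 0.0
            neg2, sigma2, beta, XtX_inv = self._profile(h)
        cov = sigma2 * XtX_inv if converged else None
        return KinshipLMMResults(self, h=h, sigma2=sigma2, beta=beta,
                                 cov_beta=cov, neg2ll=neg2, converged=converged)


@dataclass
class KinshipLMMResults:
    """REML estimates, fixed-effect GLS coefficients and the SNP scan."""

    model: KinshipLMM
    h: float
    sigma2: float
    beta: np.ndarray | None
    cov_beta: np.ndarray | None
    neg2ll: float
    converged: bool

    # -- variance components --------------------------------------------
    @property
    def sigma_g2(self) -> float:
        return self.h * self.sigma2

    @property
    def sigma_e2(self) -> float:
        return (1.0 - self.h) * self.sigma2

    @property
    def heritability(self) -> float:
        return self.h

    @property
    def loglik_reml(self) -> float:
        return -0.5 * self.neg2ll

    @property
    def n_used(self) -> int:
        return self.model.nobs

    # -- fixed effects ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta)), index=self.model.exog_names)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.model.exog_names)

    def summary(self) -> str:
        lines = [
            "Kinship linear mixed model (REML)",
            "=" * 58,
            f"No. observations: {self.n_used:>8}   converged: {self.converged}",
            f"sigma_g^2: {self.sigma_g2:>10.4f}   sigma_e^2: {self.sigma_e2:>10.4f}",
            f"heritability ratio h: {self.h:>7.4f}   REML loglik: {self.loglik_reml:.3f}",
            "-" * 58,
            f"{'':<16}{'coef':>10}{'std err':>10}{'z':>9}{'P>|z|':>11}",
        ]
        for name in self.model.exog_names:
            lines.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>9.3f}{self.pvalues[name]:>11.3e}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- SNP scan --------------------------------------------------------
    def scan(self, dosages: np.ndarray, snp_ids=None) -> pd.DataFrame:
        """Per-SNP GLS association tests with h fixed at the null estimate.

        ``dosages``: (n, S) aligned with the model rows; missing calls are
        mean-imputed per SNP.  Returns a frame with beta, se, p, n_used and
        a ``reason`` column (monomorphic / collinear) for untestable SNPs.
        """
        if not self.converged:
            raise LmmError("cannot scan from a non-converged null fit")
        G = np.asarray(dosages, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        if G.shape[0] != self.model.nobs:
            raise LmmError("dosage rows do not match model observations")
        d, U, ys, Xs = self.model._eigen()
        w = self.h * d + (1.0 - self.h)
        sw = np.sqrt(w)
        Xt, yt = Xs / sw[:, None], ys / sw
        Q, _ = np.linalg.qr(Xt)
        y_r = yt - Q @ (Q.T @ yt)
        n, p = Xt.shape

        S = G.shape[1]
        out = {k: np.full(S, np.nan) for k in ("beta", "se", "p")}
        n_used = np.full(S, self.n_used)
        reason = np.array([""] * S, dtype=object)
        for j in range(S):
            g = G[:, j].copy()
            miss = np.isnan(g)
            if miss.all():
                reason[j] = "all_missing"
                continue
            if miss.any():
                g[miss] = g[~miss].mean()
            if np.ptp(g[~np.isnan(g)]) == 0 or np.var(g) == 0:
                reason[j] = "monomorphic"
                continue
            gt = (U.T @ g) / sw
            g_r = gt - Q @ (Q.T @ gt)
            gg = float(g_r @ g_r)
            if gg <= 1e-10 * float(gt @ gt):
                reason[j] = "collinear"
                continue
            beta = float(g_r @ y_r) / gg
            rss = float(y_r @ y_r) - beta**2 * gg
            df = n - p - 1
            sigma2 = max(rss, 0.0) / df
            se = np.sqrt(sigma2 / gg)
            out["beta"][j] = beta
            out["se"][j] = se
            out["p"][j] = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else np.nan
        idx = pd.Index(snp_ids if snp_ids is not None else range(S), name="snp_id")
        return pd.DataFrame({**out, "n_used": n_used, "reason": reason}, index=idx)
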