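"""Maximum-likelihood spatial error model (SEM).

The model is a linear regression whose disturbance follows a simultaneous
autoregressive process over a spatial weights matrix W:

    y = X beta + u,      u = lambda W u + eps,      eps ~ N(0, sigma^2 I)

so that (I - lambda W) u = eps. Its log-likelihood is

    l(beta, lambda, sigma^2) = -(n/2) ln(2 pi sigma^2) + ln|I - lambda W|
                               - (1 / 2 sigma^2) || (I - lambda W)(y - X beta) ||^2

The log-determinant is evaluated from the (precomputed, cached) real
eigenvalues of the row-standardized W: ln|I - lambda W| = sum ln(1 - lambda w_i).

Estimation profiles beta and sigma^2 out analytically: for a candidate
lambda, beta(lambda) is the least-squares fit of (I - lambda W) y on
(I - lambda W) X and sigma^2(lambda) the mean squared residual; the
resulting one-dimensional concentrated likelihood is maximized by bounded
Brent search over the interior of the feasible eigenvalue interval. The
whole procedure is deterministic.

Standard errors: beta uses the exact GLS covariance sigma^2 (Xs' Xs)^-1 at
the optimum (Xs the spatially filtered design); lambda uses the curvature
of the profile likelihood (numerical second derivative), which equals the
Schur complement of the full observed information for the profiled
parameters. Confidence intervals are Wald.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, DataError
from .weights import SpatialWeights

__all__ = ["SpatialErrorModel", "SEMResults"]

_Z975 = stats.norm.ppf(0.975)


class SpatialErrorModel:
    """Spatial error model of ``endog`` on ``exog`` over ``weights``.

    Parameters
    ----------
    endog : (n,) array
        Outcome vector (e.g. a per-cell pollutant-concentration change).
    exog : (n, p) array
        Design matrix. An intercept column is *not* added automatically;
        use :meth:`from_dataframe` for the convenient path.
    weights : SpatialWeights
        Row-standardized contiguity weights over the same n units.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, weights: SpatialWeights, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not isinstance(weights, SpatialWeights):
            raise DataError("weights must be a SpatialWeights instance")
        if len(y) != X.shape[0] or len(y) != weights.n:
            raise DataError(
                f"dimension mismatch: y has {len(y)} rows, X has {X.shape[0]}, "
                f"weights have {weights.n}"
            )
        if not np.isfinite(y).all() or not np.isfinite(X).all():
            raise DataError("endog/exog contain non-finite values")
        n, p = X.shape
        if n <= p + 2:
            raise DataError(f"need n > p + 2 observations (n={n}, p={p})")
        names = list(exog_names) if exog_names is not None else [f"x{j}" for j in range(p)]
        if len(names) != p:
            raise DataError("exog_names length does not match design width")
        self._check_rank(X, names)
        self.endog = y
        self.exog = X
        self.weights = weights
        self.exog_names = names
        self.nobs = n

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, terms,
                       weights: SpatialWeights, add_intercept: bool = True):
        """Build a model from named columns of a per-cell analysis table.

        Rows must be aligned with the weights ordering. With
        ``add_intercept`` a leading constant column named ``intercept`` is
        prepended.
        """
        missing = [c for c in [outcome, *terms] if c not in data.columns]
        if missing:
            raise DataError(f"analysis table is missing columns: {missing}")
        sub = data[[outcome, *terms]]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise DataError(f"missing values in columns: {bad}")
        X = sub[list(terms)].to_numpy(dtype=float)
        names = list(terms)
        if add_intercept:
            X = np.column_stack([np.ones(len(sub)), X])
            names = ["intercept"] + names
        return cls(sub[outcome].to_numpy(dtype=float), X, weights, exog_names=names)

    @staticmethod
    def _check_rank(X, names):
        # QR with column pivoting names the offending columns on rank loss
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            offenders = [names[j] for j in piv[rank:]]
            raise DataError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                f"collinear columns: {offenders}"
            )

    # ------------------------------------------------------------------ #

    def _filtered(self, lam: float):
        """Spatially filtered data (I - lam W) y and (I - lam W) X."""
        W = self.weights.W
        ys = self.endog - lam * (W @ self.endog)
        Xs = self.exog - lam * (W @ self.exog)
        return ys, Xs

    def loglike(self, beta, lam: float, sigma2: float) -> float:
        """Exact log-likelihood at the given parameter values."""
        lo, hi = self.weights.lambda_bounds()
        if not (lo < lam < hi):
            raise DataError(f"lambda {lam} outside feasible interval ({lo:.4f}, {hi:.4f})")
        if sigma2 <= 0:
            raise DataError("sigma2 must be positive")
        beta = np.asarray(beta, dtype=float).ravel()
        if beta.shape[0] != self.exog.shape[1]:
            raise DataError("beta length does not match design width")
        n = self.nobs
        resid = self.endog - self.exog @ beta
        fr = resid - lam * (self.weights.W @ resid)
        logdet = float(np.log1p(-lam * self.weights.eigenvalues()).sum())
        return (-0.5 * n * np.log(2 * np.pi * sigma2) + logdet
                - 0.5 * (fr @ fr) / sigma2)

    def _profile(self, lam: float):
        """Profiled beta, sigma^2, and the concentrated log-likelihood at lam."""
        n = self.nobs
        ys, Xs = self._filtered(lam)
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        sigma2 = float(resid @ resid) / n
        logdet = float(np.log1p(-lam * self.weights.eigenvalues()).sum())
        cll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
        return beta, sigma2, cll

    def fit(self, interval_frac: float = 0.99, xtol: float = 1e-10) -> "SEMResults":
        """Maximize the likelihood; returns a :class:`SEMResults`.

        ``interval_frac`` shrinks the open eigenvalue-feasible interval for
        lambda to a closed search bracket (99% of it by default). Raises
        :class:`ConvergenceError` when the optimizer reports failure or the
        optimum pins against the bracket boundary.
        """
        lo, hi = self.weights.lambda_bounds()
        mid = 0.5 * (lo + hi)
        a = mid + interval_frac * (lo - mid)
        b = mid + interval_frac * (hi - mid)
        trace = []

        def nll(lam):
            cll = self._profile(lam)[2]
            trace.append((float(lam), float(cll)))
            return -cll

        res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded",
                                       options={"xatol": xtol})
        if not res.success:
            raise ConvergenceError(
                f"lambda search did not converge: {res.message}", trace=trace)
        lam = float(res.x)
        edge = 1e-4 * (b - a)
        if lam - a < edge or b - lam < edge:
            raise ConvergenceError(
                f"lambda estimate {lam:.6f} pinned to the search boundary "
                f"[{a:.4f}, {b:.4f}]; the autoregressive parameter is not "
                "interior — inspect the weights or the model", trace=trace)
        beta, sigma2, _ = self._profile(lam)
        llf = self.loglike(beta, lam, sigma2)

        _, Xs = self._filtered(lam)
        XtX = Xs.T @ Xs
        cov_beta = sigma2 * np.linalg.inv(XtX)
        se_beta = np.sqrt(np.diag(cov_beta))

        # profile-likelihood curvature for the lambda standard error
        h = max(1e-5 * (b - a), 1e-7)
        h = min(h, lam - a, b - lam)
        c0 = self._profile(lam)[2]
        cp = self._profile(lam + h)[2]
        cm = self._profile(lam - h)[2]
        d2 = (cp - 2 * c0 + cm) / h**2
        lam_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.nan

        return SEMResults(self, np.asarray(beta), se_beta, cov_beta, lam, lam_se,
                          sigma2, float(llf), trace)


class SEMResults:
    """Fitted spatial error model.

    Attributes
    ----------
    params : (p,) array of coefficient estimates (named via ``exog_names``)
    bse : asymptotic standard errors of ``params``
    lam, lam_se : spatial autoregressive parameter and its standard error
    sigma2 : ML error variance
    llf : maximized log-likelihood
    """

    def __init__(self, model, params, bse, cov_params, lam, lam_se, sigma2, llf, trace):
        self.model = model
        self.params = params
        self.bse = bse
        self._cov_params = cov_params
        self.lam = lam
        self.lam_se = lam_se
        self.sigma2 = sigma2
        self.llf = llf
        self.nobs = model.nobs
        self.exog_names = model.exog_names
        self._trace = trace

    @property
    def zvalues(self):
        return self.params / self.bse

    @property
    def pvalues(self):
        """Two-sided Wald p-values for the regression coefficients."""
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05):
        """(p, 2) array of Wald confidence bounds at level 1 - alpha."""
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def cov_params(self):
        return self._cov_params

    @property
    def resid_response(self):
        """Raw residuals y - X beta (spatially correlated under the model)."""
        return self.model.endog - self.model.exog @ self.params

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "term": self.exog_names,
                "estimate": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "z": self.zvalues,
                "pvalue": self.pvalues,
                "significant": self.pvalues < 0.05,
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "Spatial Error Model (maximum likelihood)",
            "=" * 72,
            f"No. observations: {self.nobs:>8d}    Log-likelihood: {self.llf:.4f}",
            f"lambda: {self.lam:.6f} (se {self.lam_se:.6f})    sigma2: {self.sigma2:.6f}",
            "-" * 72,
            f"{'term':<24}{'coef':>12}{'se':>10}{'z':>8}{'P>|z|':>8}{'[0.025':>10}{'0.975]':>10}",
        ]
        ci = self.conf_int()
        for j, name in enumerate(self.exog_names):
            lines.append(
                f"{name:<24}{self.params[j]:>12.5g}{self.bse[j]:>10.3g}"
                f"{self.zvalues[j]:>8.2f}{self.pvalues[j]:>8.3f}"
                f"{ci[j, 0]:>10.4g}{ci[j, 1]:>10.4g}"
            )
        lines.append("=" * 72)
        return "\n".join(lines)
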