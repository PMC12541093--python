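"""Warped Bayesian linear regression normative models.

The model for one region of interest is

    phi(y_n) = w' phi(x_n) + eps_s,    eps_s ~ N(0, 1/beta_s)

with a monotone likelihood warp ``phi(y)`` (sinh-arcsinh family) mapping the
response to a Gaussian latent space, a covariate basis expansion ``phi(x)``
(cubic B-spline in age + sex + fixed-site indicators) and a per-site noise
precision ``beta_s``.  The weights carry an isotropic Gaussian prior
``w ~ N(0, alpha^{-1} I)``; hyperparameters (alpha, the beta_s, and the warp
shape) are set by minimising the negative log marginal likelihood with
Powell's derivative-free method.

Deviation (z) scores standardise an observation against the predictive
distribution in the latent space,

    z_nd = (phi(y_nd) - yhat_nd) / sqrt(sigma_d^2 + (sigma*_d)^2)

where ``sigma_d^2 = 1/beta_s`` is the data-noise variance and
``(sigma*_d)^2 = phi(x)' A^{-1} phi(x)`` the modelling-uncertainty variance
from the posterior over the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .basis import BSplineBasis
from .warp import WarpParams, identity_warp

__all__ = [
    "WarpedBLR",
    "WarpedBLRResults",
    "PredictiveDistribution",
    "NormativeModel",
    "NormativeModelResults",
    "ConvergenceError",
    "fit_cohort_models",
    "deviation_matrix",
]


class ConvergenceError(RuntimeError):
    """Hyperparameter search failed; ``best_so_far`` holds the best state found."""

    def __init__(self, message: str, best_so_far=None):
        super().__init__(message)
        self.best_so_far = best_so_far


@dataclass
class PredictiveDistribution:
    """Latent-space predictive distribution for a batch of records."""

    yhat: np.ndarray            #: predicted latent mean per record
    noise_variance: np.ndarray  #: sigma_d^2 = 1/beta_s of each record's site
    model_variance: np.ndarray  #: (sigma*_d)^2 from posterior weight uncertainty

    @property
    def total_variance(self) -> np.ndarray:
        return self.noise_variance + self.model_variance


class WarpedBLR:
    """Bayesian linear regression with optional likelihood warping.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector (one ROI measure per record), finite.
    exog : array-like, shape (n, d)
        Design matrix (see :class:`~pdnorm.basis.BSplineBasis`).
    sites : array-like of str, optional
        Per-record site labels; omitted means a single site.
    """

    MIN_RECORDS = 20

    def __init__(self, endog, exog, sites=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-D with one row per response")
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("response contains non-finite values")
        if self.endog.shape[0] < self.MIN_RECORDS:
            raise ValueError(
                f"need at least {self.MIN_RECORDS} records, got {self.endog.shape[0]}"
            )
        if sites is None:
            sites = np.zeros(self.endog.shape[0], dtype=object)
            sites[:] = "site0"
        sites = np.asarray(sites, dtype=object)
        self.site_labels = tuple(pd.unique(sites))
        lookup = {s: i for i, s in enumerate(self.site_labels)}
        self._site_idx = np.asarray([lookup[s] for s in sites], dtype=int)

    # ---- marginal likelihood -------------------------------------------------

    def _posterior(self, t, alpha, beta_per_record):
        X = self.exog
        d = X.shape[1]
        A = alpha * np.eye(d) + (X.T * beta_per_record) @ X
        b = X.T @ (beta_per_record * t)
        try:
            cho = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            # jitter for near-singular A
            cho = np.linalg.cholesky(A + 1e-8 * np.eye(d))
        m = np.linalg.solve(A, b)
        logdet_A = 2.0 * np.sum(np.log(np.diag(cho)))
        return A, m, logdet_A

    def _neg_log_marginal(self, warp: WarpParams, alpha: float, betas: np.ndarray):
        y = self.endog
        n, d = self.exog.shape
        t = warp.forward(y)
        if not np.all(np.isfinite(t)):
            return np.inf, None
        beta_n = betas[self._site_idx]
        A, m, logdet_A = self._posterior(t, alpha, beta_n)
        r = t - self.exog @ m
        energy = 0.5 * np.sum(beta_n * r * r) + 0.5 * alpha * (m @ m)
        nll = (
            energy
            + 0.5 * logdet_A
            - 0.5 * np.sum(np.log(beta_n))
            - 0.5 * d * np.log(alpha)
            + 0.5 * n * np.log(2.0 * np.pi)
            - np.sum(warp.log_jacobian(y))
        )
        return nll, (A, m)

    def _unpack(self, theta, warped: bool):
        s = len(self.site_labels)
        alpha = float(np.exp(np.clip(theta[0], -20, 20)))
        betas = np.exp(np.clip(theta[1 : 1 + s], -20, 20))
        if warped:
            xi, log_eta, eps, log_delta = theta[1 + s : 5 + s]
            warp = WarpParams(
                xi=float(xi),
                eta=float(np.exp(np.clip(log_eta, -20, 20))),
                epsilon=float(np.clip(eps, -3, 3)),
                delta=float(np.exp(np.clip(log_delta, -2.0, 2.0))),
            )
        else:
            warp = self._fixed_warp
        return warp, alpha, betas

    def fit(
        self,
        warp: str | None = "sinh-arcsinh",
        n_restarts: int = 3,
        seed: int = 0,
        xtol: float = 1e-6,
        maxiter: int = 2000,
        canonicalize: float = 20.0,
    ) -> "WarpedBLRResults":
        """Optimise hyperparameters by Powell search on the marginal likelihood.

        ``warp=None`` fits a plain (identity-warp) BLR in standardised response
        units; ``warp="sinh-arcsinh"`` additionally fits the four warp
        parameters.  Several seeded restarts are run and the best marginal
        likelihood wins.

        The warp's affine part and the latent Gaussian's location/scale are
        jointly near-redundant (a flat likelihood ridge), so with the warp on
        the objective adds ``canonicalize * (mean(t)^2 + log(sd(t))^2)`` on
        the warped response ``t``.  This pins the latent space to zero mean /
        unit sd — picking one canonical point on the ridge so warp parameters
        are identifiable — while leaving the fitted distribution essentially
        unchanged.  The stored ``nll`` is the pure negative log marginal
        likelihood at the optimum.
        """
        if warp not in (None, "none", "sinh-arcsinh"):
            raise ValueError(f"unknown warp family {warp!r}")
        warped = warp == "sinh-arcsinh"
        y = self.endog
        mu, sd = float(np.mean(y)), float(np.std(y))
        sd = sd if sd > 0 else 1.0
        self._fixed_warp = identity_warp(mu, sd)

        s = len(self.site_labels)
        theta0 = np.zeros(1 + s + (4 if warped else 0))
        theta0[0] = np.log(1e-3)  # weakly regularising prior precision
        # latent response is ~standardised, so unit noise precision to start
        if warped:
            theta0[1 + s : 5 + s] = [mu, np.log(sd), 0.0, 0.0]

        rng = np.random.default_rng(seed)
        best = None
        n_converged = 0
        for k in range(max(1, n_restarts)):
            start = theta0.copy()
            if k > 0:
                start[0] += rng.normal(0, 2.0)
                start[1 : 1 + s] += rng.normal(0, 0.5, size=s)
                if warped:
                    start[3 + s] += rng.normal(0, 0.3)   # epsilon
                    start[4 + s] += rng.normal(0, 0.2)   # log delta

            def objective(theta):
                w, a, b = self._unpack(theta, warped)
                nll, _ = self._neg_log_marginal(w, a, b)
                if not np.isfinite(nll):
                    return 1e12
                if warped and canonicalize > 0:
                    t = w.forward(y)
                    sd_t = np.std(t)
                    if sd_t <= 0 or not np.isfinite(sd_t):
                        return 1e12
                    nll += canonicalize * (np.mean(t) ** 2 + np.log(sd_t) ** 2)
                return nll

            res = optimize.minimize(
                objective,
                start,
                method="Powell",
                options={"xtol": xtol, "ftol": xtol, "maxiter": maxiter},
            )
            if res.success:
                n_converged += 1
            if best is None or res.fun < best.fun:
                best = res
        if n_converged == 0:
            raise ConvergenceError(
                "Powell search did not converge in any restart", best_so_far=best
            )
        warp_p, alpha, betas = self._unpack(best.x, warped)
        nll_pure, _ = self._neg_log_marginal(warp_p, alpha, betas)
        return self._results(warp_p, alpha, betas, nll=float(nll_pure), converged=True)

    def fit_fixed(
        self, alpha: float, betas, warp_params: WarpParams | None = None
    ) -> "WarpedBLRResults":
        """Posterior at externally fixed hyperparameters (no optimisation)."""
        betas = np.atleast_1d(np.asarray(betas, dtype=float))
        if betas.size == 1 and len(self.site_labels) > 1:
            betas = np.repeat(betas, len(self.site_labels))
        warp_p = warp_params if warp_params is not None else identity_warp()
        nll, _ = self._neg_log_marginal(warp_p, alpha, betas)
        return self._results(warp_p, alpha, betas, nll=float(nll), converged=True)

    def _results(self, warp_p, alpha, betas, nll, converged):
        if np.any(betas <= 0):
            raise ValueError("noise precisions must be positive")
        t = warp_p.forward(self.endog)
        beta_n = betas[self._site_idx]
        A, m, _ = self._posterior(t, alpha, beta_n)
        cov = np.linalg.inv(A)
        return WarpedBLRResults(
            model=self,
            params=m,
            cov_params=cov,
            alpha=float(alpha),
            betas=np.asarray(betas, dtype=float),
            warp=warp_p,
            nll=nll,
            converged=converged,
        )


@dataclass
class WarpedBLRResults:
    """Fitted warped-BLR model: posterior weights, hyperparameters, warp."""

    model: WarpedBLR
    params: np.ndarray        #: posterior mean of the weights w
    cov_params: np.ndarray    #: posterior covariance A^{-1} of the weights
    alpha: float              #: prior precision hyperparameter
    betas: np.ndarray         #: per-site noise precisions beta_s
    warp: WarpParams
    nll: float                #: negative log marginal likelihood at the optimum
    converged: bool
    site_labels: tuple = field(init=False)

    def __post_init__(self):
        self.site_labels = self.model.site_labels

    @property
    def log_marginal_likelihood(self) -> float:
        return -self.nll

    def bse(self) -> np.ndarray:
        """Posterior standard deviations of the weights."""
        return np.sqrt(np.diag(self.cov_params))

    # ---- prediction and scoring ---------------------------------------------

    def _noise_variance(self, sites, n: int) -> np.ndarray:
        if sites is None:
            if len(self.site_labels) > 1:
                raise ValueError("site labels required for a multi-site model")
            idx = np.zeros(n, dtype=int)
        else:
            sites = np.asarray(sites, dtype=object)
            try:
                idx = np.asarray(
                    [self.site_labels.index(s) for s in sites], dtype=int
                )
            except ValueError as exc:
                raise KeyError(f"unknown site label in prediction: {exc}") from exc
        return 1.0 / self.betas[idx]

    def predict(self, exog, sites=None) -> PredictiveDistribution:
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[1] != self.params.shape[0]:
            raise ValueError(
                f"design has {X.shape[1]} columns, model expects {self.params.shape[0]}"
            )
        yhat = X @ self.params
        model_var = np.einsum("ij,jk,ik->i", X, self.cov_params, X)
        noise_var = self._noise_variance(sites, X.shape[0])
        return PredictiveDistribution(
            yhat=yhat, noise_variance=noise_var, model_variance=np.maximum(model_var, 0)
        )

    def zscores(self, endog, exog, sites=None) -> np.ndarray:
        """Latent-space deviation scores for observed responses."""
        pred = self.predict(exog, sites)
        return compute_zscores(np.asarray(endog, dtype=float), pred, self.warp)

    def centiles(self, exog, sites=None, levels=(2.5, 25, 50, 75, 97.5)) -> np.ndarray:
        """Centile curves in measurement units; shape (len(levels), n_records).

        The q-centile is the inverse warp of ``yhat + Phi^{-1}(q) * sqrt(total
        variance)``; monotonicity of the warp guarantees non-crossing curves.
        """
        levels = np.asarray(levels, dtype=float)
        if np.any(levels <= 0) or np.any(levels >= 100):
            raise ValueError("centile levels must lie strictly between 0 and 100")
        pred = self.predict(exog, sites)
        sdev = np.sqrt(pred.total_variance)
        out = np.empty((levels.size, pred.yhat.size))
        for i, q in enumerate(levels):
            out[i] = self.warp.inverse(pred.yhat + stats.norm.ppf(q / 100.0) * sdev)
        return out

    def summary(self) -> str:
        lines = [
            "Warped Bayesian Linear Regression Results",
            "=" * 57,
            f"No. records:        {self.model.endog.shape[0]}",
            f"No. design columns: {self.params.shape[0]}",
            f"Warp family:        "
            + ("affine (identity shape)" if self.warp.is_identity_shape else "sinh-arcsinh"),
            f"Log marginal lik.:  {self.log_marginal_likelihood:.4f}",
            f"Prior precision:    {self.alpha:.6g}",
            "-" * 57,
            f"{'coef':>10} {'post.mean':>12} {'post.sd':>12}",
        ]
        sd = self.bse()
        for j, (m, s) in enumerate(zip(self.params, sd)):
            lines.append(f"{'w[%d]' % j:>10} {m:>12.5f} {s:>12.5f}")
        lines.append("-" * 57)
        for lab, b in zip(self.site_labels, self.betas):
            lines.append(f"noise sd (site {lab}): {1.0 / np.sqrt(b):.5f}")
        w = self.warp
        lines.append(
            f"warp: xi={w.xi:.4f} eta={w.eta:.4f} epsilon={w.epsilon:.4f} delta={w.delta:.4f}"
        )
        return "\n".join(lines)


def compute_zscores(obs, pred: PredictiveDistribution, warp: WarpParams) -> np.ndarray:
    """Deviation scores: warped observation standardised by the predictive sd."""
    total = pred.total_variance
    if np.any(total <= 0):
        raise FloatingPointError("nonpositive total predictive variance")
    t = warp.forward(np.asarray(obs, dtype=float))
    return (t - pred.yhat) / np.sqrt(total)


# ---- cohort-level convenience ------------------------------------------------


class NormativeModel:
    """One-ROI normative model bound to a cohort table and covariate basis."""

    def __init__(self, cohort: pd.DataFrame, roi: str, basis: BSplineBasis):
        if roi not in cohort.columns:
            raise KeyError(f"ROI column {roi!r} not in cohort table")
        self.roi = roi
        self.basis = basis
        self.cohort = cohort
        self._X = basis.design_from_frame(cohort)
        self._y = cohort[roi].to_numpy(dtype=float)
        self._sites = cohort["site"].astype(str).to_numpy()
        self._blr = WarpedBLR(self._y, self._X, sites=self._sites)

    @classmethod
    def from_cohort(cls, cohort, roi, basis=None, n_interior_knots=5):
        if basis is None:
            ages = cohort["age"].to_numpy(dtype=float)
            basis = BSplineBasis(
                age_range=(float(ages.min()), float(ages.max())),
                sites=tuple(pd.unique(cohort["site"].astype(str))),
                n_interior_knots=n_interior_knots,
            )
        return cls(cohort, roi, basis)

    def fit(self, warp="sinh-arcsinh", **kwargs) -> "NormativeModelResults":
        res = self._blr.fit(warp=warp, **kwargs)
        return NormativeModelResults(roi=self.roi, basis=self.basis, blr=res)


@dataclass
class NormativeModelResults:
    """Fitted per-ROI normative model with cohort-table aware scoring."""

    roi: str
    basis: BSplineBasis
    blr: WarpedBLRResults

    def predict_table(self, table: pd.DataFrame) -> PredictiveDistribution:
        X = self.basis.design_from_frame(table)
        return self.blr.predict(X, sites=table["site"].astype(str).to_numpy())

    def zscores_table(self, table: pd.DataFrame) -> pd.Series:
        X = self.basis.design_from_frame(table)
        z = self.blr.zscores(
            table[self.roi].to_numpy(dtype=float),
            X,
            sites=table["site"].astype(str).to_numpy(),
        )
        return pd.Series(z, index=table.index, name=self.roi)

    def centile_curves(
        self, ages, sex=0, site=None, levels=(2.5, 25, 50, 75, 97.5)
    ) -> pd.DataFrame:
        ages = np.asarray(ages, dtype=float)
        site = site if site is not None else self.basis.sites[0]
        X = self.basis.design_matrix(
            ages, np.full(ages.shape, float(sex)), np.full(ages.shape, site, dtype=object)
        )
        curves = self.blr.centiles(
            X, sites=np.full(ages.shape, site, dtype=object), levels=levels
        )
        return pd.DataFrame(curves.T, index=ages, columns=[float(q) for q in levels])

    def summary(self) -> str:
        return f"ROI: {self.roi}\n" + self.blr.summary()

    # ---- serialisation (structured text, one file per ROI) -------------------

    def to_dict(self) -> dict:
        b = self.basis
        w = self.blr.warp
        return {
            "schema": "pdnorm-normative-roi/1",
            "roi": self.roi,
            "basis": {
                "age_range": list(b.age_range),
                "sites": list(b.sites),
                "n_interior_knots": b.n_interior_knots,
                "degree": b.degree,
            },
            "weights": self.blr.params.tolist(),
            "cov_params": self.blr.cov_params.tolist(),
            "alpha": self.blr.alpha,
            "betas": self.blr.betas.tolist(),
            "warp": {"xi": w.xi, "eta": w.eta, "epsilon": w.epsilon, "delta": w.delta},
            "nll": self.blr.nll,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModelResults":
        if d.get("schema") != "pdnorm-normative-roi/1":
            raise ValueError(f"unsupported model schema {d.get('schema')!r}")
        basis = BSplineBasis(
            age_range=tuple(d["basis"]["age_range"]),
            sites=tuple(d["basis"]["sites"]),
            n_interior_knots=d["basis"]["n_interior_knots"],
            degree=d["basis"]["degree"],
        )
        warp = WarpParams(**d["warp"])
        blr = WarpedBLRResults.__new__(WarpedBLRResults)
        blr.model = None
        blr.params = np.asarray(d["weights"], dtype=float)
        blr.cov_params = np.asarray(d["cov_params"], dtype=float)
        blr.alpha = float(d["alpha"])
        blr.betas = np.asarray(d["betas"], dtype=float)
        blr.warp = warp
        blr.nll = float(d["nll"])
        blr.converged = True
        blr.site_labels = tuple(d["basis"]["sites"])
        return cls(roi=d["roi"], basis=basis, blr=blr)


def fit_cohort_models(
    cohort: pd.DataFrame,
    rois,
    basis: BSplineBasis | None = None,
    warp="sinh-arcsinh",
    **fit_kwargs,
) -> dict[str, NormativeModelResults]:
    """Fit one normative model per ROI on a shared covariate basis."""
    if basis is None:
        ages = cohort["age"].to_numpy(dtype=float)
        basis = BSplineBasis(
            age_range=(float(ages.min()), float(ages.max())),
            sites=tuple(pd.unique(cohort["site"].astype(str))),
        )
    out = {}
    for roi in rois:
        out[roi] = NormativeModel(cohort, roi, basis).fit(warp=warp, **fit_kwargs)
    return out


def deviation_matrix(
    models: dict[str, NormativeModelResults], table: pd.DataFrame
) -> pd.DataFrame:
    """Subjects-by-ROIs z-score matrix from per-ROI fitted models."""
    cols = {roi: res.zscores_table(table) for roi, res in models.items()}
    Z = pd.DataFrame(cols, index=table.index)
    if "subject_id" in table.columns:
        Z.index = pd.Index(table["subject_id"], name="subject_id")
    return Z
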