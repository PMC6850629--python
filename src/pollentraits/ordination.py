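"""Constrained ordination and the fourth-corner trait x environment model.

Two Model/Results pairs in the statsmodels idiom:

* :class:`RDA` — redundancy analysis: PCA of the part of a multivariate
  response (taxon abundances per year, or CWM traits per year) explained by
  linear environmental constraints.  Significance of each constraint comes
  from a permuted ANOVA whose permutations are *cyclic shifts* of the year
  ordering — the restricted scheme that preserves the autocorrelation
  structure of a single time series (with n years there are n-1 distinct
  non-identity shifts, hence 93 permutations for 94 samples).

* :class:`FourthCorner` — a log-linear model on the stacked year x taxon
  counts, log E[n_it] = alpha_t + gamma_i + sum_kj beta_kj E_kt z_ij, whose
  interaction matrix beta (environment x trait) is the "fourth corner"
  linking the year x environment and taxa x trait tables through the
  abundance table.  Significance is an analysis of deviance against the
  no-interaction model, with a parametric bootstrap (resampling counts from
  the fitted null model) providing the reference distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .io import ValidationError

logger = logging.getLogger("pollentraits")

__all__ = ["RDA", "RDAResults", "FourthCorner", "FourthCornerResults", "restricted_permutation_anova"]


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r, piv = scipy.linalg.qr(x, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol] or [names[piv[rank]]]
        raise ValidationError(f"constraints are rank deficient; collinear columns: {sorted(bad)}")


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

class RDA:
    """Redundancy analysis of a years x variables response on years x k constraints.

    The response columns are centered (optionally standardized with
    ``scale_response=True``, appropriate when the columns have different
    units, e.g. a CWM trait matrix); the constraints are centered.
    """

    def __init__(self, response, constraints, scale_response: bool = False):
        self.response = pd.DataFrame(response).astype(float)
        self.constraints = pd.DataFrame(constraints).astype(float)
        if len(self.response) != len(self.constraints):
            raise ValidationError("response and constraints must have the same number of rows")
        if len(self.response) < 3:
            raise ValidationError("RDA needs at least 3 rows (years)")
        if self.response.isna().any().any() or self.constraints.isna().any().any():
            raise ValidationError("RDA inputs must not contain missing values")
        self.scale_response = scale_response

    def _prepared(self) -> tuple[np.ndarray, np.ndarray]:
        y = _center(self.response.to_numpy())
        if self.scale_response:
            sd = y.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            y = y / sd
        x = _center(self.constraints.to_numpy())
        _check_full_rank(x, list(self.constraints.columns))
        return y, x

    def fit(self) -> "RDAResults":
        y, x = self._prepared()
        n = y.shape[0]
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        fitted = x @ beta
        resid = y - fitted
        u, s, vt = np.linalg.svd(fitted, full_matrices=False)
        n_axes = min(x.shape[1], y.shape[1])
        eig_c = (s[:n_axes] ** 2) / (n - 1)
        _, s_r, _ = np.linalg.svd(resid, full_matrices=False)
        eig_u = (s_r ** 2) / (n - 1)
        eig_u = eig_u[eig_u > max(1e-12, eig_u.max(initial=0.0) * 1e-12)]
        total = float(y.var(axis=0, ddof=1).sum())
        return RDAResults(
            model=self,
            eigenvalues_constrained=eig_c,
            eigenvalues_unconstrained=eig_u,
            total_variance=total,
            site_scores=pd.DataFrame(
                u[:, :n_axes] * s[:n_axes],
                index=self.response.index,
                columns=[f"RDA{i + 1}" for i in range(n_axes)],
            ),
            variable_scores=pd.DataFrame(
                vt[:n_axes].T,
                index=self.response.columns,
                columns=[f"RDA{i + 1}" for i in range(n_axes)],
            ),
        )


@dataclass
class RDAResults:
    model: RDA
    eigenvalues_constrained: np.ndarray
    eigenvalues_unconstrained: np.ndarray
    total_variance: float
    site_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    anova_table: pd.DataFrame | None = None

    @property
    def constrained_variance(self) -> float:
        return float(self.eigenvalues_constrained.sum())

    @property
    def unconstrained_variance(self) -> float:
        return float(self.eigenvalues_unconstrained.sum())

    @property
    def axis_proportions(self) -> np.ndarray:
        """Proportion of total variance per constrained axis."""
        return self.eigenvalues_constrained / self.total_variance

    def anova(self, n_perm: int = 93, seed: int | None = None) -> pd.DataFrame:
        y, x = self.model._prepared()
        table = restricted_permutation_anova(
            y, x, list(self.model.constraints.columns), n_perm=n_perm, seed=seed
        )
        self.anova_table = table
        return table

    def summary(self) -> str:
        lines = [
            "Redundancy analysis",
            f"  rows (years): {len(self.model.response)}   response columns: {self.model.response.shape[1]}"
            f"   constraints: {self.model.constraints.shape[1]}",
            f"  total variance:        {self.total_variance:.6g}",
            f"  constrained variance:  {self.constrained_variance:.6g}"
            f" ({100 * self.constrained_variance / self.total_variance:.1f}%)",
            f"  unconstrained variance:{self.unconstrained_variance: .6g}",
            "  axis proportions of total variance: "
            + ", ".join(f"RDA{i + 1}: {p:.1%}" for i, p in enumerate(self.axis_proportions)),
        ]
        if self.anova_table is not None:
            lines.append("  permutation ANOVA (restricted cyclic shifts):")
            lines.append(self.anova_table.to_string())
        return "\n".join(lines)


def _marginal_stats(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-constraint marginal explained SS and pseudo-F (each given the others)."""
    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    rss = float(((y - fitted) ** 2).sum())
    ss_full = float((fitted ** 2).sum())
    df_resid = n - 1 - p
    denom = rss / df_resid if df_resid > 0 else np.nan
    ss_k = np.empty(p)
    for k in range(p):
        xr = np.delete(x, k, axis=1)
        if xr.shape[1]:
            br, *_ = np.linalg.lstsq(xr, y, rcond=None)
            ss_red = float(((xr @ br) ** 2).sum())
        else:
            ss_red = 0.0
        ss_k[k] = ss_full - ss_red
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_k / denom if denom > 0 else np.full(p, np.inf)
    return ss_k, f, rss


def restricted_permutation_anova(
    response, constraints, names: list[str] | None = None, n_perm: int = 93, seed: int | None = None
) -> pd.DataFrame:
    """Marginal permutation tests of each constraint under cyclic-shift permutations.

    The year ordering of the (centered) response is cyclically shifted; with n
    rows there are n-1 distinct non-identity shifts.  ``n_perm = n-1`` uses all
    of them (deterministic); fewer draws a seeded subset; more is an error.
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never 0.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(constraints, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    if names is None:
        names = [f"x{k}" for k in range(p)]
    if n_perm > n - 1:
        raise ValidationError(f"n_perm={n_perm} exceeds the {n - 1} distinct cyclic shifts")
    ss_obs, f_obs, rss = _marginal_stats(y, x)
    if n_perm == n - 1:
        shifts = np.arange(1, n)
    else:
        rng = np.random.default_rng(seed)
        shifts = rng.choice(np.arange(1, n), size=n_perm, replace=False)
    exceed = np.zeros(p)
    for s in shifts:
        _, f_perm, _ = _marginal_stats(np.roll(y, s, axis=0), x)
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + len(shifts))
    table = pd.DataFrame(
        {
            "Variance": ss_obs / (n - 1),
            "F": f_obs,
            "P": pvals,
        },
        index=pd.Index(names, name="constraint"),
    )
    table.loc["Residual"] = [rss / (n - 1), np.nan, np.nan]
    table.attrs["n_permutations"] = int(len(shifts))
    return table


# ---------------------------------------------------------------------------
# fourth corner
# ---------------------------------------------------------------------------

class FourthCorner:
    """Fourth-corner model linking environment to traits through abundances.

    Parameters
    ----------
    abundance : years x taxa count table (non-negative integers).
    environment : years x k environmental variables.
    traits : taxa x m trait values; rows must be complete for included taxa.
    family : 'negative_binomial' (default; pollen counts are overdispersed) or
        'poisson'.  The negative-binomial dispersion is estimated by method of
        moments from the Poisson fit of the no-interaction model and held
        fixed in both models so the deviances are comparable.
    standardize : z-score environments (over years) and traits (over taxa)
        before fitting, making the beta matrix comparable across pairs.
    """

    def __init__(self, abundance, environment, traits, family: str = "negative_binomial",
                 standardize: bool = True):
        self.abundance = pd.DataFrame(abundance)
        self.environment = pd.DataFrame(environment).astype(float)
        self.traits = pd.DataFrame(traits).astype(float)
        if family not in ("poisson", "negative_binomial"):
            raise ValidationError(f"unknown family {family!r}")
        self.family_name = family
        self.standardize = standardize
        a = self.abundance.to_numpy()
        if np.any(a < 0) or not np.allclose(a, np.round(a)):
            raise ValidationError("abundance must contain non-negative integer counts")
        if len(self.abundance) != len(self.environment):
            raise ValidationError("abundance and environment must have the same rows (years)")
        if list(self.abundance.columns) != list(self.traits.index):
            self.traits = self.traits.reindex(self.abundance.columns)
        if self.traits.isna().any().any():
            bad = list(self.traits.index[self.traits.isna().any(axis=1)])
            raise ValidationError(f"taxa with incomplete trait rows: {bad}")
        self._build_design()

    def _build_design(self) -> None:
        n, q = self.abundance.shape
        k, m = self.environment.shape[1], self.traits.shape[1]
        e = self.environment.to_numpy()
        z = self.traits.to_numpy()
        if self.standardize:
            e = (e - e.mean(0)) / e.std(0, ddof=1)
            zsd = z.std(0, ddof=1)
            self.dropped_traits = [
                str(c) for c, s in zip(self.traits.columns, zsd) if s == 0 or not np.isfinite(s)
            ]
            if self.dropped_traits:
                logger.warning(
                    "fourth corner: constant trait columns dropped from interactions: %s",
                    self.dropped_traits,
                )
            keep = zsd > 0
            z = (z[:, keep] - z[:, keep].mean(0)) / zsd[keep]
            self._trait_cols = [c for c, k_ in zip(self.traits.columns, keep) if k_]
        else:
            self.dropped_traits = []
            self._trait_cols = list(self.traits.columns)
        self._env_std, self._trait_std = e, z

        year = np.repeat(np.arange(n), q)
        taxon = np.tile(np.arange(q), n)
        blocks = [np.ones((n * q, 1))]
        year_d = np.zeros((n * q, n - 1))
        year_d[np.arange(n * q), :] = (year[:, None] == np.arange(1, n)[None, :])
        taxon_d = (taxon[:, None] == np.arange(1, q)[None, :]).astype(float)
        blocks += [year_d, taxon_d]
        inter = (e[year][:, :, None] * z[taxon][:, None, :]).reshape(n * q, -1)
        self._x_null = np.hstack(blocks)
        self._x_full = np.hstack(blocks + [inter])
        self._n_inter = inter.shape[1]
        self._y = self.abundance.to_numpy().reshape(-1).astype(float)

    def _glm(self, y, x, family) -> sm.GLM:
        return sm.GLM(y, x, family=family)

    def _fit_pair(self, y: np.ndarray, maxiter: int):
        """Fit null and full models to a count vector; returns (res_null, res_full, family)."""
        if self.family_name == "poisson":
            fam = sm.families.Poisson()
            alpha = 0.0
        else:
            pois = self._glm(y, self._x_null, sm.families.Poisson()).fit(maxiter=maxiter)
            mu = pois.fittedvalues
            alpha = float(max(1e-8, np.sum((y - mu) ** 2 - mu) / np.sum(mu ** 2)))
            fam = sm.families.NegativeBinomial(alpha=alpha)
        res_null = self._glm(y, self._x_null, fam).fit(maxiter=maxiter)
        # warm-start the full model from the no-interaction fit: the extra
        # interaction columns start at zero, which stabilises IRLS on large
        # sparse count tables
        start = np.concatenate([res_null.params, np.zeros(self._n_inter)])
        res_full = self._glm(y, self._x_full, fam).fit(maxiter=maxiter, start_params=start)
        res_null = self._ensure_converged(res_null, y, self._x_null, fam, maxiter, "no-interaction")
        res_full = self._ensure_converged(res_full, y, self._x_full, fam, maxiter, "full")
        return res_null, res_full, fam, alpha

    def _ensure_converged(self, res, y, x, fam, maxiter, label):
        """IRLS can enter a two-point limit cycle on overdispersed tables;
        polish such fits with L-BFGS from the IRLS iterate."""
        if getattr(res, "converged", True):
            return res
        polished = self._glm(y, x, fam).fit(
            start_params=np.asarray(res.params), method="lbfgs", maxiter=2000, disp=0
        )
        retvals = getattr(polished, "mle_retvals", {}) or {}
        if retvals.get("converged", False):
            logger.info("fourth-corner %s model: IRLS cycle polished by L-BFGS", label)
            return polished
        raise RuntimeError(
            f"fourth-corner {label} model did not converge after {maxiter} IRLS iterations "
            "and L-BFGS polishing"
        )

    def fit(self, maxiter: int = 200) -> "FourthCornerResults":
        res_null, res_full, fam, alpha = self._fit_pair(self._y, maxiter)
        k = self.environment.shape[1]
        n_kept = len(self._trait_cols)
        beta = res_full.params[-self._n_inter:].reshape(k, n_kept)
        se = res_full.bse[-self._n_inter:].reshape(k, n_kept)
        coef = pd.DataFrame(np.nan, index=self.environment.columns, columns=self.traits.columns)
        bse = coef.copy()
        coef.loc[:, self._trait_cols] = beta
        bse.loc[:, self._trait_cols] = se
        return FourthCornerResults(
            model=self,
            coefficients=coef,
            bse=bse,
            deviance_full=float(res_full.deviance),
            deviance_null=float(res_null.deviance),
            alpha=alpha,
            _family=fam,
            _mu_null=np.asarray(res_null.fittedvalues),
            maxiter=maxiter,
        )


@dataclass
class FourthCornerResults:
    model: FourthCorner
    coefficients: pd.DataFrame  # environment x trait interaction matrix
    bse: pd.DataFrame
    deviance_full: float
    deviance_null: float
    alpha: float
    _family: object
    _mu_null: np.ndarray
    maxiter: int
    n_bootstraps: int | None = None
    pvalue: float | None = None

    @property
    def lr(self) -> float:
        """Likelihood-ratio (deviance-difference) statistic for the interactions."""
        return self.deviance_null - self.deviance_full

    def _simulate_null(self, rng: np.random.Generator) -> np.ndarray:
        mu = self._mu_null
        if self.model.family_name == "poisson":
            return rng.poisson(mu).astype(float)
        lam = rng.gamma(shape=1.0 / self.alpha, scale=mu * self.alpha)
        return rng.poisson(lam).astype(float)

    def anova(self, n_boot: int = 99, seed: int | None = None) -> float:
        """Analysis of deviance: parametric bootstrap p for the interaction matrix.

        Counts are resampled from the fitted no-interaction model, both models
        refit, and p = (1 + #{LR* >= LR}) / (1 + n_boot) — never zero.
        """
        rng = np.random.default_rng(seed)
        lr_obs = self.lr
        exceed = 0
        for _ in range(n_boot):
            y_star = self._simulate_null(rng)
            rn, rf, _, _ = self.model._fit_pair(y_star, self.maxiter)
            if rn.deviance - rf.deviance >= lr_obs - 1e-10:
                exceed += 1
        self.n_bootstraps = n_boot
        self.pvalue = (1.0 + exceed) / (1.0 + n_boot)
        return self.pvalue

    def summary(self) -> str:
        lines = [
            "Fourth-corner analysis",
            f"  family: {self.model.family_name}"
            + (f" (alpha = {self.alpha:.4g})" if self.model.family_name == "negative_binomial" else ""),
            f"  deviance: full {self.deviance_full:.4f}, no-interaction {self.deviance_null:.4f}",
            f"  LR statistic: {self.lr:.4f}",
        ]
        if self.pvalue is not None:
            lines.append(f"  bootstrap p ({self.n_bootstraps} bootstraps): {self.pvalue:.4g}")
        lines.append("  interaction coefficients (environment x trait):")
        lines.append(self.coefficients.round(4).to_string())
        return "\n".join(lines)
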