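"""Generalized least squares with continuous-time AR(1) errors, and the
trait-shuffle permutation null for CWM-environment regressions.

The community-level model regresses one community property per fit on the
three environmental variables (precipitation, erosion rate, fire activity):

    y = X beta + eps,   corr(eps_s, eps_t) = phi ** (|t_s - t_t| / u)

with real-valued time separation |t_s - t_t| (suited to irregularly spaced
samples) measured in units of u = 100 years, so phi is well scaled given the
~72-year mean sample spacing.  Response and predictors are z-scored before
fitting so the coefficients are standardized.  phi is estimated by maximum
likelihood: the profile log-likelihood is evaluated on a phi grid and refined
by golden-section search; beta then follows in closed form by GLS.  ML (not
REML) is used so AIC comparisons between the two fire-index variants of the
model are coherent.

Significance of an observed coefficient is judged against a permutation null
built by shuffling whole trait rows across taxa (keeping each taxon's trait
set intact), recomputing the CWM series and refitting the model; the central
95% interval of the shuffled coefficients is the envelope.  Wald p-values are
reported alongside, but the envelope is the conservative headline criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .alignment import AlignedEnvironment
from .community import CWMSeries, TRAIT_PROPERTIES, build_cwm_series
from .io import PollenRecord, ValidationError
from .traits import TraitTable

logger = logging.getLogger("pollentraits")

__all__ = [
    "CAR1GLS",
    "CAR1GLSResults",
    "PermutationEnvelope",
    "gls_car1",
    "select_fire_index",
    "trait_shuffle_envelope",
]

DEFAULT_PHI_GRID = np.linspace(0.0, 0.98, 50)
PREDICTORS = ("precipitation", "erosion_rate", "fire")


def _corr_matrix(t: np.ndarray, phi: float, time_unit: float) -> np.ndarray:
    d = np.abs(t[:, None] - t[None, :]) / time_unit
    if phi == 0.0:
        return np.eye(len(t))
    return phi ** d


class CAR1GLS:
    """GLS regression with continuous-time AR(1) error correlation.

    Parameters
    ----------
    endog : response vector (one value per sample age).
    exog : predictor matrix; a constant column is appended automatically.
    ages_bp : sample ages in calibrated years BP (distinct).
    time_unit : years per unit of the correlation exponent (default 100), so
        the reported phi is the error correlation across ``time_unit`` years.
    phi : fix the autocorrelation parameter instead of estimating it
        (``phi=0`` reduces the fit to OLS).
    """

    def __init__(self, endog, exog, ages_bp, time_unit: float = 100.0, phi: float | None = None):
        y = np.asarray(endog, dtype=float)
        x = pd.DataFrame(exog).astype(float)
        ages = np.asarray(ages_bp, dtype=float)
        if len(y) != len(x) or len(y) != len(ages):
            raise ValidationError("endog, exog and ages must have equal length")
        keep = np.isfinite(y) & np.isfinite(x.to_numpy()).all(axis=1)
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            logger.info("gls_car1: dropping %d rows with missing values (listwise)", self.n_dropped)
        y, x, ages = y[keep], x.loc[keep], ages[keep]
        # estimating phi needs a reasonable series length; with phi fixed a
        # minimal over-determined system suffices
        min_rows = 8 if phi is None else x.shape[1] + 2
        if len(y) < min_rows:
            raise ValidationError(f"need at least {min_rows} usable rows, have {len(y)}")
        if len(np.unique(ages)) != len(ages):
            raise ValidationError("sample ages must be distinct")
        self.endog = y
        self.exog_names = [str(c) for c in x.columns] + ["const"]
        self.exog = np.column_stack([x.to_numpy(), np.ones(len(y))])
        self.t = -ages  # calendar time
        self.time_unit = float(time_unit)
        self.fixed_phi = phi

    @property
    def nobs(self) -> int:
        return len(self.endog)

    def _whiten(self, phi: float):
        r = _corr_matrix(self.t, phi, self.time_unit)
        chol = scipy.linalg.cholesky(r, lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        yw = scipy.linalg.solve_triangular(chol, self.endog, lower=True)
        xw = scipy.linalg.solve_triangular(chol, self.exog, lower=True)
        return yw, xw, logdet

    def profile_loglik(self, phi: float) -> float:
        """Profile (over beta, sigma) ML log-likelihood at a given phi."""
        yw, xw, logdet = self._whiten(phi)
        beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        rss = float(((yw - xw @ beta) ** 2).sum())
        n = self.nobs
        if rss <= 0 or not np.isfinite(rss):
            raise ValidationError("non-finite or zero GLS likelihood (degenerate response)")
        sigma2 = rss / n
        return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)

    def fit(self, phi_grid: np.ndarray = DEFAULT_PHI_GRID, refine: bool = True) -> "CAR1GLSResults":
        if self.fixed_phi is not None:
            phi = float(self.fixed_phi)
        else:
            lls = np.array([self.profile_loglik(p) for p in phi_grid])
            i = int(np.argmax(lls))
            phi = float(phi_grid[i])
            if refine and 0 < i < len(phi_grid) - 1:
                phi = _golden_max(self.profile_loglik, phi_grid[i - 1], phi_grid[i + 1])
            if i == len(phi_grid) - 1:
                warnings.warn(
                    f"CAR1 autocorrelation estimate at the grid boundary (phi={phi:.3f})",
                    RuntimeWarning,
                    stacklevel=2,
                )
        yw, xw, logdet = self._whiten(phi)
        beta, *_ = np.linalg.lstsq(xw, yw, rcond=None)
        resid_w = yw - xw @ beta
        rss_w = float(resid_w @ resid_w)
        n, p = self.nobs, self.exog.shape[1]
        llf = self.profile_loglik(phi)
        sigma2 = rss_w / (n - p)
        cov = sigma2 * np.linalg.inv(xw.T @ xw)
        bse = np.sqrt(np.diag(cov))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
        raw_resid = self.endog - self.exog @ beta
        tss = float(((self.endog - self.endog.mean()) ** 2).sum())
        pseudo_r2 = 1.0 - float(raw_resid @ raw_resid) / tss if tss > 0 else np.nan
        # parameter count for AIC: beta's + sigma (+ phi when estimated)
        k = p + 1 + (0 if self.fixed_phi is not None else 1)
        idx = pd.Index(self.exog_names)
        return CAR1GLSResults(
            model=self,
            params=pd.Series(beta, index=idx),
            bse=pd.Series(bse, index=idx),
            tvalues=pd.Series(tvals, index=idx),
            pvalues=pd.Series(pvals, index=idx),
            phi=phi,
            llf=llf,
            n_params=k,
            pseudo_r2=pseudo_r2,
            nobs=n,
        )


def _golden_max(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    g = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - g * (b - a), a + g * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


@dataclass
class CAR1GLSResults:
    """Fit of one community property on the environmental predictors."""

    model: CAR1GLS
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    phi: float
    llf: float
    n_params: int
    pseudo_r2: float
    nobs: int
    response_name: str = ""
    fire_index: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    def summary(self) -> str:
        tab = pd.DataFrame(
            {"beta": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )
        head = f"GLS with continuous-time AR(1) errors"
        if self.response_name:
            head += f" — {self.response_name}"
        lines = [
            head,
            f"  n = {self.nobs}   phi = {self.phi:.4f} per {self.model.time_unit:g} yr"
            f"   logLik = {self.llf:.4f}   AIC = {self.aic:.4f}   pseudo-R2 = {self.pseudo_r2:.4f}",
        ]
        if self.fire_index:
            lines.append(f"  fire index used: {self.fire_index}")
        lines.append(tab.round(4).to_string())
        return "\n".join(lines)


def gls_car1(
    response,
    predictors,
    ages_bp,
    time_unit: float = 100.0,
    phi: float | None = None,
    standardize: bool = True,
) -> CAR1GLSResults:
    """Fit one community property on a predictor matrix with CAR(1) errors.

    With ``standardize=True`` (the default) both sides are z-scored over the
    usable rows, so the returned coefficients are standardized effect sizes.
    """
    y = np.asarray(response, dtype=float)
    x = pd.DataFrame(predictors).astype(float)
    if standardize:
        keep = np.isfinite(y) & np.isfinite(x.to_numpy()).all(axis=1)
        y = (y - np.nanmean(y[keep])) / np.nanstd(y[keep], ddof=1)
        x = (x - x[keep].mean()) / x[keep].std(ddof=1)
    return CAR1GLS(y, x, ages_bp, time_unit=time_unit, phi=phi).fit()


def select_fire_index(
    response,
    environment: AlignedEnvironment,
    ages_bp,
    time_unit: float = 100.0,
    standardize: bool = True,
) -> CAR1GLSResults:
    """Fit the model with each fire index and keep the lower-AIC fit.

    Ties go to the closest-previous index.  If AIC and pseudo-R2 disagree
    about the winner, AIC decides and the disagreement is logged.
    """
    fits = {}
    for which in ("prev", "max"):
        res = gls_car1(
            response, environment.predictors(which), ages_bp, time_unit=time_unit, standardize=standardize
        )
        res.fire_index = which
        fits[which] = res
    chosen = "prev" if fits["prev"].aic <= fits["max"].aic else "max"
    other = "max" if chosen == "prev" else "prev"
    if fits[chosen].pseudo_r2 < fits[other].pseudo_r2:
        logger.info(
            "fire-index selection: AIC prefers %s but R2 prefers %s; AIC wins", chosen, other
        )
    return fits[chosen]


# ---------------------------------------------------------------------------
# trait-shuffle permutation envelope
# ---------------------------------------------------------------------------

@dataclass
class PermutationEnvelope:
    """Central 95% interval of standardized coefficients under trait shuffling.

    ``table`` has one row per (property, predictor) with the observed beta,
    the 2.5th/97.5th percentile bounds over shuffles, and whether the observed
    value falls outside the envelope.
    """

    table: pd.DataFrame
    n_shuffles: int
    fire_index: dict = field(default_factory=dict)

    def outside(self, prop: str, predictor: str) -> bool:
        return bool(self.table.loc[(prop, predictor), "outside"])

    def summary(self) -> str:
        return (
            f"Trait-shuffle permutation envelope ({self.n_shuffles} shuffles)\n"
            + self.table.round(4).to_string()
        )


class _SharedGLS:
    """Standardized CAR1-GLS fits for many responses sharing X and ages.

    The correlation Cholesky factors, whitened design and its pseudo-inverse
    depend only on (phi, rows, X), so they are precomputed once per phi-grid
    point and reused across thousands of shuffled responses; phi is resolved
    on the grid (the refinement step changes beta negligibly).
    """

    def __init__(self, x_std: np.ndarray, t: np.ndarray, time_unit: float,
                 phi_grid: np.ndarray = DEFAULT_PHI_GRID):
        self.n = len(t)
        self.phi_grid = phi_grid
        self._per_phi = []
        for phi in phi_grid:
            r = _corr_matrix(t, phi, time_unit)
            chol = scipy.linalg.cholesky(r, lower=True)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            xw = scipy.linalg.solve_triangular(chol, x_std, lower=True)
            pinv = np.linalg.pinv(xw)
            self._per_phi.append((chol, logdet, xw, pinv))

    def fit(self, y_std: np.ndarray) -> tuple[np.ndarray, float]:
        """Best-phi (on the grid) GLS coefficients for a standardized response."""
        best_ll, best_beta, best_phi = -np.inf, None, 0.0
        n = self.n
        for phi, (chol, logdet, xw, pinv) in zip(self.phi_grid, self._per_phi):
            yw = scipy.linalg.solve_triangular(chol, y_std, lower=True)
            beta = pinv @ yw
            rss = float(((yw - xw @ beta) ** 2).sum())
            if rss <= 0:
                continue
            ll = -0.5 * (n * np.log(2.0 * np.pi * rss / n) + logdet + n)
            if ll > best_ll:
                best_ll, best_beta, best_phi = ll, beta, phi
        if best_beta is None:
            raise ValidationError("degenerate shuffled response (zero variance)")
        return best_beta, best_phi


def _property_matrix(
    c_tree: np.ndarray,
    theta: np.ndarray,
    c_arec: np.ndarray,
    arec_useful: float,
) -> np.ndarray:
    """Vectorized per-sample property matrix (n x 7, TRAIT_PROPERTIES order).

    ``theta`` columns: wood_density, ln_leaf_area, adult_height, seed_mass,
    compound_leaves, zoochorous, useful — one row per tree taxon in the count
    matrix's column order.  Used by the shuffle loop; agrees with
    :func:`pollentraits.community.build_cwm_series` (asserted by tests).
    """
    out = np.empty((c_tree.shape[0], 7))
    for j in range(6):
        w = theta[:, j]
        m = np.isfinite(w)
        den = c_tree[:, m].sum(axis=1)
        num = c_tree[:, m] @ w[m]
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        out[:, j] = val * 100.0 if j >= 4 else val
    u = theta[:, 6]
    den = c_tree.sum(axis=1) + c_arec
    num = c_tree @ u + c_arec * arec_useful
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, 6] = np.where(den > 0, 100.0 * num / np.where(den > 0, den, 1.0), np.nan)
    return out


def trait_shuffle_envelope(
    record: PollenRecord,
    trait_table: TraitTable,
    environment: AlignedEnvironment,
    n_shuffles: int = 1000,
    seed: int | None = None,
    fire_index: str = "auto",
    time_unit: float = 100.0,
    cwm_series: CWMSeries | None = None,
    exhaustive: bool = False,
) -> PermutationEnvelope:
    """Permutation envelope for the seven trait-based community properties.

    Each shuffle permutes whole trait-table rows across taxa (each taxon keeps
    a coherent trait set), recomputes the CWM series and refits the GLS per
    property with the fire index chosen for the observed fit.  The envelope is
    the central 95% interval of each standardized coefficient over shuffles;
    an observed coefficient is flagged only if it falls outside.  The
    Poaceae : tree ratio is not trait-based and is excluded.

    With ``exhaustive=True`` (only feasible for <= 8 taxa) every permutation
    is enumerated once instead of sampling ``n_shuffles`` random shuffles.
    """
    series = cwm_series if cwm_series is not None else build_cwm_series(record, trait_table)
    ages = record.ages
    t = -ages

    observed: dict[str, pd.Series] = {}
    fire_used: dict[str, str] = {}
    for prop in TRAIT_PROPERTIES:
        y = series.data[prop]
        y_arr = y.to_numpy()
        y_scale = max(1.0, np.abs(np.nanmean(y_arr)))
        if np.nanstd(y_arr) <= 1e-12 * y_scale:
            # a constant community property (e.g. a trait constant across taxa)
            # has nothing to explain: beta = 0 by convention
            logger.info("property %s is constant over time; observed beta set to 0", prop)
            observed[prop] = pd.Series(0.0, index=list(PREDICTORS))
            fire_used[prop] = fire_index if fire_index != "auto" else "prev"
            continue
        if fire_index == "auto":
            res = select_fire_index(y, environment, ages, time_unit=time_unit)
        else:
            res = gls_car1(y, environment.predictors(fire_index), ages, time_unit=time_unit)
            res.fire_index = fire_index
        res.response_name = prop
        observed[prop] = res.params.reindex(list(PREDICTORS))
        fire_used[prop] = res.fire_index

    # shuffle machinery: counts and trait matrix over the table's tree taxa
    counts_mat = record.counts_matrix()
    tree_taxa = [name for name in trait_table.data.index if record.taxon(name).is_tree]
    c_tree = counts_mat[tree_taxa].to_numpy(dtype=float)
    theta0 = trait_table.data.loc[tree_taxa].to_numpy(dtype=float)  # 6 traits + useful
    arec = [x.name for x in record.taxa if x.is_arecaceae]
    c_arec = counts_mat[arec].to_numpy(dtype=float).sum(axis=1) if arec else np.zeros(len(counts_mat))
    arec_useful = float(any(record.taxon(a).is_useful for a in arec))

    # one shared whitening cache per (fire index, row pattern)
    caches: dict[tuple, _SharedGLS] = {}

    def fitter(which: str, rows: np.ndarray) -> _SharedGLS:
        key = (which, rows.tobytes())
        if key not in caches:
            x = environment.predictors(which).to_numpy()[rows]
            x_std = (x - x.mean(0)) / x.std(0, ddof=1)
            x_std = np.column_stack([x_std, np.ones(rows.sum())])
            caches[key] = _SharedGLS(x_std, t[rows], time_unit)
        return caches[key]

    if exhaustive:
        from itertools import permutations
        from math import factorial

        if len(tree_taxa) > 8:
            raise ValidationError("exhaustive enumeration is only feasible for <= 8 taxa")
        n_shuffles = factorial(len(tree_taxa))
        perm_iter = iter(np.array(p) for p in permutations(range(len(tree_taxa))))
    rng = np.random.default_rng(seed)
    betas = {prop: [] for prop in TRAIT_PROPERTIES}
    done = 0
    while done < n_shuffles:
        perm = next(perm_iter) if exhaustive else rng.permutation(len(tree_taxa))
        props = _property_matrix(c_tree, theta0[perm], c_arec, arec_useful)
        if np.all(~np.isfinite(props), axis=0).any():
            logger.info("trait shuffle produced an all-missing property column; resampled")
            continue
        for j, prop in enumerate(TRAIT_PROPERTIES):
            y = props[:, j]
            rows = np.isfinite(y)
            yy = y[rows]
            sd = yy.std(ddof=1) if rows.sum() > 1 else 0.0
            if sd <= 1e-12 * max(1.0, abs(yy.mean()) if rows.any() else 1.0):
                betas[prop].append(np.zeros(3))  # degenerate shuffle: beta = 0
                continue
            if rows.sum() < 8:
                betas[prop].append(np.full(3, np.nan))
                continue
            y_std = (yy - yy.mean()) / sd
            beta, _ = fitter(fire_used[prop], rows).fit(y_std)
            betas[prop].append(beta[:3])
        done += 1

    rows_out = []
    for prop in TRAIT_PROPERTIES:
        b = np.asarray(betas[prop])
        obs = observed[prop].to_numpy()
        # a constant trait yields identical shuffles and a zero-width envelope
        lo = np.nanpercentile(b, 2.5, axis=0)
        hi = np.nanpercentile(b, 97.5, axis=0)
        for i, pred in enumerate(PREDICTORS):
            rows_out.append(
                {
                    "property": prop,
                    "predictor": pred,
                    "observed": obs[i],
                    "lower": lo[i],
                    "upper": hi[i],
                    "outside": bool(obs[i] < lo[i] or obs[i] > hi[i]),
                }
            )
    table = pd.DataFrame(rows_out).set_index(["property", "predictor"])
    return PermutationEnvelope(table=table, n_shuffles=n_shuffles, fire_index=fire_used)
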