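"""Age-effect modelling and age-partialled correlation screening.

Outcomes (behavioural, cognitive and graph metrics) are modelled as

    y = beta0 + f(age) + eps,   eps ~ N(0, sigma^2),

with f a penalized cubic regression spline: a natural cubic spline through
k knots placed at quantiles of age, parameterized by its values at the
knots, penalized by the integrated squared second derivative, and centred
(sum-to-zero over the data) for identifiability against the intercept.
The smoothing parameter is chosen by restricted maximum likelihood (REML).
The reported effective degrees of freedom (EDF) is the trace of the
smooth's influence matrix; EDF ~ 1 means the penalty has shrunk the fit to
a straight line.  The smooth term's significance is assessed with a
rank-based Wald test on the spline coefficients (pseudo-inverse of their
posterior covariance at a rank tied to the EDF), referred to an F
distribution -- the standard approximate test for penalized smooths.

Metric-cognition associations are screened with partial Pearson
correlations controlling for age, Benjamini-Hochberg FDR within metric
family, and a moderate-effect filter |r| > 0.400.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

K_COGNITIVE_DEFAULT = 10
K_GRAPH_DEFAULT = 12


# --------------------------------------------------------------------------
# Cubic regression spline basis
# --------------------------------------------------------------------------


class CubicRegressionSpline:
    """Natural cubic regression spline basis with bending-energy penalty.

    The basis functions are the cardinal natural cubic splines through the
    knots (function i equals 1 at knot i, 0 at the others), so the
    coefficients are the spline's values at the knots.  The penalty is the
    exact integral of the product of second derivatives, computed from the
    piecewise-linear second-derivative representation.
    """

    def __init__(self, x: np.ndarray, k: int):
        x = np.asarray(x, dtype=np.float64)
        uniq = np.unique(x)
        if uniq.size < k:
            raise ValueError(
                f"need at least k={k} distinct covariate values; got {uniq.size}"
            )
        knots = np.quantile(uniq, np.linspace(0.0, 1.0, k))
        knots = np.unique(knots)
        if knots.size < k:
            raise ValueError("quantile knots collapsed; reduce k")
        self.knots = knots
        self.k = k
        self._cardinal = CubicSpline(knots, np.eye(k), axis=0, bc_type="natural")
        # second derivatives of each cardinal function at the knots
        m = self._cardinal(knots, 2)  # (k, k): m[l, i] = f_i''(t_l)
        h = np.diff(knots)
        # hat-function mass matrix on the knot grid
        a = np.zeros((k, k))
        for l, hl in enumerate(h):
            a[l, l] += hl / 3.0
            a[l + 1, l + 1] += hl / 3.0
            a[l, l + 1] += hl / 6.0
            a[l + 1, l] += hl / 6.0
        self.penalty = m.T @ a @ m
        self.penalty = 0.5 * (self.penalty + self.penalty.T)

    def basis(self, x: np.ndarray) -> np.ndarray:
        return self._cardinal(np.asarray(x, dtype=np.float64))


# --------------------------------------------------------------------------
# GAM fit
# --------------------------------------------------------------------------


@dataclass
class GamFit:
    outcome: str
    n: int
    k: int
    method: str
    smoothing_parameter: float
    intercept_estimate: float
    intercept_se: float
    intercept_t: float
    intercept_p: float
    edf: float
    ref_df: float
    f_stat: float
    p_smooth: float
    fitted: np.ndarray
    sigma2: float


def _penalized_solve(
    x: np.ndarray, y: np.ndarray, pen_root: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stable penalized least squares via QR of the augmented system.

    Returns (beta, R, rss_plus_penalty) where R is the triangular factor
    with R'R = X'X + lam * S.
    """
    aug = np.vstack([x, np.sqrt(lam) * pen_root])
    aug_y = np.concatenate([y, np.zeros(pen_root.shape[0])])
    q, r = np.linalg.qr(aug)
    beta = np.linalg.solve(r, q.T @ aug_y)
    resid = aug_y - aug @ beta
    return beta, r, float(resid @ resid)


def _reml_score(
    loglam: float,
    x: np.ndarray,
    y: np.ndarray,
    pen_root: np.ndarray,
    log_eig_pen: float,
    pen_rank: int,
    n: int,
    mp: int,
) -> float:
    lam = np.exp(loglam)
    _, r, rss_pen = _penalized_solve(x, y, pen_root, lam)
    diag = np.abs(np.diag(r))
    if np.any(diag <= 0):
        return np.inf
    sigma2 = max(rss_pen / (n - mp), 1e-300)
    logdet_d = 2.0 * np.log(diag).sum()
    logdet_pen = pen_rank * loglam + log_eig_pen
    return float(
        (n - mp) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_d - logdet_pen
    )


def fit_age_gam(
    y: np.ndarray,
    age: np.ndarray,
    k: int = K_COGNITIVE_DEFAULT,
    outcome: str = "y",
    smoothing_parameter: float | None = None,
) -> GamFit:
    """Penalized cubic-regression-spline fit of an outcome on age (REML).

    Rows with missing values are dropped (and logged).  Raises when fewer
    than k complete observations remain or the outcome is constant.  A
    fixed ``smoothing_parameter`` bypasses REML selection (a very large
    value shrinks the smooth to the least-squares straight line).
    """
    y = np.asarray(y, dtype=np.float64)
    age = np.asarray(age, dtype=np.float64)
    ok = np.isfinite(y) & np.isfinite(age)
    if not ok.all():
        logger.info("%s: dropping %d rows with missing values", outcome, int((~ok).sum()))
        y, age = y[ok], age[ok]
    n = y.size
    if n < k:
        raise ValueError(f"{outcome}: n={n} below basis dimension k={k}")
    if np.ptp(y) == 0:
        raise ValueError(f"{outcome}: constant outcome; degenerate fit")

    crs = CubicRegressionSpline(age, k)
    b = crs.basis(age)
    # centring constraint: smooth sums to zero over the data
    c = b.mean(axis=0)
    q, _ = np.linalg.qr(c[:, None], mode="complete")
    z = q[:, 1:]                      # (k, k-1) null space of the constraint
    xs = b @ z
    ss = z.T @ crs.penalty @ z
    ss = 0.5 * (ss + ss.T)

    x = np.hstack([np.ones((n, 1)), xs])
    p = x.shape[1]
    s_bar = np.zeros((p, p))
    s_bar[1:, 1:] = ss

    eig_w, eig_v = np.linalg.eigh(s_bar)
    tol = eig_w.max() * 1e-9
    pos = eig_w > tol
    pen_rank = int(pos.sum())      # k - 2 for a natural-spline penalty
    log_eig_pen = float(np.log(eig_w[pos]).sum())
    mp = p - pen_rank              # penalty null-space dimension (intercept + linear)
    # root of the penalty: pen_root' pen_root = S
    pen_root = (np.sqrt(eig_w[pos])[:, None] * eig_v[:, pos].T)

    if smoothing_parameter is not None:
        lam = float(smoothing_parameter)
        method = "fixed"
    else:
        grid = np.linspace(-8.0, 28.0, 37)
        scores = [
            _reml_score(ll, x, y, pen_root, log_eig_pen, pen_rank, n, mp)
            for ll in grid
        ]
        best = grid[int(np.argmin(scores))]
        res = minimize_scalar(
            _reml_score,
            bounds=(best - 1.5, best + 1.5),
            method="bounded",
            args=(x, y, pen_root, log_eig_pen, pen_rank, n, mp),
        )
        lam = float(np.exp(res.x))
        method = "REML"

    beta, r_fac, _ = _penalized_solve(x, y, pen_root, lam)
    r_inv = np.linalg.inv(r_fac)
    dinv = r_inv @ r_inv.T                 # (X'X + lam S)^{-1}
    fitted = x @ beta
    rss = float(((y - fitted) ** 2).sum())
    f_mat = dinv @ (x.T @ x)               # influence of the data on beta
    edf_total = float(np.trace(f_mat))
    edf_smooth = float(np.clip(edf_total - 1.0, 1e-8, k - 1))
    edf1_total = float(np.trace(2.0 * f_mat - f_mat @ f_mat))
    edf1_smooth = float(np.clip(edf1_total - 1.0, edf_smooth, k - 1))

    rdf = n - edf_total
    sigma2 = rss / rdf
    vb = sigma2 * dinv                     # Bayesian covariance of beta

    # intercept line of the report
    se0 = float(np.sqrt(vb[0, 0]))
    t0 = float(beta[0] / se0)
    p0 = float(2.0 * sps.t.sf(abs(t0), rdf))

    # rank-based Wald test of the smooth term
    f_stat, ref_df, p_smooth = _smooth_wald_test(
        beta[1:], vb[1:, 1:], edf1_smooth, rdf
    )

    return GamFit(
        outcome=outcome, n=n, k=k, method=method, smoothing_parameter=lam,
        intercept_estimate=float(beta[0]), intercept_se=se0,
        intercept_t=t0, intercept_p=p0,
        edf=edf_smooth, ref_df=ref_df, f_stat=f_stat, p_smooth=p_smooth,
        fitted=fitted, sigma2=sigma2,
    )


def _smooth_wald_test(
    beta_s: np.ndarray, v_s: np.ndarray, rank: float, rdf: float
) -> tuple[float, float, float]:
    """Wald test of H0: smooth = 0 using a rank-``rank`` pseudo-inverse.

    ``rank`` may be fractional (it follows the term's alternative EDF);
    the fractional part down-weights the last retained eigendirection.
    The statistic divided by its rank is referred to F(rank, rdf).
    """
    w, u = np.linalg.eigh(v_s)
    order = np.argsort(w)[::-1]
    w, u = w[order], u[:, order]
    kk = int(np.floor(rank))
    nu = rank - kk
    proj = u.T @ beta_s
    with np.errstate(divide="ignore"):
        contrib = np.where(w > 0, proj**2 / w, 0.0)
    stat = float(contrib[:kk].sum())
    if nu > 0.05 and kk < beta_s.size:
        stat += float(nu * contrib[kk])
        r_eff = kk + nu
    else:
        r_eff = max(kk, 1)
    f_stat = stat / r_eff
    p = float(sps.f.sf(f_stat, r_eff, rdf))
    return float(f_stat), float(r_eff), p


# --------------------------------------------------------------------------
# Partial correlation
# --------------------------------------------------------------------------


@dataclass
class PartialCorrelation:
    x_name: str
    y_name: str
    covariate: str
    r: float
    p: float
    n: int
    q_bh: float | None = None
    passes_screen: bool | None = None


def partial_corr(
    x: np.ndarray,
    y: np.ndarray,
    covariate: np.ndarray,
    x_name: str = "x",
    y_name: str = "y",
    covariate_name: str = "age",
) -> PartialCorrelation:
    """Pearson correlation of x and y after regressing the covariate out of
    both; p from t = r sqrt((n-3)/(1-r^2)) on n-3 df."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(covariate, dtype=np.float64)
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValueError("inputs must be finite")
    design = np.column_stack([np.ones(n), z])

    def residuals(v: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ coef

    rx, ry = residuals(x), residuals(y)
    sx, sy = float(np.sqrt((rx**2).sum())), float(np.sqrt((ry**2).sum()))
    # treat numerically-exact linear functions of the covariate as degenerate
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance after removing the covariate")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 3) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 3))
    return PartialCorrelation(
        x_name=x_name, y_name=y_name, covariate=covariate_name, r=r, p=p, n=n
    )


# --------------------------------------------------------------------------
# Multiple testing and the correlation screen
# --------------------------------------------------------------------------


def bh_adjust(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def screen_correlations(
    pairs,
    covariate: np.ndarray,
    min_abs_r: float = 0.400,
    q: float = 0.05,
    gam_pvalues: dict[str, float] | None = None,
    prefilter_alpha: float = 0.05,
) -> pd.DataFrame:
    """Age-partialled correlation screen with per-family FDR.

    ``pairs`` is an iterable of (metric_name, x, score_name, y, family).
    If ``gam_pvalues`` is given, only metrics whose age-GAM smooth p-value
    is below ``prefilter_alpha`` enter the screen (correlations are run
    solely on measures with a significant age effect).  BH adjustment runs
    within each metric family; a pair is reported when its adjusted p is
    below ``q`` AND |r| exceeds ``min_abs_r``.  Result is sorted by |r|
    descending; an empty candidate set yields an empty frame.
    """
    cov = np.asarray(covariate, dtype=np.float64)
    rows = []
    for metric, x, score, y, family in pairs:
        if gam_pvalues is not None:
            gp = gam_pvalues.get(metric)
            if gp is None or gp >= prefilter_alpha:
                continue
        pc = partial_corr(x, y, cov, x_name=metric, y_name=score)
        rows.append(
            {"metric": metric, "score": score, "family": family,
             "r": pc.r, "p": pc.p, "n": pc.n}
        )
    df = pd.DataFrame(rows, columns=["metric", "score", "family", "r", "p", "n"])
    if df.empty:
        df["q_bh"] = []
        df["passes_screen"] = []
        return df
    df["q_bh"] = np.nan
    for fam, idx in df.groupby("family").groups.items():
        adj, _ = bh_adjust(df.loc[idx, "p"].to_numpy(), q=q)
        df.loc[idx, "q_bh"] = adj
    df["passes_screen"] = (df["q_bh"] < q) & (df["r"].abs() > min_abs_r)
    return df.sort_values("r", key=np.abs, ascending=False, ignore_index=True)
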