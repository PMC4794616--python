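"""Quantifying the adaptive substitutions lost to Hill-Robertson interference.

Across recombination-rate bins, the adaptive nonsynonymous rate Ka+ rises
with the crossover rate and plateaus above ~2 cM/Mb; the plateau is read as
the rate that would be realized without interference (Ka+_noHRi), and the
shortfall of the fitted local-regression curve below the plateau in
low-recombination bins, weighted by the number of nonsynonymous sites in
each bin, gives the fraction of adaptive substitutions lost:

    Total_noHRi = sum_i La(i) * Ka+_noHRi                      (all bins)
    Total_lost  = sum_i La(i) * (Ka+_noHRi - Ka+(i)')          (bins below the
                                                                threshold)
    f_HRi       = Total_lost / Total_noHRi

where Ka+(i)' is the LOESS prediction for bin i and La(i) its 0-fold site
total.  Also provides the linear vs. curvilinear (y = a + b e^{-cx}) model
comparison, Spearman rank correlations and ANCOVA used to characterize the
Ka+ ~ recombination relationship.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "CurveFit",
    "HRiResult",
    "fit_linear",
    "fit_curvilinear",
    "compare_fits",
    "loess_predict",
    "asymptotic_ka",
    "estimate_fhri",
    "fraction_lost",
    "spearman_rho",
    "ancova",
]


@dataclass
class CurveFit:
    """Least-squares fit of bin Ka+ against recombination rate."""

    kind: str  # "linear" or "curvilinear"
    a: float
    b: float
    c: float | None
    r2: float
    aic: float
    rss: float
    df_resid: int
    flagged: bool = False  # degenerate/unidentifiable parameterization

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.a + self.b * x
        return self.a + self.b * np.exp(-self.c * x)


@dataclass
class HRiResult:
    """f_HRi and its ingredients for one data set or gene category."""

    ka_no_hri: float
    total_no_hri: float
    total_lost: float
    f_hri: float
    clamped: bool
    per_bin_predictions: np.ndarray
    rr_threshold: float


def _gaussian_aic(rss, n, k):
    # k counts the error variance as a parameter, matching standard
    # regression AIC (R's AIC for lm/nls); floor guards the perfect-fit case
    return n * np.log(2.0 * np.pi * max(rss, 1e-300) / n) + n + 2.0 * k


def fit_linear(x, y) -> CurveFit:
    """Ordinary least squares y = a + b x with R^2 and Gaussian AIC."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for the linear fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    X = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return CurveFit("linear", float(coef[0]), float(coef[1]), None, r2,
                    _gaussian_aic(rss, len(x), 3), rss, len(x) - 2)


def _conditional_linear(x, y, c):
    """Best (a, b) for fixed decay rate c, by linear least squares."""
    E = np.exp(-c * x)
    X = np.column_stack([np.ones_like(x), E])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_curvilinear(x, y, starts=(1e-6, 0.25, 0.5, 1.0, 2.0, 4.0)) -> CurveFit:
    """Nonlinear least squares for y = a + b e^{-c x}.

    Multi-start over a grid of decay rates c, with (a, b) initialized from
    the conditional linear solve at each start; the best residual sum of
    squares wins.  The near-zero start covers the c -> 0 limit where the
    model degenerates to a straight line, so the fit never does worse than
    the nested linear model.  A fit with |b| indistinguishable from 0 leaves
    c unidentifiable and is flagged (a is then the mean of y).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for the curvilinear fit")

    def residuals(theta):
        a, b, c = theta
        return a + b * np.exp(-np.clip(c * x, -700, 700)) - y

    def jac(theta):
        _, b, c = theta
        E = np.exp(-np.clip(c * x, -700, 700))
        return np.column_stack([np.ones_like(x), E, -b * x * E])

    best = None
    diagnostics = []
    for c0 in starts:
        (a0, b0), _ = _conditional_linear(x, y, c0)
        try:
            res = least_squares(residuals, [a0, b0, c0], jac=jac, ftol=1e-10,
                                xtol=1e-10, gtol=1e-10, max_nfev=150)
        except Exception as exc:  # pragma: no cover - numerical edge
            diagnostics.append(f"c0={c0}: {exc}")
            continue
        rss = float(2.0 * res.cost)
        diagnostics.append(f"c0={c0}: rss={rss:.3e} status={res.status}")
        if best is None or rss < best[1]:
            best = (res, rss)
    if best is None:
        raise RuntimeError("curvilinear fit failed from every start:\n"
                           + "\n".join(diagnostics))
    res, rss = best
    a, b, c = (float(v) for v in res.x)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    flagged = abs(b) < 1e-12 * max(1.0, abs(a))
    return CurveFit("curvilinear", a, b, c, r2,
                    _gaussian_aic(rss, len(x), 4), rss, len(x) - 3, flagged)


def compare_fits(linear: CurveFit, curvilinear: CurveFit):
    """Extra-sum-of-squares F test of the curvilinear model against the
    nested linear one (one extra parameter), plus the AIC difference.

    Returns (F, p, delta_aic); delta_aic = AIC_linear - AIC_curvilinear, so
    positive values favour the curvilinear model.
    """
    n = linear.df_resid + 2
    if curvilinear.df_resid + 3 != n:
        raise ValueError("fits are not on the same data")
    df2 = n - 3
    if curvilinear.rss > linear.rss:
        F = 0.0
    else:
        F = (linear.rss - curvilinear.rss) / (curvilinear.rss / df2)
    p = float(stats.f.sf(F, 1, df2))
    return F, p, linear.aic - curvilinear.aic


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def loess_predict(x, y, span=1.0, query=None):
    """Local quadratic regression with tricube weights (R loess defaults,
    degree 2), evaluated at the observed x (or at ``query``).

    Each local fit uses the ceil(span * n) nearest points, weighted by
    (1 - (d / d_max)^3)^3.  Deterministic.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 5:
        raise ValueError("need at least 5 points for LOESS")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    q = int(np.ceil(span * len(x)))
    q = max(q, 4)  # a quadratic plus one degree of freedom
    query = x if query is None else np.asarray(query, float)
    preds = np.empty(len(query))
    for i, x0 in enumerate(query):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(len(idx))
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
        X = np.column_stack([np.ones(len(idx)), x[idx] - x0, (x[idx] - x0) ** 2])
        W = np.sqrt(w)
        coef, _, _, _ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        preds[i] = coef[0]
    return preds


# ---------------------------------------------------------------------------
# f_HRi
# ---------------------------------------------------------------------------

def asymptotic_ka(bins, rr_threshold=2.0):
    """Rate of adaptive evolution without interference: the unweighted mean
    of bin Ka+ over bins whose mean recombination rate exceeds the threshold
    (2 cM/Mb by default; 5 cM/Mb for categories with no visible asymptote).

    ``bins`` is a sequence of (mean_rr, ka_plus) pairs.
    """
    eligible = [ka for rr, ka in bins if rr > rr_threshold]
    if not eligible:
        raise ValueError(
            f"no bin above {rr_threshold} cM/Mb: lower the threshold or check "
            "the recombination map")
    return float(np.mean(eligible))


def fraction_lost(total_no_hri, total_lost):
    """f_HRi = Total_lost / Total_noHRi (the quantity the whole analysis
    exists to report)."""
    if total_no_hri <= 0:
        raise ValueError("total adaptive substitutions without HRi must be > 0")
    return total_lost / total_no_hri


def estimate_fhri(mean_rr, la, predictions, ka_no_hri, rr_threshold=2.0,
                  clamp=False) -> HRiResult:
    """Fraction of adaptive substitutions lost to interference.

    Parameters
    ----------
    mean_rr, la, predictions : arrays aligned by bin
        Bin mean recombination rate, bin 0-fold site totals La(i), and the
        LOESS-predicted Ka+(i)'.
    ka_no_hri : float
        Asymptotic Ka+ (see :func:`asymptotic_ka`).
    clamp : bool
        Replace negative predictions by 0 before computing the losses (the
        local regression can dip below zero at very low recombination).

    The no-interference total runs over *all* bins; the lost total only over
    bins below the recombination threshold.
    """
    mean_rr = np.asarray(mean_rr, float)
    la = np.asarray(la, float)
    preds = np.asarray(predictions, float).copy()
    if not (len(mean_rr) == len(la) == len(preds)):
        raise ValueError("bins, site totals and predictions must align")
    if np.any(la <= 0):
        raise ValueError("every bin needs a positive 0-fold site total")
    clamped = False
    if clamp:
        neg = preds < 0
        clamped = bool(neg.any())
        preds[neg] = 0.0
    total_no_hri = float(np.sum(la * ka_no_hri))
    below = mean_rr < rr_threshold
    total_lost = float(np.sum(la[below] * (ka_no_hri - preds[below])))
    return HRiResult(
        ka_no_hri=ka_no_hri,
        total_no_hri=total_no_hri,
        total_lost=total_lost,
        f_hri=fraction_lost(total_no_hri, total_lost),
        clamped=clamped,
        per_bin_predictions=preds,
        rr_threshold=rr_threshold,
    )


# ---------------------------------------------------------------------------
# correlation and ANCOVA summaries
# ---------------------------------------------------------------------------

def spearman_rho(x, y):
    """Spearman rank correlation (average ranks for ties) with the
    t-approximation p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ancova(y, x, group):
    """Parallel-lines analysis of covariance.

    Fits three nested OLS models - common line, per-group intercepts with a
    common slope, and per-group slopes - and compares them with F tests.

    Returns a dict with the common-slope estimate and its p value, the
    intercept-difference test (does adding group intercepts improve on the
    common line?) and the slope-heterogeneity test (do slopes differ?).
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "x": np.asarray(x, float),
                       "g": pd.Categorical(group)})
    if df["g"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if (df.groupby("g", observed=True).size() < 3).any():
        raise ValueError("every group needs at least 3 points")
    import statsmodels.formula.api as smf

    m_common = smf.ols("y ~ x", df).fit()
    m_intercepts = smf.ols("y ~ x + C(g)", df).fit()
    m_slopes = smf.ols("y ~ x * C(g)", df).fit()
    if np.linalg.matrix_rank(m_slopes.model.exog) < m_slopes.model.exog.shape[1]:
        raise ValueError("singular design in the per-group-slopes model")
    cmp_int = sm.stats.anova_lm(m_common, m_intercepts)
    cmp_slope = sm.stats.anova_lm(m_intercepts, m_slopes)
    return {
        "common_slope": float(m_intercepts.params["x"]),
        "common_slope_p": float(m_intercepts.pvalues["x"]),
        "intercept_F": float(cmp_int["F"].iloc[1]),
        "intercept_p": float(cmp_int["Pr(>F)"].iloc[1]),
        "slope_F": float(cmp_slope["F"].iloc[1]),
        "slope_p": float(cmp_slope["Pr(>F)"].iloc[1]),
    }
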