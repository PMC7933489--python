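"""Causal-effect estimators for two-sample MR.

All estimators regress per-SNP outcome log-ORs on exposure effect sizes with
inverse-variance weights w_j = 1 / se_y[j]^2:

* :func:`ivw_multivariable` — weighted least squares through the origin
  (the IVW assumption: no direct SNP-outcome effects);
* :func:`egger_multivariable` — the same regression with a free intercept,
  which estimates the average directional pleiotropic effect, after
  orienting every SNP to a positive effect on the exposure of interest;
* :func:`wald_ratio` — the single-SNP estimate by / bx;
* :func:`ivw_univariable` — the K = 1 special case.

Standard errors default to multiplicative random-effects scaling: the
model-based SEs are inflated by max(1, sqrt(Q / df)) so that between-SNP
heterogeneity widens, and can never narrow, the confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    ConfigError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from .heterogeneity import HeterogeneityResult, cochran_q
from .sumstats import HarmonizedPanel, orient_to_exposure

Z95 = 1.959963984540054  #: normal 97.5% quantile used for 95% CIs


@dataclass
class MREstimate:
    """One exposure's causal estimate under a named method.

    ``theta`` is the effect on the outcome log-OR scale per unit of the
    exposure (per SD for standardized traits); ``or_`` = exp(theta) with the
    95% CI ``ci95``. Intercept fields are populated only for MR-Egger.
    """

    exposure: str
    method: str                     # wald | ivw_uni | ivw_multi | egger_multi
    theta: float
    se_theta: float
    pvalue: float
    or_: float
    ci95: tuple[float, float]
    n_snps: int
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None
    i2: float | None = None

    def __post_init__(self) -> None:
        if not self.se_theta > 0:
            raise ConfigError(f"se_theta must be > 0 (got {self.se_theta})")
        if self.method == "egger_multi":
            assert self.intercept is not None
        else:
            assert self.intercept is None


def to_odds_ratio(theta: float, se_theta: float, z: float = Z95) -> tuple[float, tuple[float, float]]:
    """Map a log-OR effect and SE to an odds ratio with 95% CI."""
    if not se_theta > 0:
        raise ConfigError("se_theta must be > 0")
    return float(np.exp(theta)), (
        float(np.exp(theta - z * se_theta)),
        float(np.exp(theta + z * se_theta)),
    )


def wald_ratio(
    by: float,
    se_y: float,
    bx: float,
    z: float = Z95,
    exposure: str = "exposure",
    se_x: float | None = None,
) -> MREstimate:
    """Single-SNP causal estimate theta = by / bx.

    The default CI propagates outcome uncertainty only: the per-allele
    outcome CI endpoints are divided by bx and ordered, i.e.
    ``(exp((by - z se_y)/bx), exp((by + z se_y)/bx))`` ascending, and the
    p-value equals the outcome-association p. Passing ``se_x`` switches to
    the first-order delta method that also propagates exposure uncertainty.
    """
    if bx == 0:
        raise UndefinedRatioError("wald ratio undefined for bx = 0")
    if not se_y > 0:
        raise ConfigError("se_y must be > 0")
    theta = by / bx
    if se_x is None:
        se_theta = se_y / abs(bx)
        lo, hi = sorted((np.exp((by - z * se_y) / bx), np.exp((by + z * se_y) / bx)))
        pvalue = 2.0 * stats.norm.sf(abs(by) / se_y)
    else:
        se_theta = np.sqrt(se_y**2 / bx**2 + by**2 * se_x**2 / bx**4)
        lo, hi = sorted(np.exp((theta - z * se_theta, theta + z * se_theta)))
        pvalue = 2.0 * stats.norm.sf(abs(theta) / se_theta)
    return MREstimate(
        exposure=exposure, method="wald",
        theta=float(theta), se_theta=float(se_theta), pvalue=float(pvalue),
        or_=float(np.exp(theta)), ci95=(float(lo), float(hi)), n_snps=1,
    )


def _wls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    se_scaling: str,
    colnames: list[str],
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Weighted least squares via the scaled QR route.

    Returns (coefficients, SEs, weighted RSS, residual df). SEs follow the
    requested scaling: ``fixed`` uses the model-based covariance
    (X'WX)^-1; ``multiplicative`` inflates it by max(1, Q/df).
    """
    if se_scaling not in ("fixed", "multiplicative"):
        raise ConfigError(f"unknown se_scaling {se_scaling!r}")
    J, p = X.shape
    df = J - p  # may be 0 for an exactly determined fit (single-SNP Wald case)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    # rank check before solving so collinearity is reported by name
    u, s, vt = np.linalg.svd(Xw, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-12:
        null_dir = np.abs(vt[-1])
        involved = [colnames[k] for k in np.nonzero(null_dir > 1e-8)[0]]
        raise CollinearityError(
            f"weighted normal matrix is singular; dependent columns: {involved}"
        )
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss_w = float(resid @ resid)
    cov_fixed = np.linalg.inv(Xw.T @ Xw)
    scale = 1.0 if (se_scaling == "fixed" or df == 0) else max(1.0, rss_w / df)
    se = np.sqrt(scale * np.diag(cov_fixed))
    return beta, se, rss_w, df


def _coef_pvalues(beta, se, df, dist: str) -> np.ndarray:
    t = np.abs(beta) / se
    if dist == "t":
        return 2.0 * stats.t.sf(t, df)
    if dist == "normal":
        return 2.0 * stats.norm.sf(t)
    raise ConfigError(f"unknown pvalue_dist {dist!r}")


def ivw_multivariable(
    panel: HarmonizedPanel,
    se_scaling: str = "multiplicative",
    pvalue_dist: str = "t",
) -> list[MREstimate]:
    """Multivariable MR-IVW: zero-intercept WLS of by on all K exposures.

    Returns one :class:`MREstimate` per exposure; each carries the shared
    panel-level I² from the joint fit.
    """
    J, K = panel.B.shape
    if J < K:
        raise InsufficientInstrumentsError(f"J = {J} instruments for K = {K} exposures")
    if np.any(np.all(panel.B == 0, axis=0)):
        k = int(np.nonzero(np.all(panel.B == 0, axis=0))[0][0])
        raise CollinearityError(f"exposure {panel.exposures[k]!r} has all-zero effects")
    w = 1.0 / panel.se_y**2
    theta, se, _, df = _wls(panel.B, panel.by, w, se_scaling, list(panel.exposures))
    pvals = _coef_pvalues(theta, se, df, "normal" if df == 0 else pvalue_dist)
    het = cochran_q(panel, theta, with_intercept=False) if df > 0 else None
    method = "ivw_uni" if K == 1 else "ivw_multi"
    out = []
    for k, name in enumerate(panel.exposures):
        or_, ci = to_odds_ratio(theta[k], se[k])
        out.append(MREstimate(
            exposure=name, method=method,
            theta=float(theta[k]), se_theta=float(se[k]), pvalue=float(pvals[k]),
            or_=or_, ci95=ci, n_snps=J, i2=None if het is None else het.i2,
        ))
    return out


def ivw_univariable(
    panel: HarmonizedPanel,
    se_scaling: str = "multiplicative",
    pvalue_dist: str = "t",
) -> MREstimate:
    """Univariable MR-IVW on a K = 1 panel (see :meth:`HarmonizedPanel.select_exposure`)."""
    if panel.n_exposures != 1:
        raise ConfigError("ivw_univariable requires a single-exposure panel")
    return ivw_multivariable(panel, se_scaling=se_scaling, pvalue_dist=pvalue_dist)[0]


def egger_multivariable(
    panel: HarmonizedPanel,
    exposure_index: int,
    se_scaling: str = "multiplicative",
    pvalue_dist: str = "t",
) -> MREstimate:
    """Multivariable MR-Egger for one exposure of interest.

    The panel is first oriented so every SNP has a non-negative effect on the
    chosen exposure (the intercept is only identified relative to an
    orientation convention); the regression then includes a free intercept
    whose estimate is the average direct (pleiotropic) SNP-outcome effect.
    A full per-exposure Egger table is obtained by calling this once per
    exposure, re-orienting each time.
    """
    J, K = panel.B.shape
    if J <= K + 1:
        raise InsufficientInstrumentsError(
            f"J = {J} instruments cannot fit K = {K} slopes plus an intercept"
        )
    oriented = orient_to_exposure(panel, exposure_index)
    X = np.column_stack([np.ones(J), oriented.B])
    w = 1.0 / oriented.se_y**2
    names = ["(intercept)"] + list(panel.exposures)
    beta, se, _, df = _wls(X, oriented.by, w, se_scaling, names)
    pvals = _coef_pvalues(beta, se, df, pvalue_dist)
    het = cochran_q(oriented, beta[1:], with_intercept=True, intercept=beta[0])
    k = exposure_index + 1
    or_, ci = to_odds_ratio(beta[k], se[k])
    return MREstimate(
        exposure=panel.exposures[exposure_index], method="egger_multi",
        theta=float(beta[k]), se_theta=float(se[k]), pvalue=float(pvals[k]),
        or_=or_, ci95=ci, n_snps=J,
        intercept=float(beta[0]), se_intercept=float(se[0]), p_intercept=float(pvals[0]),
        i2=het.i2,
    )


def egger_table(panel: HarmonizedPanel, **kwargs) -> list[MREstimate]:
    """Per-exposure MR-Egger estimates, re-orienting for each exposure."""
    return [egger_multivariable(panel, k, **kwargs) for k in range(panel.n_exposures)]


def estimates_to_frame(estimates: list[MREstimate]):
    """Flatten estimates into a table mirroring the usual MR report layout."""
    import pandas as pd

    nan = float("nan")
    rows = []
    for e in estimates:
        rows.append({
            "exposure": e.exposure, "method": e.method,
            "theta": e.theta, "se": e.se_theta,
            "OR": e.or_, "CI_low": e.ci95[0], "CI_high": e.ci95[1],
            "P": e.pvalue, "I2": nan if e.i2 is None else e.i2,
            "intercept": nan if e.intercept is None else e.intercept,
            "intercept_P": nan if e.p_intercept is None else e.p_intercept,
            "n_snps": e.n_snps,
        })
    return pd.DataFrame(rows)
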