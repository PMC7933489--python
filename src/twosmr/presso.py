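"""Pleiotropy residual-sum-and-outlier (PRESSO-style) test.

Detects SNPs whose outcome effects are inconsistent with the multivariable
IVW fit. For every SNP j the model is refitted without it (leave-one-out)
and its weighted squared residual against the leave-one-out prediction is
recorded; the observed global statistic is the sum of these. Significance is
calibrated by parametric simulation: outcome effects are redrawn from
Normal(B_j · theta_{-j}, se_y[j]) with exposure effects held fixed
(two-sample MR makes exposure noise independent of the outcome, and at
genome-wide-significant instruments it is second order), and the statistic
recomputed on each replicate.

All leave-one-out fits reuse rank-one downdates of the weighted normal
matrix, so the simulation is a batched matrix product rather than n_sim × J
separate regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InsufficientInstrumentsError
from .mr import MREstimate, egger_table, ivw_multivariable
from .sumstats import HarmonizedPanel


@dataclass
class PressoResult:
    """Global RSS test with per-SNP outlier p-values.

    ``p_global`` uses add-one smoothing, (1 + #{sim >= obs}) / (n_sim + 1).
    ``per_snp_p`` is the raw simulated exceedance proportion multiplied by J
    (Bonferroni) and capped at 1; it can reach exactly 0 when no replicate
    exceeds the observed residual, which is what permits flagging at small
    n_sim.
    """

    rss_obs: float
    p_global: float
    per_snp_p: np.ndarray
    outliers: list[str]
    n_sim: int
    seed: int
    rss_per_snp: np.ndarray = field(default=None)
    rsids: np.ndarray = field(default=None)


def _loo_structures(B: np.ndarray, w: np.ndarray):
    """Inverse leave-one-out normal matrices A_{-j}^-1, shape (J, K, K)."""
    A = (B * w[:, None]).T @ B
    outer = w[:, None, None] * B[:, :, None] * B[:, None, :]
    A_loo = A[None, :, :] - outer
    return np.linalg.inv(A_loo)


def _loo_rss(B, by, w, Ainv):
    """Per-SNP weighted squared residuals against leave-one-out predictions.

    Accepts ``by`` of shape (J,) or batched (S, J); returns matching shape.
    """
    by2 = np.atleast_2d(by)                       # (S, J)
    c_full = by2 * w @ B                           # (S, K)
    c_loo = c_full[:, None, :] - (w * by2)[:, :, None] * B[None, :, :]   # (S, J, K)
    theta_loo = np.einsum("jkl,sjl->sjk", Ainv, c_loo)                   # (S, J, K)
    pred = np.einsum("jk,sjk->sj", B, theta_loo)                         # (S, J)
    rss = w * (by2 - pred) ** 2
    return rss[0] if np.ndim(by) == 1 else rss, (pred[0] if np.ndim(by) == 1 else pred)


def presso_test(
    panel: HarmonizedPanel,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
) -> PressoResult:
    """Run the global and per-SNP outlier test on a harmonized panel.

    Deterministic given (panel, n_sim, seed). Requires J >= K + 3 so every
    leave-one-out fit keeps positive residual degrees of freedom.
    """
    J, K = panel.B.shape
    if n_sim <= 0:
        raise ConfigError("n_sim must be positive (no null distribution otherwise)")
    if J < K + 3:
        raise InsufficientInstrumentsError(f"PRESSO needs J >= K + 3 (J={J}, K={K})")
    B, by, se_y = panel.B, panel.by, panel.se_y
    w = 1.0 / se_y**2
    Ainv = _loo_structures(B, w)
    rss_j, pred = _loo_rss(B, by, w, Ainv)
    rss_obs = float(rss_j.sum())

    rng = np.random.default_rng(seed)
    by_star = pred[None, :] + se_y[None, :] * rng.standard_normal((n_sim, J))
    rss_star, _ = _loo_rss(B, by_star, w, Ainv)
    p_global = (1 + int(np.sum(rss_star.sum(axis=1) >= rss_obs))) / (n_sim + 1)
    raw = (rss_star >= rss_j[None, :]).mean(axis=0)
    per_snp_p = np.minimum(1.0, raw * J)
    outliers = [str(r) for r, p in zip(panel.rsids, per_snp_p) if p < alpha]
    return PressoResult(
        rss_obs=rss_obs, p_global=float(p_global), per_snp_p=per_snp_p,
        outliers=outliers, n_sim=n_sim, seed=seed,
        rss_per_snp=rss_j, rsids=np.asarray(panel.rsids),
    )


@dataclass
class ExcludeRefitResult:
    """Side-by-side estimates with and without the flagged SNPs."""

    panel: HarmonizedPanel                  # flagged SNPs removed
    ivw_excluded: list[MREstimate]
    egger_excluded: list[MREstimate]
    ivw_included: list[MREstimate]
    egger_included: list[MREstimate]


def exclude_and_refit(panel: HarmonizedPanel, result: PressoResult) -> ExcludeRefitResult:
    """Remove flagged outliers and refit IVW and Egger, keeping both versions."""
    ivw_in = ivw_multivariable(panel)
    egger_in = egger_table(panel)
    reduced = panel.drop_rsids(result.outliers) if result.outliers else panel
    if result.outliers:
        ivw_ex = ivw_multivariable(reduced)
        egger_ex = egger_table(reduced)
    else:
        ivw_ex, egger_ex = ivw_in, egger_in
    return ExcludeRefitResult(
        panel=reduced,
        ivw_excluded=ivw_ex, egger_excluded=egger_ex,
        ivw_included=ivw_in, egger_included=egger_in,
    )


def presso_to_frame(result: PressoResult):
    """Per-SNP table: rsid, leave-one-out RSS, adjusted p, flagged."""
    import pandas as pd

    flagged = set(result.outliers)
    return pd.DataFrame({
        "rsid": result.rsids,
        "rss": result.rss_per_snp,
        "p_adjusted": result.per_snp_p,
        "flagged": [r in flagged for r in result.rsids],
    })
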