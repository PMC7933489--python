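"""Between-SNP heterogeneity of an MR fit: Cochran's Q, H², and I².

Q is the weighted residual sum of squares of the fitted regression, using
the same inverse-variance weights as the fit itself. Under homogeneity it is
approximately chi-squared with the residual degrees of freedom, so H² = Q/df
near 1 indicates sampling noise only and I² = max(0, (Q - df)/Q) · 100 is
the percent of variation beyond sampling error. I² categories follow the
conventional 25/50/75 reference values, collapsed onto three labels with a
"moderate-to-high" annotation for the [50, 75) band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DegenerateFitError


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with derived H² and I² (percent) and a categorical label."""

    q: float
    df: int
    h2: float
    i2: float
    category: str
    annotation: str | None = None


def categorize_i2(i2: float) -> tuple[str, str | None]:
    """Map an I² percentage onto {low, moderate, high}.

    [0, 25) is low, [25, 75) moderate, [75, 100) high; the [50, 75) band
    additionally carries a "moderate-to-high" annotation so the conventional
    50% reference value is not lost in the three-way collapse.
    """
    if not (0 <= i2 < 100):
        raise ConfigError(f"i2 must be in [0, 100) (got {i2})")
    if i2 < 25:
        return "low", None
    if i2 < 75:
        return "moderate", "moderate-to-high" if i2 >= 50 else None
    return "high", None


def cochran_q(
    panel,
    theta: np.ndarray,
    with_intercept: bool = False,
    intercept: float = 0.0,
) -> HeterogeneityResult:
    """Weighted residual heterogeneity of a (multivariable) MR fit.

    Parameters
    ----------
    panel
        A :class:`~twosmr.sumstats.HarmonizedPanel`.
    theta
        The fitted K-vector of causal effects (excluding any intercept).
    with_intercept
        Whether the fit estimated an intercept; reduces df by one and adds
        ``intercept`` to the fitted values.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    J, K = panel.B.shape
    if theta.shape != (K,):
        raise ConfigError(f"theta has shape {theta.shape}, expected ({K},)")
    df = J - K - (1 if with_intercept else 0)
    if df <= 0:
        raise DegenerateFitError(f"residual df = {df} <= 0")
    fitted = panel.B @ theta + (intercept if with_intercept else 0.0)
    w = 1.0 / panel.se_y**2
    q = float(np.sum(w * (panel.by - fitted) ** 2))
    h2 = q / df
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    category, annotation = categorize_i2(i2)
    return HeterogeneityResult(q=q, df=df, h2=h2, i2=i2, category=category, annotation=annotation)
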