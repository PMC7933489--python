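"""Summary-level GWAS simulator with known causal ground truth.

The generative model follows the standard two-sample MR causal diagram:
J SNPs carry effects gamma (J x K) on K exposures; each exposure has a
causal effect theta_k on a binary outcome (log-OR scale); a configurable
fraction of SNPs additionally carries a direct outcome effect alpha_j
(pleiotropy that bypasses the exposures). The true per-SNP outcome
association is

    by_j = sum_k gamma[j, k] * theta[k] + alpha_j

and observed effects add independent Gaussian noise on the exposure and
outcome sides (two-sample independence), with standard errors
1 / sqrt(2 * maf * (1 - maf) * n) as for a per-allele regression
coefficient of a standardized trait at sample size n.

The simulation is entirely at the summary level: no individual genotypes or
logistic outcomes are drawn, because the pipeline consumes summary
statistics and the linear summary-level model is the regime in which IVW
and Egger estimators are defined.

Defaults mirror a lipids-to-coronary-artery-disease study: three exposures
in SD units with causal log-ORs (0.44, -0.15, 0.21), exposure GWAS of
300k, outcome GWAS of ~550k, and a 30% cross-trait pleiotropy fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .instruments import LDMatrix
from .sumstats import CANON_COLS, HarmonizedPanel, TraitSumStats, harmonize

#: non-palindromic allele pairs cycled across simulated variants
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

_P_FLOOR = 1e-300  # keep simulated p-values inside (0, 1]


@dataclass
class SimConfig:
    """Generative parameters for one synthetic two-sample MR study.

    Effect magnitudes for nonzero SNP-exposure entries are drawn as
    ``gamma_scale * Uniform(0.5, 2)`` — bounded away from zero, as effects at
    genome-wide-significant instruments are — with signs per ``gamma_sign``
    (``"random"``, or ``"positive"`` to emulate coding every effect allele as
    the trait-increasing allele). ``gamma_density="dense"`` gives every SNP
    an effect on every exposure. Under the default sparse law each SNP has
    one primary exposure
    (assigned round-robin) and, with probability ``pleiotropy_frac``, one
    secondary exposure drawn from ``secondary_traits`` (default: any other
    exposure). ``primary_exposures`` restricts which traits receive primary
    effects, letting the remaining traits act as secondary-only traits (the
    metabolic-trait columns of a cross-trait pleiotropy table). A
    ``direct_frac`` fraction of SNPs receives a direct outcome effect
    alpha ~ Normal(alpha_mean, alpha_sd).
    """

    J: int = 300
    exposures: tuple[str, ...] = ("LDL-C", "HDL-C", "TG")
    exposure_scales: tuple[str, ...] = ("sd", "sd", "sd")
    theta: tuple[float, ...] = (0.44, -0.15, 0.21)
    outcome: str = "CAD"
    n_exp: int = 300_000
    n_out: int = 550_000
    pleiotropy_frac: float = 0.3
    primary_exposures: tuple[str, ...] | None = None
    secondary_traits: tuple[str, ...] | None = None
    direct_frac: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    gamma_scale: float = 0.03
    gamma_sign: str = "random"
    gamma_density: str = "sparse"
    gamma: np.ndarray | None = None          # explicit (J, K) override
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: tuple[tuple, ...] | None = None  # (size, r2) or (size, r2, "ar")
    within_block_bp: int = 10_000
    block_gap_bp: int = 20_000_000
    seed: int = 1

    def __post_init__(self) -> None:
        K = len(self.exposures)
        if len(self.theta) != K or len(self.exposure_scales) != K:
            raise ConfigError("theta/exposure_scales inconsistent with exposures")
        if not (0 <= self.pleiotropy_frac <= 1 and 0 <= self.direct_frac <= 1):
            raise ConfigError("fractions must lie in [0, 1]")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ConfigError("sample sizes must be positive")
        if self.gamma is not None and np.shape(self.gamma) != (self.J, K):
            raise ConfigError(f"explicit gamma must have shape ({self.J}, {K})")
        if self.gamma_sign not in ("random", "positive"):
            raise ConfigError("gamma_sign must be 'random' or 'positive'")
        if self.gamma_density not in ("sparse", "dense"):
            raise ConfigError("gamma_density must be 'sparse' or 'dense'")
        if self.ld_blocks is not None and sum(b[0] for b in self.ld_blocks) != self.J:
            raise ConfigError("ld_blocks sizes must sum to J")

    @property
    def K(self) -> int:
        return len(self.exposures)


@dataclass
class SimTruth:
    """Realized ground truth backing a simulated dataset."""

    gamma: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    pleiotropic_snps: set[str] = field(default_factory=set)
    outlier_snps: set[str] = field(default_factory=set)


def _positions(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic chrom/pos layout honouring the LD block structure."""
    blocks = config.ld_blocks or tuple((1, 0.0) for _ in range(config.J))
    pos = np.empty(config.J, dtype=np.int64)
    start = 1_000_000
    i = 0
    for b in blocks:
        size = b[0]
        pos[i : i + size] = start + np.arange(size) * config.within_block_bp
        start = pos[i + size - 1] + config.block_gap_bp
        i += size
    chrom = np.full(config.J, "1", dtype=object)
    return chrom, pos


def _draw_gamma(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """SNP-exposure effect matrix and the pleiotropic-SNP indicator."""
    J, K = config.J, config.K
    if config.gamma is not None:
        return np.asarray(config.gamma, dtype=float).copy(), np.zeros(J, dtype=bool)

    def magnitudes(size):
        mag = config.gamma_scale * rng.uniform(0.5, 2.0, size=size)
        if config.gamma_sign == "random":
            mag *= rng.choice([-1.0, 1.0], size=size)
        return mag

    if config.gamma_density == "dense":
        # every SNP affects every exposure (pleiotropy_frac does not apply)
        return magnitudes((J, K)), np.ones(J, dtype=bool)

    gamma = np.zeros((J, K))
    prim_names = config.primary_exposures or config.exposures
    prim_pool = [config.exposures.index(t) for t in prim_names]
    primary = np.asarray(prim_pool)[np.arange(J) % len(prim_pool)]
    gamma[np.arange(J), primary] = magnitudes(J)
    pleio = rng.random(J) < config.pleiotropy_frac
    sec_names = config.secondary_traits or config.exposures
    sec_pool = [config.exposures.index(t) for t in sec_names]
    for j in np.nonzero(pleio)[0]:
        choices = [k for k in sec_pool if k != primary[j]]
        if not choices:
            pleio[j] = False
            continue
        k = int(rng.choice(choices))
        gamma[j, k] = magnitudes(1)[0]
    return gamma, pleio


#: the strong-instrument regime used by recovery and calibration scenarios:
#: effect sizes and exposure sample size large enough that exposure
#: measurement error is negligible (the NOME approximation under which IVW,
#: Egger, and the PRESSO parametric null are exact), so deviations measure
#: the estimators rather than regression dilution.
STRONG_INSTRUMENTS = dict(gamma_scale=0.2, n_exp=10_000_000_000)


def simulate_sumstats(
    config: SimConfig,
) -> tuple[list[TraitSumStats], TraitSumStats, SimTruth]:
    """Generate exposure and outcome summary statistics plus ground truth.

    Byte-identical output for identical configs (single seeded generator).
    """
    rng = np.random.default_rng(config.seed)
    J, K = config.J, config.K
    chrom, pos = _positions(config)
    maf = rng.uniform(*config.maf_range, size=J)
    gamma, pleio = _draw_gamma(config, rng)

    alpha = np.zeros(J)
    n_direct = int(round(config.direct_frac * J))
    direct_idx = rng.choice(J, size=n_direct, replace=False) if n_direct else np.array([], int)
    if n_direct:
        alpha[direct_idx] = config.alpha_mean + config.alpha_sd * rng.standard_normal(n_direct)

    theta = np.asarray(config.theta, dtype=float)
    by_true = gamma @ theta + alpha

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exp)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_out)
    bx_obs = gamma + se_x[:, None] * rng.standard_normal((J, K))
    by_obs = by_true + se_y * rng.standard_normal(J)

    rsids = np.array([f"rs{j + 1:06d}" for j in range(J)], dtype=object)
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(J)]
    ea = np.array([p[0] for p in pairs], dtype=object)
    oa = np.array([p[1] for p in pairs], dtype=object)

    def build(trait, scale, beta, se):
        p = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), _P_FLOOR, 1.0)
        df = pd.DataFrame({
            "rsid": rsids, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "eaf": maf, "beta": beta, "se": se, "pvalue": p,
            "n": float(config.n_exp if scale != "log_or_outcome" else config.n_out),
        })
        return df

    exposures = []
    for k, name in enumerate(config.exposures):
        df = build(name, config.exposure_scales[k], bx_obs[:, k], se_x)
        exposures.append(TraitSumStats(name, config.exposure_scales[k], df[CANON_COLS]))
    odf = build(config.outcome, "log_or_outcome", by_obs, se_y)
    odf["n"] = float(config.n_out)
    outcome = TraitSumStats(config.outcome, "log_or", odf[CANON_COLS])

    truth = SimTruth(
        gamma=gamma, theta=theta, alpha=alpha,
        pleiotropic_snps={str(r) for r in rsids[pleio]},
        outlier_snps={str(r) for r in rsids[direct_idx]},
    )
    return exposures, outcome, truth


def simulate_panel(config: SimConfig) -> tuple[HarmonizedPanel, SimTruth]:
    """Convenience: simulate and harmonize in one step (no variants drop)."""
    exposures, outcome, truth = simulate_sumstats(config)
    return harmonize(exposures, outcome), truth


def simulate_ld_blocks(config: SimConfig) -> LDMatrix:
    """Block-diagonal r² matrix matching the simulated variant layout.

    Each block entry is ``(size, r2)`` for constant within-block r² or
    ``(size, r2, "ar")`` for AR-style decay r2**|i - k|; across blocks r² is
    zero. Positions match :func:`simulate_sumstats` for the same config.
    """
    blocks = config.ld_blocks or tuple((1, 0.0) for _ in range(config.J))
    for b in blocks:
        if not (0.0 <= b[1] <= 1.0):
            raise ValidationError(f"block r2 {b[1]} outside [0, 1]")
    J = config.J
    r2 = np.zeros((J, J))
    i = 0
    for b in blocks:
        size, rho = b[0], b[1]
        decay = len(b) > 2 and b[2] == "ar"
        idx = np.arange(size)
        block = rho ** np.abs(idx[:, None] - idx[None, :]) if decay else np.full((size, size), rho)
        r2[i : i + size, i : i + size] = block
        i += size
    np.fill_diagonal(r2, 1.0)
    chrom, pos = _positions(config)
    rsids = [f"rs{j + 1:06d}" for j in range(J)]
    return LDMatrix(rsids=rsids, r2=r2, chrom=chrom, pos=pos)
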