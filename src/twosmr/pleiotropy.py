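"""Cross-trait pleiotropy screening of instrument sets.

For each exposure trait's instruments, tabulate the percentage that are also
associated with every secondary trait at a Bonferroni-corrected threshold,
and build "restricted" instrument sets purged of any such association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sumstats import TraitSumStats

logger = logging.getLogger("twosmr")


def bonferroni_threshold(alpha: float, m: int, sig_figs: int | None = None) -> float:
    """Family-wise threshold alpha / m, optionally rounded for display."""
    if m < 1:
        raise ConfigError("m must be >= 1")
    if not (0 < alpha < 1):
        raise ConfigError("alpha must be in (0, 1)")
    t = alpha / m
    if sig_figs is not None:
        t = float(f"{t:.{sig_figs}g}")
    return t


@dataclass
class PleiotropyTable:
    """Cross-trait pleiotropy percentages.

    ``percent.loc[e, s]`` is the percentage of exposure e's instruments whose
    association p-value with secondary trait s falls below ``threshold``;
    ``numer``/``denom`` hold the matching counts. Cells with an empty
    denominator are NaN (flagged, never silently zero).
    """

    percent: pd.DataFrame
    numer: pd.DataFrame
    denom: pd.DataFrame
    threshold: float


def _secondary_pvalues(rsids: Sequence[str], stats: TraitSumStats) -> pd.Series:
    """p-values of the given rsids in a secondary trait (NaN where absent)."""
    lut = stats.df.set_index("rsid")["pvalue"]
    return lut.reindex(rsids)


def pleiotropy_crosstab(
    instrument_sets: Mapping[str, TraitSumStats],
    secondary_stats: Mapping[str, TraitSumStats],
    threshold: float,
    composite: Sequence[str] | None = None,
    composite_name: str | None = None,
) -> PleiotropyTable:
    """Percentage of each trait's instruments associated with each secondary trait.

    Instruments missing from a secondary trait's statistics shrink that
    cell's denominator (with a logged count) rather than counting as
    non-pleiotropic. When ``composite`` names a secondary-trait subset, an
    extra any-of column is appended (a variant counts if it passes the
    threshold for at least one member; no multiplicity re-adjustment).
    """
    exposures = list(instrument_sets)
    secondaries = list(secondary_stats)
    cols = list(secondaries)
    if composite:
        unknown = set(composite) - set(secondaries)
        if unknown:
            raise ConfigError(f"composite traits not in secondary stats: {sorted(unknown)}")
        composite_name = composite_name or ("any of " + ", ".join(composite))
        cols.append(composite_name)
    percent = pd.DataFrame(index=exposures, columns=cols, dtype=float)
    numer = pd.DataFrame(0, index=exposures, columns=cols, dtype=int)
    denom = pd.DataFrame(0, index=exposures, columns=cols, dtype=int)
    for e in exposures:
        rsids = list(instrument_sets[e].rsids)
        if not rsids:
            logger.warning("pleiotropy_crosstab: exposure %s has no instruments", e)
            percent.loc[e, :] = np.nan
            continue
        pmat = {s: _secondary_pvalues(rsids, secondary_stats[s]) for s in secondaries}
        for s in secondaries:
            p = pmat[s]
            present = p.notna()
            n_missing = int((~present).sum())
            if n_missing:
                logger.info("crosstab %s x %s: %d instruments missing", e, s, n_missing)
            d = int(present.sum())
            n = int((p[present] < threshold).sum())
            denom.loc[e, s], numer.loc[e, s] = d, n
            percent.loc[e, s] = 100.0 * n / d if d else np.nan
        if composite:
            hit = pd.concat(
                [(pmat[s] < threshold) for s in composite], axis=1
            ).any(axis=1)
            present = pd.concat([pmat[s].notna() for s in composite], axis=1).any(axis=1)
            d = int(present.sum())
            n = int(hit[present].sum())
            denom.loc[e, composite_name], numer.loc[e, composite_name] = d, n
            percent.loc[e, composite_name] = 100.0 * n / d if d else np.nan
    return PleiotropyTable(percent=percent, numer=numer, denom=denom, threshold=threshold)


def restricted_set_filter(
    instruments: TraitSumStats,
    secondary_stats: Mapping[str, TraitSumStats],
    threshold: float,
) -> tuple[TraitSumStats, dict]:
    """Drop instruments with any secondary-trait p below ``threshold``.

    Returns the surviving instruments plus diagnostics of the residual
    pleiotropy signal among survivors: the fraction of their secondary
    p-values below 0.1 (a left-shift indicator; 0.1 is expected under a
    uniform null) and the deciles of that p-value distribution.
    """
    rsids = list(instruments.rsids)
    pmat = pd.DataFrame({s: _secondary_pvalues(rsids, ss) for s, ss in secondary_stats.items()})
    keep = ~(pmat < threshold).any(axis=1)
    survivors = instruments.take(np.nonzero(keep.to_numpy())[0])
    surv_p = pmat[keep.to_numpy()].to_numpy().ravel()
    surv_p = surv_p[~np.isnan(surv_p)]
    diagnostics = {
        "n_input": len(rsids),
        "n_retained": len(survivors),
        "frac_secondary_p_below_0.1": float(np.mean(surv_p < 0.1)) if surv_p.size else np.nan,
        "secondary_p_deciles": (
            np.quantile(surv_p, np.linspace(0.1, 0.9, 9)).tolist() if surv_p.size else []
        ),
    }
    return survivors, diagnostics
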