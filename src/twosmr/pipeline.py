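"""End-to-end analysis: selection -> clumping -> pleiotropy -> MR -> PRESSO -> locus MR.

Stage order is fixed: per-trait genome-wide selection, LD clumping,
cross-trait pleiotropy tabulation, multivariable MR on the lipid-style
exposure subset (K small), PRESSO exclusion and refit, the same for the
full exposure set, and finally per-locus univariable MR. Every filtering
step logs its input/output counts so dropped variants are accounted for.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .heterogeneity import cochran_q
from .instruments import (
    CLUMP_R2,
    CLUMP_WINDOW_BP,
    GW_ALPHA,
    LOCUS_HALF_WIDTH_BP,
    LDMatrix,
    Locus,
    clump,
    locus_window,
    read_locus_table,
    select_genome_wide,
)
from .mr import MREstimate, estimates_to_frame, ivw_univariable, wald_ratio
from .pleiotropy import PleiotropyTable, bonferroni_threshold, pleiotropy_crosstab
from .presso import ExcludeRefitResult, PressoResult, presso_test, presso_to_frame, exclude_and_refit
from .sumstats import TraitSumStats, harmonize, read_sumstats

logger = logging.getLogger("twosmr")


@dataclass
class RunConfig:
    """One analysis run: inputs, thresholds, and output location."""

    exposures: list[dict]                 # {path, trait, scale, column_map?}
    outcome: dict                         # {path, trait, scale, column_map?}
    outdir: str = "twosmr_out"
    ld_path: str | None = None
    ld_format: str = "square"             # square | long
    locus_path: str | None = None
    primary_exposures: list[str] | None = None   # the K-small subset (e.g. lipids)
    composite_secondary: list[str] | None = None
    gw_alpha: float = GW_ALPHA
    clump_r2: float = CLUMP_R2
    clump_window_bp: int = CLUMP_WINDOW_BP
    locus_half_width_bp: int = LOCUS_HALF_WIDTH_BP
    pleiotropy_alpha: float = 0.05
    pleiotropy_m: int | None = None       # default: total distinct instruments
    presso: bool = True
    presso_alpha: float = 0.05
    n_sim: int = 1000
    seed: int = 1
    strict: bool = False                  # lenient row validation by default in runs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad run configuration: {exc}") from exc

    def digest(self) -> str:
        blob = yaml.safe_dump(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All tables produced by one run, plus provenance."""

    pleiotropy_table: PleiotropyTable | None
    mr_primary: ExcludeRefitResult | None       # K-small exposure subset
    mr_full: ExcludeRefitResult | None          # all exposures
    presso_primary: PressoResult | None
    presso_full: PressoResult | None
    locus_estimates: list[MREstimate]
    counts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _load_traits(config: RunConfig) -> tuple[list[TraitSumStats], TraitSumStats]:
    exposures = []
    for spec in config.exposures:
        exposures.append(read_sumstats(
            spec["path"], column_map=spec.get("column_map"),
            trait_scale=spec.get("scale", "sd"), trait=spec["trait"],
            strict=config.strict,
        ))
    o = config.outcome
    outcome = read_sumstats(
        o["path"], column_map=o.get("column_map"),
        trait_scale=o.get("scale", "log_or"), trait=o["trait"],
        strict=config.strict,
    )
    return exposures, outcome


def _mr_block(
    exposures: list[TraitSumStats],
    outcome: TraitSumStats,
    instrument_rsids: set[str],
    config: RunConfig,
    label: str,
    counts: dict,
) -> tuple[ExcludeRefitResult | None, PressoResult | None]:
    subset = [e.subset(instrument_rsids) for e in exposures]
    panel = harmonize(subset, outcome.subset(instrument_rsids))
    counts[f"{label}_panel_snps"] = panel.n_snps
    logger.info("%s: harmonized panel of %d SNPs x %d exposures", label, panel.n_snps, panel.n_exposures)
    presso_res = None
    if config.presso:
        presso_res = presso_test(panel, n_sim=config.n_sim, alpha=config.presso_alpha, seed=config.seed)
        counts[f"{label}_presso_outliers"] = len(presso_res.outliers)
        refit = exclude_and_refit(panel, presso_res)
    else:
        refit = exclude_and_refit(panel, PressoResult(
            rss_obs=np.nan, p_global=np.nan, per_snp_p=np.ones(panel.n_snps),
            outliers=[], n_sim=0, seed=config.seed,
            rss_per_snp=np.full(panel.n_snps, np.nan), rsids=panel.rsids,
        ))
    return refit, presso_res


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute every stage and write all tables under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    exposures, outcome = _load_traits(config)
    ld = None
    if config.ld_path:
        ld = (LDMatrix.from_square_tsv if config.ld_format == "square"
              else LDMatrix.from_long_tsv)(config.ld_path)

    # 1. instrument selection per exposure trait
    instrument_sets: dict[str, TraitSumStats] = {}
    for e in exposures:
        sig = select_genome_wide(e, alpha=config.gw_alpha)
        counts[f"{e.trait}_gw_significant"] = len(sig)
        if ld is not None:
            sig = clump(sig, ld, r2_max=config.clump_r2, window_bp=config.clump_window_bp)
        counts[f"{e.trait}_instruments"] = len(sig)
        logger.info("%s: %d instruments after selection/clumping", e.trait, len(sig))
        instrument_sets[e.trait] = sig

    all_instruments = sorted(set().union(*(set(s.rsids) for s in instrument_sets.values())))
    counts["distinct_instruments"] = len(all_instruments)

    # 2. cross-trait pleiotropy table
    m = config.pleiotropy_m or max(1, len(all_instruments))
    threshold = bonferroni_threshold(config.pleiotropy_alpha, m)
    counts["pleiotropy_threshold"] = threshold
    secondary = {e.trait: e for e in exposures}
    table1 = pleiotropy_crosstab(
        instrument_sets, secondary, threshold,
        composite=config.composite_secondary,
    )
    table1.percent.to_csv(outdir / "pleiotropy_table.tsv", sep="\t")

    # 3. multivariable MR: primary (K-small) subset, then all exposures
    primary_names = config.primary_exposures or [e.trait for e in exposures]
    primary = [e for e in exposures if e.trait in primary_names]
    primary_rsids = set().union(*(set(instrument_sets[e.trait].rsids) for e in primary))
    mr_primary, presso_primary = _mr_block(primary, outcome, primary_rsids, config, "primary", counts)

    mr_full, presso_full = (None, None)
    if set(primary_names) != {e.trait for e in exposures}:
        mr_full, presso_full = _mr_block(
            exposures, outcome, set(all_instruments), config, "full", counts
        )

    for label, refit, pres in (("primary", mr_primary, presso_primary),
                               ("full", mr_full, presso_full)):
        if refit is None:
            continue
        frame = pd.concat([
            estimates_to_frame(refit.ivw_excluded).assign(presso_excluded=True),
            estimates_to_frame(refit.egger_excluded).assign(presso_excluded=True),
            estimates_to_frame(refit.ivw_included).assign(presso_excluded=False),
            estimates_to_frame(refit.egger_included).assign(presso_excluded=False),
        ], ignore_index=True)
        frame.to_csv(outdir / f"mr_{label}.tsv", sep="\t", index=False)
        if pres is not None:
            presso_to_frame(pres).to_csv(outdir / f"presso_{label}.tsv", sep="\t", index=False)

    # 4. monogenic locus MR
    locus_estimates: list[MREstimate] = []
    if config.locus_path:
        loci = read_locus_table(config.locus_path)
        for row in loci.itertuples(index=False):
            locus = Locus(gene=row.gene, chrom=str(row.chrom), tss=int(row.tss))
            trait = getattr(row, "trait", primary_names[0])
            inst = locus_window(instrument_sets[trait], locus,
                                half_width_bp=config.locus_half_width_bp)
            counts[f"locus_{locus.gene}_snps"] = len(inst)
            if not len(inst):
                logger.warning("locus %s: no instruments in window", locus.gene)
                continue
            exp = next(e for e in exposures if e.trait == trait)
            lp = harmonize([exp.subset(set(inst.rsids))], outcome.subset(set(inst.rsids)))
            if lp.n_snps == 1:
                est = wald_ratio(lp.by[0], lp.se_y[0], lp.B[0, 0], exposure=trait)
            else:
                est = ivw_univariable(lp)
            est.exposure = f"{locus.gene}:{trait}"
            locus_estimates.append(est)
        if locus_estimates:
            estimates_to_frame(locus_estimates).to_csv(
                outdir / "locus_mr.tsv", sep="\t", index=False
            )

    provenance = {"config_digest": config.digest(), "seed": config.seed, "version": __version__}
    manifest = {"counts": counts, "provenance": provenance}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))

    return AnalysisReport(
        pleiotropy_table=table1,
        mr_primary=mr_primary, mr_full=mr_full,
        presso_primary=presso_primary, presso_full=presso_full,
        locus_estimates=locus_estimates,
        counts=counts, provenance=provenance,
    )


def significance_annotation(estimates: list[MREstimate], m: int) -> pd.DataFrame:
    """Tabulate estimates with a Bonferroni significance flag at 0.05 / m."""
    frame = estimates_to_frame(estimates)
    threshold = 0.05 / m
    frame["significant"] = frame["P"] < threshold
    frame["threshold"] = threshold
    return frame
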