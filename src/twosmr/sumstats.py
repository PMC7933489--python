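"""Per-trait GWAS summary statistics: reading, validation, harmonization.

A :class:`TraitSumStats` holds one trait's per-variant association statistics
(effect sizes in SD units for continuous traits, log odds ratios for binary
traits). :func:`harmonize` aligns several exposure traits and one outcome
trait to a common effect allele and returns a :class:`HarmonizedPanel`, the
J x K design matrix consumed by every MR regression downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyPanelError, ValidationError

logger = logging.getLogger("twosmr")

TRAIT_SCALES = ("sd", "log_or", "raw")

#: canonical column order for summary-statistics tables
CANON_COLS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]
REQUIRED_COLS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One variant's association with one trait."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None


def _row_problem(row) -> str | None:
    """Return a description of the first invariant the row violates, else None."""
    if not (row.se > 0):
        return f"se must be > 0 (got {row.se})"
    if not (0 < row.pvalue <= 1):
        return f"pvalue must be in (0, 1] (got {row.pvalue})"
    if row.pos < 1:
        return f"pos must be >= 1 (got {row.pos})"
    ea, oa = row.effect_allele, row.other_allele
    if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
        return f"alleles must be A/C/G/T (got {ea}/{oa})"
    if ea == oa:
        return f"effect and other allele identical ({ea})"
    if not np.isnan(row.eaf) and not (0 <= row.eaf <= 1):
        return f"eaf must be in [0, 1] (got {row.eaf})"
    if np.isnan(row.beta):
        return "beta is missing"
    return None


@dataclass
class TraitSumStats:
    """One trait's GWAS summary statistics with unique rsids.

    Parameters
    ----------
    trait
        Trait name (e.g. ``"HDL-C"``).
    trait_scale
        ``"sd"`` for standardized continuous traits, ``"log_or"`` for binary
        traits, ``"raw"`` for untransformed units (e.g. mmHg).
    df
        Table with the canonical columns; assumed already validated.
    """

    trait: str
    trait_scale: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_scale not in TRAIT_SCALES:
            raise ConfigError(
                f"trait_scale must be one of {TRAIT_SCALES}, got {self.trait_scale!r}"
            )
        missing = [c for c in CANON_COLS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"summary statistics missing columns: {missing}")
        if self.df["rsid"].duplicated().any():
            dup = self.df.loc[self.df["rsid"].duplicated(), "rsid"].iloc[0]
            raise ValidationError(f"duplicate rsid in {self.trait}: {dup}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def rsids(self) -> pd.Series:
        return self.df["rsid"]

    def records(self) -> Iterable[VariantRecord]:
        for row in self.df.itertuples(index=False):
            yield VariantRecord(
                rsid=row.rsid, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                beta=row.beta, se=row.se, pvalue=row.pvalue,
                eaf=None if np.isnan(row.eaf) else row.eaf,
                n=None if np.isnan(row.n) else row.n,
            )

    def subset(self, mask_or_rsids) -> "TraitSumStats":
        """Restrict to a boolean mask or an rsid collection, preserving order."""
        if isinstance(mask_or_rsids, (pd.Series, np.ndarray)) and getattr(
            mask_or_rsids, "dtype", None
        ) == bool:
            sub = self.df.loc[np.asarray(mask_or_rsids)]
        else:
            keep = set(mask_or_rsids)
            sub = self.df[self.df["rsid"].isin(keep)]
        return replace(self, df=sub.reset_index(drop=True))

    def take(self, indices) -> "TraitSumStats":
        """Positional row selection (keeps the given order)."""
        return replace(self, df=self.df.iloc[np.asarray(indices, dtype=int)].reset_index(drop=True))

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        trait: str,
        trait_scale: str = "sd",
        strict: bool = True,
    ) -> "TraitSumStats":
        """Build validated summary statistics from a raw data frame.

        In strict mode the first invariant violation raises
        :class:`ValidationError` naming the offending rsid; in lenient mode
        violating rows are dropped and counted in the log.
        """
        df = frame.copy()
        for col in ("eaf", "n"):
            if col not in df.columns:
                df[col] = np.nan
        missing = [c for c in REQUIRED_COLS if c not in df.columns]
        if missing:
            raise ConfigError(f"missing required columns: {missing}")

        df["rsid"] = df["rsid"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        for col in ("effect_allele", "other_allele"):
            df[col] = df[col].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pvalue", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df = df[CANON_COLS]

        bad_idx, problems = [], []
        for i, row in enumerate(df.itertuples(index=False)):
            problem = _row_problem(row)
            if problem is not None:
                if strict:
                    raise ValidationError(f"{trait} rsid {row.rsid}: {problem}")
                bad_idx.append(i)
                problems.append(problem)
        if bad_idx:
            logger.warning(
                "%s: dropped %d invalid rows (first: %s)",
                trait, len(bad_idx), problems[0],
            )
            df = df.drop(df.index[bad_idx]).reset_index(drop=True)
        return cls(trait=trait, trait_scale=trait_scale, df=df.reset_index(drop=True))


_DEFAULT_COLUMN_MAP = {c: c for c in CANON_COLS}


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_scale: str = "sd",
    trait: str | None = None,
    strict: bool = True,
    sep: str | None = None,
) -> TraitSumStats:
    """Read delimited (TSV/CSV, optionally gzipped) summary statistics.

    ``column_map`` maps canonical names (``rsid``, ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
    ``pvalue``, ``n``) to the file's column names; unmapped optional columns
    (``eaf``, ``n``) are filled with NaN.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        name = str(path)
        if name.endswith(".gz"):
            name = name[:-3]
        sep = "," if name.endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep)
    rename = {}
    for canon, source in cmap.items():
        if source in raw.columns:
            rename[source] = canon
        elif canon in REQUIRED_COLS:
            raise ConfigError(f"column {source!r} (for {canon}) not found in {path}")
    frame = raw.rename(columns=rename)
    if trait is None:
        trait = str(path)
    return TraitSumStats.from_frame(frame, trait=trait, trait_scale=trait_scale, strict=strict)


def write_sumstats(sumstats: TraitSumStats, path, sep: str = "\t") -> None:
    """Write summary statistics as headered delimited text (canonical columns)."""
    sumstats.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Harmonized panel
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedPanel:
    """Allele-aligned SNP-by-trait effect table for MR regressions.

    Rows are variants (J), columns of ``B`` are exposures (K); ``by``/``se_y``
    hold the outcome log-OR effects. Every row refers to a single effect
    allele across all K + 1 traits.
    """

    rsids: np.ndarray            # (J,) str
    chrom: np.ndarray            # (J,) str
    pos: np.ndarray              # (J,) int
    effect_allele: np.ndarray    # (J,) str
    other_allele: np.ndarray     # (J,) str
    exposures: list[str]
    B: np.ndarray                # (J, K)
    SE_B: np.ndarray             # (J, K)
    P_B: np.ndarray              # (J, K)
    by: np.ndarray               # (J,)
    se_y: np.ndarray             # (J,)
    outcome: str = "outcome"
    exposure_scales: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        J, K = self.B.shape
        for name, arr, shape in [
            ("SE_B", self.SE_B, (J, K)), ("P_B", self.P_B, (J, K)),
            ("by", self.by, (J,)), ("se_y", self.se_y, (J,)),
            ("rsids", self.rsids, (J,)), ("pos", self.pos, (J,)),
        ]:
            if np.shape(arr) != shape:
                raise ValidationError(f"panel field {name} has shape {np.shape(arr)}, expected {shape}")
        if len(self.exposures) != K:
            raise ValidationError("exposure names inconsistent with B")
        if J and not np.all(self.se_y > 0):
            raise ValidationError("se_y must be > 0 elementwise")
        if not self.exposure_scales:
            self.exposure_scales = ["sd"] * K

    @property
    def n_snps(self) -> int:
        return self.B.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.B.shape[1]

    def take(self, idx) -> "HarmonizedPanel":
        idx = np.asarray(idx, dtype=int)
        return HarmonizedPanel(
            rsids=self.rsids[idx], chrom=self.chrom[idx], pos=self.pos[idx],
            effect_allele=self.effect_allele[idx], other_allele=self.other_allele[idx],
            exposures=list(self.exposures),
            B=self.B[idx], SE_B=self.SE_B[idx], P_B=self.P_B[idx],
            by=self.by[idx], se_y=self.se_y[idx],
            outcome=self.outcome, exposure_scales=list(self.exposure_scales),
        )

    def drop_rsids(self, rsids: Iterable[str]) -> "HarmonizedPanel":
        drop = set(rsids)
        missing = drop - set(self.rsids.tolist())
        if missing:
            raise ValidationError(f"rsids not in panel: {sorted(missing)}")
        keep = np.array([r not in drop for r in self.rsids])
        if not keep.any():
            raise EmptyPanelError("dropping the requested rsids empties the panel")
        return self.take(np.nonzero(keep)[0])

    def select_exposure(self, index_or_name) -> "HarmonizedPanel":
        """Restrict to one exposure column (a K = 1 view for univariable MR)."""
        k = (self.exposures.index(index_or_name)
             if isinstance(index_or_name, str) else int(index_or_name))
        return HarmonizedPanel(
            rsids=self.rsids, chrom=self.chrom, pos=self.pos,
            effect_allele=self.effect_allele, other_allele=self.other_allele,
            exposures=[self.exposures[k]],
            B=self.B[:, [k]], SE_B=self.SE_B[:, [k]], P_B=self.P_B[:, [k]],
            by=self.by, se_y=self.se_y,
            outcome=self.outcome, exposure_scales=[self.exposure_scales[k]],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: rsid, chrom, pos, alleles, per-exposure beta/se/p, outcome."""
        data: dict[str, np.ndarray] = {
            "rsid": self.rsids, "chrom": self.chrom, "pos": self.pos,
            "effect_allele": self.effect_allele, "other_allele": self.other_allele,
        }
        for k, name in enumerate(self.exposures):
            data[f"beta.{name}"] = self.B[:, k]
            data[f"se.{name}"] = self.SE_B[:, k]
            data[f"p.{name}"] = self.P_B[:, k]
        data[f"beta.{self.outcome}"] = self.by
        data[f"se.{self.outcome}"] = self.se_y
        return pd.DataFrame(data)

    def to_sumstats(self) -> tuple[list[TraitSumStats], TraitSumStats]:
        """Re-express the panel as per-trait summary statistics (eaf unset)."""
        base = pd.DataFrame({
            "rsid": self.rsids, "chrom": self.chrom, "pos": self.pos,
            "effect_allele": self.effect_allele, "other_allele": self.other_allele,
            "eaf": np.nan, "n": np.nan,
        })
        exposures = []
        for k, name in enumerate(self.exposures):
            df = base.copy()
            df["beta"], df["se"], df["pvalue"] = self.B[:, k], self.SE_B[:, k], self.P_B[:, k]
            exposures.append(TraitSumStats(name, self.exposure_scales[k], df[CANON_COLS]))
        df = base.copy()
        df["beta"], df["se"] = self.by, self.se_y
        df["pvalue"] = 2.0 * _norm_sf(np.abs(self.by) / self.se_y)
        outcome = TraitSumStats(self.outcome, "log_or", df[CANON_COLS])
        return exposures, outcome


def _norm_sf(z):
    from scipy.stats import norm

    return np.clip(norm.sf(z), np.finfo(float).tiny, None)


def write_panel(panel: HarmonizedPanel, path, sep: str = "\t") -> None:
    """Write the panel as delimited text (5 + 3K + 2 columns, see to_frame)."""
    panel.to_frame().to_csv(path, sep=sep, index=False)


def read_panel(path, outcome: str | None = None, sep: str = "\t") -> HarmonizedPanel:
    """Read a panel written by :func:`write_panel`.

    Column order determines the exposure list; the last beta/se pair is the
    outcome (or name it explicitly via ``outcome``).
    """
    df = pd.read_csv(path, sep=sep)
    traits = [c[len("beta."):] for c in df.columns if c.startswith("beta.")]
    if not traits:
        raise ConfigError(f"no beta.<trait> columns found in {path}")
    if outcome is None:
        outcome = traits[-1]
    exposures = [t for t in traits if t != outcome]
    return HarmonizedPanel(
        rsids=df["rsid"].astype(str).to_numpy(),
        chrom=df["chrom"].astype(str).to_numpy(),
        pos=df["pos"].astype(np.int64).to_numpy(),
        effect_allele=df["effect_allele"].to_numpy(),
        other_allele=df["other_allele"].to_numpy(),
        exposures=exposures,
        B=df[[f"beta.{t}" for t in exposures]].to_numpy(float),
        SE_B=df[[f"se.{t}" for t in exposures]].to_numpy(float),
        P_B=df[[f"p.{t}" for t in exposures]].to_numpy(float),
        by=df[f"beta.{outcome}"].to_numpy(float),
        se_y=df[f"se.{outcome}"].to_numpy(float),
        outcome=outcome,
    )


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def is_palindromic(ea: str, oa: str) -> bool:
    """A/T and C/G variants cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT.get(ea) == oa


def _align_trait(
    ref: pd.DataFrame,
    trait_df: pd.DataFrame,
    trait: str,
    drop_palindromic: bool,
    ambiguity_band: tuple[float, float],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flip a trait's effects onto the reference effect allele, rsid by rsid.

    Matching tries, in order: same alleles, swapped alleles (beta negated,
    eaf -> 1 - eaf), strand-complement alleles, swapped complement. Palindromic
    variants are dropped outright when ``drop_palindromic``; otherwise they
    are aligned by allele frequency and dropped only when either frequency is
    missing or inside the ambiguity band.
    """
    merged = ref.merge(trait_df, on="rsid", suffixes=("_ref", ""), how="inner")
    lo, hi = ambiguity_band
    keep, flip = [], []
    counts = {"incompatible": 0, "palindromic": 0}
    for row in merged.itertuples(index=False):
        ea, oa = row.effect_allele, row.other_allele
        rea, roa = row.effect_allele_ref, row.other_allele_ref
        pal = is_palindromic(ea, oa)
        if pal:
            if drop_palindromic:
                counts["palindromic"] += 1
                continue
            if not (ea == rea and oa == roa) and not (ea == roa and oa == rea):
                counts["incompatible"] += 1
                continue
            # allele labels cannot resolve strand: use frequency concordance
            eaf_ref, eaf = row.eaf_ref, row.eaf
            if np.isnan(eaf_ref) or np.isnan(eaf) or lo <= eaf <= hi or lo <= eaf_ref <= hi:
                counts["palindromic"] += 1
                continue
            same = (ea == rea)
            freq = eaf if same else 1.0 - eaf
            do_flip = abs(freq - eaf_ref) > abs((1.0 - freq) - eaf_ref)
            keep.append(row.rsid)
            flip.append(do_flip != (not same))  # net sign flip vs reference allele
            continue
        if ea == rea and oa == roa:
            keep.append(row.rsid); flip.append(False)
        elif ea == roa and oa == rea:
            keep.append(row.rsid); flip.append(True)
        elif _COMPLEMENT[ea] == rea and _COMPLEMENT[oa] == roa:
            keep.append(row.rsid); flip.append(False)
        elif _COMPLEMENT[ea] == roa and _COMPLEMENT[oa] == rea:
            keep.append(row.rsid); flip.append(True)
        else:
            counts["incompatible"] += 1
    out = trait_df.set_index("rsid").loc[keep].reset_index()
    flip_arr = np.asarray(flip, dtype=bool)
    if len(out):
        out.loc[flip_arr, "beta"] = -out.loc[flip_arr, "beta"]
        out.loc[flip_arr, "eaf"] = 1.0 - out.loc[flip_arr, "eaf"]
        out["effect_allele"] = ref.set_index("rsid").loc[out["rsid"], "effect_allele"].to_numpy()
        out["other_allele"] = ref.set_index("rsid").loc[out["rsid"], "other_allele"].to_numpy()
    for reason, n in counts.items():
        if n:
            logger.info("harmonize %s: dropped %d %s variants", trait, n, reason)
    return out, counts


def harmonize(
    exposures: Sequence[TraitSumStats],
    outcome: TraitSumStats,
    drop_palindromic: bool = False,
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedPanel:
    """Align exposures and outcome to one effect allele per variant.

    The reference allele is the first exposure's effect allele. The panel is
    complete-case: only variants present with full data in every trait are
    kept. With ``drop_palindromic=True`` all A/T and C/G variants are removed;
    by default they are frequency-aligned, with ambiguous ones (eaf missing or
    inside ``ambiguity_band``) dropped.
    """
    if not exposures:
        raise ConfigError("at least one exposure is required")
    traits = list(exposures) + [outcome]
    ref = exposures[0].df[["rsid", "chrom", "pos", "effect_allele", "other_allele", "eaf"]]
    aligned: list[pd.DataFrame] = []
    common: set[str] | None = None
    for ss in traits:
        adf, _ = _align_trait(ref, ss.df, ss.trait, drop_palindromic, ambiguity_band)
        complete = adf.dropna(subset=["beta", "se", "pvalue"])
        n_missing = len(adf) - len(complete)
        if n_missing:
            logger.info("harmonize %s: dropped %d rows with missing data", ss.trait, n_missing)
        aligned.append(complete)
        rs = set(complete["rsid"])
        common = rs if common is None else (common & rs)
    if not common:
        raise EmptyPanelError("no overlapping variants across all traits after harmonization")

    order = [r for r in ref["rsid"] if r in common]
    idx = pd.Index(order)
    mats = [df.set_index("rsid").loc[idx] for df in aligned]
    K = len(exposures)
    first = mats[0]
    return HarmonizedPanel(
        rsids=np.asarray(order, dtype=object),
        chrom=first["chrom"].astype(str).to_numpy(),
        pos=first["pos"].astype(np.int64).to_numpy(),
        effect_allele=first["effect_allele"].to_numpy(),
        other_allele=first["other_allele"].to_numpy(),
        exposures=[e.trait for e in exposures],
        B=np.column_stack([m["beta"].to_numpy(float) for m in mats[:K]]),
        SE_B=np.column_stack([m["se"].to_numpy(float) for m in mats[:K]]),
        P_B=np.column_stack([m["pvalue"].to_numpy(float) for m in mats[:K]]),
        by=mats[K]["beta"].to_numpy(float),
        se_y=mats[K]["se"].to_numpy(float),
        outcome=outcome.trait,
        exposure_scales=[e.trait_scale for e in exposures],
    )


def orient_to_exposure(panel: HarmonizedPanel, exposure_index: int) -> HarmonizedPanel:
    """Flip rows so the chosen exposure column is elementwise non-negative.

    For every variant whose effect on the exposure of interest is negative,
    all exposure betas and the outcome beta are negated (equivalent to
    recoding the effect allele); SEs and p-values are untouched. Zero betas
    are left alone, so the operation is idempotent.
    """
    K = panel.n_exposures
    if not (0 <= exposure_index < K):
        raise ConfigError(f"exposure_index {exposure_index} out of range for K={K}")
    flip = panel.B[:, exposure_index] < 0
    sign = np.where(flip, -1.0, 1.0)
    ea = panel.effect_allele.copy()
    oa = panel.other_allele.copy()
    ea[flip], oa[flip] = panel.other_allele[flip], panel.effect_allele[flip]
    return HarmonizedPanel(
        rsids=panel.rsids, chrom=panel.chrom, pos=panel.pos,
        effect_allele=ea, other_allele=oa,
        exposures=list(panel.exposures),
        B=panel.B * sign[:, None], SE_B=panel.SE_B.copy(), P_B=panel.P_B.copy(),
        by=panel.by * sign, se_y=panel.se_y.copy(),
        outcome=panel.outcome, exposure_scales=list(panel.exposure_scales),
    )
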