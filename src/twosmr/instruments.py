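"""Instrument selection: genome-wide significance, LD clumping, locus windows.

Clumping follows the usual greedy scheme: repeatedly keep the most significant
remaining variant and discard every remaining variant on the same chromosome
within the distance window whose r-squared with it exceeds the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sumstats import TraitSumStats

logger = logging.getLogger("twosmr")

GW_ALPHA = 1e-8          #: genome-wide significance level for instrument selection
CLUMP_R2 = 0.01          #: maximum r-squared between kept instruments
CLUMP_WINDOW_BP = 10_000_000   #: clumping radius around the index variant
LOCUS_HALF_WIDTH_BP = 1_000_000  #: monogenic locus window half-width around the TSS


@dataclass
class LDMatrix:
    """Pairwise r-squared between M variants.

    ``r2`` must be symmetric with unit diagonal and entries in [0, 1].
    """

    rsids: list[str]
    r2: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = len(self.rsids)
        self.r2 = np.asarray(self.r2, dtype=float)
        if self.r2.shape != (m, m):
            raise ValidationError(f"LD matrix shape {self.r2.shape} != ({m}, {m})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValidationError("LD matrix is not symmetric")
        if m and not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValidationError("LD matrix diagonal must be 1")
        if self.r2.size and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def lookup(self, a: str, b: str) -> float | None:
        """r2 between two rsids, or None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_square_tsv(cls, path, sep: str = "\t") -> "LDMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(rsids=[str(r) for r in df.index], r2=df.to_numpy(float))

    @classmethod
    def from_long_tsv(cls, path, sep: str = "\t") -> "LDMatrix":
        """Triple format: rsid_a, rsid_b, r2; unlisted pairs are r2 = 0."""
        df = pd.read_csv(path, sep=sep)
        df.columns = ["rsid_a", "rsid_b", "r2"][: len(df.columns)]
        rsids = sorted(set(df["rsid_a"].astype(str)) | set(df["rsid_b"].astype(str)))
        idx = {r: i for i, r in enumerate(rsids)}
        m = len(rsids)
        r2 = np.eye(m)
        for row in df.itertuples(index=False):
            i, j = idx[str(row.rsid_a)], idx[str(row.rsid_b)]
            r2[i, j] = r2[j, i] = float(row.r2)
        np.fill_diagonal(r2, 1.0)
        return cls(rsids=rsids, r2=r2)

    def to_square_tsv(self, path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(path, sep=sep)


@dataclass(frozen=True)
class Locus:
    """A gene locus anchored at its transcription start site (1-based bp)."""

    gene: str
    chrom: str
    tss: int

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValidationError(f"tss must be >= 1 (got {self.tss})")


def read_locus_table(path, sep: str = "\t") -> pd.DataFrame:
    """Locus table: gene, chrom, tss (+ optional trait column for pipelines)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("gene", "chrom", "tss"):
        if col not in df.columns:
            raise ValidationError(f"locus table missing column {col!r}")
    df["chrom"] = df["chrom"].astype(str)
    df["tss"] = df["tss"].astype(np.int64)
    return df


def select_genome_wide(sumstats: TraitSumStats, alpha: float = GW_ALPHA) -> TraitSumStats:
    """Subset to variants with p strictly below ``alpha``, order preserved."""
    return sumstats.subset((sumstats.df["pvalue"] < alpha).to_numpy())


def clump(
    snps: TraitSumStats,
    ld: LDMatrix,
    r2_max: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> TraitSumStats:
    """Greedy LD clumping of a set of variants.

    The most significant remaining variant (ties: smaller position, then
    lexicographic rsid) is kept; every remaining variant on the same
    chromosome within ``window_bp`` of it with r2 > ``r2_max`` is discarded.
    Pairs absent from ``ld`` are treated as unlinked (r2 = 0) with a logged
    warning. Returns the kept variants in selection order.
    """
    df = snps.df
    if not len(df):
        return snps.take([])
    rsid = df["rsid"].to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    pval = df["pvalue"].to_numpy()
    order = np.lexsort((rsid, pos, pval))  # primary key last in lexsort
    alive = np.ones(len(df), dtype=bool)
    kept: list[int] = []
    n_unknown = 0
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        for j in order:
            if not alive[j]:
                continue
            if chrom[j] != chrom[i] or abs(int(pos[j]) - int(pos[i])) > window_bp:
                continue
            r2 = ld.lookup(rsid[i], rsid[j])
            if r2 is None:
                n_unknown += 1
                continue
            if r2 > r2_max:
                alive[j] = False
    if n_unknown:
        logger.warning("clump: %d pairs absent from LD matrix treated as r2=0", n_unknown)
    return snps.take(kept)


def locus_window(
    snps: TraitSumStats,
    locus: Locus,
    half_width_bp: int = LOCUS_HALF_WIDTH_BP,
) -> TraitSumStats:
    """Variants on the locus chromosome within ±``half_width_bp`` of the TSS."""
    df = snps.df
    mask = (df["chrom"].astype(str) == str(locus.chrom)) & (
        (df["pos"] - locus.tss).abs() <= half_width_bp
    )
    return snps.subset(mask.to_numpy())
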