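import numpy as np
import pandas as pd
import pytest

from twosmr.sumstats import CANON_COLS, HarmonizedPanel, TraitSumStats


def make_sumstats(rows, trait="trait", trait_scale="sd", strict=True):
    """Build TraitSumStats from a list of dicts with sensible defaults."""
    defaults = {
        "chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.01, "pvalue": 1e-10, "n": 1e5,
    }
    filled = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.setdefault("rsid", f"rs{i + 1}")
        d.update(r)
        filled.append(d)
    df = pd.DataFrame(filled)
    return TraitSumStats.from_frame(df[ [c for c in CANON_COLS if c in df.columns] ],
                                    trait=trait, trait_scale=trait_scale, strict=strict)


def random_panel(J=50, K=3, seed=0, theta=None):
    """Random harmonized panel with outcome generated from a known theta."""
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = rng.normal(0, 0.3, size=K)
    B = rng.normal(0, 0.05, size=(J, K))
    SE_B = np.full((J, K), 0.005)
    se_y = rng.uniform(0.002, 0.006, size=J)
    by = B @ np.asarray(theta) + se_y * rng.standard_normal(J)
    return HarmonizedPanel(
        rsids=np.array([f"rs{j + 1}" for j in range(J)], dtype=object),
        chrom=np.full(J, "1", dtype=object),
        pos=np.arange(J, dtype=np.int64) * 100_000 + 1,
        effect_allele=np.full(J, "A", dtype=object),
        other_allele=np.full(J, "G", dtype=object),
        exposures=[f"X{k + 1}" for k in range(K)],
        B=B, SE_B=SE_B,
        P_B=np.full((J, K), 1e-10),
        by=by, se_y=se_y, outcome="Y",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
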