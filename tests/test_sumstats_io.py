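"""Reading, validation, harmonization, and orientation of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from twosmr import (
    EmptyPanelError,
    ValidationError,
    harmonize,
    ivw_multivariable,
    orient_to_exposure,
    read_panel,
    read_sumstats,
    write_panel,
    write_sumstats,
)
from conftest import make_sumstats, random_panel

TSV = """rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn
rs1\t1\t100\ta\tg\t0.2\t0.10\t0.01\t1e-20\t10000
rs2\t1\t200\tC\tT\t0.4\t-0.05\t0.02\t0.01\t10000
rs3\t2\t300\tG\tA\t0.9\t0.00\t0.03\t1.0\t10000
"""


def test_read_normalizes_and_roundtrips(tmp_path):
    p = tmp_path / "ss.tsv"
    p.write_text(TSV)
    ss = read_sumstats(p, trait="lipid")
    assert len(ss) == 3
    assert list(ss.df["effect_allele"]) == ["A", "C", "G"]  # upper-cased
    out = tmp_path / "out.tsv"
    write_sumstats(ss, out)
    back = read_sumstats(out, trait="lipid")
    pd.testing.assert_frame_equal(ss.df, back.df)


def test_strict_validation_names_offending_row(tmp_path):
    bad = TSV.replace("rs2\t1\t200\tC\tT\t0.4\t-0.05\t0.02",
                      "rs2\t1\t200\tC\tT\t0.4\t-0.05\t0.0")
    p = tmp_path / "bad.tsv"
    p.write_text(bad)
    with pytest.raises(ValidationError, match="rs2"):
        read_sumstats(p, trait="lipid", strict=True)
    lenient = read_sumstats(p, trait="lipid", strict=False)
    assert list(lenient.rsids) == ["rs1", "rs3"]


@pytest.mark.parametrize("pvalue", [0.0, 1.5, -0.1])
def test_invalid_pvalues_rejected(pvalue):
    with pytest.raises(ValidationError):
        make_sumstats([{"pvalue": pvalue}])


def test_harmonize_sign_flip_under_allele_swap():
    exp = make_sumstats([{"rsid": "rs1", "effect_allele": "A", "other_allele": "G",
                          "beta": 0.10, "eaf": 0.2}], trait="X")
    out = make_sumstats([{"rsid": "rs1", "effect_allele": "G", "other_allele": "A",
                          "beta": -0.05, "eaf": 0.8}], trait="Y", trait_scale="log_or")
    panel = harmonize([exp], out)
    assert panel.n_snps == 1
    assert panel.by[0] == pytest.approx(0.05)
    assert panel.B[0, 0] == pytest.approx(0.10)


def test_harmonize_drops_palindromic_when_requested():
    exp = make_sumstats([
        {"rsid": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.2},
        {"rsid": "rs2", "effect_allele": "A", "other_allele": "G", "eaf": 0.2},
    ], trait="X")
    out = make_sumstats([
        {"rsid": "rs1", "effect_allele": "A", "other_allele": "T", "eaf": 0.2},
        {"rsid": "rs2", "effect_allele": "A", "other_allele": "G", "eaf": 0.2},
    ], trait="Y", trait_scale="log_or")
    panel = harmonize([exp], out, drop_palindromic=True)
    assert list(panel.rsids) == ["rs2"]
    # default mode keeps unambiguous palindromic variants via frequency alignment
    panel2 = harmonize([exp], out, drop_palindromic=False)
    assert list(panel2.rsids) == ["rs1", "rs2"]
    # but drops them when the frequency is ambiguous
    exp_amb = make_sumstats([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
                              "eaf": 0.5}], trait="X")
    out_amb = make_sumstats([{"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
                              "eaf": 0.5}], trait="Y", trait_scale="log_or")
    with pytest.raises(EmptyPanelError):
        harmonize([exp_amb], out_amb)


def test_harmonize_restricts_to_common_rsids():
    exp = make_sumstats([{"rsid": "rs1"}, {"rsid": "rs2", "pos": 2000}], trait="X")
    out = make_sumstats([{"rsid": "rs1"}], trait="Y", trait_scale="log_or")
    panel = harmonize([exp], out)
    assert list(panel.rsids) == ["rs1"]
    only = make_sumstats([{"rsid": "rs9"}], trait="Y", trait_scale="log_or")
    with pytest.raises(EmptyPanelError):
        harmonize([exp], only)


def test_harmonize_is_idempotent():
    panel = random_panel(J=20, K=2, seed=4)
    exposures, outcome = panel.to_sumstats()
    again = harmonize(exposures, outcome)
    np.testing.assert_allclose(again.B, panel.B)
    np.testing.assert_allclose(again.by, panel.by)
    np.testing.assert_allclose(again.se_y, panel.se_y)
    assert list(again.rsids) == list(panel.rsids)


def test_sign_flip_consistency_of_inputs():
    """Flipping alleles + negating beta in an input trait leaves the panel unchanged."""
    panel = random_panel(J=15, K=2, seed=9)
    exposures, outcome = panel.to_sumstats()
    flipped = outcome.df.copy()
    flipped["beta"] = -flipped["beta"]
    flipped["effect_allele"], flipped["other_allele"] = (
        outcome.df["other_allele"], outcome.df["effect_allele"],
    )
    from twosmr.sumstats import TraitSumStats
    outcome2 = TraitSumStats(outcome.trait, outcome.trait_scale, flipped)
    p1 = harmonize(exposures, outcome)
    p2 = harmonize(exposures, outcome2)
    np.testing.assert_allclose(p1.by, p2.by)
    np.testing.assert_allclose(p1.B, p2.B)


def test_orientation_negates_rows_and_is_idempotent():
    panel = random_panel(J=30, K=3, seed=2)
    oriented = orient_to_exposure(panel, 1)
    assert np.all(oriented.B[:, 1] >= 0)
    np.testing.assert_allclose(np.abs(oriented.B), np.abs(panel.B))
    np.testing.assert_allclose(oriented.SE_B, panel.SE_B)
    twice = orient_to_exposure(oriented, 1)
    np.testing.assert_allclose(twice.B, oriented.B)
    np.testing.assert_allclose(twice.by, oriented.by)
    # involution on the rows it flips
    back = orient_to_exposure(panel, 1)
    flip = panel.B[:, 1] < 0
    np.testing.assert_allclose(back.B[flip], -panel.B[flip])


@pytest.mark.parametrize("k", [0, 1, 2])
def test_ivw_is_orientation_invariant(k):
    """Zero-intercept WLS is unchanged by row sign flips (50-SNP random panel)."""
    panel = random_panel(J=50, K=3, seed=11)
    base = ivw_multivariable(panel)
    oriented = ivw_multivariable(orient_to_exposure(panel, k))
    for a, b in zip(base, oriented):
        assert a.theta == pytest.approx(b.theta, rel=1e-12)
        assert a.se_theta == pytest.approx(b.se_theta, rel=1e-12)


def test_panel_write_read_and_schema(tmp_path):
    panel = random_panel(J=8, K=6, seed=5)
    path = tmp_path / "panel.tsv"
    write_panel(panel, path)
    header = path.read_text().splitlines()[0].split("\t")
    assert len(header) == 5 + 3 * 6 + 2  # id/locus/allele block + 3 per exposure + outcome pair
    back = read_panel(path, outcome="Y")
    np.testing.assert_allclose(back.B, panel.B)
    np.testing.assert_allclose(back.by, panel.by)
    assert back.exposures == panel.exposures


def test_write_empty_panel_is_header_only(tmp_path):
    panel = random_panel(J=4, K=2, seed=6).take([])
    path = tmp_path / "empty.tsv"
    write_panel(panel, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1
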