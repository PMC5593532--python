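"""2^-ddCt quantification, group comparison and power analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cerna_forge.errors import DataError
from cerna_forge.validation import (
    CtRecord,
    ddct_fold_change,
    group_compare,
    qpcr_summarize,
    ttest_power,
)

import _oracles


def ct_table(case_dct, control_dct, ref_ct=20.0, gene="G", ref="Actb"):
    """Build a Ct table with the requested per-sample dCt values."""
    rows = []
    for i, d in enumerate(case_dct):
        rows.append((f"c{i}", "case", gene, ref_ct + d, False))
        rows.append((f"c{i}", "case", ref, ref_ct, True))
    for i, d in enumerate(control_dct):
        rows.append((f"k{i}", "control", gene, ref_ct + d, False))
        rows.append((f"k{i}", "control", ref, ref_ct, True))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene_id", "ct", "is_reference"]
    )


class TestDdct:
    def test_zero_ddct_means_fold_one(self):
        table = ct_table([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        res = ddct_fold_change(table, "G", ["Actb"])
        assert res.mean_fc == pytest.approx(1.0)
        assert res.mean_fc_control == pytest.approx(1.0)

    def test_minus_one_ddct_doubles(self):
        table = ct_table([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert ddct_fold_change(table, "G", ["Actb"]).mean_fc == pytest.approx(2.0)

    def test_hand_arithmetic_example(self):
        # case dCt {2,2,2}, control dCt {4,4,4} -> ddCt = -2, fold = 4
        table = ct_table([2.0, 2.0, 2.0], [4.0, 4.0, 4.0])
        res = ddct_fold_change(table, "G", ["Actb"])
        assert res.mean_fc == pytest.approx(4.0)
        assert res.direction == "up"

    def test_missing_reference_names_sample_and_gene(self):
        table = ct_table([2.0, 2.0], [3.0, 3.0])
        table = table[~((table["sample_id"] == "k1") & (table["gene_id"] == "Actb"))]
        with pytest.raises(DataError, match="k1"):
            ddct_fold_change(table, "G", ["Actb"])

    def test_control_mean_fold_is_one_by_construction(self):
        rng = np.random.default_rng(2)
        table = ct_table(list(rng.normal(2, 0.5, 6)), list(rng.normal(4, 0.5, 6)))
        res = ddct_fold_change(table, "G", ["Actb"])
        # geometric centering: control dCt mean is the baseline
        control_folds = 2.0 ** -(np.array(sorted(
            table[(table["group"] == "control") & (table["gene_id"] == "G")]["ct"]
        )) - 20.0 - np.mean(
            table[(table["group"] == "control") & (table["gene_id"] == "G")]["ct"] - 20.0
        ))
        assert res.mean_fc_control == pytest.approx(float(control_folds.mean()))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000), st.floats(-5, 5))
    def test_global_ct_shift_leaves_folds_unchanged(self, seed, shift):
        rng = np.random.default_rng(seed)
        base = ct_table(list(rng.normal(2, 1, 5)), list(rng.normal(3, 1, 5)))
        res = ddct_fold_change(base, "G", ["Actb"])
        shifted = base.copy()
        # per-sample global shift: add a constant to every gene of a sample
        for i, s in enumerate(shifted["sample_id"].unique()):
            shifted.loc[shifted["sample_id"] == s, "ct"] += shift + i * 0.37
        res_shift = ddct_fold_change(shifted, "G", ["Actb"])
        assert res_shift.mean_fc == pytest.approx(res.mean_fc, rel=1e-9)
        assert res_shift.p_value == pytest.approx(res.p_value, rel=1e-6, abs=1e-12)

    def test_summary_uses_biotype_references(self):
        rows = []
        for i in range(3):
            for grp, tag in (("case", "c"), ("control", "k")):
                s = f"{tag}{i}"
                rows += [
                    (s, grp, "mir_x", 22.0 + (1.0 if grp == "case" else 0.0), False),
                    (s, grp, "U6", 18.0, True),
                    (s, grp, "Actb", 17.0, True),
                ]
        table = pd.DataFrame(
            rows, columns=["sample_id", "group", "gene_id", "ct", "is_reference"]
        )
        out = qpcr_summarize(table, {"mir_x": "miRNA"})
        assert out.loc[0, "mean_fc_case"] == pytest.approx(0.5)
        assert out.loc[0, "direction"] == "down"


class TestGroupCompare:
    def test_identical_groups_give_p_one(self):
        assert group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self):
        p = group_compare([10.0, 11.0, 12.0], [0.0, 1.0, 2.0])
        assert p < 0.001
        assert p == pytest.approx(
            _oracles.pooled_t_p([10.0, 11.0, 12.0], [0.0, 1.0, 2.0]), abs=1e-8
        )

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(1)
        a, b = list(rng.normal(size=5)), list(rng.normal(size=6))
        assert group_compare(a, b) == pytest.approx(group_compare(b, a))

    def test_matches_integration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            a = rng.normal(size=int(rng.integers(2, 8)))
            b = rng.normal(size=int(rng.integers(2, 8)))
            assert group_compare(a, b) == pytest.approx(
                _oracles.pooled_t_p(list(a), list(b)), abs=1e-8
            )


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert ttest_power(0.0, 8, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_reported_design_rounds_to_081(self):
        power = ttest_power(1.523, 8, alpha=0.05, tails="two")
        assert round(power, 2) == 0.81

    def test_monotone_in_n_and_limits(self):
        assert ttest_power(1.0, 20) > ttest_power(1.0, 10)
        assert ttest_power(1.0, 2000) > 0.999

    def test_one_tailed_exceeds_two_tailed(self):
        assert ttest_power(1.0, 10, tails="one") > ttest_power(1.0, 10, tails="two")

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ttest_power(-1.0, 8)
        with pytest.raises(ValueError):
            ttest_power(1.0, 8, alpha=1.5)
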