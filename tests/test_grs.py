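"""Sign assignment, signed risk scores and quartile classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxescore.containers import CategorySelection, ValidationError
from gxescore.grs import (
    QuartileCutpoints,
    assign_signs,
    build_profiles,
    classify,
    classify_series,
    compute_grs,
    quartile_cutpoints,
)


def selection(category, entries):
    return CategorySelection(
        category=category,
        table=pd.DataFrame(entries, columns=["snp_id", "coef", "p"]),
    )


def signed_selection(category, snp_signs):
    table = pd.DataFrame(
        [
            {"snp_id": s, "coef": sign * 0.1, "p": 0.01, "sign": float(sign)}
            for s, sign in snp_signs.items()
        ]
    )
    if category == "EE":  # coef sign is reversed relative to the stored sign
        table["coef"] = -table["coef"]
    return CategorySelection(category=category, table=table)


class TestAssignSigns:
    @pytest.mark.parametrize(
        "category, coef, expected",
        [
            ("CE", 0.006, 1.0),    # positive diet interaction counts positively
            ("FE", -0.01, -1.0),   # negative interaction counts negatively
            ("TE", 0.00056, 1.0),
            ("EE", -0.14, 1.0),    # exercise reversal: fat-loss allele scores +1
            ("EE", 0.15, -1.0),
        ],
    )
    def test_sign_rule(self, category, coef, expected):
        sel = selection(category, [("rs1", coef, 0.01)])
        signed = assign_signs(sel)
        assert signed.table.loc[0, "sign"] == expected

    def test_zero_coefficient_is_error(self):
        with pytest.raises(ValidationError, match="undefined sign"):
            assign_signs(selection("CE", [("rs1", 0.0, 0.01)]))

    def test_empty_selection_passes_through(self):
        signed = assign_signs(CategorySelection(category="CE"))
        assert len(signed) == 0


class TestComputeGrs:
    def test_signed_sum_of_counts(self, genotype_builder):
        g = genotype_builder({"a": [2], "b": [1], "c": [0]})
        sel = signed_selection("CE", {"a": 1, "b": -1, "c": 1})
        assert compute_grs(g, sel).iloc[0] == 1.0

    def test_all_zero_counts_give_zero(self, genotype_builder):
        g = genotype_builder({"a": [0], "b": [0]})
        sel = signed_selection("CE", {"a": 1, "b": -1})
        assert compute_grs(g, sel).iloc[0] == 0.0

    def test_missing_genotype_contributes_expected_count(self, genotype_builder):
        g = genotype_builder({"a": [np.nan], "b": [0]}, mafs={"a": 0.25, "b": 0.25})
        sel = signed_selection("CE", {"a": 1, "b": 1})
        assert compute_grs(g, sel).iloc[0] == 0.5

    def test_unknown_snp_is_error(self, genotype_builder):
        g = genotype_builder({"a": [1]})
        sel = signed_selection("CE", {"zzz": 1})
        with pytest.raises(ValidationError, match="absent"):
            compute_grs(g, sel)

    def test_unsigned_selection_is_error(self, genotype_builder):
        g = genotype_builder({"a": [1]})
        with pytest.raises(ValidationError, match="signed"):
            compute_grs(g, selection("CE", [("a", 0.1, 0.01)]))

    def test_integer_scores_bounded_by_sign_group_sizes(self, genotype_builder):
        rng = np.random.default_rng(7)
        g = genotype_builder({f"s{i}": rng.integers(0, 3, 50).astype(float) for i in range(6)})
        sel = signed_selection("CE", {f"s{i}": (1 if i < 4 else -1) for i in range(6)})
        scores = compute_grs(g, sel)
        assert (scores == scores.round()).all()
        assert scores.max() <= 2 * 4 and scores.min() >= -2 * 2


class TestQuartiles:
    def test_linear_interpolation_octet(self):
        cuts = quartile_cutpoints(pd.Series(np.arange(1.0, 9.0)))
        assert (cuts.q25, cuts.q50, cuts.q75) == (2.75, 4.5, 6.25)

    def test_constant_scores_degenerate(self):
        cuts = quartile_cutpoints(pd.Series([3.0] * 10))
        assert (cuts.q25, cuts.q50, cuts.q75) == (3.0, 3.0, 3.0)

    def test_median_interior_for_bimodal(self):
        scores = pd.Series([0.0] * 500 + [100.0] * 500)
        cuts = quartile_cutpoints(scores)
        assert 0.0 <= cuts.q50 <= 100.0

    def test_too_few_individuals_is_error(self):
        with pytest.raises(ValidationError, match="at least 4"):
            quartile_cutpoints(pd.Series([1.0, 2.0, 3.0]))

    def test_nearest_rank_method_uses_order_statistic(self):
        cuts = quartile_cutpoints(pd.Series(np.arange(1.0, 9.0)), method="nearest-rank")
        assert cuts.q25 == 2.0 and cuts.q50 == 4.0 and cuts.q75 == 6.0


class TestClassify:
    CUTS = QuartileCutpoints(q25=2.0, q50=4.0, q75=6.0)

    @pytest.mark.parametrize(
        "score, expected",
        [
            (1.9, "VL"),
            (2.0, "L"),    # boundary rounds up into L
            (3.9, "L"),
            (4.0, "H"),
            (6.0, "VH"),   # boundary rounds up into VH
            (9.0, "VH"),
        ],
    )
    def test_boundaries(self, score, expected):
        assert classify(score, self.CUTS) == expected

    def test_degenerate_cutpoints_cascade_to_vh(self):
        cuts = QuartileCutpoints(q25=3.0, q50=3.0, q75=3.0)
        assert classify(3.0, cuts) == "VH"

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(-50, 50), min_size=8, max_size=60),
        st.integers(-20, 20),
    )
    def test_translation_invariance(self, values, shift):
        # scores are integer-valued in practice (signed allele counts)
        scores = pd.Series(values, name="CE_grs", dtype=float)
        base = classify_series(scores, quartile_cutpoints(scores))
        shifted = scores + shift
        moved = classify_series(shifted, quartile_cutpoints(shifted))
        assert (base.to_numpy() == moved.to_numpy()).all()

    def test_allele_flip_leaves_classes_unchanged(self, genotype_builder):
        rng = np.random.default_rng(11)
        counts = {f"s{i}": rng.integers(0, 3, 200).astype(float) for i in range(5)}
        g = genotype_builder(counts)
        sel = signed_selection("CE", {f"s{i}": (1 if i % 2 else -1) for i in range(5)})
        scores = compute_grs(g, sel)
        base = classify_series(scores, quartile_cutpoints(scores))

        flipped_counts = dict(counts)
        flipped_counts["s0"] = 2.0 - counts["s0"]
        g2 = genotype_builder(flipped_counts)
        signs = {f"s{i}": (1 if i % 2 else -1) for i in range(5)}
        signs["s0"] = -signs["s0"]
        scores2 = compute_grs(g2, signed_selection("CE", signs))
        flipped = classify_series(scores2, quartile_cutpoints(scores2))
        assert (base.to_numpy() == flipped.to_numpy()).all()

    def test_class_proportions_near_quarter_on_tie_free_scores(self):
        rng = np.random.default_rng(4)
        n = 2000
        scores = pd.Series(rng.normal(size=n), name="CE_grs")
        classes = classify_series(scores, quartile_cutpoints(scores))
        props = classes.value_counts(normalize=True)
        for cls in ("VL", "L", "H", "VH"):
            assert props[cls] == pytest.approx(0.25, abs=100 / n / 100 + 0.001)


class TestBuildProfiles:
    def test_stored_cutpoints_classify_new_individuals(self, genotype_builder):
        rng = np.random.default_rng(5)
        g = genotype_builder({f"s{i}": rng.integers(0, 3, 100).astype(float) for i in range(4)})
        sel = {"CE": signed_selection("CE", {f"s{i}": 1 for i in range(4)})}
        _, cuts = build_profiles(g, sel)
        g_new = genotype_builder({f"s{i}": [2.0, 0.0] for i in range(4)})
        profiles, _ = build_profiles(g_new, sel, cutpoints=cuts)
        assert profiles.loc[profiles.index[0], "CE_grs"] == 8.0
        assert profiles["CE_class"].iloc[0] == "VH"
        assert profiles["CE_class"].iloc[1] == "VL"
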