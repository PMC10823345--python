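"""Volumetric response classification and rater-agreement statistics."""

import itertools

import numpy as np
import pytest

from bmseg.metrics import label_components
from bmseg.response import (
    CATEGORY_CODES,
    ResponseConfig,
    TimepointPair,
    agreement_stats,
    classify_response,
    confusion_and_agreement,
    correspond_lesions,
    diameter_to_volume_ratio,
    icc_2_1,
    volume_to_diameter_ratio,
)


class TestDiameterVolumeRule:
    def test_twenty_percent_diameter_is_72_8_percent_volume(self):
        assert diameter_to_volume_ratio(0.20) == pytest.approx(0.728)

    def test_trivial_points(self):
        assert diameter_to_volume_ratio(0.0) == 0.0
        assert diameter_to_volume_ratio(1.0) == pytest.approx(7.0)

    def test_inverse_recovers_delta(self):
        for delta in (-0.5, -0.1, 0.0, 0.2, 1.0, 3.0):
            ratio = diameter_to_volume_ratio(delta)
            assert volume_to_diameter_ratio(ratio) == pytest.approx(delta, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            diameter_to_volume_ratio(-1.0)
        with pytest.raises(ValueError):
            volume_to_diameter_ratio(-1.5)


def component_set(boxes, shape=(24, 24, 24)):
    mask = np.zeros(shape, np.uint8)
    for box in boxes:
        mask[box] = 1
    return label_components(mask, (1, 1, 1))


class TestCorrespondence:
    def test_identical_sets_fully_linked(self):
        cs = component_set([(slice(2, 5),) * 3, (slice(10, 14),) * 3])
        cmap = correspond_lesions(
            TimepointPair(baseline=cs, followup=cs), ResponseConfig()
        )
        assert len(cmap.links) == 2
        assert cmap.resolved == [] and cmap.new_lesions == []

    def test_new_distant_blob_detected(self):
        base = component_set([(slice(2, 5),) * 3])
        fup = component_set([(slice(2, 5),) * 3, (slice(18, 21),) * 3])
        cmap = correspond_lesions(
            TimepointPair(baseline=base, followup=fup), ResponseConfig()
        )
        assert len(cmap.new_lesions) == 1

    def test_vanished_lesion_is_resolved(self):
        base = component_set([(slice(2, 5),) * 3, (slice(18, 21),) * 3])
        fup = component_set([(slice(2, 5),) * 3])
        cmap = correspond_lesions(
            TimepointPair(baseline=base, followup=fup), ResponseConfig()
        )
        assert len(cmap.resolved) == 1

    def test_single_voxel_blob_is_sub_threshold(self):
        base = component_set([(slice(2, 5),) * 3])
        fup_mask = np.zeros((24, 24, 24), np.uint8)
        fup_mask[2:5, 2:5, 2:5] = 1
        fup_mask[20, 20, 20] = 1
        fup = label_components(fup_mask, (1, 1, 1))
        cmap = correspond_lesions(
            TimepointPair(baseline=base, followup=fup),
            ResponseConfig(new_lesion_min_voxels=2),
        )
        assert cmap.new_lesions == [] and len(cmap.sub_threshold) == 1

    def test_nearby_nonoverlapping_lesion_links_by_centroid(self):
        base = component_set([(slice(2, 5),) * 3])
        fup = component_set([(slice(6, 9),) * 3])  # 4 mm away, no overlap
        cmap = correspond_lesions(
            TimepointPair(baseline=base, followup=fup),
            ResponseConfig(correspondence_max_centroid_distance_mm=10.0),
        )
        assert len(cmap.links) == 1 and cmap.new_lesions == []


def classify_volumes(v_base, v_fup, new_lesion, threshold=0.728):
    """Run classify_response on synthetic single-blob grids scaled to the
    requested volumes (1 voxel = 1 mm^3)."""
    shape = (40, 40, 40)
    base_mask = np.zeros(shape, np.uint8)
    base_mask.ravel()[: int(v_base)] = 1
    fup_mask = np.zeros(shape, np.uint8)
    fup_mask.ravel()[: int(v_fup)] = 1
    if new_lesion:
        fup_mask[35:38, 35:38, 35:38] = 1
    pair = TimepointPair(
        baseline=label_components(base_mask, (1, 1, 1)),
        followup=label_components(fup_mask, (1, 1, 1)),
    )
    cfg = ResponseConfig(pd_volume_increase_threshold=threshold)
    cmap = correspond_lesions(pair, cfg)
    return classify_response(pair, cmap, cfg)


class TestClassifyResponse:
    def test_boundary_volume_increase_is_pd(self):
        # 1000 -> 1728 mm^3 == +72.8%: boundary inclusive
        res = classify_volumes(1000, 1728, new_lesion=False)
        assert res.category == "PD"
        assert res.reasons == ["volume_increase_ge_threshold"]

    def test_total_disappearance_is_cr(self):
        res = classify_volumes(1000, 0, new_lesion=False)
        assert res.category == "CR" and res.reasons == ["total_disappearance"]

    def test_new_lesion_forces_pd_without_volume_rule(self):
        res = classify_volumes(1000, 500, new_lesion=True)
        assert res.category == "PD" and "new_lesion" in res.reasons

    def test_zero_baseline_is_an_error(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_volumes(0, 100, new_lesion=False)

    def test_truth_table_against_independent_enumeration(self):
        # independent statement of the rule, evaluated on a grid that
        # brackets the 0.728 boundary
        def reference(rel_change, new_lesion, fup_zero):
            if new_lesion or rel_change >= 0.728:
                return "PD"
            if fup_zero:
                return "CR"
            return "PR_SD"

        v_base = 1000
        for rel, new in itertools.product(
            [-1.0, -0.5, 0.0, 0.727, 0.728, 0.729, 2.0], [False, True]
        ):
            v_fup = round(v_base * (1 + rel))
            res = classify_volumes(v_base, v_fup, new_lesion=new)
            fup_zero = v_fup == 0 and not new
            assert res.category == reference(rel, new, fup_zero), (rel, new)


class TestAgreement:
    def test_identical_lists(self):
        stats = confusion_and_agreement(["CR", "PD", "PR_SD"], ["CR", "PD", "PR_SD"])
        assert stats.percent_agreement == 100.0
        assert np.trace(stats.confusion) == 3
        assert stats.confusion.sum() == 3

    def test_single_total_disagreement(self):
        stats = confusion_and_agreement(["CR"], ["PD"])
        assert stats.percent_agreement == 0.0

    def test_58_pair_cohort_with_seven_discordances(self):
        # 4 over-called (PR_SD -> PD), 1 under-called PD -> PR_SD,
        # 2 under-called PR_SD -> CR, remaining 51 concordant
        rater = ["PR_SD"] * 4 + ["PD"] + ["PR_SD"] * 2
        algo = ["PD"] * 4 + ["PR_SD"] + ["CR"] * 2
        rater += ["CR"] * 3 + ["PR_SD"] * 20 + ["PD"] * 28
        algo += ["CR"] * 3 + ["PR_SD"] * 20 + ["PD"] * 28
        stats = confusion_and_agreement(rater, algo)
        assert stats.n == 58
        assert round(stats.percent_agreement, 1) == 87.9

    def test_marginals_match_category_counts(self):
        a = ["CR", "PD", "PD", "PR_SD", "PR_SD", "PR_SD"]
        b = ["PD", "PD", "CR", "PR_SD", "CR", "PD"]
        stats = confusion_and_agreement(a, b)
        assert stats.confusion.sum(axis=1).tolist() == [1, 3, 2]
        assert stats.confusion.sum(axis=0).tolist() == [2, 1, 3]

    def test_length_mismatch_and_unknown_category(self):
        with pytest.raises(ValueError):
            confusion_and_agreement(["CR"], ["CR", "PD"])
        with pytest.raises(ValueError):
            confusion_and_agreement(["CR"], ["XX"])


def anova_icc_oracle(x):
    """Explicit sums-of-squares two-way ANOVA ICC(2,1), written independently
    of the implementation (plain loops)."""
    n, k = x.shape
    grand = x.mean()
    msr = sum((row.mean() - grand) ** 2 for row in x) * k / (n - 1)
    msc = sum((x[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_identical_raters_give_one(self):
        icc, ci = icc_2_1(np.array([[1, 1], [2, 2], [5, 5], [9, 9]], float))
        assert icc == 1.0 and ci == (1.0, 1.0)

    def test_hand_anova_case(self):
        # A=(1,2,3,4), B=(2,3,4,5): MSR=10/3, MSC=2, MSE=0 -> 10/13
        icc, _ = icc_2_1(np.array([[1, 2], [2, 3], [3, 4], [4, 5]], float))
        assert round(icc, 3) == 0.769

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 3))
        icc1, _ = icc_2_1(x)
        icc2, _ = icc_2_1(2.5 * x - 7.0)
        assert icc1 == pytest.approx(icc2, abs=1e-12)

    def test_constant_matrix_reports_missing(self):
        icc, ci = icc_2_1(np.full((4, 2), 3.0))
        assert icc is None and ci is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(3, 10)), int(rng.integers(2, 5))
        x = rng.normal(size=(n, k)) + 2 * rng.normal(size=(n, 1))
        icc, _ = icc_2_1(x)
        assert icc == pytest.approx(anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_point_and_interval(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(11)
        n, k = 12, 3
        x = rng.normal(size=(n, k)) + 2 * rng.normal(size=(n, 1))
        icc, ci = icc_2_1(x)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": x.ravel(),
        })
        res = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        row = res.loc[res["Type"] == "ICC(A,1)"].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-12)
        assert ci[0] == pytest.approx(row["CI95"][0], abs=0.01)
        assert ci[1] == pytest.approx(row["CI95"][1], abs=0.01)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_2_1(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_agreement_stats_uses_ordinal_coding(self):
        a = ["CR", "PR_SD", "PD", "PD"]
        b = ["CR", "PR_SD", "PD", "PR_SD"]
        stats = agreement_stats(a, b)
        coded = np.array(
            [[CATEGORY_CODES[x] for x in a], [CATEGORY_CODES[y] for y in b]]
        ).T
        expected, _ = icc_2_1(coded)
        assert stats.icc == pytest.approx(expected)
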