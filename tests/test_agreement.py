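"""Agreement statistics against brute-force set oracles and rank tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camagree.agreement import (
    agreement_across_cams,
    agreement_across_models,
    compare_groups,
    correlate_with_liquid_loss,
    damage_fraction,
    iou,
    mean_iou,
)
from camagree.exceptions import ContractError, DomainError


def _set_iou(a, b):
    """Brute-force pixel-set oracle for IoU."""
    sa = {t for t in zip(*np.nonzero(a))}
    sb = {t for t in zip(*np.nonzero(b))}
    union = sa | sb
    return 1.0 if not union else len(sa & sb) / len(union)


class TestIoU:
    def test_identical_masks(self):
        m = np.eye(4, dtype=np.uint8)
        assert iou(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert iou(a, b) == 0.0

    def test_hand_enumerated_overlap(self):
        a = np.zeros((2, 2), dtype=np.uint8)
        b = np.zeros((2, 2), dtype=np.uint8)
        a[0, 0] = a[0, 1] = 1
        b[0, 1] = b[1, 1] = 1
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_policy(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        assert iou(z, z) == 1.0
        assert np.isnan(iou(z, z, both_empty=np.nan))

    def test_shape_mismatch(self):
        with pytest.raises(ContractError):
            iou(np.zeros((2, 2)), np.zeros((3, 3)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_set_oracle_and_is_symmetric(self, seed):
        r = np.random.default_rng(seed)
        a = (r.uniform(size=(8, 8)) < 0.4).astype(np.uint8)
        b = (r.uniform(size=(8, 8)) < 0.4).astype(np.uint8)
        v = iou(a, b)
        assert v == pytest.approx(_set_iou(a, b))
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0


class TestMeanIoU:
    def test_all_identical_pairs(self, rng):
        masks = [(rng.uniform(size=(6, 6)) < 0.5).astype(np.uint8) for _ in range(5)]
        assert mean_iou(masks, masks) == 1.0

    def test_mean_of_two_known_ious(self):
        m = np.ones((2, 2), dtype=np.uint8)
        z = np.zeros((2, 2), dtype=np.uint8)
        o = np.ones((2, 2), dtype=np.uint8)
        o[0, 0] = 0
        # pair 1: identical -> 1.0; pair 2: disjoint single cells -> 0.0
        a1 = np.zeros((2, 2), dtype=np.uint8); a1[0, 0] = 1
        a2 = np.zeros((2, 2), dtype=np.uint8); a2[1, 1] = 1
        assert mean_iou([m, a1], [m, a2]) == pytest.approx(0.5)

    def test_matches_oracle_on_random_stack(self, rng):
        a = [(rng.uniform(size=(8, 8)) < 0.4).astype(np.uint8) for _ in range(20)]
        b = [(rng.uniform(size=(8, 8)) < 0.4).astype(np.uint8) for _ in range(20)]
        expected = np.mean([_set_iou(x, y) for x, y in zip(a, b)])
        assert mean_iou(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            mean_iou([np.zeros((2, 2))], [])


class TestPhiStatistics:
    def test_identical_masks_give_phi_one(self, rng):
        m = (rng.uniform(size=(6, 6)) < 0.5).astype(np.uint8)
        rec = agreement_across_cams({f"m{i}": m for i in range(5)}, model_id="a")
        assert rec.value == 1.0
        rec = agreement_across_models({f"net{i}": m for i in range(4)}, method_id="c")
        assert rec.value == 1.0

    def test_six_masks_average_fifteen_pairs(self, rng):
        masks = {f"m{i}": (rng.uniform(size=(6, 6)) < 0.5).astype(np.uint8)
                 for i in range(6)}
        rec = agreement_across_cams(masks, model_id="x")
        assert rec.n_pairs == 15
        from itertools import combinations

        expected = np.mean([_set_iou(masks[i], masks[j])
                            for i, j in combinations(sorted(masks), 2)])
        assert rec.value == pytest.approx(expected)

    def test_hand_enumerated_three_method_case(self):
        # pairwise IoUs {1, 0, 0} -> phi = 1/3
        a = np.zeros((2, 2), dtype=np.uint8); a[0, 0] = 1
        c = np.zeros((2, 2), dtype=np.uint8); c[1, 1] = 1
        rec = agreement_across_cams({"m1": a, "m2": a.copy(), "m3": c})
        assert rec.value == pytest.approx(1 / 3)
        assert rec.n_pairs == 3

    def test_order_invariance(self, rng):
        masks = {f"m{i}": (rng.uniform(size=(6, 6)) < 0.5).astype(np.uint8)
                 for i in range(4)}
        shuffled = dict(reversed(list(masks.items())))
        assert (agreement_across_cams(masks).value
                == agreement_across_cams(shuffled).value)

    def test_exclude_policy_drops_empty_pairs(self):
        z = np.zeros((2, 2), dtype=np.uint8)
        a = np.ones((2, 2), dtype=np.uint8)
        rec = agreement_across_cams({"m1": z, "m2": z, "m3": a},
                                    both_empty="exclude")
        # kept pairs: (z,a)=0 twice; (z,z) dropped
        assert rec.value == 0.0
        rec_one = agreement_across_cams({"m1": z, "m2": z, "m3": a})
        assert rec_one.value == pytest.approx(1 / 3)

    def test_fewer_than_two_masks_rejected(self):
        with pytest.raises(ContractError):
            agreement_across_cams({"only": np.zeros((2, 2))})


class TestDamageFraction:
    def test_full_and_empty(self):
        fg = np.ones((4, 4), dtype=np.uint8)
        assert damage_fraction(fg, fg) == 1.0
        assert damage_fraction(np.zeros_like(fg), fg) == 0.0

    def test_checkerboard_is_half(self):
        fg = np.ones((4, 4), dtype=np.uint8)
        cb = np.indices((4, 4)).sum(axis=0) % 2
        assert damage_fraction(cb, fg) == 0.5

    def test_empty_foreground_rejected(self):
        with pytest.raises(DomainError):
            damage_fraction(np.ones((2, 2)), np.zeros((2, 2)))


class TestLiquidLossCorrelation:
    def test_perfect_monotone_sequences(self):
        up = correlate_with_liquid_loss([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4])
        assert up.coefficient == pytest.approx(1.0)
        down = correlate_with_liquid_loss([0.4, 0.3, 0.2, 0.1], [1, 2, 3, 4])
        assert down.coefficient == pytest.approx(-1.0)

    def test_constant_input_flagged_undefined(self):
        res = correlate_with_liquid_loss([0.5, 0.5, 0.5], [1, 2, 3])
        assert res.undefined and np.isnan(res.coefficient)

    def test_generator_coupling_detected_across_seeds(self):
        """Monte-Carlo: with slope > 0 the rank correlation between realised
        damage and drawn liquid loss is significantly positive."""
        from camagree import GeneratorConfig, generate_dataset

        hits = 0
        for seed in range(10):
            cfg = GeneratorConfig(image_size=32, n_samples_per_group=10,
                                  slices_per_sample=2, seed=seed)
            samples = generate_dataset(cfg)
            res = correlate_with_liquid_loss(
                [s.damage_fraction for s in samples],
                [s.liquid_loss_pct for s in samples])
            hits += res.coefficient > 0 and res.p_value < 0.05
        assert hits >= 9

    def test_too_few_observations(self):
        with pytest.raises(ContractError):
            correlate_with_liquid_loss([1, 2], [1, 2])


class TestCompareGroups:
    def test_exchangeable_groups_give_high_p(self):
        h, p = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert h == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_separated_groups_give_small_p(self):
        h, p = compare_groups({"a": [1, 2, 3, 4], "b": [101, 102, 103, 104]})
        assert p < 0.05

    def test_label_permutation_leaves_h_unchanged(self, rng):
        groups = {k: list(rng.normal(size=6)) for k in "abc"}
        h1, _ = compare_groups(groups)
        h2, _ = compare_groups({"c": groups["c"], "a": groups["a"], "b": groups["b"]})
        assert h1 == pytest.approx(h2)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ContractError):
            compare_groups({"a": [1, 2, 3]})
        with pytest.raises(ContractError):
            compare_groups({"a": [1, 2], "b": [3]})

    def test_type_one_error_is_calibrated_under_null(self):
        """Empirical size of the 5% test under an exchangeable null."""
        r = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = r.normal(size=(3, 10))
            _, p = compare_groups({"a": x[0], "b": x[1], "c": x[2]})
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07
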