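import numpy as np
import pytest
from sklearn.base import clone

from celldet import (
    Box,
    Detection,
    NonMaxSuppressor,
    brute_force_suppression,
    mcnms,
    scnms,
    threshold_detections,
)
from celldet.geometry import boxes_to_array, pairwise_jaccard

from conftest import random_detections


def det(box, cls, p, k=3):
    probs = [(1 - p) / (k - 1)] * k
    probs[cls] = p
    return Detection(box=box, probs=tuple(probs))


A = Box(0, 0, 10, 10)
B = Box(1, 1, 11, 11)  # Jaccard(A, B) = 81/119 ~ 0.68


class TestDetection:
    def test_argmax_class_and_score(self):
        d = Detection(Box(0, 0, 5, 5), (0.1, 0.7, 0.2))
        assert d.argmax_class == 1 and d.score == 0.7

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            Detection(Box(0, 0, 5, 5), (0.5, 1.2))
        with pytest.raises(ValueError):
            Detection(Box(0, 0, 5, 5), ())


class TestThreshold:
    def test_boundary_inclusive(self):
        dets = [det(A, 0, p) for p in (0.9, 0.5, 0.49)]
        assert threshold_detections(dets, 0.5) == dets[:2]

    def test_empty_and_vacuous(self):
        assert threshold_detections([], 0.5) == []
        dets = [det(A, 0, 0.4)]
        assert threshold_detections(dets, 0.0) == dets

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            threshold_detections([], 1.5)


class TestSingleVsMultiClass:
    def test_scnms_keeps_cross_class_overlap(self):
        dets = [det(A, 0, 0.9), det(B, 1, 0.8)]
        result = scnms(dets, 0.3)
        assert len(result.kept) == 2  # different classes never suppress each other

    def test_scnms_suppresses_within_class(self):
        dets = [det(A, 0, 0.9), det(B, 0, 0.8)]
        result = scnms(dets, 0.3)
        assert result.kept == (dets[0],)
        assert result.suppressed == ((dets[1], 0),)

    def test_mcnms_resolves_cross_class_contradiction(self):
        dets = [det(A, 0, 0.9), det(B, 1, 0.8)]
        result = mcnms(dets, 0.3)
        assert result.kept == (dets[0],)

    def test_disjoint_boxes_all_kept(self):
        dets = [det(Box(0, 0, 10, 10), 0, 0.9), det(Box(50, 50, 60, 60), 1, 0.8)]
        assert len(mcnms(dets, 0.3).kept) == 2

    def test_single_detection_kept(self):
        dets = [det(A, 0, 0.9)]
        assert scnms(dets, 0.3).kept == (dets[0],)

    def test_equal_scores_tie_break_to_smaller_index(self):
        dets = [det(A, 0, 0.8), det(B, 1, 0.8)]
        result = mcnms(dets, 0.3)
        assert result.kept_indices == (0,)

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            mcnms([], -0.1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode,impl", [("single_class", scnms), ("multi_class", mcnms)])
    def test_greedy_matches_brute_force(self, mode, impl, rng):
        for _ in range(200):
            dets = random_detections(rng, int(rng.integers(0, 11)))
            eta = float(rng.uniform(0.1, 0.9))
            got = impl(dets, eta)
            want = brute_force_suppression(dets, eta, mode)
            assert got.kept_indices == want.kept_indices
            assert got.kept == want.kept

    def test_oracle_refuses_large_instances(self, rng):
        with pytest.raises(ValueError):
            brute_force_suppression(random_detections(rng, 13), 0.3)


class TestSuppressionLaws:
    def test_mcnms_extras_over_scnms_only_arise_from_suppression_chains(self, rng):
        """A box kept by joint NMS but dropped by per-class NMS can exist only
        when its same-class suppressor was itself removed by a higher-scoring
        cross-class box (a suppression chain); otherwise the multi-class kept
        set is contained in the single-class one."""
        for _ in range(200):
            dets = random_detections(rng, 15)
            multi = mcnms(dets, 0.3)
            single = scnms(dets, 0.3)
            extras = set(multi.kept_indices) - set(single.kept_indices)
            suppressed_by = {
                dets.index(d): s for d, s in multi.suppressed
            }
            for i in extras:
                # find the single-class suppressor of i and verify the chain
                sc_sup_idx = next(
                    s2 for d2, s2 in single.suppressed if d2 is dets[i]
                )
                assert dets[sc_sup_idx].argmax_class == dets[i].argmax_class
                # that suppressor fell to a cross-class box in the joint pass
                assert sc_sup_idx in suppressed_by
                killer = suppressed_by[sc_sup_idx]
                assert dets[killer].argmax_class != dets[sc_sup_idx].argmax_class

    def test_chain_counterexample_where_joint_pass_keeps_more(self):
        """Explicit three-box chain: a top-scoring class-1 box removes the
        class-0 runner-up in the joint pass, reviving the class-0 box that the
        per-class pass suppresses.  Documents why subset inclusion between the
        two kept sets is not a law of greedy suppression."""
        z = det(Box(0, 0, 10, 10), 1, 0.95)   # top score, class 1
        y = det(Box(2, 0, 12, 10), 0, 0.90)   # overlaps z at 2/3 >= 0.3
        x = det(Box(7, 0, 17, 10), 0, 0.70)   # overlaps y at 1/3 >= 0.3, z at 0.176 < 0.3
        dets = [z, y, x]
        single = scnms(dets, 0.3)
        multi = mcnms(dets, 0.3)
        assert set(single.kept_indices) == {0, 1}   # per class: z and y survive
        assert set(multi.kept_indices) == {0, 2}    # jointly: y falls, x revives
        assert not set(multi.kept_indices) <= set(single.kept_indices)

    def test_no_contradictory_overlap_after_mcnms(self, rng):
        for _ in range(50):
            dets = random_detections(rng, 20)
            kept = mcnms(dets, 0.3).kept
            if len(kept) > 1:
                arr = boxes_to_array([d.box for d in kept])
                jac = pairwise_jaccard(arr, arr)
                np.fill_diagonal(jac, 0)
                assert jac.max() < 0.3

    @pytest.mark.parametrize("impl", [scnms, mcnms])
    def test_idempotence(self, impl, rng):
        for _ in range(30):
            dets = random_detections(rng, 15)
            once = impl(dets, 0.3)
            twice = impl(list(once.kept), 0.3)
            assert twice.kept == once.kept
            assert not twice.suppressed

    def test_kept_and_suppressed_partition_input(self, rng):
        dets = random_detections(rng, 20)
        result = mcnms(dets, 0.3)
        assert result.n_input == len(dets)
        ids = {id(d) for d in result.kept} | {id(d) for d, _ in result.suppressed}
        assert ids == {id(d) for d in dets}


class TestNonMaxSuppressor:
    def test_sklearn_protocol_and_defaults(self):
        nms = NonMaxSuppressor()
        assert clone(nms).get_params() == {"eta": 0.3, "varrho": 0.5, "mode": "multi_class"}

    def test_transform_thresholds_then_suppresses(self, rng):
        dets = random_detections(rng, 20)
        got = NonMaxSuppressor(eta=0.3, varrho=0.5).fit_transform(dets)
        want = mcnms(threshold_detections(dets, 0.5), 0.3)
        assert got.kept == want.kept

    def test_single_class_mode(self, rng):
        dets = random_detections(rng, 20)
        got = NonMaxSuppressor(mode="single_class", varrho=0.0).fit_transform(dets)
        assert got.kept == scnms(dets, 0.3).kept

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            NonMaxSuppressor(eta=1.5).fit()
        with pytest.raises(ValueError):
            NonMaxSuppressor(mode="nope").fit()
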