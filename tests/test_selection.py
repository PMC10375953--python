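import numpy as np
import pytest

from stseg import network as N
from stseg import selection as S
from stseg.records import IGNORE_LABEL, DatasetState, SegmentationRecord
from stseg.tape import Node


def brute_mean_iou(a, b, ignore=IGNORE_LABEL):
    """Independent set-based pixel-count implementation of the class-mean IoU."""
    valid = (a != ignore) & (b != ignore)
    classes = sorted(set(a[valid].ravel().tolist()) | set(b[valid].ravel().tolist()))
    vals = []
    for c in classes:
        pix_a = {t for t in zip(*np.nonzero((a == c) & valid))}
        pix_b = {t for t in zip(*np.nonzero((b == c) & valid))}
        vals.append(len(pix_a & pix_b) / len(pix_a | pix_b))
    return sum(vals) / len(vals)


class MaskModel:
    """A stub checkpoint whose prediction is a fixed mask (for oracle tests)."""

    def __init__(self, mask, n_classes):
        self.mask = np.asarray(mask)
        self.config = N.NetworkConfig(n_classes=n_classes)

    def forward_logits(self, tp, x, dropout_on=False, rng=None):
        t = self.config.n_classes
        onehot = np.zeros((x.value.shape[0], t) + self.mask.shape, np.float32)
        for c in range(t):
            onehot[:, c][:, self.mask == c] = 10.0
        return Node(onehot)


def mask_ensemble(masks, n_classes):
    ens = S.CheckpointEnsemble(config=N.NetworkConfig(n_classes=n_classes),
                               checkpoints=[{} for _ in masks])
    return ens, [MaskModel(m, n_classes) for m in masks]


class TestMeanIou:
    def test_identical_masks(self):
        m = np.array([[0, 1], [2, 1]])
        assert S.mean_iou(m, m) == 1.0

    def test_disjoint_masks(self):
        assert S.mean_iou(np.zeros((3, 3), int), np.ones((3, 3), int)) == 0.0

    def test_hand_computed_two_class_case(self):
        a = np.array([[0, 0], [1, 1]])
        b = np.array([[0, 1], [1, 1]])
        # IoU(class0)=1/2, IoU(class1)=2/3 -> mean 7/12
        assert S.mean_iou(a, b) == pytest.approx(7 / 12)

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = rng.integers(0, 4, (9, 9))
            b = rng.integers(0, 4, (9, 9))
            a[rng.random((9, 9)) < 0.2] = IGNORE_LABEL
            b[a == IGNORE_LABEL] = IGNORE_LABEL
            assert S.mean_iou(a, b) == pytest.approx(brute_mean_iou(a, b))

    def test_all_ignore_rejected(self):
        m = np.full((2, 2), IGNORE_LABEL)
        with pytest.raises(ValueError):
            S.mean_iou(m, m)

    def test_invariant_to_consistent_relabeling(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, (8, 8))
        b = rng.integers(0, 3, (8, 8))
        perm = {0: 2, 1: 0, 2: 1}
        ap = np.vectorize(perm.get)(a)
        bp = np.vectorize(perm.get)(b)
        assert S.mean_iou(ap, bp) == pytest.approx(S.mean_iou(a, b))


class TestStabilityScore:
    def _record(self, shape=(8, 8)):
        return SegmentationRecord(image_id="u0",
                                  image=np.full(shape, 0.5, np.float32))

    def test_identical_predictions_reach_upper_bound(self):
        m = np.random.default_rng(0).integers(0, 3, (8, 8))
        ens, models = mask_ensemble([m] * 4, 3)
        out = S.stability_score(self._record(), ens, models=models)
        assert out.s_i == pytest.approx(3.0)
        assert np.array_equal(out.pseudo_mask, m)

    def test_disjoint_predictions_score_zero(self):
        final = np.zeros((4, 4), int)
        ens, models = mask_ensemble([np.ones((4, 4), int)] * 3 + [final], 2)
        out = S.stability_score(self._record((4, 4)), ens, models=models)
        assert out.s_i == 0.0

    def test_three_checkpoint_toy_matches_pairwise_mean_iou(self):
        rng = np.random.default_rng(3)
        masks = [rng.integers(0, 3, (6, 6)) for _ in range(3)]
        ens, models = mask_ensemble(masks, 3)
        out = S.stability_score(self._record((6, 6)), ens, models=models)
        expected = S.mean_iou(masks[0], masks[2]) + S.mean_iou(masks[1], masks[2])
        assert out.s_i == pytest.approx(expected)

    def test_bounds_on_random_ensembles(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            masks = [rng.integers(0, 4, (8, 8)) for _ in range(4)]
            ens, models = mask_ensemble(masks, 4)
            out = S.stability_score(self._record(), ens, models=models)
            assert 0.0 <= out.s_i <= 3.0

    def test_ensemble_requires_two_checkpoints(self):
        with pytest.raises(ValueError):
            S.CheckpointEnsemble(config=N.NetworkConfig(n_classes=2),
                                 checkpoints=[{}])


class TestRankAndSelect:
    def _scores(self, values, ids=None):
        ids = ids or [f"im{i}" for i in range(len(values))]
        return [S.StabilityScore(image_id=i, s_i=v, pseudo_mask=np.zeros((2, 2)))
                for i, v in zip(ids, values)]

    def test_top_quarter_of_eight(self):
        scores = self._scores([0.1, 2.9, 0.5, 1.7, 2.2, 0.3, 0.9, 1.1])
        assert S.rank_and_select(scores, 0.25) == ["im1", "im4"]

    def test_fraction_one_returns_all(self):
        scores = self._scores([1.0, 2.0, 3.0])
        assert set(S.rank_and_select(scores, 1.0)) == {"im0", "im1", "im2"}

    def test_ties_broken_by_ascending_image_id(self):
        scores = self._scores([1.0, 1.0, 1.0, 1.0],
                              ids=["d", "b", "c", "a"])
        assert S.rank_and_select(scores, 0.5) == ["a", "b"]

    def test_deterministic_under_input_permutation(self):
        rng = np.random.default_rng(5)
        scores = self._scores(list(rng.random(12)))
        base = S.rank_and_select(scores, 0.25)
        for _ in range(5):
            perm = [scores[i] for i in rng.permutation(len(scores))]
            assert S.rank_and_select(perm, 0.25) == base

    def test_minimum_one_selected_and_empty_rejected(self):
        assert len(S.rank_and_select(self._scores([0.5, 0.1]), 0.1)) == 1
        with pytest.raises(ValueError):
            S.rank_and_select([], 0.5)


class TestUpdateDatasets:
    def _state(self, n_lab=3, n_unl=5):
        img = np.zeros((4, 4), np.float32)
        lab = np.zeros((4, 4), np.uint8)
        return DatasetState(
            labeled=[SegmentationRecord(f"l{i}", img, lab) for i in range(n_lab)],
            unlabeled=[SegmentationRecord(f"u{i}", img) for i in range(n_unl)])

    def test_empty_selection_is_noop(self):
        state = self._state()
        out = S.update_datasets(state, [], {})
        assert out.ids("labeled") == state.ids("labeled")
        assert out.ids("unlabeled") == state.ids("unlabeled")

    def test_counts_after_admission(self):
        state = self._state(10, 40)
        masks = {f"u{i}": np.zeros((4, 4), np.uint8) for i in range(10)}
        out = S.update_datasets(state, list(masks), masks, round_index=1)
        assert len(out.labeled) == 20 and len(out.unlabeled) == 30
        assert len(out.labeled) + len(out.unlabeled) == 50
        assert all(r.provenance == "pseudo" and r.round_admitted == 1
                   for r in out.pseudo_labeled)

    def test_readmission_rejected(self):
        state = self._state()
        masks = {"u0": np.zeros((4, 4), np.uint8)}
        out = S.update_datasets(state, ["u0"], masks)
        with pytest.raises(ValueError):
            S.update_datasets(out, ["u0"], masks)

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="not in the unlabeled pool"):
            S.update_datasets(self._state(), ["ghost"], {"ghost": None})

    def test_human_labels_never_overwritten(self):
        state = self._state()
        out = S.update_datasets(state, ["u1"], {"u1": np.ones((4, 4), np.uint8)})
        for r in out.labeled:
            if r.image_id.startswith("l"):
                assert r.provenance == "human"
                assert np.all(r.label == 0)
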