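"""Region labelling, training-set assembly and the voxel classifier."""

import numpy as np
import pytest

from vitreoseg.features import FeatureStack
from vitreoseg.region_model import (
    RegionModelConfig,
    build_training_set,
    labels_from_surfaces,
    predict_probabilities,
    train_region_classifier,
    training_mask_from_surfaces,
)
from vitreoseg.types import SurfaceSet


def flat_surfaces(vt, vb, ilm, rpe, shape=(2, 3)):
    mk = lambda v: np.full(shape, v, dtype=float)
    return SurfaceSet(mk(vt), mk(vb), mk(ilm), mk(rpe))


class TestLabels:
    def test_band_sizes_from_convention(self):
        s = flat_surfaces(10, 12, 20, 40)
        labels = labels_from_surfaces(s, (2, 3, 64))
        counts = np.bincount(labels[0, 0], minlength=5)
        assert counts.tolist() == [10, 2, 8, 20, 24]
        assert counts.sum() == 64

    def test_missing_vitreous_is_vitreous_down_to_ilm(self):
        s = flat_surfaces(np.nan, np.nan, 20, 40)
        labels = labels_from_surfaces(s, (2, 3, 64))
        assert np.all(labels[..., :20] == 0)
        assert np.all(labels[..., 20:40] == 3)

    def test_attached_has_no_gap_band(self):
        s = flat_surfaces(17, 20, 20, 40)
        labels = labels_from_surfaces(s, (2, 3, 64))
        col = labels[0, 0]
        assert np.all(col[17:20] == 1)
        assert not np.any(col == 2)

    def test_ordering_violation_names_ascan(self):
        vt = np.full((2, 3), 10.0)
        vb = np.full((2, 3), 13.0)
        ilm = np.full((2, 3), 20.0)
        rpe = np.full((2, 3), 40.0)
        ilm[1, 2] = 45.0  # ILM below RPE
        with pytest.raises(ValueError, match=r"bscan=1, ascan=2"):
            labels_from_surfaces(SurfaceSet(vt, vb, ilm, rpe), (2, 3, 64))

    def test_labels_nondecreasing_along_ascans(self, small_phantoms):
        _, truth = small_phantoms["steep_vma"]
        assert np.all(np.diff(truth.region_labels.astype(int), axis=2) >= 0)


class TestTrainingMask:
    def test_exclusion_zone_brute_force(self):
        s = flat_surfaces(30, 33, 40, 55, shape=(1, 2))
        mask = training_mask_from_surfaces(s, (1, 2, 64), exclusion_voxels=20)
        for z in range(64):
            expected = not (30 - 20 <= z < 30)
            assert mask[0, 0, z] == expected

    def test_missing_vitreous_excludes_supra_ilm(self):
        s = flat_surfaces(np.nan, np.nan, 40, 55, shape=(1, 1))
        mask = training_mask_from_surfaces(s, (1, 1, 64))
        assert not mask[0, 0, :40].any()
        assert mask[0, 0, 40:].all()


def _toy_stack(labels, seed=0):
    """Features that weakly encode the label, with noise."""
    rng = np.random.default_rng(seed)
    vals = labels[..., None].astype(np.float32) + rng.normal(
        0, 0.3, labels.shape + (2,)
    ).astype(np.float32)
    return FeatureStack(vals, ["f0", "f1"])


class TestTrainingSet:
    def _full_labels(self):
        s = flat_surfaces(10, 13, 20, 40, shape=(4, 8))
        return labels_from_surfaces(s, (4, 8, 64))

    def test_balanced_cap(self):
        labels = self._full_labels()
        X, y = build_training_set([_toy_stack(labels)], [labels], per_class_cap=30, seed=0)
        assert len(y) == 150
        assert np.bincount(y, minlength=5).tolist() == [30] * 5

    def test_missing_class_error_lists_names(self):
        s = flat_surfaces(np.nan, np.nan, 20, 40, shape=(4, 8))
        labels = labels_from_surfaces(s, (4, 8, 64))
        with pytest.raises(ValueError, match="VMI, VMI_ILM"):
            build_training_set([_toy_stack(labels)], [labels], per_class_cap=30)

    def test_excluded_voxels_never_sampled(self):
        labels = self._full_labels()
        # feature 0 encodes the axial index so rows are identifiable
        z = np.broadcast_to(np.arange(64, dtype=np.float32), labels.shape)
        stack = FeatureStack(z[..., None].copy(), ["zpos"])
        s = flat_surfaces(10, 13, 20, 40, shape=(4, 8))
        mask = training_mask_from_surfaces(s, (4, 8, 64), exclusion_voxels=5)
        X, _ = build_training_set([stack], [labels], [mask], per_class_cap=10_000, seed=0)
        assert not np.any((X[:, 0] >= 5) & (X[:, 0] < 10))

    def test_deterministic_under_seed(self):
        labels = self._full_labels()
        a = build_training_set([_toy_stack(labels)], [labels], per_class_cap=40, seed=3)
        b = build_training_set([_toy_stack(labels)], [labels], per_class_cap=40, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        clf = train_region_classifier(X, y, RegionModelConfig(n_trees=10), seed=0)
        assert clf.score(X, y) == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(600, 4))
        y = rng.integers(0, 5, 600)
        clf = train_region_classifier(X[:400], y[:400], RegionModelConfig(n_trees=20), seed=0)
        acc = clf.score(X[400:], y[400:])
        assert abs(acc - 0.2) < 0.10

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 3))
        y = rng.integers(0, 3, 300)
        p1 = train_region_classifier(X, y, seed=4).predict_proba(X)
        p2 = train_region_classifier(X, y, seed=4).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            train_region_classifier(np.zeros((5, 2)), np.zeros(4))


class TestPredict:
    def test_probabilities_normalized(self, small_phantoms, small_bank, small_cascade):
        from vitreoseg.features import extract_features

        vol = small_phantoms["shallow_vma"][0]
        pm = predict_probabilities(
            extract_features(vol, small_bank), small_cascade.classifiers[0]
        )
        sums = pm.probs.sum(axis=-1)
        assert np.abs(sums - 1.0).max() < 1e-6
        assert pm.probs.min() >= 0

    def test_single_tree_gives_one_hot(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)
        clf = train_region_classifier(X, y, RegionModelConfig(n_trees=1), seed=0)
        stack = FeatureStack(X.reshape(1, 10, 10, 2).astype(np.float32), ["f0", "f1"])
        pm = predict_probabilities(stack, clf)
        assert set(np.unique(pm.probs)) <= {0.0, 1.0}

    def test_layout_mismatch_names_features(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, 60)
        clf = train_region_classifier(X, y, seed=0, feature_names=["a", "b"])
        stack = FeatureStack(np.zeros((1, 6, 10, 2), np.float32), ["a", "c"])
        with pytest.raises(ValueError, match="feature layout mismatch"):
            predict_probabilities(stack, clf)

    def test_accuracy_improves_with_training_set_size(
        self, small_phantoms, small_bank
    ):
        """More training voxels give higher held-out voxel accuracy."""
        from vitreoseg.features import extract_features

        pairs = [small_phantoms[c] for c in ("attached", "shallow_vma", "steep_vma")]
        stacks = [extract_features(v, small_bank) for v, _ in pairs]
        lmaps = [t.region_labels for _, t in pairs]
        masks = [
            training_mask_from_surfaces(t.surfaces, v.data.shape) for v, t in pairs
        ]
        vol, truth = small_phantoms["complete_pvd"]
        test_stack = extract_features(vol, small_bank)
        accs = []
        for cap in (60, 2000):
            X, y = build_training_set(stacks, lmaps, masks, per_class_cap=cap, seed=0)
            clf = train_region_classifier(X, y, RegionModelConfig(n_trees=15), seed=0)
            pred = predict_probabilities(test_stack, clf).argmax_labels
            ok = training_mask_from_surfaces(truth.surfaces, vol.data.shape)
            accs.append((pred[ok] == truth.region_labels[ok]).mean())
        assert accs[1] > accs[0]

    def test_noisefree_phantom_argmax_matches_truth_off_surface(
        self, noisefree_phantoms, small_bank
    ):
        """>=90% voxel agreement outside a ±2-voxel band around the surfaces."""
        from vitreoseg.features import extract_features
        from vitreoseg.region_model import labels_from_surfaces, training_mask_from_surfaces

        pairs = [noisefree_phantoms[c] for c in ("attached", "shallow_vma")]
        stacks = [extract_features(v, small_bank) for v, _ in pairs]
        lmaps = [t.region_labels for _, t in pairs]
        masks = [
            training_mask_from_surfaces(t.surfaces, v.data.shape) for v, t in pairs
        ]
        X, y = build_training_set(stacks, lmaps, masks, per_class_cap=3000, seed=0)
        clf = train_region_classifier(X, y, RegionModelConfig(n_trees=20), seed=0)

        vol, truth = noisefree_phantoms["steep_vma"]
        pred = predict_probabilities(extract_features(vol, small_bank), clf).argmax_labels
        nz = vol.data.shape[2]
        z = np.arange(nz)[None, None, :]
        near = np.zeros(vol.data.shape, bool)
        for name in ("vit_top", "vit_bottom", "ilm", "rpe"):
            surf = getattr(truth.surfaces, name)
            with np.errstate(invalid="ignore"):
                near |= np.abs(z - np.nan_to_num(surf[..., None], nan=-99)) <= 2
        # exclude the annotation-uncertainty band above the cortex as well
        mask = training_mask_from_surfaces(truth.surfaces, vol.data.shape)
        ok = (~near) & mask
        agree = (pred[ok] == truth.region_labels[ok]).mean()
        assert agree >= 0.90
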