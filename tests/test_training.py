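"""Training regimes: warm starts, checkpoint selection, scoring, features."""

import numpy as np
import pytest

from antsemble.datamodel import (
    VIEWS,
    DatasetSplit,
    EmptyDatasetError,
    ImageSample,
    MultiViewDataset,
    SpecimenRecord,
    View,
    split_dataset,
)
from antsemble.synthgen import GenusArchetype, SynthConfig, make_archetypes, render_view
from antsemble.training import (
    Hyperparams,
    TrainedModel,
    extract_penultimate_features,
    load_checkpoint,
    save_checkpoint,
    score_image,
    train_general,
    train_specific,
    train_transfer,
)

from conftest import tiny_architecture


def _memorizable_split(n_labels=2, size=16):
    """8 distinct constant-ish images, 2 labels; trivially memorizable."""
    rng = np.random.default_rng(0)
    specimens = []
    for i in range(8):
        genus = (i % n_labels) + 1
        sid = f"m{i}"
        pixels = np.clip(0.5 + 0.4 * np.sign(genus - 1.5)
                         + 0.05 * rng.random((size, size)), 0, 1)
        images = {v: [ImageSample(sid, v, pixels)] if v is View.HEAD else []
                  for v in VIEWS}
        specimens.append(SpecimenRecord(sid, genus, images))
    ds = MultiViewDataset(specimens)
    return DatasetSplit(train=ds, validation=MultiViewDataset([]),
                        test=MultiViewDataset([]), seed=0,
                        fractions=(1.0, 0.0, 0.0))


class TestTrainingLoop:
    def test_zero_iterations_returns_initialization(self, small_split):
        arch = tiny_architecture(3)
        hp = Hyperparams(iterations=0, seed=3)
        m1, h1 = train_general(small_split, arch, hp)
        m2, h2 = train_general(small_split, arch, hp)
        assert h1.points == [] and h1.best_iteration == 0
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_overfits_memorizable_set(self):
        split = _memorizable_split()
        arch = tiny_architecture(2, input_size=16)
        hp = Hyperparams(iterations=200, batch_size=8, validation_interval=50,
                         seed=1)
        model, _ = train_general(split, arch, hp)
        pairs = [(s.pictures(View.HEAD)[0], s.genus) for s in split.train]
        hits = sum(int(np.argmax(score_image(model, img)) + 1 == g)
                   for img, g in pairs)
        assert hits == len(pairs)

    def test_same_seed_same_history(self, small_split):
        arch = tiny_architecture(3)
        hp = Hyperparams(iterations=100, validation_interval=25, seed=11)
        _, h1 = train_general(small_split, arch, hp)
        _, h2 = train_general(small_split, arch, hp)
        assert h1.points == h2.points
        assert h1.best_iteration == h2.best_iteration

    def test_checkpoint_selection_is_argmax_earliest(self, trained_models):
        for key in ("general", "specific"):
            _, hist = trained_models[key]
            accs = [acc for _, _, acc in hist.points]
            best = max(accs)
            first_best_iter = next(it for it, _, acc in hist.points
                                   if acc == best)
            assert hist.best_iteration == first_best_iter

    def test_empty_view_raises(self, small_split):
        arch = tiny_architecture(3)
        # build a split whose train part has no head pictures
        stripped = MultiViewDataset([
            SpecimenRecord(s.specimen_id, s.genus,
                           {v: ([] if v is View.HEAD else list(s.pictures(v)))
                            for v in VIEWS})
            for s in small_split.train.specimens
        ])
        bad = DatasetSplit(stripped, small_split.validation, small_split.test,
                           seed=0, fractions=(0.6, 0.2, 0.2))
        with pytest.raises(EmptyDatasetError):
            train_specific(bad, View.HEAD, arch, Hyperparams(iterations=10,
                                                             validation_interval=10))


class TestTransfer:
    def test_warm_start_equality_at_zero_iterations(self, small_split,
                                                    trained_models):
        parent, _ = trained_models["general"]
        child, hist = train_transfer(parent, small_split, View.HEAD,
                                     Hyperparams(iterations=0, seed=9))
        for a, b in zip(child.weights, parent.weights):
            np.testing.assert_array_equal(a, b)
        assert child.provenance["parent"]["regime"] == "general"

    def test_rejects_non_general_parent(self, small_split, trained_models):
        specific, _ = trained_models["specific"]
        with pytest.raises(ValueError, match="general"):
            train_transfer(specific, small_split, View.HEAD,
                           Hyperparams(iterations=0))


class TestViewInformativeness:
    def test_informative_view_trains_better(self):
        """With all signal in the head view, the head-specific model beats the
        dorsum-specific one in a majority of training seeds (construction
        forces it: dorsum images are identical across genera up to jitter)."""
        shared = np.full(5, 0.5)
        rng = np.random.default_rng(0)
        common = {v: rng.random(4) for v in VIEWS}
        archetypes = []
        for g in range(1, 4):
            vp = {v: common[v].copy() for v in VIEWS}
            vp[View.HEAD] = np.roll(np.array([0.05, 0.5, 0.95, 0.5]), g)
            archetypes.append(GenusArchetype(g, shared.copy(), vp))
        cfg = SynthConfig(n_genera=3, specimens_per_genus=12, image_size=32,
                          noise_sd=0.05, extra_picture_prob=0.0, seed=0)
        specimens = []
        for a in archetypes:
            for i in range(cfg.specimens_per_genus):
                sid = f"g{a.genus}s{i}"
                images = {
                    v: [ImageSample(sid, v, render_view(
                        a, v, cfg,
                        seed=np.random.SeedSequence((a.genus, i, vi))).pixels)]
                    for vi, v in enumerate(VIEWS)
                }
                specimens.append(SpecimenRecord(sid, a.genus, images))
        split = split_dataset(MultiViewDataset(specimens), (0.5, 0.25, 0.25),
                              seed=0)
        arch = tiny_architecture(3)
        wins = 0
        for seed in range(5):
            hp = Hyperparams(iterations=150, validation_interval=50, seed=seed)
            _, hh = train_specific(split, View.HEAD, arch, hp)
            _, hd = train_specific(split, View.DORSUM, arch, hp)
            wins += int(hh.best_accuracy > hd.best_accuracy)
        assert wins >= 3


class TestScoring:
    def test_score_sums_to_one(self, trained_models, small_split):
        model, _ = trained_models["general"]
        img = small_split.test.specimens[0].pictures(View.HEAD)[0]
        scores = score_image(model, img)
        assert scores.shape == (3,)
        assert scores.sum() == pytest.approx(1.0, abs=1e-6)
        assert (scores > 0).all()

    def test_zeroed_final_layer_gives_uniform(self, trained_models, small_split):
        model, _ = trained_models["general"]
        clone = TrainedModel(model.arch, [w.copy() for w in model.weights],
                             "general", None)
        net = clone.network()
        final = net.layers[net.linear_indices[-1]]
        for p in final.params:
            p[...] = 0.0
        img = small_split.test.specimens[0].pictures(View.DORSUM)[0]
        np.testing.assert_allclose(score_image(clone, img), np.full(3, 1 / 3),
                                   atol=1e-7)

    def test_raising_a_logit_raises_its_score(self, trained_models, small_split):
        model, _ = trained_models["general"]
        img = small_split.test.specimens[0].pictures(View.PROFILE)[0]
        before = score_image(model, img)
        bumped = TrainedModel(model.arch, [w.copy() for w in model.weights],
                              "general", None)
        net = bumped.network()
        final = net.layers[net.linear_indices[-1]]
        final.params[1][1] += 2.0  # raise label 2's logit bias
        after = score_image(bumped, img)
        assert after[1] > before[1]


class TestFeatures:
    def test_penultimate_length_matches_descriptor(self, trained_models,
                                                   small_split):
        model, _ = trained_models["general"]
        img = small_split.test.specimens[0].pictures(View.HEAD)[0]
        feats = extract_penultimate_features(model, img)
        assert feats.shape == (16,)  # second fully connected width
        assert (feats >= 0).all()  # post-ReLU activations
        np.testing.assert_array_equal(
            feats, extract_penultimate_features(model, img))

    def test_requires_two_fc_layers(self, small_split):
        from antsemble.netspec import ArchitectureDescriptor, LayerSpec

        arch = ArchitectureDescriptor(
            [LayerSpec("input"),
             LayerSpec("fully_connected", out_channels=3),
             LayerSpec("softmax"), LayerSpec("loss")],
            input_size=32, input_channels=1, n_labels=3,
        )
        model, _ = train_general(small_split, arch,
                                 Hyperparams(iterations=0))
        img = small_split.test.specimens[0].pictures(View.HEAD)[0]
        with pytest.raises(ValueError, match="fully connected"):
            extract_penultimate_features(model, img)


class TestCheckpoints:
    def test_round_trip(self, tmp_path, trained_models, small_split):
        model, hist = trained_models["transfer"]
        path = save_checkpoint(model, hist, tmp_path / "ckpt")
        loaded, lhist = load_checkpoint(path)
        assert loaded.regime == "transfer"
        assert loaded.view is View.HEAD
        assert lhist.best_iteration == hist.best_iteration
        img = small_split.test.specimens[0].pictures(View.HEAD)[0]
        np.testing.assert_allclose(score_image(loaded, img),
                                   score_image(model, img), atol=1e-7)
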