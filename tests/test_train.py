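"""Finger-disjoint splitting, training loop, and PAD metrics."""

import numpy as np
import pandas as pd
import pytest

from veinlive.train import (Confusion, TrainConfig, evaluate,
                            metrics_from_confusion, split_dataset, train)


def synthetic_manifest(n_live=200, n_attack=100, seed=0):
    """Manifest shaped like the full study: 2 live clips per finger, one
    attack clip per prosthesis, three species."""
    rows = []
    for i in range(n_live):
        rows.append({"path": f"live_{i}", "label": "bona_fide",
                     "species": "none", "finger_id": i // 2, "seed": i})
    species = ["a4_paper", "pvc", "laser_film"]
    for j in range(n_attack):
        rows.append({"path": f"attack_{j}", "label": "attack",
                     "species": species[j % 3],
                     "finger_id": n_live // 2 + j, "seed": n_live + j})
    return pd.DataFrame(rows)


class TestSplit:
    def test_full_scale_sizes(self):
        """A 400-clip manifest at 8:2 splits into 320 train / 80 validation."""
        manifest = synthetic_manifest(n_live=200, n_attack=200)
        tr, va = split_dataset(manifest, ratio=0.8, seed=0)
        assert len(tr) == 320 and len(va) == 80

    def test_finger_disjoint(self):
        manifest = synthetic_manifest()
        for seed in range(5):
            tr, va = split_dataset(manifest, seed=seed)
            assert not set(tr.finger_id) & set(va.finger_id)

    def test_stratified_by_label(self):
        tr, va = split_dataset(synthetic_manifest(), seed=1)
        assert (tr.label == "bona_fide").sum() == 160
        assert (va.label == "bona_fide").sum() == 40

    def test_deterministic(self):
        manifest = synthetic_manifest()
        tr1, va1 = split_dataset(manifest, seed=3)
        tr2, va2 = split_dataset(manifest, seed=3)
        pd.testing.assert_frame_equal(tr1, tr2)
        pd.testing.assert_frame_equal(va1, va2)

    def test_tiny_manifest_keeps_both_sides_populated(self):
        """Even a 6-clip manifest leaves every label represented on both
        sides of the split."""
        manifest = synthetic_manifest(n_live=4, n_attack=2)
        tr, va = split_dataset(manifest, ratio=0.8, seed=0)
        for side in (tr, va):
            assert set(side.label) == {"bona_fide", "attack"}

    def test_too_few_fingers_rejected(self):
        manifest = synthetic_manifest(n_live=2, n_attack=2)
        manifest.loc[manifest.label == "bona_fide", "finger_id"] = 0
        with pytest.raises(ValueError):
            split_dataset(manifest)


def _toy_data(n=16, seed=0, separable=True):
    """Tiny linearly separable image set: class differs by channel mean."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3, 16, 16)).astype(np.float32) * 0.1
    y = np.arange(n) % 2
    if separable:
        X[y == 1, 0] += 1.0
    return X, y


def _tiny_model(seed=0):
    from veinlive import nn
    rng = np.random.default_rng(seed)
    return nn.Sequential(nn.Conv2d(3, 4, 3, stride=2, padding=1, rng=rng),
                         nn.SiLU(), nn.Flatten(),
                         nn.Linear(4 * 8 * 8, 2, rng=rng))


class TestTrain:
    def test_smoke_single_epoch(self):
        X, y = _toy_data()
        _, history = train(_tiny_model(), (X, y),
                           config=TrainConfig(epochs=1, lr=1e-3, batch_size=8))
        assert len(history["loss"]) == 1

    def test_loss_decreases_on_separable_data(self):
        """First-5-epoch training loss decreases monotonically in >= 4 of 5
        seeds."""
        good = 0
        for seed in range(5):
            X, y = _toy_data(seed=seed)
            _, h = train(_tiny_model(seed), (X, y),
                         config=TrainConfig(epochs=5, lr=1e-3, batch_size=8,
                                            seed=seed))
            if all(b < a for a, b in zip(h["loss"], h["loss"][1:])):
                good += 1
        assert good >= 4

    def test_cosine_schedule_applied(self):
        X, y = _toy_data()
        _, h = train(_tiny_model(), (X, y),
                     config=TrainConfig(epochs=4, lr=1e-3, batch_size=8))
        assert h["lr"][-1] < h["lr"][0]
        assert h["lr"][0] == pytest.approx(1e-3)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train(_tiny_model(), (np.zeros((0, 3, 16, 16), np.float32),
                                  np.zeros(0, int)))


class TestMetrics:
    def test_perfect_classifier(self):
        conf = Confusion(n_bf=50, bf_rejected=0,
                         attacks={"pvc": (30, 0), "a4_paper": (20, 0)})
        res = metrics_from_confusion(conf)
        assert res.acr == 1.0 and res.apcer_max == 0.0 and res.bpcer == 0.0

    def test_hand_computed_confusion(self):
        """100 attacks with 5 accepted, 200 bona fide with 2 rejected:
        APCER 0.05, BPCER 0.01, ACR 293/300."""
        conf = Confusion(n_bf=200, bf_rejected=2,
                         attacks={"a4_paper": (100, 5)})
        res = metrics_from_confusion(conf)
        assert res.apcer_by_species["a4_paper"] == pytest.approx(0.05)
        assert res.bpcer == pytest.approx(0.01)
        assert res.acr == pytest.approx(293 / 300)

    def test_total_error(self):
        conf = Confusion(n_bf=10, bf_rejected=10, attacks={"pvc": (10, 10)})
        assert metrics_from_confusion(conf).acr == 0.0

    def test_weighted_error_identity_on_random_confusions(self):
        """ACR = 1 - (sum_s APCER_s N_s + BPCER N_BF) / N_total."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_bf = int(rng.integers(1, 50))
            conf = Confusion(n_bf=n_bf,
                             bf_rejected=int(rng.integers(0, n_bf + 1)))
            for s in ("a4_paper", "pvc", "laser_film"):
                n = int(rng.integers(1, 40))
                conf.attacks[s] = (n, int(rng.integers(0, n + 1)))
            res = metrics_from_confusion(conf)
            n_total = conf.total()
            weighted = sum(res.apcer_by_species[s] * conf.attacks[s][0]
                           for s in conf.attacks) + res.bpcer * conf.n_bf
            assert res.acr == pytest.approx(1 - weighted / n_total)

    def test_empty_confusion_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(Confusion(n_bf=0, bf_rejected=0))


class _ConstantModel:
    """Always predicts bona fide with overwhelming logit margin."""

    def eval(self):
        return self

    def __call__(self, x):
        from veinlive.nn import Tensor
        n = x.data.shape[0]
        logits = np.zeros((n, 2), np.float32)
        logits[:, 0] = 10.0
        return Tensor(logits)


class TestEvaluate:
    def test_always_bona_fide_predictor(self):
        X = np.zeros((12, 3, 8, 8), np.float32)
        y = np.array([0] * 6 + [1] * 6)
        res = evaluate(_ConstantModel(), X, y,
                       species=["none"] * 6 + ["pvc"] * 6)
        assert res.apcer_max == 1.0 and res.bpcer == 0.0

    def test_zero_threshold_rejects_all(self):
        """Any nonzero attack probability exceeds threshold 0: BPCER = 1."""
        X = np.zeros((8, 3, 8, 8), np.float32)
        y = np.array([0] * 4 + [1] * 4)
        res = evaluate(_ConstantModel(), X, y, threshold=0.0)
        assert res.bpcer == 1.0

    def test_identity_holds_on_random_predictions(self):
        rng = np.random.default_rng(1)

        class _RandomModel:
            def eval(self):
                return self

            def __call__(self, x):
                from veinlive.nn import Tensor
                return Tensor(rng.standard_normal(
                    (x.data.shape[0], 2)).astype(np.float32))

        X = np.zeros((30, 3, 8, 8), np.float32)
        y = rng.integers(0, 2, 30)
        species = [["none", "pvc"][v] for v in y]
        res = evaluate(_RandomModel(), X, y, species)
        conf = res.confusion
        errors = conf.bf_rejected + sum(a for _, a in conf.attacks.values())
        assert res.acr == pytest.approx(1 - errors / conf.total())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_ConstantModel(), np.zeros((0, 3, 8, 8), np.float32),
                     np.zeros(0, int))
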