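"""CNN engine: architecture contracts, gradients, training sanity."""

import hashlib

import numpy as np
import pytest

from radguide.deepnet import (
    ArchConfig,
    TrainConfig,
    build_extractor,
    cross_entropy,
    extract_latent,
    latent_table,
    predict_classes,
    pretrain,
)
from radguide.io_core import Volume

TINY = dict(input_shape=(16, 16, 16), init_channels=4, growth_rate=3,
            n_dense_blocks=2, layers_per_block=1)


def random_volumes(n, shape, seed, class_shift=None, labels=None):
    """Random-noise volumes, optionally with a class-dependent mean offset."""
    rng = np.random.default_rng(seed)
    vols = []
    for i in range(n):
        data = rng.standard_normal(shape) * 0.1 + 1.0
        if class_shift is not None:
            data += class_shift[labels[i]]
        vols.append(Volume(data, (2, 2, 2), id=f"s{i:03d}"))
    return vols


def params_hash(network):
    h = hashlib.sha256()
    for p, _ in network.params():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()


class TestArchitecture:
    def test_resnet_eight_blocks_is_18_weight_layers(self):
        net = build_extractor(ArchConfig(family="resnet", n_blocks=8,
                                         base_channels=4))
        assert net.n_weight_layers == 18

    def test_densenet_block_structure(self):
        cfg = ArchConfig(family="densenet", n_dense_blocks=4,
                         layers_per_block=2, growth_rate=4, init_channels=8)
        net = build_extractor(cfg)
        from radguide.deepnet._models import DenseLayer
        from radguide.deepnet._nn import AvgPool3d, Conv3d
        dense_layers = [l for l in net.features.layers if isinstance(l, DenseLayer)]
        transitions = [l for l in net.features.layers
                       if isinstance(l, Conv3d) and l.k == 1]
        assert len(dense_layers) == 8  # 4 blocks x 2 layers
        assert len(transitions) == 3   # between consecutive blocks

    def test_n_latent_is_channels_times_spatial(self):
        net = build_extractor(ArchConfig(family="densenet"))
        c, d, h, w = net.latent_shape
        assert net.n_latent == c * d * h * w
        assert net.latent_names()[0] == "DenseNet_Latent_0"
        assert len(net.latent_names()) == net.n_latent

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(input_shape=(4, 4, 4))


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        cfg = ArchConfig(family="densenet", seed=1, **TINY)
        net = build_extractor(cfg)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 16, 16, 16)).astype(np.float32)
        y = np.array([0, 2])
        loss, dl = cross_entropy(net.forward_logits(x, train=True), y)
        net.backward_logits(dl)
        checked = 0
        for p, g in net.params()[::4]:
            flat, gflat = p.ravel(), g.ravel()
            idx = flat.size // 2
            eps = 1e-3
            orig = flat[idx]
            flat[idx] = orig + eps
            l1, _ = cross_entropy(net.forward_logits(x, train=True), y)
            flat[idx] = orig - eps
            l2, _ = cross_entropy(net.forward_logits(x, train=True), y)
            flat[idx] = orig
            numeric = (l1 - l2) / (2 * eps)
            assert numeric == pytest.approx(float(gflat[idx]), abs=2e-3)
            checked += 1
        assert checked >= 3


class TestPretrain:
    def _volumes(self):
        labels = ["HC", "IPD", "MSA", "PSP"] * 6
        shift = {"HC": 0.0, "IPD": -0.15, "MSA": 0.2, "PSP": -0.3}
        vols = random_volumes(24, (16, 16, 16), seed=5, class_shift=shift,
                              labels=labels)
        return vols, labels

    def test_loss_decreases(self):
        vols, labels = self._volumes()
        net = build_extractor(ArchConfig(family="densenet", seed=2, **TINY))
        tr = pretrain(net, vols, labels, TrainConfig(epochs=8, batch_size=8, seed=0))
        assert tr.log.loss.iloc[-1] < tr.log.loss.iloc[0]

    def test_single_class_rejected(self):
        vols, _ = self._volumes()
        net = build_extractor(ArchConfig(family="densenet", seed=2, **TINY))
        with pytest.raises(ValueError, match="2 classes"):
            pretrain(net, vols[:4], ["HC"] * 4, TrainConfig(epochs=1))

    def test_same_seed_identical_parameters(self):
        vols, labels = self._volumes()
        hashes = []
        for _ in range(2):
            net = build_extractor(ArchConfig(family="densenet", seed=3, **TINY))
            pretrain(net, vols, labels, TrainConfig(epochs=2, batch_size=8, seed=1))
            hashes.append(params_hash(net))
        assert hashes[0] == hashes[1]

    def test_label_shuffled_control_near_chance(self):
        """With permuted labels, held-out accuracy stays inside the 95%
        binomial band around chance (0.25 for 4 balanced classes)."""
        vols, labels = self._volumes()
        rng = np.random.default_rng(42)
        shuffled = list(rng.permutation(labels))
        net = build_extractor(ArchConfig(family="densenet", seed=4, **TINY))
        held_vols = random_volumes(24, (16, 16, 16), seed=77,
                                   class_shift={"HC": 0.0, "IPD": -0.15,
                                                "MSA": 0.2, "PSP": -0.3},
                                   labels=labels)
        tr = pretrain(net, vols, shuffled, TrainConfig(epochs=6, batch_size=8, seed=2))
        preds, _ = predict_classes(tr, held_vols)
        acc = np.mean([a == b for a, b in zip(preds, labels)])
        from scipy import stats
        lo, hi = stats.binom.interval(0.95, 24, 0.25)
        assert lo <= acc * 24 <= hi


class TestLatentExtraction:
    def _trained(self):
        vols, labels = random_volumes(8, (16, 16, 16), seed=1), None
        labels = ["HC", "IPD", "MSA", "PSP"] * 2
        net = build_extractor(ArchConfig(family="densenet", seed=5, **TINY))
        return pretrain(net, vols, labels, TrainConfig(epochs=1, batch_size=4, seed=0)), vols

    def test_length_and_determinism(self):
        tr, vols = self._trained()
        v = vols[0]
        lat1 = extract_latent(tr, v)
        lat2 = extract_latent(tr, v)
        assert lat1.shape == (tr.n_latent,)
        np.testing.assert_array_equal(lat1, lat2)

    def test_zero_volume_finite(self):
        tr, _ = self._trained()
        z = Volume(np.zeros((16, 16, 16)), (2, 2, 2), id="z")
        lat = extract_latent(tr, z)
        assert np.isfinite(lat).all()
        np.testing.assert_array_equal(lat, extract_latent(tr, z))

    def test_shape_mismatch_rejected(self):
        tr, _ = self._trained()
        with pytest.raises(ValueError, match="shape"):
            extract_latent(tr, Volume(np.zeros((8, 8, 8)), (2, 2, 2)))

    def test_latent_table_columns(self):
        tr, vols = self._trained()
        table = latent_table(tr, vols[:3])
        assert table.shape == (3, tr.n_latent)
        assert table.features[0] == "DenseNet_Latent_0"
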