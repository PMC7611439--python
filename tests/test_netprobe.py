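import numpy as np
import pandas as pd
import pytest

from symperc import netprobe, stimuli
from symperc.netprobe import ProbeNetwork


def identity_net(acts: np.ndarray, W: np.ndarray, b: np.ndarray) -> ProbeNetwork:
    """Network whose 'images' are row indices (ints or 1x1 arrays) into a
    fixed activation matrix."""

    def extractor(images):
        idx = [int(np.asarray(im).flat[0]) for im in np.atleast_1d(images)]
        return acts[idx]

    return ProbeNetwork(extractor, W, b)


def brute_force_delta(acts, W, b, image_rows, true_classes, unit):
    """Oracle: rebuild the head without the unit and re-run the forward pass."""

    def softmax(z):
        e = np.exp(z - z.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    A = acts[image_rows]
    p_o = softmax(A @ W + b)
    keep = [u for u in range(W.shape[0]) if u != unit]
    p_m = softmax(A[:, keep] @ W[keep] + b)
    k = np.arange(len(image_rows))
    return np.abs(p_o[k, true_classes] - p_m[k, true_classes]).mean()


@pytest.fixture(scope="module")
def toy_setup():
    rng = np.random.default_rng(0)
    n_units, n_classes, n_img = 12, 3, 9
    acts = rng.random((n_img, n_units))
    W = rng.normal(size=(n_units, n_classes))
    b = rng.normal(size=n_classes)
    net = identity_net(acts, W, b)
    rows = np.arange(n_img)
    true = net.predict(rows)  # use predicted labels so all probes are 'correct'
    return acts, W, b, net, rows, true


class TestProbeNetwork:
    def test_probabilities_sum_to_one(self, toy_setup):
        _, _, _, net, rows, _ = toy_setup
        p = net.probabilities(rows)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_ablation_leaves_weights_intact(self, toy_setup):
        _, W, _, net, rows, _ = toy_setup
        before = net.weights.copy()
        net.probabilities(rows, ablate_unit=3)
        np.testing.assert_array_equal(net.weights, before)

    def test_out_of_range_unit_rejected(self, toy_setup):
        _, _, _, net, rows, _ = toy_setup
        with pytest.raises(IndexError):
            net.probabilities(rows, ablate_unit=99)


class TestUnitImportance:
    def test_zero_weight_unit_has_zero_delta(self, toy_setup):
        acts, W, b, _, rows, true = toy_setup
        W = W.copy()
        W[5, :] = 0.0
        net = identity_net(acts, W, b)
        true = net.predict(rows)
        report = netprobe.unit_importance(net, rows, true)
        assert report.delta[5] == 0.0

    def test_single_image_definition(self):
        # one unit whose ablation moves the true-class probability 0.9 -> 0.6
        acts = np.array([[1.0, 1.0]])
        # craft logits: with both units, p(class 0) = 0.9; ablating unit 1 -> 0.6
        z_full = np.log(np.array([0.9, 0.1]))
        z_abl = np.log(np.array([0.6, 0.4]))
        W = np.stack([z_abl, z_full - z_abl])
        b = np.zeros(2)
        net = identity_net(acts, W, b)
        report = netprobe.unit_importance(net, np.array([0]), np.array([0]))
        assert report.delta[1] == pytest.approx(0.3, abs=1e-12)

    def test_matches_remove_unit_oracle(self, toy_setup):
        acts, W, b, net, rows, true = toy_setup
        report = netprobe.unit_importance(net, rows, true)
        for unit in range(W.shape[0]):
            expected = brute_force_delta(acts, W, b, rows, true, unit)
            assert report.delta[unit] == pytest.approx(expected, abs=1e-10)

    def test_misclassified_probe_images_rejected(self, toy_setup):
        _, _, _, net, rows, true = toy_setup
        wrong = true.copy()
        wrong[0] = (wrong[0] + 1) % net.n_classes
        with pytest.raises(ValueError):
            netprobe.unit_importance(net, rows, wrong)

    def test_topk_bottomk_sizes_scale_with_units(self, toy_setup):
        _, _, _, net, rows, true = toy_setup
        report = netprobe.unit_importance(net, rows, true)
        assert report.k == max(1, net.n_units // 10)
        assert len(report.top_k) == len(report.bottom_k) == report.k
        assert report.delta[report.top_k].min() >= report.delta[report.bottom_k].max()


class TestUnitSetDistances:
    def _simple_set(self, n):
        labels = pd.DataFrame({"image_id": [f"im{i}" for i in range(n)]})
        return stimuli.StimulusSet([np.full((2, 2), i + 1.0) for i in range(n)], labels)

    def test_identical_images_distance_zero(self):
        acts = np.array([[1.0, 2.0], [1.0, 2.0]])
        net = identity_net(acts, np.zeros((2, 2)), np.zeros(2))
        sset = self._simple_set(2)
        d = netprobe.unit_set_distances(net, stimuli.StimulusSet([np.array([[0.0]]), np.array([[1.0]])], sset.labels))
        assert d["distance"].iloc[0] == 0.0

    def test_one_hot_activations_sqrt_two(self):
        acts = np.eye(3)
        net = identity_net(acts, np.zeros((3, 2)), np.zeros(2))
        labels = pd.DataFrame({"image_id": ["a", "b", "c"]})
        sset = stimuli.StimulusSet([np.array([[0.0]]), np.array([[1.0]]), np.array([[2.0]])], labels)
        d = netprobe.unit_set_distances(net, sset)
        np.testing.assert_allclose(d["distance"], np.sqrt(2.0))

    def test_subset_distance_never_exceeds_full(self, rng):
        acts = rng.random((6, 10))
        net = identity_net(acts, np.zeros((10, 2)), np.zeros(2))
        labels = pd.DataFrame({"image_id": [f"i{k}" for k in range(6)]})
        images = [np.array([[float(k)]]) for k in range(6)]
        sset = stimuli.StimulusSet(images, labels)
        full = netprobe.unit_set_distances(net, sset)
        sub = netprobe.unit_set_distances(net, sset, unit_subset=[0, 3, 7])
        assert (sub["distance"] <= full["distance"] + 1e-12).all()

    def test_empty_subset_rejected(self, rng):
        acts = rng.random((3, 4))
        net = identity_net(acts, np.zeros((4, 2)), np.zeros(2))
        labels = pd.DataFrame({"image_id": ["a", "b", "c"]})
        sset = stimuli.StimulusSet([np.array([[0.0]])] * 3, labels)
        with pytest.raises(ValueError):
            netprobe.unit_set_distances(net, sset, unit_subset=[])


def relation_table(d_sym, d_asym):
    rows = [{"image_a": f"s{i}", "image_b": f"t{i}", "distance": d, "relation": "symmetric_symmetric"} for i, d in enumerate(d_sym)]
    rows += [{"image_a": f"u{i}", "image_b": f"v{i}", "distance": d, "relation": "disjoint_asymmetric"} for i, d in enumerate(d_asym)]
    return pd.DataFrame(rows)


class TestSmi:
    def test_equal_means_give_zero(self):
        out = netprobe.smi(relation_table([2.0, 2.0], [2.0, 2.0, 2.0]))
        assert out["smi"] == 0.0

    def test_hand_computed_value(self):
        out = netprobe.smi(relation_table([3.0], [1.0]))
        assert out["smi"] == pytest.approx(0.5)
        assert out["d_sym"] == 3.0 and out["d_asym"] == 1.0

    def test_bounded_for_nonnegative_distances(self, rng):
        out = netprobe.smi(relation_table(rng.random(21), rng.random(420)))
        assert -1.0 <= out["smi"] <= 1.0

    def test_missing_relation_rejected(self):
        table = pd.DataFrame({"distance": [1.0], "relation": ["symmetric_symmetric"]})
        with pytest.raises(ValueError):
            netprobe.smi(table)


class TestBootstrapSmi:
    def test_constant_distances_zero_sd(self):
        table = relation_table([2.0] * 5, [1.0] * 10)
        out = netprobe.bootstrap_smi(table, n_boot=200, seed=0)
        assert out["sd"] < 1e-12
        assert out["mean"] == pytest.approx((2 - 1) / (2 + 1))

    def test_mean_close_to_plugin_estimate(self, rng):
        table = relation_table(rng.random(21) + 1.0, rng.random(420) + 0.5)
        plug = netprobe.smi(table)["smi"]
        out = netprobe.bootstrap_smi(table, n_boot=2000, seed=0)
        assert abs(out["mean"] - plug) < 2 * max(out["sd"], 1e-12)

    def test_seeded_replicates_identical(self, rng):
        table = relation_table(rng.random(10), rng.random(20))
        a = netprobe.bootstrap_smi(table, n_boot=500, seed=4)
        b = netprobe.bootstrap_smi(table, n_boot=500, seed=4)
        np.testing.assert_array_equal(a["replicates"], b["replicates"])

    def test_small_n_boot_warns(self, rng):
        table = relation_table(rng.random(5), rng.random(5))
        with pytest.warns(UserWarning):
            netprobe.bootstrap_smi(table, n_boot=50, seed=0)


class FakeUnitNet(ProbeNetwork):
    pass


def gabor_response_net(response_fn, n_units):
    """Net whose unit activations depend only on the Gabor's frequency label."""

    def extractor(images):
        # images are (frequency, orientation) tuples packed as arrays
        return np.stack([response_fn(float(im[0, 0])) for im in images])

    return ProbeNetwork(extractor, np.zeros((n_units, 2)), np.zeros(2))


class TestSfModulation:
    def _freq_set(self):
        freqs = stimuli.DEFAULT_FREQUENCIES
        rows, images = [], []
        for o in range(8):
            for f in freqs:
                rows.append({"image_id": f"g-{o}-{f}", "orientation_deg": o * 22.5, "frequency": f})
                images.append(np.full((1, 1), f))
        return stimuli.StimulusSet(images, pd.DataFrame(rows))

    def test_flat_tuning_gives_zero(self):
        net = gabor_response_net(lambda f: np.ones(4), 4)
        out = netprobe.sf_modulation(net, self._freq_set())
        np.testing.assert_allclose(out["mi"], 0.0)

    def test_hand_computed_ratio(self):
        # A_hsf = 2, A_lsf = 1 -> MI = 1/3
        net = gabor_response_net(lambda f: np.array([2.0 if f >= 0.25 else 1.0]), 1)
        out = netprobe.sf_modulation(net, self._freq_set())
        assert out["mi"].iloc[0] == pytest.approx(1.0 / 3.0)
        assert out["A_hsf"].iloc[0] == pytest.approx(2.0)
        assert out["A_lsf"].iloc[0] == pytest.approx(1.0)

    def test_high_frequency_only_unit_saturates(self):
        net = gabor_response_net(lambda f: np.array([1.0 if f >= 0.25 else 0.0]), 1)
        out = netprobe.sf_modulation(net, self._freq_set())
        assert out["mi"].iloc[0] == pytest.approx(1.0)

    def test_silent_unit_reported_missing(self):
        net = gabor_response_net(lambda f: np.zeros(1), 1)
        out = netprobe.sf_modulation(net, self._freq_set())
        assert np.isnan(out["mi"].iloc[0])

    def test_missing_frequencies_rejected(self):
        rows = [{"image_id": "g", "orientation_deg": 0.0, "frequency": 0.06}]
        sset = stimuli.StimulusSet([np.zeros((1, 1))], pd.DataFrame(rows))
        net = gabor_response_net(lambda f: np.ones(1), 1)
        with pytest.raises(ValueError):
            netprobe.sf_modulation(net, sset)

    def test_on_real_gabor_bank(self, small_set):
        bank = stimuli.gabor_bank(size=64)
        labels = small_set.labels["left_part"].to_numpy(int)
        net = netprobe.make_toy_network(16, 4, small_set.images, labels, seed=0)
        out = netprobe.sf_modulation(net, bank)
        finite = out["mi"].dropna()
        assert len(finite) > 0
        assert finite.between(-1, 1).all()


class TestMakeToyNetwork:
    def test_separable_data_high_accuracy(self, small_set):
        labels = small_set.labels["left_part"].to_numpy(int)
        net = netprobe.make_toy_network(64, 4, small_set.images, labels, seed=0)
        acc = np.mean(net.predict(small_set.images) == labels)
        assert acc > 0.9

    def test_deterministic_per_seed(self, small_set):
        labels = small_set.labels["left_part"].to_numpy(int)
        a = netprobe.make_toy_network(16, 4, small_set.images, labels, seed=3)
        b = netprobe.make_toy_network(16, 4, small_set.images, labels, seed=3)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.bias, b.bias)

    def test_softmax_normalization(self, small_set):
        labels = small_set.labels["left_part"].to_numpy(int)
        net = netprobe.make_toy_network(16, 4, small_set.images, labels, seed=1)
        p = net.probabilities(small_set.images)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_degenerate_training_data_rejected(self, small_set):
        with pytest.raises(ValueError):
            netprobe.make_toy_network(8, 2, small_set.images, np.zeros(len(small_set)), seed=0)

    def test_unit_budget_enforced(self, small_set):
        labels = small_set.labels["left_part"].to_numpy(int)
        with pytest.raises(ValueError):
            netprobe.make_toy_network(1024, 4, small_set.images, labels, seed=0)


class TestMirrorAugmentationContrast:
    def test_mirror_trained_network_shows_larger_smi(self):
        # statistical, seed-averaged property on trainable-extractor networks
        lib = stimuli.make_part_library(5, canvas=64, seed=0)
        sset = stimuli.compose_two_part_objects(lib)
        ids = np.arange(len(sset))
        mirrored = [im[:, ::-1].copy() for im in sset.images]
        diffs = []
        for seed in range(5):
            net_aug = netprobe.make_toy_network(
                64, len(sset), sset.images + mirrored, np.concatenate([ids, ids]),
                seed=seed, train_extractor=True,
            )
            net_plain = netprobe.make_toy_network(
                64, len(sset), sset.images, ids, seed=seed, train_extractor=True
            )
            smi_aug = netprobe.smi(netprobe.unit_set_distances(net_aug, sset))["smi"]
            smi_plain = netprobe.smi(netprobe.unit_set_distances(net_plain, sset))["smi"]
            diffs.append(smi_aug - smi_plain)
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 4
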