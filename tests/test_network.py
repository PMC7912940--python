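import numpy as np
import pytest

from msbrainseg.exceptions import ConfigurationError, ValidationError
from msbrainseg.network import (
    NetworkConfig,
    build_network,
    count_parameters,
    enumerate_parameters,
    forward_windows,
    load_checkpoint,
    pooled_size,
    save_checkpoint,
    softmax,
    toy_config,
)

TOY = toy_config()  # window 17, kernels (3,3,3), maps (2,2,2), concat 2


def test_reference_parameter_count_and_subtotals():
    cfg = NetworkConfig()
    assert count_parameters(cfg) == 2_856_932
    model = build_network(cfg, seed=0)
    pathway_total = sum(
        p.size for stages in model.pathways for conv, _, _ in stages for p in conv.params()
    )
    concat_total = sum(p.size for p in model.concat_conv.params())
    fc_total = sum(p.size for p in model.fc.params())
    assert pathway_total == 2_492_256
    assert concat_total == 331_904
    assert fc_total == 32_772
    assert pathway_total + concat_total + fc_total == 2_856_932


def test_output_width_linearity():
    base = count_parameters(NetworkConfig())
    wider = count_parameters(NetworkConfig(n_classes=8))
    assert wider - base == 8192 * 4 + 4


def test_closed_form_matches_enumeration_on_random_configs(rng):
    for _ in range(20):
        cfg = NetworkConfig(
            window_size=int(rng.integers(9, 33)),
            pathway_kernels=tuple(int(k) for k in rng.choice([3, 5, 7], size=3)),
            pathway_maps=tuple(int(m) for m in rng.integers(2, 9, size=3)),
            concat_maps=int(rng.integers(2, 9)),
            n_classes=int(rng.integers(2, 6)),
            conv_bias=bool(rng.integers(0, 2)),
            fc_bias=bool(rng.integers(0, 2)),
        )
        assert count_parameters(cfg) == enumerate_parameters(build_network(cfg, seed=0))


def test_reference_spatial_trace():
    cfg = NetworkConfig()
    assert cfg.spatial_trace() == [65, 32, 16, 8]
    assert cfg.concat_maps * 8 * 8 == 8192 == cfg.derived_flat_features()


@pytest.mark.parametrize(
    "n,kernel,stride,expected",
    [(65, 3, 2, 32), (32, 3, 2, 16), (16, 2, 2, 8), (17, 3, 2, 8), (8, 3, 2, 4), (4, 2, 2, 2)],
)
def test_pooled_size_examples(n, kernel, stride, expected):
    assert pooled_size(n, kernel, stride) == expected


def test_pooled_size_matches_window_enumeration():
    """Ceiling-mode sizing equals counting stride-spaced window starts: keep
    stepping while the previous window did not yet reach the input's end."""
    for n in range(2, 40):
        for k in (2, 3):
            for s in (1, 2, 3):
                if n < k:
                    continue
                count, pos = 1, 0
                while pos < n - k:
                    pos += s
                    count += 1
                assert pooled_size(n, k, s) == count


def test_toy_trace_and_forward(rng):
    assert TOY.spatial_trace() == [17, 8, 4, 2]
    model = build_network(TOY, seed=0)
    probs = model.predict_proba(rng.random((3, 17, 17)).astype(np.float32))
    assert probs.shape == (3, 4)
    assert model.flat_features == TOY.concat_maps * 4


def test_softmax_normalization_full_network(rng):
    model = build_network(NetworkConfig(), seed=0)
    probs = model.predict_proba(rng.random((4, 65, 65)).astype(np.float32))
    assert probs.shape == (4, 4)
    assert (probs >= 0).all()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


def test_model_depends_on_input(rng):
    model = build_network(TOY, seed=0)
    x = rng.random((1, 17, 17)).astype(np.float32)
    assert not np.allclose(model.predict_proba(x), model.predict_proba(2 * x))


class TestForwardWindows:
    def test_evaluation_determinism(self, rng):
        model = build_network(TOY, seed=1)
        x = rng.random((6, 17, 17)).astype(np.float32)
        np.testing.assert_array_equal(forward_windows(model, x), forward_windows(model, x))

    def test_empty_batch(self):
        model = build_network(TOY, seed=1)
        assert forward_windows(model, np.zeros((0, 17, 17))).shape == (0, 4)

    def test_permutation_equivariance(self, rng):
        model = build_network(TOY, seed=1)
        x = rng.random((5, 17, 17)).astype(np.float32)
        perm = rng.permutation(5)
        np.testing.assert_allclose(
            forward_windows(model, x)[perm], forward_windows(model, x[perm]), atol=1e-6
        )

    def test_wrong_patch_side_rejected(self, rng):
        model = build_network(TOY, seed=1)
        with pytest.raises(ValidationError):
            forward_windows(model, rng.random((2, 15, 15)))


def test_training_mode_gradient_matches_finite_differences(rng):
    """Backprop through convs, pools and the head agrees with central
    differences (float32 tolerance)."""
    cfg = NetworkConfig(
        window_size=9, pathway_kernels=(3, 3), pathway_maps=(3, 2), concat_maps=3, dropout_rate=0.0
    )
    model = build_network(cfg, seed=1)
    x = rng.random((4, 9, 9)).astype(np.float32)
    y = rng.integers(0, 4, 4)
    eye = np.eye(4, dtype=np.float32)

    def loss():
        p = softmax(model.forward_logits(x, train=True).astype(np.float64))
        return -np.log(p[np.arange(4), y]).mean()

    p = softmax(model.forward_logits(x, train=True))
    model.backward((p - eye[y]) / 4)
    params, grads = model.parameters(), model.gradients()
    eps = 1e-3
    checked = 0
    for P, G in zip(params, grads):
        flat, gflat = P.reshape(-1), G.reshape(-1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss()
            flat[idx] = orig - eps
            lm = loss()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[idx]) <= 0.05 * max(abs(num), abs(gflat[idx]), 1e-3)
            checked += 1
    assert checked >= 20


def test_config_validation():
    with pytest.raises(ConfigurationError):
        NetworkConfig(pathway_kernels=(11, 7), pathway_maps=(128, 96, 64))
    with pytest.raises(ConfigurationError):
        NetworkConfig(flat_features=4096)  # inconsistent with the spatial trace
    with pytest.raises(ConfigurationError):
        NetworkConfig(n_classes=1)
    # stating the derived value explicitly is allowed
    assert NetworkConfig(flat_features=8192).derived_flat_features() == 8192


def test_checkpoint_round_trip(tmp_path, rng):
    from msbrainseg.augment import NormalizationStats

    model = build_network(TOY, seed=3)
    stats = NormalizationStats(mean=0.2, sd=1.5)
    save_checkpoint(model, stats, tmp_path / "ckpt")
    loaded, loaded_stats = load_checkpoint(tmp_path / "ckpt")
    assert loaded_stats == stats
    x = rng.random((3, 17, 17)).astype(np.float32)
    np.testing.assert_array_equal(model.predict_proba(x), loaded.predict_proba(x))


def test_checkpoint_hash_mismatch(tmp_path):
    import json

    model = build_network(TOY, seed=3)
    save_checkpoint(model, None, tmp_path / "ckpt")
    sidecar = json.loads((tmp_path / "ckpt.json").read_text())
    sidecar["config_hash"] = "deadbeefdeadbeef"
    (tmp_path / "ckpt.json").write_text(json.dumps(sidecar))
    with pytest.raises(ValidationError, match="hash"):
        load_checkpoint(tmp_path / "ckpt")
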