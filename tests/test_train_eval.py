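"""Loss closed forms, data loading, training loop behaviour, evaluation."""

import json

import numpy as np
import pytest
from PIL import Image

import lesionseg as ls
from lesionseg import metrics as metrics_mod
from lesionseg.nn import Tensor
from lesionseg.synthetic_data import generate_dataset, write_isic_dataset
from lesionseg.train_eval import (
    TrainConfig,
    evaluate,
    load_isic_layout,
    normalize_image,
    segmentation_loss,
    train,
    write_overlay,
)


def test_config_defaults_match_documented_setup():
    cfg = TrainConfig()
    assert (cfg.input_size, cfg.learning_rate, cfg.batch_size, cfg.max_epochs) == (224, 1e-4, 4, 100)
    with pytest.raises(ValueError, match="loss"):
        TrainConfig(loss="focal")
    with pytest.raises(ValueError, match="divisible"):
        TrainConfig(input_size=100)


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "train.yaml"
    path.write_text(
        "input_size: 96\nlearning_rate: 0.001\nvariant: no_aspp\n"
        "augmentation: {p_rotate: 0.0, seed: 9}\n"
    )
    cfg = TrainConfig.from_yaml(path)
    assert cfg.input_size == 96 and cfg.variant == "no_aspp"
    assert cfg.augmentation.p_rotate == 0.0 and cfg.augmentation.seed == 9
    path.write_text("augmentation: null\n")
    assert TrainConfig.from_yaml(path).augmentation is None


def test_loss_zero_at_exact_match_and_ln2_at_half():
    mask = np.zeros((1, 1, 4, 4), dtype=np.float32)
    mask[0, 0, :2] = 1.0
    exact = segmentation_loss(Tensor(mask.copy()), mask, "dice")
    assert exact.item() == pytest.approx(0.0, abs=1e-6)
    half = segmentation_loss(Tensor(np.full_like(mask, 0.5)), mask, "bce")
    assert half.item() == pytest.approx(np.log(2.0), rel=1e-5)
    with pytest.raises(ValueError, match="shape"):
        segmentation_loss(Tensor(mask), np.zeros((1, 1, 2, 2)))


def test_loss_decreases_over_ten_steps_on_fixed_sample(tiny_samples):
    cfg = TrainConfig(input_size=96, width_multiplier=0.25, learning_rate=1e-3,
                      batch_size=1, max_epochs=10, seed=3, augmentation=None)
    log, _ = train(cfg, tiny_samples[:1], max_steps=10)
    losses = [e["train_loss"] for e in log.epochs]
    assert losses[-1] < losses[0]
    assert min(losses) == losses[-1] or losses[-1] < losses[0] * 0.8


def test_load_isic_layout_pairs_and_orphans(tmp_path):
    samples, _, _ = generate_dataset(5, size=48, seed=0)
    write_isic_dataset(samples, tmp_path)
    loaded = load_isic_layout(tmp_path, input_size=32)
    assert len(loaded) == 5
    assert loaded[0].image.shape == (32, 32, 3) and loaded[0].mask.shape == (32, 32)
    assert set(np.unique(loaded[0].mask)) <= {0, 1}

    # mixed extensions still pair
    png_img = (samples[0].image * 255).astype(np.uint8)
    Image.fromarray(png_img).save(tmp_path / "images" / "SYN_0000099.png")
    Image.fromarray((samples[0].mask * 255).astype(np.uint8)).save(
        tmp_path / "masks" / "SYN_0000099_segmentation.png"
    )
    assert len(load_isic_layout(tmp_path, 32)) == 6

    (tmp_path / "masks" / "GHOST_segmentation.png").write_bytes(
        (tmp_path / "masks" / "SYN_0000000_segmentation.png").read_bytes()
    )
    with pytest.raises(ValueError, match="GHOST"):
        load_isic_layout(tmp_path, 32)
    with pytest.raises(FileNotFoundError):
        load_isic_layout(tmp_path / "nope")


def test_one_step_updates_nearly_all_parameters(tiny_samples):
    cfg = TrainConfig(input_size=96, width_multiplier=0.25, learning_rate=1e-3,
                      batch_size=4, max_epochs=1, seed=0, augmentation=None)
    ls.nn.seed_all(cfg.seed)
    model = ls.build_model(cfg.variant, cfg.model_config())
    before = {k: v.data.copy() for k, v in model.named_parameters()}
    train(cfg, tiny_samples[:4], max_steps=1, model=model)
    changed = sum(1 for k, v in model.named_parameters() if not np.array_equal(before[k], v.data))
    assert changed / len(before) >= 0.99


def test_training_is_deterministic_given_seed(tiny_samples):
    finals = []
    for _ in range(2):
        cfg = TrainConfig(input_size=96, width_multiplier=0.25, learning_rate=1e-3,
                          batch_size=4, max_epochs=2, seed=11)
        log, _ = train(cfg, tiny_samples[:4], max_steps=2)
        finals.append(log.epochs[-1]["train_loss"])
    assert abs(finals[0] - finals[1]) < 1e-6


def test_run_log_is_written_and_reconstructable(tmp_path, tiny_samples):
    cfg = TrainConfig(input_size=96, width_multiplier=0.25, learning_rate=1e-3,
                      batch_size=4, max_epochs=1, seed=0, augmentation=None)
    log, model = train(cfg, tiny_samples[:4], tiny_samples[4:6], out_dir=tmp_path, max_steps=1)
    lines = [json.loads(l) for l in (tmp_path / "run_log.jsonl").read_text().splitlines()]
    assert lines[0]["run"]["seed"] == 0 and lines[0]["run"]["param_count"] == model.num_parameters()
    assert "val_dice" in lines[1]
    restored = ls.load_checkpoint(log.checkpoint)
    x = Tensor(np.zeros((1, 3, 96, 96), dtype=np.float32))
    model.eval()
    np.testing.assert_array_equal(restored(x).data, model(x).data)


class _OracleModel:
    """Stub predictor that returns the ground-truth masks it is asked about."""

    training = False

    def __init__(self, samples):
        self._masks = [s.mask for s in samples]
        self._cursor = 0

    def eval(self):
        return self

    def train(self):
        return self

    def predict(self, imgs, threshold=None):
        out = np.stack(self._masks[self._cursor : self._cursor + len(imgs)])
        self._cursor += len(imgs)
        return out


def test_evaluating_ground_truth_scores_perfectly(tiny_samples):
    cfg = TrainConfig(input_size=96, width_multiplier=0.25)
    micro, macro, per_image = evaluate(_OracleModel(tiny_samples), tiny_samples, cfg)
    assert micro.as_row() == (1.0, 1.0, 1.0, 1.0, 1.0)
    assert macro.as_row() == (1.0, 1.0, 1.0, 1.0, 1.0)
    # aggregation agrees with the metrics module on the same counts
    counts = [c for _, _, c in per_image]
    assert metrics_mod.aggregate(counts, "micro") == micro
    assert metrics_mod.aggregate(counts, "macro") == macro


def test_evaluate_is_deterministic_for_a_fixed_model(tiny_samples):
    model = ls.build_model("full", ls.ModelConfig.reduced(0.25, 96), seed=0)
    r1 = evaluate(model, tiny_samples[:3], TrainConfig(input_size=96, width_multiplier=0.25))
    r2 = evaluate(model, tiny_samples[:3], TrainConfig(input_size=96, width_multiplier=0.25))
    assert r1[0] == r2[0] and r1[1] == r2[1]


def test_normalize_image_shape_and_scale():
    img = np.full((8, 8, 3), 0.5, dtype=np.float32)
    out = normalize_image(img)
    assert out.shape == (3, 8, 8)
    assert abs(out[0, 0, 0] - (0.5 - 0.485) / 0.229) < 1e-6


def test_overlay_writer_produces_png(tmp_path, tiny_samples):
    s = tiny_samples[0]
    path = tmp_path / "overlay.png"
    write_overlay(s, s.mask, path)
    img = np.asarray(Image.open(path))
    assert img.shape == (96, 96, 3)
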