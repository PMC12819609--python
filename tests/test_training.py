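"""Training pipeline at micro scale: determinism, learning, evaluation
oracles, resume, ablation report structure."""

import json

import numpy as np
import pytest

from afcnet import ModelConfig, TrainConfig
from afcnet.metrics import METRIC_NAMES, MetricReport, compute_metrics, confusion
from afcnet.synthdata import SynthSpec, generate_sample, smoke_spec
from afcnet.training import (
    ablate,
    evaluate,
    evaluate_arrays,
    load_checkpoint,
    save_checkpoint,
    train_seeds,
    train_single_seed,
)

MICRO_MODEL = dict(backbone_name="tiny_test", common_width=8, input_size=48)


def _arrays(n, size=48, seed=3, spec=None):
    spec = spec or SynthSpec(image_size=size, seed=seed)
    pairs = [generate_sample(spec, i) for i in range(n)]
    return (
        np.stack([p.image.transpose(2, 0, 1) for p in pairs]),
        np.stack([p.mask for p in pairs]),
    )


@pytest.fixture(scope="module")
def micro_arrays():
    return _arrays(12)


class TestTrainSingleSeed:
    def test_two_epochs_deterministic(self, micro_arrays):
        imgs, masks = micro_arrays
        mc = ModelConfig(**MICRO_MODEL)
        tc = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seeds=(42,))
        _, log1, _ = train_single_seed(mc, tc, imgs, masks, seed=42)
        _, log2, _ = train_single_seed(mc, tc, imgs, masks, seed=42)
        assert log1 == log2

    def test_loss_decreases_on_smoke_data(self):
        imgs, masks = _arrays(16, spec=smoke_spec(image_size=48, seed=5))
        mc = ModelConfig(**MICRO_MODEL)
        tc = TrainConfig(
            epochs=100, batch_size=4, learning_rate=1e-3, max_steps=60,
            seeds=(42,), use_augmentation=False,
        )
        _, log, _ = train_single_seed(mc, tc, imgs, masks, seed=42)
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_resume_from_state(self, micro_arrays, tmp_path):
        imgs, masks = micro_arrays
        mc = ModelConfig(**MICRO_MODEL)
        tc = TrainConfig(epochs=1, batch_size=4, seeds=(42,), max_steps=2)
        model, _, _ = train_single_seed(mc, tc, imgs, masks, seed=42)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        resumed = load_checkpoint(tmp_path / "ckpt.npz")
        state = resumed.state_dict()
        model2, log, _ = train_single_seed(mc, tc, imgs, masks, seed=42, init_state=state)
        assert len(log) == 1  # continued training without error


class TestEvaluate:
    class _OracleModel:
        """Stub that returns the ground truth it is asked about."""

        def __init__(self, masks):
            self._masks = masks
            self._i = 0
            self.config = ModelConfig(**MICRO_MODEL)

        def eval(self):
            return self

        def __call__(self, x):
            from afcnet.assembly import SegmentationOutput
            from afcnet.nd import Tensor

            m = self._masks[self._i % len(self._masks)]
            self._i += 1
            prob = np.clip(m.astype(float), 0.01, 0.99)[None, None]
            return SegmentationOutput(
                probability=Tensor(prob),
                binary_mask=(prob >= 0.5).astype(np.uint8),
            )

    def test_oracle_model_scores_one(self, micro_arrays):
        imgs, masks = micro_arrays
        mean, per = evaluate_arrays(self._OracleModel(masks), imgs, masks)
        assert all(v == 1.0 for v in mean.as_dict().values())
        assert len(per) == len(imgs)

    def test_constant_background_predictor_dice_zero(self, micro_arrays):
        imgs, masks = micro_arrays

        class Background(self._OracleModel):
            def __call__(self, x):
                out = super().__call__(x)
                out.binary_mask = np.zeros_like(out.binary_mask)
                return out

        mean, _ = evaluate_arrays(Background(masks), imgs, masks)
        assert mean.dice == 0.0

    def test_mean_equals_loop_reference(self, micro_arrays):
        imgs, masks = micro_arrays
        from afcnet import build_model

        model = build_model(ModelConfig(**MICRO_MODEL), seed=1)
        mean, per = evaluate_arrays(model, imgs, masks)
        refs = []
        for i in range(len(imgs)):
            from afcnet.nd import Tensor

            out = model(Tensor(imgs[i : i + 1]))
            refs.append(compute_metrics(confusion(out.binary_mask[0, 0], masks[i])))
        for name in METRIC_NAMES:
            assert getattr(mean, name) == pytest.approx(
                np.mean([getattr(r, name) for r in refs])
            )

    def test_evaluate_from_checkpoint(self, tmp_path):
        from afcnet import build_model, generate_dataset

        rows = generate_dataset(SynthSpec(image_size=48, seed=9), 3, tmp_path)
        model = build_model(ModelConfig(**MICRO_MODEL), seed=0)
        save_checkpoint(model, tmp_path / "m.npz")
        mean, per = evaluate(tmp_path / "m.npz", rows)
        assert isinstance(mean, MetricReport) and len(per) == 3


class TestMultiSeedProtocol:
    def test_four_seed_run_produces_checkpoints_and_summary(self, micro_arrays, tmp_path):
        imgs, masks = micro_arrays
        mc = ModelConfig(**MICRO_MODEL)
        tc = TrainConfig(epochs=1, batch_size=4, seeds=(42, 8, 36, 120), max_steps=2)
        report = train_seeds(
            mc, tc, (imgs[:8], masks[:8]), out_dir=tmp_path, eval_arrays=(imgs[8:], masks[8:])
        )
        for seed in (42, 8, 36, 120):
            assert (tmp_path / f"seed{seed}.npz").exists()
            assert (tmp_path / f"seed{seed}_log.jsonl").exists()
        for name in METRIC_NAMES:
            assert len(report["metrics"][name]["per_seed"]) == 4
            assert report["metrics"][name]["spread"] >= 0.0
        assert (tmp_path / "report.json").exists()

    def test_reports_bit_identical_across_runs(self, micro_arrays, tmp_path):
        imgs, masks = micro_arrays
        mc = ModelConfig(**MICRO_MODEL)
        tc = TrainConfig(epochs=1, batch_size=4, seeds=(42, 8), max_steps=2)
        kwargs = dict(eval_arrays=(imgs[8:], masks[8:]))
        r1 = train_seeds(mc, tc, (imgs[:8], masks[:8]), out_dir=tmp_path / "a", **kwargs)
        r2 = train_seeds(mc, tc, (imgs[:8], masks[:8]), out_dir=tmp_path / "b", **kwargs)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
        assert (tmp_path / "a/report.json").read_bytes() == (tmp_path / "b/report.json").read_bytes()


@pytest.fixture(scope="module")
def report(tmp_path_factory):
    imgs, masks = _arrays(10)
    mc = ModelConfig(**MICRO_MODEL)
    tc = TrainConfig(epochs=1, batch_size=4, seeds=(42, 8), max_steps=1)
    out = tmp_path_factory.mktemp("ablate")
    return ablate(mc, tc, (imgs[:8], masks[:8]), (imgs[8:], masks[8:]), out_dir=out), out


class TestAblate:
    def test_four_variants_five_metrics(self, report):
        rep, _ = report
        assert [r["variant"] for r in rep["variants"]] == [
            "baseline", "+MAFF", "+MAFF+MDCA", "+MAFF+MDCA+UFR",
        ]
        for row in rep["variants"]:
            assert set(row["metrics"]) == set(METRIC_NAMES)

    def test_param_counts_strictly_increase(self, report):
        rep, _ = report
        counts = [r["param_count"] for r in rep["variants"]]
        assert counts == sorted(counts) and len(set(counts)) == 4

    def test_pvalues_present_and_valid(self, report):
        rep, _ = report
        for m in METRIC_NAMES:
            for key, p in rep["pvalues"][m].items():
                assert 0.0 <= p <= 1.0, key

    def test_outputs_written(self, report):
        _, out = report
        assert (out / "ablation.json").exists()
        table = (out / "ablation.tsv").read_text().splitlines()
        assert len(table) == 5  # header + 4 variants

    def test_rerun_identical(self):
        imgs, masks = _arrays(8)
        mc = ModelConfig(**MICRO_MODEL)
        tc = TrainConfig(epochs=1, batch_size=4, seeds=(42, 8), max_steps=1)
        r1 = ablate(mc, tc, (imgs[:6], masks[:6]), (imgs[6:], masks[6:]))
        r2 = ablate(mc, tc, (imgs[:6], masks[:6]), (imgs[6:], masks[6:]))
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
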