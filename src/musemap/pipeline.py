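"""End-to-end orchestration: synthesis, training, mapping, diagnosis.

One :class:`PipelineConfig` carries every stage's parameters plus a single
global seed; each stage derives its own seed deterministically from the
global one, so stages are independently reproducible.

The default configuration is the *desk-scale* study: quarter-scale-ish
synthetic images (288 x 224), 64-px windows with 16-px steps and 32-px
mirror padding (preserving the window/pad and kernel = ceil(window/step)
ratios of the full-scale 256/10/128/26 geometry), a 4 x 4 voting kernel at
the 95% threshold, and a 20-image unfixed test set split 10/10 between
classes.  It trains the classifier on FFPE-domain patches only, then
compares image-level diagnostic accuracy with and without CycleGAN
translation — the pipeline's central claim.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import ClfTrainConfig, train_classifier
from .evaluation import (DiagnosisRecord, Table1Accounting, round1,
                         run_condition_experiment)
from .gan import GanTrainConfig, train_cyclegan
from .mapping import WindowConfig
from .synthetic import (DegradeSpec, PatchDataset, SceneSpec, SyntheticImage,
                        degrade_to_unfixed, extract_patches, generate_ffpe_image)
from .voting import VotingConfig, voting_kernel_size

_STAGES = ("synth_train", "synth_val", "synth_test", "gan", "clf")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All knobs of the desk-scale experiment, YAML-loadable."""

    seed: int = 0
    # scene geometry
    image_width: int = 288
    image_height: int = 224
    cancer_fraction: float = 0.26
    n_glands: int = 1
    nucleus_density: float = 110.0
    # dataset sizes
    n_train_pos: int = 6
    n_train_neg: int = 5
    n_val_pos: int = 2
    n_val_neg: int = 2
    n_test_pos: int = 10
    n_test_neg: int = 10
    # degradation (unfixed-domain model)
    blur_sigma: float = 1.2
    bg_amplitude: float = 60.0
    bg_length_scale: float = 48.0
    contrast: float = 0.55
    # patch extraction
    patch_size: int = 64
    clf_patch_step: int = 32
    gan_patch_step: int = 48
    label_threshold: float = 0.5
    # training
    gan: GanTrainConfig = field(default_factory=lambda: GanTrainConfig())
    clf: ClfTrainConfig = field(default_factory=lambda: ClfTrainConfig())
    # mapping / voting
    window: int = 64
    step: int = 16
    pad: int = 32
    vote_threshold: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        problems = []
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                problems.append(f"unknown config key: {key}")
        if problems:
            raise ValueError("; ".join(problems))
        if "gan" in raw:
            raw["gan"] = GanTrainConfig(**raw["gan"])
        if "clf" in raw:
            raw["clf"] = ClfTrainConfig(**raw["clf"])
        return cls(**raw)

    def window_config(self) -> WindowConfig:
        return WindowConfig(window=self.window, step=self.step, pad=self.pad)

    def voting_config(self) -> VotingConfig:
        return VotingConfig(kernel=voting_kernel_size(self.window, self.step),
                            vote_threshold=self.vote_threshold)

    def degrade_spec(self, seed: int) -> DegradeSpec:
        return DegradeSpec(blur_sigma=self.blur_sigma,
                           bg_amplitude=self.bg_amplitude,
                           bg_length_scale=self.bg_length_scale,
                           contrast=self.contrast, rng_seed=seed)


def _scene(cfg: PipelineConfig, positive: bool, seed: int) -> SceneSpec:
    return SceneSpec(width=cfg.image_width, height=cfg.image_height,
                     cancer_fraction=cfg.cancer_fraction if positive else 0.0,
                     n_glands=cfg.n_glands if positive else 0,
                     nucleus_density=cfg.nucleus_density, rng_seed=seed)


def make_image_set(cfg: PipelineConfig, n_pos: int, n_neg: int, base_seed: int,
                   domain: str = "ffpe", tag: str = "") -> list[SyntheticImage]:
    """Generate a labelled image set; ``domain='unfixed'`` also degrades."""
    images = []
    for k in range(n_pos + n_neg):
        positive = k < n_pos
        img = generate_ffpe_image(_scene(cfg, positive, base_seed + k))
        if domain == "unfixed":
            img = degrade_to_unfixed(img, cfg.degrade_spec(base_seed + 7000 + k))
        img.image_id = f"{tag}{domain}-{'pos' if positive else 'neg'}-{k}"
        images.append(img)
    return images


def collect_patches(images: list[SyntheticImage], size: int, step: int,
                    label_threshold: float) -> PatchDataset:
    ds = PatchDataset()
    for img in images:
        ds.extend(extract_patches(img, size, step, label_threshold))
    return ds


def run_experiment(cfg: PipelineConfig, out_dir: Path | None = None,
                   log=lambda msg: None) -> dict:
    """Full desk-scale study: synthesise, train, and compare both conditions.

    Returns a dict with the with/without-translation accountings, the
    classifier metrics, loss histories and stage wall times.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- synthetic data ---------------------------------------------------
    seed_tr = stage_seed(cfg.seed, "synth_train")
    seed_va = stage_seed(cfg.seed, "synth_val")
    seed_te = stage_seed(cfg.seed, "synth_test")
    train_ffpe = make_image_set(cfg, cfg.n_train_pos, cfg.n_train_neg,
                                seed_tr, "ffpe", "train-")
    val_ffpe = make_image_set(cfg, cfg.n_val_pos, cfg.n_val_neg,
                              seed_va, "ffpe", "val-")
    # unpaired unfixed-domain training images come from a disjoint seed range
    train_unfixed = make_image_set(cfg, cfg.n_train_pos, cfg.n_train_neg,
                                   seed_tr + 500, "unfixed", "train-")
    test_unfixed = make_image_set(cfg, cfg.n_test_pos, cfg.n_test_neg,
                                  seed_te, "unfixed", "test-")
    train_patches = collect_patches(train_ffpe, cfg.patch_size,
                                    cfg.clf_patch_step, cfg.label_threshold)
    val_patches = collect_patches(val_ffpe, cfg.patch_size,
                                  cfg.clf_patch_step, cfg.label_threshold)
    gan_a = collect_patches(train_unfixed, cfg.patch_size,
                            cfg.gan_patch_step, cfg.label_threshold)
    gan_b = collect_patches(train_ffpe, cfg.patch_size,
                            cfg.gan_patch_step, cfg.label_threshold)
    timings["synth"] = time.perf_counter() - t0
    log(f"synthesised {len(train_patches)} train / {len(val_patches)} val "
        f"FFPE patches, {len(gan_a)}+{len(gan_b)} GAN patches "
        f"({timings['synth']:.1f}s)")

    # --- classifier (FFPE domain only) ------------------------------------
    t0 = time.perf_counter()
    clf_cfg = dataclasses.replace(cfg.clf, rng_seed=stage_seed(cfg.seed, "clf"))
    classifier, clf_history = train_classifier(train_patches, val_patches, clf_cfg)
    timings["classifier"] = time.perf_counter() - t0
    log(f"classifier best val accuracy {classifier.best_val_accuracy_:.3f} "
        f"threshold {classifier.threshold_.value:.3f} "
        f"({timings['classifier']:.1f}s)")

    # --- translator -------------------------------------------------------
    t0 = time.perf_counter()
    gan_cfg = dataclasses.replace(cfg.gan, patch_size=cfg.patch_size,
                                  rng_seed=stage_seed(cfg.seed, "gan"))
    pair, discriminators, gan_history = train_cyclegan(gan_a, gan_b, gan_cfg)
    timings["gan"] = time.perf_counter() - t0
    log(f"cyclegan trained {gan_cfg.epochs} epochs, final total loss "
        f"{gan_history[-1]['l_total']:.3f} ({timings['gan']:.1f}s)")

    # --- with / without comparison ---------------------------------------
    window_cfg = cfg.window_config()
    voting_cfg = cfg.voting_config()
    t0 = time.perf_counter()
    rec_wo, acc_wo = run_condition_experiment(
        test_unfixed, None, classifier, classifier.threshold_,
        window_cfg, voting_cfg, model_name="cnn")
    timings["map_without"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    rec_wi, acc_wi = run_condition_experiment(
        test_unfixed, pair, classifier, classifier.threshold_,
        window_cfg, voting_cfg, model_name="cnn")
    timings["map_with"] = time.perf_counter() - t0
    log(f"accuracy with translation {round1(acc_wi.model_average)}%, "
        f"without {round1(acc_wo.model_average)}%")

    result = {
        "config": dataclasses.asdict(cfg),
        "accuracy_with_translation": acc_wi.model_average,
        "accuracy_without_translation": acc_wo.model_average,
        "records_with": rec_wi,
        "records_without": rec_wo,
        "accounting_with": acc_wi,
        "accounting_without": acc_wo,
        "classifier": classifier,
        "translator": pair,
        "discriminators": discriminators,
        "clf_history": clf_history,
        "gan_history": gan_history,
        "timings": timings,
        # small unpaired patch samples for external translation-quality checks
        "gan_patch_sample_a": gan_a.as_arrays()[0][:64],
        "gan_patch_sample_b": gan_b.as_arrays()[0][:64],
    }
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _records_rows(records: list[DiagnosisRecord]) -> list[dict]:
    return [{"image_id": r.image_id, "true": r.true_label,
             "predicted": r.predicted_label, "correct": r.correct}
            for r in records]


def _write_artifacts(result: dict, out_dir: Path) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result["gan_history"]).to_csv(out_dir / "gan_history.csv",
                                               index=False)
    pd.DataFrame(result["clf_history"]).to_csv(out_dir / "clf_history.csv",
                                               index=False)
    for cond in ("with", "without"):
        pd.DataFrame(_records_rows(result[f"records_{cond}"])).to_csv(
            out_dir / f"records_{cond}_translation.csv", index=False)
    accounting = {
        "with_translation": result["accounting_with"].rounded(),
        "without_translation": result["accounting_without"].rounded(),
        "accuracy_gain": round1(result["accuracy_with_translation"]
                                - result["accuracy_without_translation"]),
        "seed": result["config"]["seed"],
    }
    (out_dir / "accounting.json").write_text(json.dumps(accounting, indent=2))
    (out_dir / "timings.json").write_text(json.dumps(
        {k: round(v, 2) for k, v in result["timings"].items()}, indent=2))
    table = (result["accounting_with"].render("With translation") + "\n\n"
             + result["accounting_without"].render("Without translation") + "\n")
    (out_dir / "table.txt").write_text(table)
    result["classifier"].save(out_dir / "classifier.npz")
    from .gan import save_translator
    gan_cfg = result["config"]["gan"]
    save_translator(out_dir / "translator.npz", result["translator"],
                    result["discriminators"], ngf=gan_cfg["ngf"],
                    ndf=gan_cfg["ndf"], n_res=gan_cfg["n_res"],
                    downsample=gan_cfg["downsample"])


def run_pipeline(config: PipelineConfig, out_dir: Path,
                 log=lambda msg: None) -> int:
    """CLI entry: run the full experiment, write artifacts, return 0 on success."""
    run_experiment(config, out_dir=out_dir, log=log)
    return 0
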