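"""The four-condition domain-shift ablation.

Replicate classifiers are trained on phantom-domain M-mode segments under
each cumulative augmentation level (0 none, 1 flip+zoom, 2 +histogram
matching, 3 +brightness/contrast jitter) and evaluated on (a) the held-out
phantom split and (b) a swine-domain segment set that differs from the
training domain in appearance only. The expected picture: near-perfect
same-domain accuracy at every level, a collapse on the swine-domain set
without appearance augmentation, partial recovery once histograms are
matched to a swine reference, and the best cross-domain accuracy with
jitter added.

Swine test segments travel through the same generate → rolling-window →
resize path as the training data, so the whole pipeline — not just the
classifier — is exercised. The swine test set is balanced, 400 segments by
default.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ptxmode.augment import AugmentationPlan, build_training_set
from ptxmode.evaluate import (EvalReport, aggregate, confusion, metrics,
                              plot_mean_matrix, write_report)
from ptxmode.model import ArchitectureConfig, predict
from ptxmode.preprocess import CropRegion, RollingWindowConfig, segment_images
from ptxmode.train import TrainConfig, run_replicates, split_dataset
from ptxmode.usim import (DomainParams, MmodeSpec, PHANTOM_DOMAIN,
                          SWINE_DOMAIN, generate_mmode, make_dataset)

__all__ = ["AblationConfig", "AblationResult", "run_ablation",
           "LEVEL_NAMES", "make_segment_sets", "swine_reference_image"]

LEVEL_NAMES = {0: "none", 1: "flip_zoom", 2: "hist_norm", 3: "bright_contrast"}


@dataclass(frozen=True)
class AblationConfig:
    """Everything a re-run needs: generators, augmentation, training.

    Defaults are a desk-scale rendition of the experiment — 64² model
    input, 15 phantom captures per class split into 10 overlapping
    one-second segments each, a 400-segment balanced swine test set, three
    replicate seeds and a 10-epoch cap — chosen to keep a full 4-condition
    run in the tens of minutes on one CPU core while preserving every
    stage of the pipeline.
    """

    phantom_domain: DomainParams = PHANTOM_DOMAIN
    swine_domain: DomainParams = SWINE_DOMAIN
    spec_template: MmodeSpec = MmodeSpec()
    n_captures_per_class: int = 15
    segments_per_capture: int = 10
    swine_test_per_class: int = 200
    input_side: int = 64
    arch: ArchitectureConfig | None = None
    train: TrainConfig = TrainConfig(max_epochs=10, replicate_seeds=(0, 1, 2))
    levels: tuple[int, ...] = (0, 1, 2, 3)
    seed: int = 0

    def resolved_arch(self) -> ArchitectureConfig:
        return self.arch if self.arch is not None else ArchitectureConfig(
            input_side=self.input_side)


@dataclass
class AblationResult:
    """Per-condition evaluation reports plus the run manifest."""

    reports: dict[tuple[str, str], EvalReport]
    errors: dict[str, str]
    config: AblationConfig
    runtime_s: float

    def accuracy(self, condition: str, test_type: str) -> float | None:
        return self.reports[(condition, test_type)].mean_metrics["accuracy"]

    def save(self, out_dir: str | Path, figures: bool = True) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(self.reports, out)
        manifest = {
            "config": _manifest_dict(self.config),
            "errors": self.errors,
            "runtime_s": self.runtime_s,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if figures:
            for (cond, test_type), rep in self.reports.items():
                plot_mean_matrix(rep, f"{cond} / {test_type}",
                                 out / f"confusion_{cond}_{test_type}.png")
        return out


def _manifest_dict(cfg: AblationConfig) -> dict:
    d = asdict(cfg)
    d["arch"] = asdict(cfg.resolved_arch())
    return d


def swine_reference_image(cfg: AblationConfig) -> np.ndarray:
    """The designated swine-domain baseline (PTX-negative) reference segment.

    One fixed swine rendering, cropped to a one-second window and resized
    to the model input — the analog of a reference baseline image from the
    target domain used for histogram matching.
    """
    spec = MmodeSpec(
        duration_s=cfg.spec_template.duration_s,
        px_per_s=cfg.spec_template.px_per_s,
        height_px=cfg.spec_template.height_px,
        ptx_positive=False,
        respiration_rpm=cfg.spec_template.respiration_rpm,
        seed=cfg.seed + 900_001,
    )
    image = generate_mmode(spec, cfg.swine_domain)
    window = _window_config(cfg, n_segments=2)
    X, _ = segment_images([image], window, cfg.input_side)
    return X[0]


def _window_config(cfg: AblationConfig, n_segments: int) -> RollingWindowConfig:
    spec = cfg.spec_template
    win_w = int(round(spec.px_per_s))  # one second of columns
    return RollingWindowConfig(
        n_segments=n_segments,
        window=CropRegion(0, 0, win_w, spec.height_px),
        capture_span_px=spec.width_px,
    )


def make_segment_sets(cfg: AblationConfig):
    """Generate phantom and swine segment arrays through the full pipeline.

    Returns ``(phantom_X, phantom_y, swine_X, swine_y)`` with segments
    resized to ``cfg.input_side`` and labels 1 = PTX positive.
    """
    window = _window_config(cfg, cfg.segments_per_capture)

    phantom = make_dataset(cfg.n_captures_per_class, cfg.spec_template,
                           cfg.phantom_domain, seed=cfg.seed)
    phantom_X, phantom_y = segment_images(phantom, window, cfg.input_side)

    n_swine_caps = int(np.ceil(cfg.swine_test_per_class /
                               cfg.segments_per_capture))
    swine = make_dataset(n_swine_caps, cfg.spec_template, cfg.swine_domain,
                         seed=cfg.seed + 500_000)
    swine_X, swine_y = segment_images(swine, window, cfg.input_side)
    # trim to exactly the balanced target size, keeping class balance
    keep = []
    for cls in (0, 1):
        members = np.flatnonzero(swine_y == cls)[:cfg.swine_test_per_class]
        keep.extend(members)
    keep = np.sort(np.asarray(keep))
    return phantom_X, phantom_y, swine_X[keep], swine_y[keep]


def run_ablation(cfg: AblationConfig | None = None,
                 out_dir: str | Path | None = None,
                 verbose: bool = False) -> AblationResult:
    """Run the full ablation; failures are recorded per condition.

    For every augmentation level, three things happen: the shared phantom
    split (train/validation/test) plus the swine set are passed through
    :func:`ptxmode.augment.build_training_set` (so histogram matching, when
    active, touches every role); replicate models are trained on the
    augmented training role; and each model is evaluated on the phantom
    test role and the swine role, then aggregated across replicates.
    """
    if cfg is None:
        cfg = AblationConfig()
    t0 = time.time()

    phantom_X, phantom_y, swine_X, swine_y = make_segment_sets(cfg)
    (Xtr, ytr), (Xva, yva), (Xte, yte) = split_dataset(
        phantom_X, phantom_y, cfg.train.split_fractions, seed=cfg.seed)
    reference = swine_reference_image(cfg)
    arch = cfg.resolved_arch()

    reports: dict[tuple[str, str], EvalReport] = {}
    errors: dict[str, str] = {}

    for level in cfg.levels:
        cond = LEVEL_NAMES[level]
        try:
            plan = AugmentationPlan(
                level=level,
                reference=reference if level >= 2 else None,
                seed=cfg.seed + 10_000 + level,
            )
            roles = {
                "train": (Xtr, ytr),
                "validation": (Xva, yva),
                "test": (Xte, yte),
                "swine": (swine_X, swine_y),
            }
            aug_roles, _ = build_training_set(roles, plan)

            results, rep_errors = run_replicates(
                aug_roles["train"], aug_roles["validation"], arch, cfg.train)
            if not results:
                raise RuntimeError(
                    f"all replicates failed: {rep_errors}"
                )
            for s, exc in rep_errors.items():
                errors[f"{cond}/seed{s}"] = repr(exc)

            for test_type in ("split", "swine"):
                key = "test" if test_type == "split" else "swine"
                X_eval, y_eval = aug_roles[key]
                cms = []
                for s, network, _hist in results:
                    _, pred = predict(network, X_eval, arch.input_side)
                    cms.append(confusion(y_eval, pred))
                reports[(cond, test_type)] = aggregate(cms)
                if verbose:
                    acc = reports[(cond, test_type)].mean_metrics["accuracy"]
                    print(f"[{cond:>15s} | {test_type:5s}] "
                          f"mean accuracy = {acc:.3f}")
        except Exception as exc:  # noqa: BLE001 - per-condition isolation
            errors[cond] = repr(exc)

    result = AblationResult(reports=reports, errors=errors, config=cfg,
                            runtime_s=time.time() - t0)
    if out_dir is not None:
        result.save(out_dir)
    return result
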