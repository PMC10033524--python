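"""End-to-end pipeline: phantom cohort -> prep -> augment -> train -> eval.

A run is driven by one :class:`PipelineConfig`, fully serializable to YAML;
re-running a frozen config reproduces the cohort manifest, the train/test
split and the per-epoch training trajectory. One global seed fans out to the
stages by fixed offsets so each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .phantom import PhantomConfig, generate_cohort
from .posteval import evaluate_case, postprocess, run_experiment
from .prep import preprocess_case
from .volio import load_case

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed seed offsets per stage
_PHANTOM_OFFSET, _EXPERIMENT_OFFSET = 0, 1


@dataclass
class PipelineConfig:
    """A fully resolved run description (YAML round-trippable)."""

    out_dir: str = "runs"
    seed: int = 0
    n_cases: int = 5
    n_test: int = 2
    architectures: tuple[int, ...] = (5,)
    scenarios: tuple[int, ...] = (5,)
    train_sizes: tuple[int, ...] = (3,)
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    model: dict = field(default_factory=dict)  # ModelSpec overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    post: dict = field(default_factory=dict)  # bilateral sigmas
    checkpoint: str | None = None  # skip training, predict/evaluate only
    run_name: str | None = None

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for k in ("architectures", "scenarios", "train_sizes"):
            data[k] = list(data[k])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for k in ("architectures", "scenarios", "train_sizes"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)


def _stage(name: str):
    logger.info("stage %s: starting", name)
    return time.monotonic()


def _done(name: str, t0: float):
    logger.info("stage %s: done in %.1f s", name, time.monotonic() - t0)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Artifacts (cohort NRRDs, manifests, checkpoints, Dice reports) land
    under one run directory with the resolved config frozen alongside.
    """
    run_name = config.run_name or datetime.now(timezone.utc).strftime(
        "run-%Y%m%dT%H%M%SZ"
    )
    run_dir = Path(config.out_dir) / run_name
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    log_file = logging.FileHandler(run_dir / "run.log")
    log_file.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                            "%(name)s: %(message)s"))
    pkg_logger = logging.getLogger("bladderseg")
    pkg_logger.addHandler(log_file)
    try:
        t0 = _stage("phantom")
        template = PhantomConfig(**config.phantom)
        data_dir = run_dir / "data"
        case_dirs = generate_cohort(config.n_cases, template,
                                    seed=config.seed + _PHANTOM_OFFSET,
                                    out_dir=data_dir)
        _done("phantom", t0)

        if config.checkpoint is not None:
            return _predict_only(config, run_dir, case_dirs)

        t0 = _stage("experiment")
        results, manifest = run_experiment(
            case_dirs,
            architectures=config.architectures,
            scenarios=config.scenarios,
            train_sizes=config.train_sizes,
            n_test=config.n_test,
            seed=config.seed + _EXPERIMENT_OFFSET,
            model_kwargs=config.model,
            train_kwargs=config.train,
            out_dir=run_dir / "results",
        )
        _done("experiment", t0)
        logger.info("run complete: %d result rows in %s", len(results),
                    run_dir / "results")
        return run_dir
    finally:
        pkg_logger.removeHandler(log_file)
        log_file.close()


def _predict_only(config: PipelineConfig, run_dir: Path, case_dirs) -> Path:
    """Prediction/evaluation from an existing checkpoint, no training."""
    t0 = _stage("predict")
    from .unet3d import load_checkpoint

    model = load_checkpoint(config.checkpoint)
    target = tuple(model.spec.input_shape[:3])
    rows = []
    import pandas as pd

    for case_dir in case_dirs:
        volume, masks = load_case(case_dir)
        img, labels = preprocess_case(volume, masks, target=target)
        probs = model.predict(img[..., None])[0]
        pred = postprocess(probs, **config.post)
        rows.append(evaluate_case(pred, labels, case_id=Path(case_dir).name))
    out = run_dir / "results"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "results.csv", index=False)
    _done("predict", t0)
    return run_dir
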