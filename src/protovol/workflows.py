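"""End-to-end experiment workflows.

These functions orchestrate the study designs the package exists for:

- supervised pre-training of an encoder (with a temporary linear head and
  cross-entropy) on one binary task, to produce transferable weights;
- GE2E training of an encoder, optionally starting from such a checkpoint;
- episodic k-shot evaluation sweeping k (default 2, 20, 40);
- a supervised baseline trained on exactly the 2k support samples of an
  episode and evaluated on the same query pool as the few-shot arm.

Each workflow is deterministic given its seed, writes its artifacts (metric
JSONs, per-episode CSVs, training curves, checkpoints) under an output
directory, and logs timestamped progress to stderr. The CLI in
:mod:`protovol.cli` is a thin wrapper over these functions.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .data_io import PreprocessSpec, SampleSet, preprocess, read_manifest
from .embedding import (ClassifierHandle, EncoderHandle, EncoderSpec,
                        attach_linear_head, build_encoder, load_encoder,
                        save_encoder)
from .errors import ConfigurationError, DataError
from .fewshot import EpisodeConfig, build_episode, evaluate_many, write_results_csv
from .ge2e import GE2EConfig, TrainSchedule, train_ge2e
from .metrics import MetricsReport, roc_auc, summarize
from .synthetic import SyntheticConfig, simulate_dataset, simulate_to_disk

log = logging.getLogger("protovol")


def setup_logging(logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    for h in handlers:
        h.setFormatter(fmt)
    log.handlers = handlers
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class SupervisedSchedule:
    steps: int = 400
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class RunConfig:
    """Resolved configuration of one run; see ``load_config`` for YAML shape."""

    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    preprocess: PreprocessSpec = field(default_factory=PreprocessSpec)
    ge2e: GE2EConfig = field(default_factory=GE2EConfig)
    ge2e_schedule: TrainSchedule = field(default_factory=TrainSchedule)
    supervised_schedule: SupervisedSchedule = field(default_factory=SupervisedSchedule)
    episode: EpisodeConfig = field(default_factory=EpisodeConfig)
    synthetic: SyntheticConfig | None = None
    manifest: str | None = None
    k_values: tuple[int, ...] = (2, 20, 40)
    n_episodes: int = 20
    seed: int = 0
    out_dir: str = "runs/out"


_SECTIONS = {
    "encoder": EncoderSpec, "preprocess": PreprocessSpec, "ge2e": GE2EConfig,
    "ge2e_schedule": TrainSchedule, "supervised_schedule": SupervisedSchedule,
    "episode": EpisodeConfig, "synthetic": SyntheticConfig,
}
_TUPLE_KEYS = {"target_shape", "volume_shape", "input_shape", "channels",
               "k_values"}


def _build_section(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} for section {cls.__name__}")
    coerced = {k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
               for k, v in data.items()}
    return cls(**coerced)


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; ``overrides`` replace top-level keys.

    Sections (``encoder``, ``preprocess``, ``ge2e``, ``ge2e_schedule``,
    ``supervised_schedule``, ``episode``, ``synthetic``) map onto the
    corresponding config dataclasses; unknown keys abort rather than being
    silently ignored.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a YAML mapping")
    raw.update(overrides or {})
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigurationError(f"unknown top-level config key(s) {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTIONS and isinstance(value, dict):
            kwargs[key] = _build_section(_SECTIONS[key], value)
        elif key in _TUPLE_KEYS and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the resolved config next to the outputs, for provenance."""
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj
    Path(path).write_text(yaml.safe_dump(enc(cfg), sort_keys=False))


def load_pool(cfg: RunConfig) -> SampleSet:
    """Materialise the sample pool: synthetic config or manifest on disk."""
    if cfg.synthetic is not None:
        return simulate_dataset(cfg.synthetic)
    if cfg.manifest is not None:
        return read_manifest(cfg.manifest)
    raise ConfigurationError("config needs either a synthetic section or a manifest")


def preprocess_pool(pool: SampleSet, spec: PreprocessSpec) -> SampleSet:
    from .data_io import LabeledSample
    out = [LabeledSample(label=s.label, exam_id=s.exam_id,
                         patient_id=s.patient_id,
                         _volume=preprocess(s.volume, spec))
           for s in pool]
    return SampleSet(out, name=pool.name)


def train_supervised(clf: ClassifierHandle, train: SampleSet,
                     sched: SupervisedSchedule,
                     curve_path: str | Path | None = None) -> ClassifierHandle:
    """Cross-entropy training of encoder + linear head on a binary task."""
    if len(set(train.labels)) < 2:
        raise DataError("supervised training needs both classes present")
    rng = np.random.default_rng(sched.seed)
    vols = np.stack([s.volume.voxels for s in train])
    labels = train.labels
    opt = nn.Adam(clf, lr=sched.learning_rate)  # any .named_params() source
    curve = []
    for step in range(sched.steps):
        idx = rng.choice(len(vols), size=min(sched.batch_size, len(vols)),
                         replace=False)
        logits = clf.forward(vols[idx], train=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
        opt.zero_grad()
        clf.backward(dlogits)
        opt.step()
        curve.append((step, loss))
    if curve_path is not None:
        with open(curve_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "loss"])
            w.writerows(curve)
    return clf


def run_pretrain(cfg: RunConfig) -> Path:
    """Supervised pre-training on the configured task; writes a checkpoint."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config.resolved.yaml")
    pool = preprocess_pool(load_pool(cfg), cfg.preprocess)
    log.info("pretrain: %d samples, encoder %s", len(pool), cfg.encoder.arch)
    enc = build_encoder(cfg.encoder, seed=cfg.seed)
    clf = attach_linear_head(enc, n_classes=2, seed=cfg.seed + 1)
    train_supervised(clf, pool, cfg.supervised_schedule,
                     curve_path=out / "pretrain_curve.csv")
    ckpt = out / "encoder_pretrained.npz"
    save_encoder(clf.detach(), ckpt)
    log.info("pretrain: checkpoint written to %s", ckpt)
    return ckpt


def run_train_ge2e(cfg: RunConfig, init_checkpoint: str | Path | None = None
                   ) -> Path:
    """GE2E training, optionally initialised from a supervised checkpoint."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config.resolved.yaml")
    pool = preprocess_pool(load_pool(cfg), cfg.preprocess)
    if init_checkpoint is not None:
        enc = load_encoder(init_checkpoint, expected_spec=cfg.encoder)
        log.info("train-ge2e: initialised from %s", init_checkpoint)
    else:
        enc = build_encoder(cfg.encoder, seed=cfg.seed)
    train_ge2e(enc, pool, cfg.ge2e, cfg.ge2e_schedule,
               curve_path=out / "ge2e_curve.csv")
    ckpt = out / "encoder_ge2e.npz"
    save_encoder(enc, ckpt)
    log.info("train-ge2e: checkpoint written to %s", ckpt)
    return ckpt


def run_evaluate(cfg: RunConfig, checkpoint: str | Path | None = None,
                 encoder: EncoderHandle | None = None) -> dict:
    """Episodic evaluation sweeping k over ``cfg.k_values``.

    Writes ``metrics.json`` (per-k aggregates) plus one per-episode CSV per
    k, and returns the metrics dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "config.resolved.yaml")
    if encoder is None:
        if checkpoint is None:
            raise ConfigurationError("evaluate needs a checkpoint or an encoder")
        encoder = load_encoder(checkpoint, expected_spec=cfg.encoder)
    pool = preprocess_pool(load_pool(cfg), cfg.preprocess)
    summary: dict = {}
    for k in cfg.k_values:
        ep_cfg = dataclasses.replace(cfg.episode, k_shot=k)
        reports, agg = evaluate_many(encoder, pool, ep_cfg,
                                     n_episodes=cfg.n_episodes,
                                     base_seed=cfg.seed)
        summary[f"k={k}"] = {
            "aggregate": agg,
            "episodes": [r.to_dict() for r in reports],
        }
        with open(out / f"episodes_k{k}.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["episode", "n", "tp", "fp", "tn", "fn",
                        "acc", "sen", "spe", "auc"])
            for e, r in enumerate(reports):
                w.writerow([e, r.n, r.tp, r.fp, r.tn, r.fn,
                            r.acc, r.sen, r.spe, r.auc])
        log.info("evaluate: k=%d mean AUC %.3f over %d episodes",
                 k, agg["auc_mean"], cfg.n_episodes)
    (out / "metrics.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def run_supervised_baseline(cfg: RunConfig, k: int | None = None) -> dict:
    """Supervised comparison arm matched to the few-shot protocol.

    Draws one episode per replicate, trains a fresh encoder + head with
    cross-entropy on exactly the 2k support samples, and evaluates on the
    episode's query pool; scores are the positive-minus-negative logit
    margins. Aggregates over ``cfg.n_episodes`` replicates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = k if k is not None else max(cfg.k_values)
    pool = preprocess_pool(load_pool(cfg), cfg.preprocess)
    reports = []
    for e in range(cfg.n_episodes):
        ep_cfg = dataclasses.replace(cfg.episode, k_shot=k, seed=cfg.seed + e)
        ep = build_episode(pool, ep_cfg)
        enc = build_encoder(cfg.encoder, seed=cfg.seed + e)
        clf = attach_linear_head(enc, n_classes=2, seed=cfg.seed + e + 1)
        sched = dataclasses.replace(cfg.supervised_schedule, seed=cfg.seed + e)
        train_supervised(clf, ep.support, sched)
        vols = np.stack([s.volume.voxels for s in ep.query])
        logits = clf.forward(vols, train=False)
        from .fewshot import QueryResult
        results = [QueryResult(exam_id=s.exam_id, true_label=s.label,
                               predicted_label=int(lg[1] > lg[0]),
                               score=float(lg[1] - lg[0]),
                               distances={0: float(-lg[0]), 1: float(-lg[1])})
                   for s, lg in zip(ep.query, logits)]
        reports.append(summarize(results))
    agg = {}
    for metric in ("acc", "sen", "spe", "auc"):
        vals = [getattr(r, metric) for r in reports if getattr(r, metric) is not None]
        agg[f"{metric}_mean"] = float(np.mean(vals)) if vals else None
        agg[f"{metric}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    result = {"k": k, "aggregate": agg,
              "episodes": [r.to_dict() for r in reports]}
    (out / "baseline_metrics.json").write_text(json.dumps(result, indent=2) + "\n")
    log.info("baseline: k=%d mean AUC %.3f", k, agg["auc_mean"])
    return result


def run_simulate(cfg: RunConfig) -> Path:
    if cfg.synthetic is None:
        raise ConfigurationError("simulate needs a synthetic config section")
    out = Path(cfg.out_dir)
    manifest = simulate_to_disk(cfg.synthetic, out)
    log.info("simulate: wrote dataset under %s", out)
    return manifest
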