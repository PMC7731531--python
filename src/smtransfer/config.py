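"""YAML run configuration: validation, defaulting, and the one-command
synthetic replica experiment."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from smtransfer import synth
from smtransfer.synth import SynthConfig, generate_world, write_world
from smtransfer.transfer import TransferConfig, run_transfer_experiment

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully-resolved experiment configuration.

    Exactly one of ``synth`` (a SynthConfig block) or ``inputs`` (paths to
    real feature/label tables for the two species) must be present.
    """

    outdir: str = "smtransfer_out"
    seed: int = 0
    synth: SynthConfig | None = None
    inputs: dict | None = None
    n_draws: int = 100
    per_class: int = 500
    folds: int = 10
    test_fraction: float = 0.1
    algorithm: str = "random_forest"
    control_repeats: int = 10
    filter_mode: str = "filter-all"
    benchmark_override: bool = False
    full_scale: bool = False

    def transfer_config(self) -> TransferConfig:
        return TransferConfig(
            n_draws=self.n_draws,
            per_class=self.per_class,
            folds=self.folds,
            test_fraction=self.test_fraction,
            algorithm=self.algorithm,
            control_repeats=self.control_repeats,
            filter_mode=self.filter_mode,
            benchmark_override=self.benchmark_override,
            seed=self.seed,
        )


_RUN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_SYNTH_KEYS = {f.name for f in dataclasses.fields(SynthConfig)}
_INPUT_KEYS = {
    "features_source", "meta_source", "labels_source",
    "features_target", "meta_target", "labels_target", "shared_features",
}

REDUCED_SCALE = {"n_draws": 25, "folds": 5}


def validate_config(path_or_dict) -> RunConfig:
    """Load, validate and default a run configuration.

    Fails hard on unknown keys (naming the key), on type errors, and when
    both or neither of the synthetic block and real input paths are given.
    Referenced input files must exist at validation time.
    """
    if isinstance(path_or_dict, (str, Path)):
        path = Path(path_or_dict)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    synth_block = raw.pop("synth", None)
    inputs = raw.pop("inputs", None)
    if (synth_block is None) == (inputs is None):
        raise ConfigError("exactly one of 'synth' and 'inputs' must be present")
    cfg_kwargs = {}
    for f in dataclasses.fields(RunConfig):
        if f.name in ("synth", "inputs") or f.name not in raw:
            continue
        value = raw[f.name]
        expected = {int: (int,), float: (int, float), str: (str,), bool: (bool,)}
        for typ, ok in expected.items():
            if f.type == typ.__name__ and not isinstance(value, ok):
                raise ConfigError(f"config key {f.name!r} must be {typ.__name__}, got {value!r}")
        cfg_kwargs[f.name] = value
    if synth_block is not None:
        unknown = set(synth_block) - _SYNTH_KEYS
        if unknown:
            raise ConfigError(f"unknown synth key(s): {sorted(unknown)}")
        sc = SynthConfig(**synth_block)
        try:
            sc.validate()
        except synth.ConfigurationError as e:
            raise ConfigError(str(e)) from e
        cfg_kwargs["synth"] = sc
    else:
        unknown = set(inputs) - _INPUT_KEYS
        if unknown:
            raise ConfigError(f"unknown inputs key(s): {sorted(unknown)}")
        missing_keys = _INPUT_KEYS - set(inputs)
        if missing_keys:
            raise ConfigError(f"missing inputs key(s): {sorted(missing_keys)}")
        for key, p in inputs.items():
            if not Path(p).exists():
                raise ConfigError(f"input file for {key!r} not found: {p}")
        cfg_kwargs["inputs"] = dict(inputs)
    cfg = RunConfig(**cfg_kwargs)
    if cfg.full_scale:
        cfg.n_draws, cfg.folds = 100, 10
    elif "n_draws" not in raw and "folds" not in raw:
        cfg.n_draws, cfg.folds = REDUCED_SCALE["n_draws"], REDUCED_SCALE["folds"]
    return cfg


def replica_run(cfg: RunConfig) -> Path:
    """Execute the whole pipeline from one config; return the output dir.

    Synthetic mode: generate the two-species world, harmonize, train every
    model variant, filter, retrain, control, evaluate; write all artifacts
    (world TSVs, per-variant metric TSV, filter report, JSON summary).
    Rerunning with the same config reproduces every TSV byte-identically.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("replica run: seed=%d outdir=%s", cfg.seed, outdir)
    if cfg.synth is not None:
        sc = dataclasses.replace(cfg.synth, seed=cfg.seed)
        logger.info("generating synthetic world (seed=%d)", sc.seed)
        world = generate_world(sc)
        write_world(world, outdir / "world")
        src, tgt = world.source, world.target
        report = run_transfer_experiment(
            src.features, src.observed_labels, tgt.features, tgt.observed_labels,
            world.shared_features, cfg.transfer_config(),
            source_true=src.true_labels, target_true=tgt.true_labels,
            target_benchmark=tgt.benchmark,
        )
    else:
        from smtransfer import io as sio

        src_ft = sio.read_feature_table(cfg.inputs["features_source"], cfg.inputs["meta_source"])
        tgt_ft = sio.read_feature_table(cfg.inputs["features_target"], cfg.inputs["meta_target"])
        src_labels = sio.read_labels(cfg.inputs["labels_source"])["observed_label"]
        tgt_labels = sio.read_labels(cfg.inputs["labels_target"])["observed_label"]
        shared = Path(cfg.inputs["shared_features"]).read_text().split()
        report = run_transfer_experiment(
            src_ft, src_labels, tgt_ft, tgt_labels, shared, cfg.transfer_config()
        )

    metrics_df = report.to_frame().sort_values(["variant", "eval_set"]).reset_index(drop=True)
    metrics_df.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
    if report.filter_report is not None:
        report.filter_report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    summary = {
        "config": report.config,
        "filter_mode": report.filter_mode,
        "filter_counts": report.filter_report.counts if report.filter_report else None,
        "metrics": {
            variant: {es: {k: v for k, v in m.items()} for es, m in sets.items()}
            for variant, sets in report.metrics.items()
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("replica run complete: %s", outdir / "summary.json")
    return outdir
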