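"""Experiment configuration and end-to-end driver.

A YAML config declares the acquisition protocol, signal model,
preprocessing parameters, decoder families, hyperparameter grids,
fold count, selection modes and seeds; ``run_experiment`` executes
simulate -> preprocess -> nested CV -> statistics and writes a
deterministic directory layout with a hashed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io, stats
from .decoders import DEFAULT_GRIDS, FAMILIES
from .nested_cv import HyperparameterGrid, run_inter_subject, run_intra_subject
from .preprocess import bandpass_fir, clean_blinks, downsample
from .synthetic import (
    ProtocolSpec,
    SignalModelSpec,
    blink_topography,
    generate_dataset,
    vowels_protocol,
    words_protocol,
)

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "load_config"]

log = logging.getLogger("eegspeech")


@dataclass
class ExperimentConfig:
    protocol: dict = field(default_factory=dict)
    signal_model: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    families: list = field(default_factory=lambda: ["rlda"])
    grids: dict = field(default_factory=dict)
    k: int = 4
    modes: list = field(default_factory=lambda: ["intra"])
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def build_protocol(self) -> ProtocolSpec:
        p = dict(self.protocol)
        task = p.pop("task", "words")
        base = words_protocol if task == "words" else vowels_protocol
        if "channels" in p:
            p["channels"] = tuple(p["channels"])
        if "classes" in p:
            p["classes"] = tuple(p["classes"])
            return ProtocolSpec(task=task, **p)
        return base(**p)

    def build_signal_model(self) -> SignalModelSpec:
        m = dict(self.signal_model)
        m.setdefault("seed", self.seed)
        return SignalModelSpec(**m)

    def build_grid(self, family: str) -> HyperparameterGrid:
        dims = self.grids.get(family)
        if dims in (None, "default"):
            return HyperparameterGrid.default(family)
        return HyperparameterGrid(family=family, dimensions=dims)


load_config = ExperimentConfig.from_yaml


def validate_config(config: ExperimentConfig) -> list[str]:
    """Every violation reported with a path into the config."""
    errors = []
    if config.k < 2:
        errors.append(f"k: fold count must be >= 2, got {config.k}")
    for m in config.modes:
        if m not in ("intra", "inter"):
            errors.append(f"modes: unknown mode {m!r}")
    for fam in config.families:
        if fam not in FAMILIES:
            errors.append(f"families: unknown family {fam!r}")
            continue
        dims = config.grids.get(fam)
        if dims in (None, "default"):
            continue
        schema = DEFAULT_GRIDS[fam]
        for name, values in dims.items():
            if name not in schema:
                errors.append(
                    f"grids.{fam}.{name}: not a {fam} hyperparameter"
                )
                continue
            if not values:
                errors.append(f"grids.{fam}.{name}: empty dimension")
            for v in values:
                if v not in schema[name] and not isinstance(
                    schema[name][0], str
                ):
                    # numeric dims accept only declared grid values
                    if v not in schema[name]:
                        errors.append(
                            f"grids.{fam}.{name}: value {v!r} not in the "
                            f"declared grid {schema[name]}"
                        )
                elif isinstance(schema[name][0], str) and v not in schema[name]:
                    errors.append(
                        f"grids.{fam}.{name}: value {v!r} not in the "
                        f"declared grid {schema[name]}"
                    )
    try:
        config.build_protocol()
    except (ValueError, TypeError) as e:
        errors.append(f"protocol: {e}")
    try:
        config.build_signal_model()
    except (ValueError, TypeError) as e:
        errors.append(f"signal_model: {e}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def preprocess_dataset(dataset, config: ExperimentConfig):
    """Band-pass, ICA blink screen/removal, downsample, per subject."""
    pp = config.preprocess
    lo, hi = pp.get("band", (2.0, 40.0))
    target_fs = pp.get("target_fs", 128.0)
    threshold = pp.get("blink_threshold", 0.8)
    remove_blinks = pp.get("remove_blinks", True)
    out = []
    for s, trials in enumerate(dataset):
        t0 = time.perf_counter()
        x = bandpass_fir(trials, lo, hi)
        if remove_blinks:
            template = blink_topography(x.channel_names)
            x, screen = clean_blinks(
                x, template, threshold, seed=(config.seed + s) % (2**31)
            )
            log.info(
                "subject %s: %d blink component(s) removed",
                trials.subject_id, len(screen.flagged),
            )
        x = downsample(x, target_fs)
        log.info(
            "preprocessed %s in %.2fs", trials.subject_id,
            time.perf_counter() - t0,
        )
        out.append(x)
    return out


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the full study design at the configured scale."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    protocol = config.build_protocol()
    model = config.build_signal_model()

    t0 = time.perf_counter()
    raw = generate_dataset(protocol, model)
    io.save_dataset(out_dir / "dataset_raw.h5", raw)
    io.write_label_manifest(out_dir / "labels.csv", raw)
    log.info("simulated %d subjects in %.2fs", len(raw), time.perf_counter() - t0)

    clean = preprocess_dataset(raw, config)
    io.save_dataset(out_dir / "dataset_preprocessed.h5", clean)

    results = {}
    for family in config.families:
        grid = config.build_grid(family)
        for mode in config.modes:
            t0 = time.perf_counter()
            runner = run_intra_subject if mode == "intra" else run_inter_subject
            per_subject = runner(clean, grid, family, config.k, config.seed)
            for sid, res in per_subject.items():
                results[(sid, protocol.task, family, mode)] = res
            log.info(
                "nCV %s/%s done in %.2fs", family, mode,
                time.perf_counter() - t0,
            )

    stats.results_to_frame(results).to_csv(out_dir / "cv_results.csv", index=False)
    stats.assemble_accuracy_table(results).to_csv(
        out_dir / "accuracy_table.csv", index=False
    )
    stats.assemble_selection_table(results).to_csv(
        out_dir / "selected_hyperparameters.csv", index=False
    )
    stats.selection_frequencies(results).to_csv(
        out_dir / "selection_frequencies.csv", index=False
    )

    manifest = {
        "config": config.__dict__,
        "seed": config.seed,
        "files": {},
    }
    for p in sorted(out_dir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["files"][p.name] = _sha256(p)
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return out_dir
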