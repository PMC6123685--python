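"""End-to-end pipeline orchestration: simulate -> fit -> summarize.

One seeded configuration drives every stage; per-stage seeds are derived from
the master seed so that toggling stages on or off never changes the data
another stage sees.  A run manifest (config snapshot, input/output hashes,
per-stage statuses) is written at the end; identical config + seed reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .binding_fit import fit_curve, select_hill_coefficients, sensitization_table
from .io import write_binding_csv, write_fits_json, write_summary_tsv
from .synthetic_data import GeneratorConfig, gen_paper_panel

logger = logging.getLogger("ryrcicr")

_KNOWN_KEYS = {
    "stages", "seed", "out_dir", "wt_label", "fix_nA", "fix_nI",
    "select_hill", "noise_sd", "replicates", "inactivation",
}


class ConfigError(ValueError):
    """The pipeline configuration is invalid; all problems listed at once."""


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ("simulate", "fit", "summarize")
    seed: int = 1
    out_dir: str = "ryrcicr-out"
    wt_label: str = "WT"
    fix_nA: float = 2.0
    fix_nI: float = 1.0
    select_hill: bool = False
    noise_sd: float = 0.02
    replicates: int = 4
    inactivation: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        problems = [f"unknown config key {k!r}" for k in raw if k not in _KNOWN_KEYS]
        cfg = cls(**{k: v for k, v in raw.items() if k in _KNOWN_KEYS}) if not problems else None
        if cfg is not None:
            problems += cfg.validate()
        if problems:
            raise ConfigError("; ".join(problems))
        if isinstance(cfg.stages, list):
            cfg = dataclasses.replace(cfg, stages=tuple(cfg.stages))
        return cfg

    def validate(self) -> list[str]:
        problems = []
        known_stages = {"simulate", "fit", "summarize"}
        for stage in self.stages:
            if stage not in known_stages:
                problems.append(f"unknown stage {stage!r}")
        if not (0 <= self.seed < 2**31):
            problems.append("seed must be in [0, 2^31)")
        if self.fix_nA <= 0 or self.fix_nI <= 0:
            problems.append("Hill coefficients must be > 0")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        return problems


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_status: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")
        tmp.replace(path)  # atomic on POSIX


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    problems = config.validate()
    if problems:
        raise ConfigError("; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)

    curves = None
    fits = None
    failed = False
    for stage in config.stages:
        if failed:
            manifest.stage_status[stage] = "skipped (upstream failure)"
            continue
        try:
            if stage == "simulate":
                logger.info("simulate: generating synthetic panel (seed %d)", config.seed)
                panel = gen_paper_panel(
                    stage_seed(config.seed, "simulate"),
                    GeneratorConfig(
                        seed=config.seed,
                        noise_sd=config.noise_sd,
                        replicates=config.replicates,
                    ),
                )
                curves = panel["curves"]
                path = out / "binding.csv"
                write_binding_csv(curves, path)
                with open(out / "truth_manifest.json", "w") as fh:
                    json.dump(panel["manifest"], fh, indent=1, sort_keys=True)
                    fh.write("\n")
                manifest.outputs[str(path)] = _sha256(path)
            elif stage == "fit":
                if curves is None:
                    raise RuntimeError("fit stage requires simulate (or loaded curves)")
                na, ni = config.fix_nA, config.fix_nI
                if config.select_hill:
                    na, ni, _ = select_hill_coefficients(curves)
                    logger.info("fit: selected Hill coefficients nA=%g nI=%g", na, ni)
                fits = [
                    fit_curve(c, nA=na, nI=ni, inactivation=config.inactivation)
                    for c in curves
                ]
                path = out / "fits.json"
                write_fits_json(fits, path)
                manifest.outputs[str(path)] = _sha256(path)
            elif stage == "summarize":
                if fits is None:
                    raise RuntimeError("summarize stage requires fit")
                rows = sensitization_table(fits, wt_label=config.wt_label)
                path = out / "summary.tsv"
                write_summary_tsv(rows, path, fits)
                manifest.outputs[str(path)] = _sha256(path)
            manifest.stage_status[stage] = "ok"
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest.stage_status[stage] = f"failed: {exc}"
            failed = True

    manifest.write(out / "manifest.json")
    return manifest
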