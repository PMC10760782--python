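"""Run configuration, result serialization and run manifests.

Outputs are plain CSV (UTF-8, header row, ``.`` decimal); every run writes a
JSON manifest carrying the seed, parameter-set fingerprints and package
version so any artifact can be regenerated bit-identically.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .params import ParameterSet, Strategy, load_case_study, load_parameter_file

__all__ = ["RunConfig", "load_config", "write_manifest", "write_csv"]


@dataclass
class RunConfig:
    """Paths and settings for a pipeline run."""

    parameters: str | None = None  # scenario YAML; None -> bundled case study
    economics: str | None = None  # economics YAML; "bundled" -> synthetic fixture
    effect_only: bool = False
    n_iter: int = 5000
    seed: int = 0
    lambda_max: float = 150_000.0
    lambda_step: float = 1000.0
    output_dir: str = "results"
    extras: dict = field(default_factory=dict)

    def lambda_grid(self) -> np.ndarray:
        return np.arange(0.0, self.lambda_max + self.lambda_step / 2, self.lambda_step)


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extras"}
    kwargs = {k: v for k, v in doc.items() if k in known}
    extras = {k: v for k, v in doc.items() if k not in known}
    cfg = RunConfig(**kwargs, extras=extras)
    for name in ("parameters", "economics"):
        p = getattr(cfg, name)
        if p and p != "bundled" and not Path(p).exists():
            raise FileNotFoundError(f"config field {name!r}: file not found: {p}")
    return cfg


def load_scenario(cfg: RunConfig) -> ParameterSet:
    """Resolve a config to a ParameterSet (bundled fixtures by default)."""
    from importlib import resources

    eco_path = None
    if not cfg.effect_only:
        if cfg.economics in (None, "bundled"):
            eco_path = Path(str(resources.files("tccmodel").joinpath("data", "economics_synthetic.yaml")))
        else:
            eco_path = Path(cfg.economics)
    if cfg.parameters is None:
        main = Path(str(resources.files("tccmodel").joinpath("data", "case_study_main.yaml")))
    else:
        main = Path(cfg.parameters)
    return load_parameter_file(main, economics_path=eco_path)


def write_csv(frame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def write_manifest(
    out_dir: str | Path,
    *,
    command: str,
    seed: int | None,
    parameter_sets: dict[str, ParameterSet],
    outputs: list[str],
    notes: dict | None = None,
) -> Path:
    """Record provenance: seed, fingerprints, placeholder flags, versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "fingerprints": {k: ps.fingerprint() for k, ps in parameter_sets.items()},
        "economics_placeholder": {
            k: (ps.economics.placeholder if ps.economics is not None else None)
            for k, ps in parameter_sets.items()
        },
        "currency": next(iter(parameter_sets.values())).meta.get("currency") if parameter_sets else None,
        "price_year": next(iter(parameter_sets.values())).meta.get("price_year") if parameter_sets else None,
        "outputs": outputs,
        "notes": notes or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
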