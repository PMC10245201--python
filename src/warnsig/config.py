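"""Study configuration: YAML parsing and validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synth import PopulationSpec, RegionColorSpec, StudySpec


@dataclass
class Options:
    blackness_threshold: float = 0.2
    grid_size: int = 32
    transect_offset: float = 0.15
    hue_mode: str = "circular"          # or "linear" / "arithmetic" extraction
    back_mode: str = "pair"             # or "sum"
    ms_aggregate: str = "sum"           # or "mean"
    mds_variant: str = "classical"      # or "nonmetric"
    centroid_method: str = "gram"       # or "embedding"
    embedding_k: int = 2
    render_images: bool = False
    plots: bool = True


@dataclass
class StudyConfig:
    """Everything one pipeline run needs; the seed is always recorded."""

    seed: int
    sympatry: dict[str, list[str]]
    study: StudySpec | None = None        # synthetic input
    phenotype_csv: str | None = None      # pre-extracted input
    options: Options = field(default_factory=Options)

    def validate(self) -> "StudyConfig":
        if not self.sympatry:
            raise ConfigurationError("config is missing the sympatry map")
        if self.study is None and self.phenotype_csv is None:
            raise ConfigurationError(
                "config needs either a synthetic study spec or a phenotype CSV")
        if self.study is not None:
            self.study.validate()
        return self

    def digest(self) -> str:
        """Stable hash of the full configuration (the manifest reference)."""
        payload = {
            "seed": self.seed, "sympatry": self.sympatry,
            "phenotype_csv": self.phenotype_csv,
            "options": asdict(self.options),
            "study": _study_dict(self.study) if self.study else None,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _study_dict(study: StudySpec) -> dict:
    return {
        "seed": study.seed,
        "sympatry": {k: list(v) for k, v in study.sympatry.items()},
        "populations": [asdict(p) for p in study.populations],
    }


def study_from_dict(d: dict, seed: int | None = None,
                    sympatry: dict | None = None) -> StudySpec:
    pops = []
    for p in d["populations"]:
        colors = {k: RegionColorSpec(**v) for k, v in p["colors"].items()}
        pops.append(PopulationSpec(**{**p, "colors": colors}))
    return StudySpec(
        populations=pops,
        sympatry={k: list(v) for k, v in (sympatry or d.get("sympatry", {})).items()},
        seed=d.get("seed", seed if seed is not None else 0)).validate()


def load_config(path, seed_override: int | None = None) -> StudyConfig:
    """Read a YAML study configuration; ``seed_override`` wins over the file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigurationError("config file is not a YAML mapping")
    seed = seed_override if seed_override is not None else raw.get("seed", 0)
    sympatry = {k: list(v) for k, v in (raw.get("sympatry") or {}).items()}
    inp = raw.get("input", {}) or {}
    study = None
    if "study" in inp:
        study = study_from_dict(inp["study"], seed=seed, sympatry=sympatry or None)
        if not sympatry:
            sympatry = study.sympatry
    opts = Options(**(raw.get("options") or {}))
    cfg = StudyConfig(seed=int(seed), sympatry=sympatry, study=study,
                      phenotype_csv=inp.get("phenotype_csv"), options=opts)
    return cfg.validate()
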