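"""Run configuration: defaults, validation, and typo-tolerant key checking."""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad type, missing path)."""


PATH_FIELDS = (
    "mirnas", "interactions", "pathways", "orthologs",
    "deg_aging", "deg_parabiosis", "deg_hypothalamus", "cell_type_map",
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the published constants.

    fc_min 1.5 / alpha_deg 0.05 (aging up-filter), hypo_log2fc_min 0.1
    (hypothalamus up-filter), min_groups 2 (recurrence), min_types 5
    (widespread), min_shared 3 (shared-pathway summary), top_n 10
    (per-miRNA pathway ranking).
    """

    # input paths
    mirnas: str = ""
    interactions: str = ""
    pathways: str = ""
    orthologs: str = ""
    deg_aging: str = ""
    deg_parabiosis: str = ""
    deg_hypothalamus: str = ""
    cell_type_map: str = ""
    outdir: str = "mirderep_out"

    # policies
    evidence_policy: str = "all"  # "all" | "strong-only"
    universe_policy: str = "pathway-union"  # | "interaction-genes"
    ortholog_policy: str = "best-support"  # | "keep-all"

    # thresholds (defaults = published filter constants)
    alpha_enrichment: float = 0.05
    fc_min: float = 1.5
    hypo_log2fc_min: float = 0.1
    alpha_deg: float = 0.05
    min_groups: int = 2
    min_types: int = 5
    min_shared: int = 3
    top_n: int = 10

    seed: int = 0  # only used by the simulate stage

    def validate(self, check_paths: bool = True) -> "RunConfig":
        if self.evidence_policy not in ("all", "strong-only"):
            raise ConfigError(f"evidence_policy must be all|strong-only, got {self.evidence_policy!r}")
        if self.universe_policy not in ("pathway-union", "interaction-genes"):
            raise ConfigError(
                f"universe_policy must be pathway-union|interaction-genes, got {self.universe_policy!r}"
            )
        if self.ortholog_policy not in ("best-support", "keep-all"):
            raise ConfigError(f"ortholog_policy must be best-support|keep-all, got {self.ortholog_policy!r}")
        for name in ("alpha_enrichment", "alpha_deg"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0,1), got {v}")
        for name in ("fc_min", "hypo_log2fc_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("min_groups", "min_types", "top_n"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.min_shared < 2:
            raise ConfigError(f"min_shared must be >= 2, got {self.min_shared}")
        if check_paths:
            missing = [
                name for name in PATH_FIELDS
                if not getattr(self, name) or not Path(getattr(self, name)).exists()
            ]
            if missing:
                raise ConfigError(
                    "missing or nonexistent input path(s): "
                    + ", ".join(f"{n}={getattr(self, n)!r}" for n in missing)
                )
        return self

    def config_hash(self) -> str:
        # outdir determines where outputs land, not what they contain —
        # excluded so reruns into different directories stay byte-identical
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def validate_config(path: str | Path, check_paths: bool = True) -> RunConfig:
    """Load + validate a JSON/YAML run config; unknown keys are rejected
    with a closest-match suggestion."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    problems = []
    for key in sorted(set(data) - known):
        suggestion = difflib.get_close_matches(key, known, n=1)
        hint = f" (did you mean {suggestion[0]!r}?)" if suggestion else ""
        problems.append(f"unknown key {key!r}{hint}")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    try:
        cfg = RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    for f in fields(RunConfig):
        v = getattr(cfg, f.name)
        if f.name in PATH_FIELDS or f.name == "outdir":
            if not isinstance(v, str):
                raise ConfigError(f"{path}: {f.name} must be a string path, got {type(v).__name__}")
    return cfg.validate(check_paths=check_paths)
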