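"""Pipeline configuration: a single YAML file with full defaulting.

Every threshold of the cascade appears by name with its default, so the
effective numbers are auditable at the config surface; the effective
config (defaults merged with overrides) is echoed verbatim into the
output directory of every run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .prioritization import (
    DEFAULT_RESCUE_GENES,
    CascadeSettings,
    PrioritizationThresholds,
    RescueGeneList,
)
from .qc_frequency import QcThresholds
from .segregation import SegregationPolicy


@dataclass
class FamilyPaths:
    pedigree: str
    variants: str


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run."""

    variants: str = ""
    pedigree: str = ""
    annotations: str = ""
    output_dir: str = "famprio_out"
    rescue_genes: Optional[str] = None  # path; built-in list when absent
    other_families: list[FamilyPaths] = field(default_factory=list)
    qc: QcThresholds = field(default_factory=QcThresholds)
    segregation: SegregationPolicy = field(default_factory=SegregationPolicy)
    prioritization: PrioritizationThresholds = field(default_factory=PrioritizationThresholds)
    enable_rescue: bool = True
    enable_noncoding_track: bool = True
    enable_relatedness_matrix: bool = True
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        """Return all validation problems at once (empty = valid)."""
        errors: list[str] = []
        for name in ("variants", "pedigree", "annotations"):
            value = getattr(self, name)
            if not value:
                errors.append(f"paths.{name} is required")
            elif not Path(value).exists():
                errors.append(f"paths.{name}: file not found: {value}")
        if self.rescue_genes is not None and not Path(self.rescue_genes).exists():
            errors.append(f"paths.rescue_genes: file not found: {self.rescue_genes}")
        for i, fam in enumerate(self.other_families):
            for attr in ("pedigree", "variants"):
                p = getattr(fam, attr)
                if not Path(p).exists():
                    errors.append(f"paths.other_families[{i}].{attr}: file not found: {p}")
        return errors

    def cascade_settings(self) -> CascadeSettings:
        from .io_formats import read_rescue_genes

        if self.rescue_genes is not None:
            genes = RescueGeneList(read_rescue_genes(self.rescue_genes), provenance=self.rescue_genes)
        else:
            genes = DEFAULT_RESCUE_GENES
        return CascadeSettings(
            qc=self.qc,
            segregation=self.segregation,
            prioritization=self.prioritization,
            rescue_genes=genes,
            enable_rescue=self.enable_rescue,
            enable_noncoding_track=self.enable_noncoding_track,
        )


def _build(cls, data: dict, context: str, errors: list[str]):
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        errors.append(f"{context}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**{k: v for k, v in data.items() if k in known})
    except (TypeError, ValueError) as exc:
        errors.append(f"{context}: {exc}")
        return cls()


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load and validate a pipeline config YAML; raises with every
    problem listed at once."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    errors: list[str] = []
    paths = raw.get("paths", {}) or {}
    families = [
        _build(FamilyPaths, fam or {}, f"paths.other_families[{i}]", errors)
        for i, fam in enumerate(paths.get("other_families", []) or [])
    ]
    flags = raw.get("flags", {}) or {}
    config = PipelineConfig(
        variants=str(paths.get("variants", "") or ""),
        pedigree=str(paths.get("pedigree", "") or ""),
        annotations=str(paths.get("annotations", "") or ""),
        output_dir=str(paths.get("output_dir", "famprio_out")),
        rescue_genes=paths.get("rescue_genes"),
        other_families=families,
        qc=_build(QcThresholds, raw.get("qc", {}) or {}, "qc", errors),
        segregation=_build(SegregationPolicy, raw.get("segregation", {}) or {}, "segregation", errors),
        prioritization=_build(
            PrioritizationThresholds, raw.get("prioritization", {}) or {}, "prioritization", errors
        ),
        enable_rescue=bool(flags.get("rescue", True)),
        enable_noncoding_track=bool(flags.get("noncoding_track", True)),
        enable_relatedness_matrix=bool(flags.get("relatedness_matrix", True)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    errors += config.validate()
    if errors:
        raise ValueError(f"invalid config {path}:\n" + "\n".join(f"  - {e}" for e in errors))
    return config


def dump_effective_config(config: PipelineConfig, path: Union[str, Path]) -> None:
    """Echo the effective (defaults + overrides) config as YAML."""
    data = {
        "paths": {
            "variants": config.variants,
            "pedigree": config.pedigree,
            "annotations": config.annotations,
            "output_dir": config.output_dir,
            "rescue_genes": config.rescue_genes,
            "other_families": [asdict(f) for f in config.other_families],
        },
        "qc": asdict(config.qc),
        "segregation": asdict(config.segregation),
        "prioritization": asdict(config.prioritization),
        "flags": {
            "rescue": config.enable_rescue,
            "noncoding_track": config.enable_noncoding_track,
            "relatedness_matrix": config.enable_relatedness_matrix,
        },
        "log_level": config.log_level,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
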