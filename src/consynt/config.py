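"""Run configuration: YAML schema, validation, and defaults.

Unknown keys are rejected (a typo in a threshold name must not silently fall
back to a default) and every referenced input path is checked at validation
time, before any stage runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .counterparts import CounterpartThresholds
from .synteny import BlockCriteria


class ConfigError(ValueError):
    pass


@dataclass
class EnrichmentParams:
    alpha: float = 0.01
    continuity_correction: bool = False
    bonferroni: bool = False


@dataclass
class ConnectivityParams:
    n_sets: int = 4
    cutoff_sd: float = 3.0
    denominator: str = "all"


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    inputs: dict[str, object]
    backgrounds: dict[str, dict[str, tuple[int, int]]]
    studies: list[dict] = field(default_factory=list)
    correlation_species: str | None = None
    phenotype_species: str | None = None
    counterparts_params: CounterpartThresholds = field(
        default_factory=CounterpartThresholds
    )
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    synteny: BlockCriteria = field(default_factory=BlockCriteria)
    synteny_secondary_species: str | None = None
    phenotype_vocabulary: Path | None = None
    config_hash: str = ""


_TOP_KEYS = {
    "seed", "output_dir", "inputs", "backgrounds", "studies", "correlation",
    "phenotype_species", "counterparts_params", "enrichment", "connectivity",
    "synteny", "phenotype_vocabulary",
}
_INPUT_KEYS = {
    "risk_set", "edge_list", "phenotypes", "coordinates_primary",
    "coordinates_secondary", "coordinates_format", "gene_universe",
    "counterparts", "homology_hits",
}
_SYNTENY_KEYS = {
    "min_genes", "max_gap_bp", "max_secondary_chromosomes",
    "min_counterpart_coverage", "secondary_species",
}


def _check_keys(given: dict, allowed: set[str], where: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    raw_text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(raw_text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(data, _TOP_KEYS, str(path))
    for key in ("seed", "output_dir", "inputs"):
        if key not in data:
            raise ConfigError(f"{path}: missing required key {key!r}")

    inputs = dict(data["inputs"])
    _check_keys(inputs, _INPUT_KEYS, "inputs")
    for key, value in inputs.items():
        if key in {"counterparts", "homology_hits"}:
            for sp, p in value.items():
                if not Path(p).exists():
                    raise ConfigError(f"inputs.{key}.{sp}: no such file {p}")
        elif key != "coordinates_format" and not Path(value).exists():
            raise ConfigError(f"inputs.{key}: no such file {value}")

    backgrounds_raw = data.get("backgrounds", {})
    _check_keys(backgrounds_raw, {"conservation", "phenotypes"}, "backgrounds")
    backgrounds = {
        section: {k: (int(v[0]), int(v[1])) for k, v in table.items()}
        for section, table in backgrounds_raw.items()
    }

    synteny_raw = dict(data.get("synteny", {}))
    _check_keys(synteny_raw, _SYNTENY_KEYS, "synteny")
    secondary_species = synteny_raw.pop("secondary_species", None)

    correlation_raw = dict(data.get("correlation", {}))
    _check_keys(correlation_raw, {"species"}, "correlation")

    vocab = data.get("phenotype_vocabulary")
    if vocab is not None and not Path(vocab).exists():
        raise ConfigError(f"phenotype_vocabulary: no such file {vocab}")

    cp_raw = dict(data.get("counterparts_params", {}))
    if "length_ratio_bounds" in cp_raw:
        cp_raw["length_ratio_bounds"] = tuple(cp_raw["length_ratio_bounds"])

    return RunConfig(
        seed=int(data["seed"]),
        output_dir=Path(data["output_dir"]),
        inputs=inputs,
        backgrounds=backgrounds,
        studies=list(data.get("studies", [])),
        correlation_species=correlation_raw.get("species"),
        phenotype_species=data.get("phenotype_species"),
        counterparts_params=CounterpartThresholds(**cp_raw),
        enrichment=EnrichmentParams(**data.get("enrichment", {})),
        connectivity=ConnectivityParams(**data.get("connectivity", {})),
        synteny=BlockCriteria(**synteny_raw),
        synteny_secondary_species=secondary_species,
        phenotype_vocabulary=Path(vocab) if vocab else None,
        config_hash=hashlib.sha256(raw_text.encode()).hexdigest()[:16],
    )
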