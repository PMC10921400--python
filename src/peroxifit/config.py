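"""Run configuration: a single YAML document validated against an explicit
schema (unknown keys rejected), mapping onto the package's domain objects."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .forcefield import ExclusionPolicy, ForceConstants, ModelParameters, ParameterRanges

__all__ = ["RunConfig", "load_config"]

_SCHEMA = {
    "parameters": set(ModelParameters.__dataclass_fields__),
    "ranges": set(ParameterRanges.__dataclass_fields__),
    "force_constants": set(ForceConstants.__dataclass_fields__),
    "exclusion_policy": set(ExclusionPolicy.__dataclass_fields__),
    "u_g_min": None,
    "seed": None,
    "estimators": {"n_blocks", "msd_window", "hbond_r_cut", "hbond_theta_cut"},
    "optimizer": {"arch", "n_search", "n_refine", "delta_p", "max_iter"},
}


@dataclass
class RunConfig:
    """Validated configuration shared by the CLI commands."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    force_constants: ForceConstants = field(default_factory=ForceConstants)
    exclusion_policy: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    u_g_min: float = -1.53
    seed: int = 0
    estimators: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": asdict(self.parameters),
            "ranges": {k: list(v) for k, v in asdict(self.ranges).items()},
            "force_constants": asdict(self.force_constants),
            "exclusion_policy": asdict(self.exclusion_policy),
            "u_g_min": self.u_g_min,
            "seed": self.seed,
            "estimators": dict(self.estimators),
            "optimizer": dict(self.optimizer),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _check_keys(name: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ValueError(f"unknown key(s) in {name}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    _check_keys("config", doc, _SCHEMA)
    kwargs = {}
    if "parameters" in doc:
        _check_keys("parameters", doc["parameters"], _SCHEMA["parameters"])
        kwargs["parameters"] = ModelParameters(**doc["parameters"])
    if "ranges" in doc:
        _check_keys("ranges", doc["ranges"], _SCHEMA["ranges"])
        kwargs["ranges"] = ParameterRanges(**{k: tuple(v) for k, v in doc["ranges"].items()})
    if "force_constants" in doc:
        _check_keys("force_constants", doc["force_constants"], _SCHEMA["force_constants"])
        kwargs["force_constants"] = ForceConstants(**doc["force_constants"])
    if "exclusion_policy" in doc:
        _check_keys("exclusion_policy", doc["exclusion_policy"], _SCHEMA["exclusion_policy"])
        kwargs["exclusion_policy"] = ExclusionPolicy(**doc["exclusion_policy"])
    for key in ("u_g_min", "seed"):
        if key in doc:
            kwargs[key] = doc[key]
    for key in ("estimators", "optimizer"):
        if key in doc:
            _check_keys(key, doc[key], _SCHEMA[key])
            kwargs[key] = dict(doc[key])
    return RunConfig(**kwargs)
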