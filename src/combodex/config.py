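"""Run-configuration schema.

A run configuration is a YAML document with the sections ``io``,
``dose_response``, ``synergy``, ``markers`` and ``simulate``; every key has
a default so an empty file is a valid configuration.  Unknown keys are
tolerated with a warning so that configs written for newer versions keep
loading.
"""

from __future__ import annotations

import warnings
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, Field

from combodex.errors import ConfigError


class _Section(BaseModel):
    model_config = ConfigDict(extra="allow")


class IOConfig(_Section):
    wells: Optional[str] = None
    markers: Optional[str] = None
    qpcr: Optional[str] = None
    control_label: str = "control"


class DoseResponseConfig(_Section):
    #: fit on per-replicate wells instead of replicate means
    weight_replicates: bool = False


class SynergyConfig(_Section):
    #: interaction constant: 0 mutually exclusive, 1 mutually non-exclusive
    alpha: int = Field(default=0, ge=0, le=1)
    fa_min: float = Field(default=0.25, gt=0.0, lt=1.0)
    fa_max: float = Field(default=0.90, gt=0.0, lt=1.0)
    fa_step: float = Field(default=0.05, gt=0.0)
    #: additive band half-width on CI
    ci_tolerance: float = Field(default=0.05, ge=0.0)
    #: additive band half-width on delta-Bliss
    bliss_tolerance: float = Field(default=0.01, ge=0.0)
    #: interpolate single-agent fa at unmeasured component doses
    interpolate_singles: bool = False


class MarkersConfig(_Section):
    control_group: str = "control"


class RunConfig(_Section):
    io: IOConfig = Field(default_factory=IOConfig)
    dose_response: DoseResponseConfig = Field(default_factory=DoseResponseConfig)
    synergy: SynergyConfig = Field(default_factory=SynergyConfig)
    markers: MarkersConfig = Field(default_factory=MarkersConfig)
    simulate: Optional[dict[str, Any]] = None
    seed: int = 0


_KNOWN_TOP = set(RunConfig.model_fields)


def parse_config(raw: dict[str, Any] | None) -> RunConfig:
    """Validate a parsed YAML mapping into a :class:`RunConfig`.

    Raises :class:`~combodex.errors.ConfigError` naming the offending key
    on schema violations; unknown keys produce a warning only.
    """
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    for key in raw:
        if key not in _KNOWN_TOP:
            warnings.warn(f"unknown configuration key {key!r} ignored", stacklevel=2)
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError carries per-key locs
        raise ConfigError(f"invalid configuration: {exc}") from exc
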