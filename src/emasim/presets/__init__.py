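"""Shipped protocol presets (JSON) and their loader.

Three presets are bundled:

* ``cz_de_original`` — the original protocol (30-min sedentary rule; 10-min
  walking/running rules with 2 above-threshold outliers for walking).
* ``ie_fr_relaxed`` — the relaxed variant used at the later sites (20-min
  sedentary rule; 5-min walking/running rules with 2 below-threshold
  outliers).
* ``optimal`` — the settings the trigger-optimisation simulations selected
  (20-min sedentary; 5-min walking with below-threshold outliers and a
  17-min backwards span).  It carries no running rule.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel

from ..detection import EventRule
from ..triggers import PromptLifecycle, ScheduleConstraints, SyncModel

PRESET_NAMES = ("cz_de_original", "ie_fr_relaxed", "optimal")

#: Which preset each study site ran.
SITE_PRESETS = {"CZ": "cz_de_original", "DE": "cz_de_original",
                "FR": "ie_fr_relaxed", "IE": "ie_fr_relaxed"}


class RuleWithConstraints(BaseModel):
    rule: EventRule
    constraints: ScheduleConstraints


class ProtocolPreset(BaseModel):
    """A full event-based protocol configuration."""

    name: str
    description: str = ""
    sync: SyncModel = SyncModel()
    lifecycle: PromptLifecycle = PromptLifecycle()
    total_daily_cap: int | None = 10
    rules: dict[str, RuleWithConstraints]

    @property
    def rules_by_kind(self) -> dict[str, EventRule]:
        return {k: rc.rule for k, rc in self.rules.items()}

    @property
    def constraints_by_kind(self) -> dict[str, ScheduleConstraints]:
        return {k: rc.constraints for k, rc in self.rules.items()}


def load_preset(name_or_path: str | Path) -> ProtocolPreset:
    """Load a bundled preset by name, or any preset JSON by path."""
    p = Path(name_or_path)
    if p.suffix == ".json" and p.exists():
        data = json.loads(p.read_text())
    else:
        if name_or_path not in PRESET_NAMES:
            raise ValueError(
                f"unknown preset {name_or_path!r}; bundled presets: {PRESET_NAMES}"
            )
        ref = resources.files("emasim.presets").joinpath(f"{name_or_path}.json")
        data = json.loads(ref.read_text())
    return ProtocolPreset.model_validate(data)
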