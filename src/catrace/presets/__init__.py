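"""Bundled cohort presets and their loader."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from ..simulate import CohortPreset

PresetKey = tuple[str, str, str]  # (stage, stimulus, group)


def load_presets(path: str | Path | None = None) -> dict[PresetKey, CohortPreset]:
    """Load cohort presets from YAML; defaults to the bundled study presets."""
    if path is None:
        text = (resources.files("catrace") / "presets" / "paper.yaml").read_text()
    else:
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    defaults = data.get("defaults", {})
    presets: dict[PresetKey, CohortPreset] = {}
    for cond in data["conditions"]:
        preset = CohortPreset(**{**defaults, **cond})
        presets[(preset.stage, preset.stimulus, preset.group)] = preset
    return presets


def get_preset(
    stage: str, stimulus: str, group: str, path: str | Path | None = None
) -> CohortPreset:
    return load_presets(path)[(stage, stimulus, group)]
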