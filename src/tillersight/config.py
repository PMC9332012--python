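"""Run configuration: the pipeline operating point and per-date thresholds.

Only the binarization threshold ratio varies between observation dates
(illumination and growth stage shift the green statistics); every other
parameter is held fixed at the operating point: ``min_component_area=500``,
``step=7``, Condition-1 window 25x12, Condition-2 window 31x20.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .tipdetect import WindowSpec

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters for one run.

    ``thresholds`` maps date labels (matched as substrings of patch file
    names) to threshold ratios; ``k`` is the fallback used when no label
    matches, and the value actually consumed by the pipeline stages.
    """

    k: float = 1.1
    thresholds: dict[str, float] = field(default_factory=dict)
    min_component_area: int = 500
    step: int = 7
    window: WindowSpec = field(default_factory=WindowSpec)
    subtract_main_stem: bool = False

    def __post_init__(self) -> None:
        for label, k in {**self.thresholds, "k": self.k}.items():
            if not (0.5 <= k <= 2.0):
                raise ValueError(f"threshold ratio {label}={k} outside [0.5, 2.0]")
        if self.step < 2:
            raise ValueError("step must be >= 2")
        if self.min_component_area < 0:
            raise ValueError("min_component_area must be >= 0")

    def for_patch(self, patch_name: str) -> "RunConfig":
        """Resolve the per-date threshold for a patch by matching date labels
        against its file name (longest label wins)."""
        matches = [lbl for lbl in self.thresholds if lbl in patch_name]
        if not matches:
            return self
        label = max(matches, key=len)
        return replace(self, k=self.thresholds[label])


def load_config(path) -> RunConfig:
    """Load a YAML config file.

    Recognised keys: ``k``, ``thresholds`` (mapping of date label -> ratio),
    ``min_component_area``, ``step``, ``window`` (mapping with
    ``cond1_width`` etc.), ``subtract_main_stem``.  Unknown keys raise, so a
    typo cannot silently fall back to a default.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"k", "thresholds", "min_component_area", "step", "window", "subtract_main_stem"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    if "window" in kwargs:
        kwargs["window"] = WindowSpec(**kwargs["window"])
    if "thresholds" in kwargs:
        kwargs["thresholds"] = {str(k): float(v) for k, v in kwargs["thresholds"].items()}
    return RunConfig(**kwargs)
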