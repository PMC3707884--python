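"""Run configuration shared by the CLI, the retrospective protocol and scripts.

Defaults are the tuned operating point: all six measurements, C = 2^-3.5,
w_ratio = 2^0.6, 10 folds, 300 bp minimum intergenic length, dicodon/di-amino
windows sliding by one codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    selection: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    C: float = 2.0 ** -3.5
    w_ratio: float = 2.0 ** 0.6
    folds: int = 10
    seed: int = 0
    min_intergenic_len: int = 300
    dicodon_step: int = 3

    def __post_init__(self) -> None:
        sel = tuple(sorted(set(int(s) for s in self.selection)))
        object.__setattr__(self, "selection", sel)
        if not sel or any(s not in range(1, 7) for s in sel):
            raise ValueError("selection must be a non-empty subset of {1..6}")
        if self.C <= 0 or self.w_ratio <= 0:
            raise ValueError("C and w_ratio must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.min_intergenic_len < 0:
            raise ValueError("min_intergenic_len must be >= 0")
        if self.dicodon_step not in (3, 6):
            raise ValueError("dicodon_step must be 3 or 6")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a key/value YAML config; keyword overrides win over the file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "selection" in raw and raw["selection"] is not None:
            raw["selection"] = tuple(raw["selection"])
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        if "selection" in clean:
            clean["selection"] = tuple(clean["selection"])
        return replace(self, **clean)
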