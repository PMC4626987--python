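"""Pipeline configuration: YAML in, validated dataclass out.

Conventions stamped on all outputs: latitudes ascend south to north,
longitudes lie in [-180, 180), all year ranges are inclusive on both ends,
365-day calendar throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synth import SynthConfig


def _pair(x) -> tuple[int, int]:
    a, b = x
    return int(a), int(b)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    baseline: tuple[int, int] = (1961, 1990)
    slices: tuple[tuple[int, int], ...] = (
        (2011, 2040), (2041, 2070), (2071, 2100),
    )
    window: int = 11
    n_iter: int = 1000
    seed: int = 42
    trend_categories: tuple[str, ...] = ("Hda2",)
    denominator: str = "inclusive"
    alternative: str = "increasing"
    cities: str | None = None  # path to a CSV with columns city, lat, lon
    stages: tuple[str, ...] = (
        "synth", "bias", "atmax", "counts", "slices", "trends",
    )

    def __post_init__(self) -> None:
        for y0, y1 in self.slices:
            if y0 < self.baseline[0]:
                raise ValueError(
                    f"slice {y0}-{y1} precedes the baseline start {self.baseline[0]}"
                )
        if self.denominator not in ("inclusive", "difference"):
            raise ValueError("denominator must be 'inclusive' or 'difference'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"] = asdict(self.synth)
        return d

    def config_hash(self) -> str:
        """Stable hash over every setting, including convention flags."""
        canon = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = SynthConfig(**d.pop("synth", {}))
        if "baseline" in d:
            d["baseline"] = _pair(d["baseline"])
        if "slices" in d:
            d["slices"] = tuple(_pair(s) for s in d["slices"])
        if "trend_categories" in d:
            d["trend_categories"] = tuple(d["trend_categories"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(synth=synth, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _listify(obj):
    """Tuples/arrays -> lists so YAML dumps canonically."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
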