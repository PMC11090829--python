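"""Run configuration: one validated object threaded through the CLI.

Every knob the pipeline exposes lives here with its default, and the full
configuration is serialized into each output manifest so a run can be
reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    # image quantitation
    channel_roles: dict[str, int] = field(default_factory=lambda: {"k8": 0, "k14": 1})
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_object_px: int = 25
    tissue_policy: str = "union_k8_k14"  # | "dedicated_channel"
    tile_side_px: int | None = None  # None: derive from organoid set
    min_tissue_frac: float = 0.05
    tissue_filter_scope: str = "all"  # "all" | "ST"
    nucleus_px_range: tuple[int, int] = (50, 5000)
    # binning
    pseudocount_px: int = 1
    quantile_method: str = "linear"
    # divergence
    norm_constant: float = 0.56
    mode: str = "pooled"  # "pooled" | "mean_pairwise" | "both"
    # sample size
    least_bin_freq: float = 0.08
    confidence: float = 0.85
    # run
    seed: int = 0
    out_dir: str = "orgfid_out"
    log_level: str = "INFO"

    _CHOICES = {
        "threshold_method": ("otsu", "fixed"),
        "tissue_policy": ("union_k8_k14", "dedicated_channel"),
        "tissue_filter_scope": ("all", "ST"),
        "mode": ("pooled", "mean_pairwise", "both"),
    }

    def __post_init__(self) -> None:
        for name, choices in self._CHOICES.items():
            if getattr(self, name) not in choices:
                raise ConfigurationError(
                    f"{name}={getattr(self, name)!r} not one of {choices}"
                )
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigurationError("threshold_method='fixed' needs fixed_threshold")
        if not 0 <= self.min_tissue_frac < 1:
            raise ConfigurationError("min_tissue_frac must be in [0, 1)")
        if self.norm_constant <= 0:
            raise ConfigurationError("norm_constant must be > 0")
        if self.pseudocount_px < 1:
            raise ConfigurationError("pseudocount_px must be >= 1")
        self.channel_roles = {k: int(v) for k, v in self.channel_roles.items()}
        for required in ("k8", "k14"):
            if required not in self.channel_roles:
                raise ConfigurationError(f"channel_roles must map {required!r}")
        self.nucleus_px_range = tuple(self.nucleus_px_range)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(raw)}")
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nucleus_px_range"] = list(self.nucleus_px_range)
        return d
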