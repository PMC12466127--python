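"""Pipeline configuration: every tunable with its default, YAML-loadable."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline tunables.

    Fractions are in [0, 1]; distances in bp. ``f_min``/``f_max`` are the
    recurrence thresholds for group-specific region calling; ``flank``
    sets the variant window half-width (window length ``2*flank + 1``);
    ``hotspot_gap`` the single-linkage clustering distance;
    ``neighborhood_bp`` the curated-gene search radius; ``site_threshold``
    and ``delta_min`` the motif-site and shift-magnitude cutoffs.
    """

    f_min: float = 0.5
    f_max: float = 0.1
    min_overlap_frac: float = 0.0
    class_priority: tuple[str, ...] = ("promoter", "IE", "EE")
    flank: int = 7
    hotspot_gap: int = 7
    neighborhood_bp: int = 1_000_000
    top_k: int = 5
    top_n: int = 3
    site_threshold: float = 0.80
    delta_min: float = 0.05
    callability_threshold: float = 0.85
    concordance_threshold: float = 0.75
    pseudocount: float = 0.25
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha_sig: float = 0.001
    alpha_ns: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        self.class_priority = tuple(self.class_priority)
        self.background = tuple(self.background)
        self.validate()

    def validate(self) -> None:
        fractions = {
            "f_min": self.f_min,
            "f_max": self.f_max,
            "min_overlap_frac": self.min_overlap_frac,
            "site_threshold": self.site_threshold,
            "delta_min": self.delta_min,
            "callability_threshold": self.callability_threshold,
            "concordance_threshold": self.concordance_threshold,
            "alpha_sig": self.alpha_sig,
            "alpha_ns": self.alpha_ns,
        }
        for name, value in fractions.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]; got {value}")
        if self.f_max >= self.f_min:
            raise ValueError(
                f"f_max ({self.f_max}) must be strictly below f_min "
                f"({self.f_min})"
            )
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if self.hotspot_gap < 0:
            raise ValueError("hotspot_gap must be >= 0")
        if self.top_k < 1 or self.top_n < 1:
            raise ValueError("top_k and top_n must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if sorted(self.class_priority) != sorted(("promoter", "IE", "EE")):
            raise ValueError("class_priority must permute promoter/IE/EE")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_priority"] = list(self.class_priority)
        d["background"] = list(self.background)
        return d
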