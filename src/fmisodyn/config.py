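"""Run configuration shared by the pipeline stages and the CLI.

Defaults follow the study conditions: TBR threshold 1.4, fixed bin width
W = 0.01 g/mL, Spearman redundancy cut-off |r| > 0.8, significance level
α = 0.05, B = 1000 bootstrap replicates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .radiomics import RadiomicsConfig


@dataclass(frozen=True)
class RunConfig:
    tbr: float = 1.4
    inclusive_threshold: bool = True
    min_component_voxels: int = 0
    bin_width: float = 0.01
    q_levels: int = 64
    wavelet: str = "coif1"
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    cp_rule: str = "median"              # or "fixed"
    cp_threshold: float | None = None
    resolved_to_high: bool = False
    endpoints: tuple[str, ...] = ("os", "pfs", "lr", "dm")
    spearman_r: float = 0.8
    features: tuple[str, ...] | None = None
    auc_for: str = "significant"         # "significant" | "all" | "none"

    def radiomics(self) -> RadiomicsConfig:
        return RadiomicsConfig(
            bin_width=self.bin_width,
            q_levels=self.q_levels,
            wavelet=self.wavelet,
            features=self.features,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        mapping = dict(mapping)
        for key in ("endpoints", "features"):
            if key in mapping and mapping[key] is not None:
                mapping[key] = tuple(mapping[key])
        return cls(**mapping)
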