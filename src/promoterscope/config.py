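"""Pipeline configuration with per-value provenance and a stable hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["PipelineConfig"]

#: provenance of each default: "published" = printed in the source study's
#: methods/legends, "default" = this package's own choice.
PROVENANCE = {
    "max_gap": "published",
    "singleton_min_tpm": "published",
    "min_cluster_tpm": "published",
    "min_active_tpm": "published",
    "heatmap_flank": "published",
    "metaprofile_window": "published",
    "chipseq_score_window": "published",
    "nexus_score_window": "published",
    "n_quantiles": "published",
    "search_upstream": "default",
    "search_downstream": "default",
    "ses_bin_size": "default",
    "pseudocount": "default",
    "min_score_fraction": "default",
    "seed": "default",
}


@dataclass
class PipelineConfig:
    """All tunable thresholds and windows of the pipeline."""

    max_gap: int = 40
    singleton_min_tpm: float = 5.0
    min_cluster_tpm: float = 12.0
    min_active_tpm: float = 2.0
    search_upstream: int = 500
    search_downstream: int = 300
    heatmap_flank: int = 500          # 1001-bp TSS-centered heatmap window
    metaprofile_window: int = 201
    chipseq_score_window: int = 501
    nexus_score_window: int = 101
    n_quantiles: int = 10
    ses_bin_size: int = 1000
    pseudocount: float = 1.0
    min_score_fraction: float = 0.8
    seed: int = 0
    provenance: dict = field(default_factory=lambda: dict(PROVENANCE))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("provenance", None)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "provenance"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
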