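"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a differential network analysis run.

    tau : correlation-magnitude retention threshold (closed comparison).
    B : configuration-model replicates per group network.
    seed : root seed for all randomness in the run.
    degree_mode : "weighted" (sum of |r|) or "count" (edge count).
    missing_policy : "fail" or "drop-subject", applied at ingest.
    zero_variance_policy : "fail" or "zero", applied to constant VOIs.
    normalize : divide each subject by their whole-brain mean before analysis.
    n_swaps : swap attempts per rewiring (None = 10x edge count).
    precision : decimals used by the report writer (machine output keeps full
        precision).
    """

    tau: float = 0.7
    B: int = 1000
    seed: int = 0
    degree_mode: str = "weighted"
    missing_policy: str = "fail"
    zero_variance_policy: str = "fail"
    normalize: bool = True
    n_swaps: int | None = None
    out_dir: str = "petnet-out"
    precision: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError(f"tau must lie in (0, 1], got {self.tau}")
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B}")
        if self.degree_mode not in ("weighted", "count"):
            raise ValueError(f"unknown degree_mode {self.degree_mode!r}")
        if self.missing_policy not in ("fail", "drop-subject"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.zero_variance_policy not in ("fail", "zero"):
            raise ValueError(f"unknown zero_variance_policy {self.zero_variance_policy!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def fingerprint(self) -> str:
        """Stable hash of the configuration; recorded in every result/manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
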