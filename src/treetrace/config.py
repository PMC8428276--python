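"""Run configuration: a validated, hand-editable YAML mapping.

Unknown keys are rejected so typos fail fast instead of silently falling
back to defaults.  Every output file written by the pipeline carries the
configuration hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class LeafGroupSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    members: list[int]
    structure: Literal["linear", "parallel", "mst"] = "parallel"


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    # input
    input_path: Optional[str] = None
    input_format: Optional[Literal["mtx", "csv", "h5"]] = None
    layer: Literal["counts", "lognorm", "scaled", "zscore"] = "counts"
    preset: Optional[Literal["rare_lineage", "six_bifurcations"]] = None

    # preprocessing
    min_features_per_cell: int = 200
    min_cells_per_feature: int = 3
    scale_factor: float = 1e4
    n_hvg: int = 2000
    clip: float = 10.0

    # PCA / graph / clustering
    n_pcs: int = 10
    pc_selection: Optional[Literal["elbow", "cumvar"]] = None
    cumvar_target: float = 0.9
    k: int = 12
    algorithm: Literal["leiden", "louvain"] = "leiden"
    resolution: float = 1.0
    seed: int = 0

    # embedding
    hubs_per_cluster: int = 1
    embedding_dim: int = 3

    # trajectory
    root: Optional[int] = None
    leaf_groups: list[LeafGroupSpec] = Field(default_factory=list)

    # trend analysis
    n_bins: int = 0  # 0 -> min(100, branch size)
    n_ranks: int = 3
    lambda_sparse: Optional[float] = None
    lambda_smooth: Optional[float] = None

    # output
    outdir: str = "treetrace_out"

    # ------------------------------------------------------------------
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})
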