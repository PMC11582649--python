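"""Run configuration: a single validated key-value file driving the CLI.

Defaults mirror the conventional settings for this kind of study:
temperature 0.1, 100,000 bootstrap iterations at alpha 0.05, and a
PCA-200 / perplexity-30 / seed-42 projection.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class SamplerSettings(BaseModel):
    method: str = "knn"
    k: int = 5
    exclude_same_patient: bool = True

    @field_validator("method")
    @classmethod
    def _method(cls, v: str) -> str:
        if v not in ("knn", "random"):
            raise ValueError("sampler.method must be 'knn' or 'random'")
        return v


class BackendSettings(BaseModel):
    name: str = "mock"
    temperature: float = Field(0.1, ge=0)
    max_retries: int = Field(3, ge=1)
    error_rate: float = Field(0.0, ge=0, le=1)


class BootstrapSettings(BaseModel):
    iterations: int = Field(100_000, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    seed: int | None = None


class ProjectionSettings(BaseModel):
    pca_components: int = Field(200, ge=1)
    perplexity: float = Field(30.0, gt=0)
    seed: int = 42


class RunConfig(BaseModel):
    manifest_path: str
    embeddings_path: str
    labels: list[str]
    aliases: dict[str, str] = {}
    excluded_labels: list[str] = []
    sampler: SamplerSettings = SamplerSettings()
    backend: BackendSettings = BackendSettings()
    bootstrap: BootstrapSettings = BootstrapSettings()
    projection: ProjectionSettings = ProjectionSettings()
    output_dir: str = "runs"
    master_seed: int = 0

    @model_validator(mode="after")
    def _labels_nonempty(self) -> "RunConfig":
        if len(self.labels) < 2:
            raise ValueError("need at least 2 labels")
        return self

    def derived_seed(self, role: str) -> int:
        """Independent per-role seed derived from the master seed."""
        import hashlib

        h = hashlib.sha256(f"{self.master_seed}:{role}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)

    def validate_paths(self) -> None:
        for p in (self.manifest_path,):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
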