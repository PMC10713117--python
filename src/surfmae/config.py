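"""Configuration objects for the surface pipeline, network and training.

Defaults mirror the published protocol: surfaces sampled at 1 Å and cut to
2048 points, curvatures at scales 1/2/3/5/10 Å, 16 chemical neighbours,
mask ratio 0.6, AdamW with lr 1e-3, batch 16, 50 epochs. All configs reject
unknown keys so a typo in a YAML file fails loudly rather than silently
falling back to a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "H": 1.10,
    "O": 1.52,
    "N": 1.55,
    "S": 1.80,
    "Se": 1.90,
}

#: canonical element order used for all one-hot encodings
ELEMENTS: tuple[str, ...] = ("C", "H", "O", "N", "S", "Se")


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SurfaceConfig(_StrictModel):
    """Parameters of the smooth-distance-function surface construction."""

    smoothing_sigma: float = Field(0.5, gt=0, description="SDF soft-min temperature, Å")
    resolution: float = Field(1.0, gt=0, description="grid-thinning cell edge, Å")
    level_tolerance: float = Field(0.05, gt=0, description="max |SDF| of a kept point, Å")
    target_points: int = Field(2048, ge=1, description="points per surface after subsampling")
    max_points: int = Field(20000, ge=1, description="chains with more raw points are rejected")
    curvature_scales: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0, 5.0, 10.0])
    n_chem_neighbors: int = Field(16, ge=1)
    vdw_radii: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    @field_validator("curvature_scales")
    @classmethod
    def _scales_increasing(cls, v):
        if len(v) == 0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("curvature_scales must be non-empty and strictly increasing")
        return v

    @field_validator("vdw_radii")
    @classmethod
    def _radii_cover_elements(cls, v):
        missing = [e for e in ELEMENTS if e not in v]
        if missing:
            raise ValueError(f"vdw_radii missing elements: {missing}")
        return v


class PatchConfig(_StrictModel):
    """Patchification: g FPS centers, k' nearest neighbours each, mask ratio m."""

    g: int = Field(128, ge=1)
    k_prime: int = Field(32, ge=1)
    m: float = Field(0.6, ge=0)

    @field_validator("m")
    @classmethod
    def _m_in_range(cls, v):
        if not (0 <= v < 1):
            raise ValueError("m must lie in [0, 1)")
        return v


class ModelConfig(_StrictModel):
    d: int = Field(384, ge=8, description="token width")
    encoder_depth: int = Field(12, ge=1)
    encoder_heads: int = Field(6, ge=1)
    decoder_depth: int = Field(4, ge=1)
    decoder_heads: int = Field(6, ge=1)
    mlp_ratio: int = Field(4, ge=1)
    chem_dim: int = Field(6, description="point-encoder output width (fixed)")
    fused_dim: int = Field(16, description="chem + curvature feature width (fixed)")
    n_classes: int = Field(7, ge=2, description="pocket classifier classes")
    descriptor_dim: int = Field(64, ge=1)
    mp_hidden: int = Field(32, ge=1, description="message-passing hidden width")
    pos_n_freq: int = Field(32, ge=1, description="Fourier features per axis pair")
    pos_length_scale: float = Field(1.5, gt=0, description="positional bandwidth, Å")

    @field_validator("chem_dim")
    @classmethod
    def _chem_fixed(cls, v):
        if v != 6:
            raise ValueError("chem_dim is fixed at 6")
        return v

    @field_validator("fused_dim")
    @classmethod
    def _fused_fixed(cls, v):
        if v != 16:
            raise ValueError("fused_dim is fixed at 16")
        return v

    def validate_heads(self) -> "ModelConfig":
        if self.d % self.encoder_heads or self.d % self.decoder_heads:
            raise ValueError("token width d must be divisible by the head counts")
        return self


class TrainConfig(_StrictModel):
    lr: float = Field(1e-3, gt=0)
    batch_size: int = Field(16, ge=1)
    epochs: int = Field(50, ge=1)
    weight_decay: float = Field(0.01, ge=0)
    adam_beta2: float = Field(0.999, gt=0, lt=1)
    schedule: str = Field("constant", pattern="^(constant|cosine)$")
    finetune_lr: float = Field(1e-4, gt=0)
    finetune_epochs: int = Field(50, ge=1)

class RunConfig(_StrictModel):
    surface: SurfaceConfig = Field(default_factory=SurfaceConfig)
    patches: PatchConfig = Field(default_factory=PatchConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    seed: int = 0


def load_config(source: str | Path) -> RunConfig:
    """Load a RunConfig from YAML text or a path to a YAML file.

    Empty input yields all defaults. Unknown keys, type mismatches and
    out-of-range values raise ``ValueError`` naming the offending key.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).is_file()):
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    try:
        cfg = RunConfig(**data)
    except Exception as exc:  # pydantic ValidationError carries key locations
        raise ValueError(f"invalid config: {exc}") from exc
    cfg.model.validate_heads()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
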