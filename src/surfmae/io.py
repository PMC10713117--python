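"""Serialization: HDF5 surface caches and checkpoint archives.

HDF5 schema (schema_version 1):
    /surface/{points, normals, curvatures, chem_raw, chem_neighbor_idx}
    /atoms/{coords, types}
    attrs: config_json, seed, schema_version, chain_id, source

Checkpoints are ``.npz`` weight archives with a JSON sidecar recording the
model/surface configuration, seed and any training metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import ModelConfig, SurfaceConfig
from .ingest import AtomCloud
from .surface import SurfaceCloud

SCHEMA_VERSION = 1

_SURFACE_KEYS = ("points", "normals", "curvatures", "chem_raw", "chem_neighbor_idx")


class SchemaError(ValueError):
    """Cache file does not match the expected HDF5 schema."""


def save_surface(cloud: SurfaceCloud, path: str | Path,
                 cfg: SurfaceConfig | None = None) -> None:
    if cloud.atoms is None:
        raise ValueError("cannot cache a SurfaceCloud without its atom cloud")
    with h5py.File(path, "w") as f:
        grp = f.create_group("surface")
        for key in _SURFACE_KEYS:
            grp.create_dataset(key, data=getattr(cloud, key))
        atoms = f.create_group("atoms")
        atoms.create_dataset("coords", data=cloud.atoms.coords)
        atoms.create_dataset("types", data=cloud.atoms.types)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["seed"] = -1 if cloud.seed is None else cloud.seed
        f.attrs["chain_id"] = cloud.atoms.chain_id
        f.attrs["source"] = cloud.atoms.source
        f.attrs["config_json"] = json.dumps(cfg.model_dump() if cfg else {})


def load_surface(path: str | Path) -> SurfaceCloud:
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(f"{path}: unsupported schema version "
                              f"{f.attrs.get('schema_version')!r}")
        for key in _SURFACE_KEYS:
            if f"surface/{key}" not in f:
                raise SchemaError(f"{path}: missing dataset surface/{key}")
        if "atoms/coords" not in f or "atoms/types" not in f:
            raise SchemaError(f"{path}: missing atoms group")
        data = {key: f[f"surface/{key}"][()] for key in _SURFACE_KEYS}
        atoms = AtomCloud(f["atoms/coords"][()], f["atoms/types"][()],
                          chain_id=str(f.attrs.get("chain_id", "")),
                          source=str(f.attrs.get("source", "")))
        seed = int(f.attrs["seed"])
        return SurfaceCloud(atoms=atoms, seed=None if seed < 0 else seed, **data)


def surface_cache_roundtrip(cloud: SurfaceCloud, path: str | Path,
                            cfg: SurfaceConfig | None = None) -> SurfaceCloud:
    """Write then re-read a surface cache; arrays round-trip bit-identically."""
    save_surface(cloud, path, cfg)
    return load_surface(path)


def save_checkpoint(path: str | Path, model, meta: dict | None = None) -> None:
    """Weight archive + JSON sidecar (same stem, ``.json`` suffix)."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = {
        "model_config": model.cfg.model_dump(),
        "k_prime": model.k_prime,
        "n_parameters": model.n_parameters(),
    }
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path):
    """Rebuild a SurfaceMAE from a checkpoint archive and its sidecar."""
    from .model import SurfaceMAE

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**sidecar["model_config"])
    model = SurfaceMAE(cfg, k_prime=sidecar["k_prime"], seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as arch:
        model.load_state_dict(dict(arch))
    return model, sidecar
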