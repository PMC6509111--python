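"""File formats: NIfTI volumes with JSON condition sidecars, BIDS-style
events TSV, rating CSV, and YAML run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volumes import PatternSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_pattern_set",
    "load_pattern_set",
    "pattern_set_from_files",
    "save_events",
    "load_events",
    "save_ratings",
    "load_ratings",
    "load_config",
    "save_config",
]


def save_volume(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_pattern_set(ps: PatternSet, path: str | Path) -> Path:
    """Write a labeled 4-D stack (conditions last) plus a JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(ps.data, 0, -1)
    nib.save(nib.Nifti1Image(data, ps.affine), str(path))
    meta = {
        "subject": ps.subject,
        "conditions": [[t, s] for t, s in ps.conditions],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_pattern_set(path: str | Path) -> PatternSet:
    """Round-trip counterpart of :func:`save_pattern_set`."""
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(_sidecar(path).read_text())
    data = np.moveaxis(np.asarray(img.get_fdata(), dtype=float), -1, 0)
    conditions = [tuple(c) for c in meta["conditions"]]
    return PatternSet(
        subject=meta.get("subject", "unknown"),
        conditions=conditions,
        data=data,
        affine=img.affine,
    )


def pattern_set_from_files(
    files: dict[tuple[str, str], str | Path], subject: str | int = "subject"
) -> PatternSet:
    """Assemble a PatternSet from one NIfTI per condition.

    All volumes must share grid shape and affine; any mismatch is
    rejected rather than silently resampled.
    """
    conditions, vols, affines = [], [], []
    for cond, p in files.items():
        vol, aff = load_volume(p)
        conditions.append(tuple(cond))
        vols.append(vol)
        affines.append(aff)
    ref = affines[0]
    for cond, vol, aff in zip(conditions, vols, affines):
        if vol.shape != vols[0].shape or not np.allclose(aff, ref, atol=1e-6):
            raise ValueError(f"condition {cond} has mismatched geometry")
    return PatternSet(
        subject=subject, conditions=conditions, data=np.stack(vols), affine=ref
    )


def save_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_ratings(ratings: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ratings.to_csv(path, index=False)
    return path


def load_ratings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
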