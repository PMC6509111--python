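"""Shared volumetric containers.

A :class:`PatternSet` holds one subject's condition-wise beta volumes —
one 3-D map of regression coefficients per (target person, mental state)
condition — on a common voxel grid.  It is the exchange format between
the simulator, the first-level GLM, and the representational similarity
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

Condition = tuple[str, str]  # (target, state)


def make_affine(voxel_size_mm: float | Sequence[float]) -> np.ndarray:
    """Diagonal NIfTI affine for an isotropic (or per-axis) voxel size."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


@dataclass
class PatternSet:
    """Condition-wise beta volumes for one subject on a shared grid.

    Parameters
    ----------
    subject : str or int
        Subject identifier.
    conditions : list of (target, state)
        Ordered condition labels; one per leading slice of ``data``.
    data : ndarray, shape (n_conditions, nx, ny, nz)
        Beta volumes, stacked in condition order.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (NIfTI convention).
    """

    subject: str | int
    conditions: list[Condition]
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = [tuple(c) for c in self.conditions]
        if self.data.ndim != 4:
            raise ValueError("data must be (n_conditions, nx, ny, nz)")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.conditions)} condition labels for "
                f"{self.data.shape[0]} volumes"
            )
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        self._index = {c: i for i, c in enumerate(self.conditions)}

    # -- geometry -----------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    # -- condition access ---------------------------------------------
    @property
    def targets(self) -> list[str]:
        seen: dict[str, None] = {}
        for t, _ in self.conditions:
            seen.setdefault(t)
        return list(seen)

    def states_for(self, target: str) -> list[str]:
        return [s for t, s in self.conditions if t == target]

    def get(self, target: str, state: str) -> np.ndarray:
        return self.data[self._index[(target, state)]]

    def __contains__(self, condition: Condition) -> bool:
        return tuple(condition) in self._index

    def __iter__(self) -> Iterator[Condition]:
        return iter(self.conditions)

    def flatten(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Condition × voxel matrix, optionally restricted to a boolean mask."""
        if mask is None:
            return self.data.reshape(self.data.shape[0], -1)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid_shape:
            raise ValueError("mask shape does not match grid")
        return self.data[:, mask]

    def same_geometry(self, other: "PatternSet", atol: float = 1e-8) -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def check_shared_geometry(pattern_sets: Sequence[PatternSet]) -> None:
    """Raise if the sets do not share grid shape and affine."""
    ref = pattern_sets[0]
    for ps in pattern_sets[1:]:
        if not ref.same_geometry(ps):
            raise ValueError(
                f"subject {ps.subject!r} geometry differs from {ref.subject!r}"
            )
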