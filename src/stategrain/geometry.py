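"""State-space geometry: per-target 2-D scaling with Procrustes alignment.

Each target's within-target dissimilarity matrix is embedded in the
plane by classical (Torgerson) multidimensional scaling — deterministic
up to rotation and reflection — and the embeddings are rotated into a
common orientation by orthogonal Procrustes (no scaling, so the
mean-dissimilarity circle radii stay comparable across targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .rsa import RDM

__all__ = ["Embedding", "mds_embed", "procrustes_align", "plot_state_space"]


@dataclass
class Embedding:
    """2-D state coordinates for one target, centered at the origin.

    ``radius`` is the mean within-target dissimilarity, drawn as the
    dotted circle in state-space plots.
    """

    target: str
    states: list[str]
    coords: np.ndarray  # (n_states, 2), centered
    radius: float
    transform: np.ndarray | None = None  # orthogonal alignment applied, if any
    disparity: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n_states, 2)")
        if len(self.states) != self.coords.shape[0]:
            raise ValueError("one coordinate row per state required")
        if self.radius < 0:
            raise ValueError("radius must be nonnegative")

    def pairwise_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))


def mds_embed(rdm: RDM, target: str | None = None) -> Embedding:
    """Classical 2-D MDS of one target's state dissimilarities.

    Double-centers the squared-distance matrix and takes the top two
    eigendirections; axis signs are fixed (largest-magnitude coordinate
    positive) so repeated calls agree exactly.  The circle radius is the
    mean off-diagonal dissimilarity.
    """
    if target is None:
        targets = {t for t, _ in rdm.conditions}
        if len(targets) != 1:
            raise ValueError("RDM spans several targets; pass target explicitly")
        target = targets.pop()
    idx = [i for i, (t, _) in enumerate(rdm.conditions) if t == target]
    if len(idx) < 3:
        raise ValueError("need at least 3 states to embed")
    states = [s for t, s in rdm.conditions if t == target]
    D = rdm.matrix[np.ix_(idx, idx)]

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:2]
    lam = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lam)
    coords = coords - coords.mean(axis=0)
    for a in range(2):  # deterministic sign convention
        j = np.argmax(np.abs(coords[:, a]))
        if coords[j, a] < 0:
            coords[:, a] = -coords[:, a]
    radius = float(np.mean(D[np.triu_indices(n, k=1)]))
    return Embedding(target=target, states=states, coords=coords, radius=radius)


def procrustes_align(
    reference: Embedding, moving: Embedding
) -> Embedding:
    """Rotate/reflect ``moving`` onto ``reference`` over their shared states.

    Solves the orthogonal Procrustes problem on the common labels —
    rotation and reflection only, no scaling, so within-target pairwise
    distances and the circle radius are untouched.
    """
    common = [s for s in moving.states if s in set(reference.states)]
    if len(common) < 2:
        raise ValueError("need at least 2 shared states to align")
    ref_idx = {s: i for i, s in enumerate(reference.states)}
    mov_idx = {s: i for i, s in enumerate(moving.states)}
    A = moving.coords[[mov_idx[s] for s in common]]
    B = reference.coords[[ref_idx[s] for s in common]]
    if np.allclose(A, A[0]) or np.allclose(B, B[0]):
        raise ValueError("degenerate configuration: all points coincide")
    R, _ = orthogonal_procrustes(A, B)
    new = moving.coords @ R
    disparity = float(((A @ R - B) ** 2).sum())
    return Embedding(
        target=moving.target,
        states=list(moving.states),
        coords=new,
        radius=moving.radius,
        transform=R,
        disparity=disparity,
    )


def plot_state_space(embeddings: list[Embedding], path: str | None = None,
                     colors: list[str] | None = None):
    """Render aligned state spaces: points, dotted mean-dissimilarity
    circles, and gray lines connecting the same state across targets."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if colors is None:
        colors = ["#f2c200", "#f28500", "#d62d20", "#4477aa", "#117755"]
    state_coords: dict[str, list[np.ndarray]] = {}
    for emb, color in zip(embeddings, colors):
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1], s=30, color=color,
                   label=emb.target, zorder=3)
        theta = np.linspace(0, 2 * np.pi, 200)
        ax.plot(emb.radius * np.cos(theta), emb.radius * np.sin(theta),
                linestyle=":", color=color, linewidth=1.2, zorder=1)
        for s, xy in zip(emb.states, emb.coords):
            state_coords.setdefault(s, []).append(xy)
    for pts in state_coords.values():
        for a, b in combinations(pts, 2):
            ax.plot([a[0], b[0]], [a[1], b[1]], color="0.7",
                    linewidth=0.6, zorder=0)
    ax.set_aspect("equal")
    ax.legend(frameon=False)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
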