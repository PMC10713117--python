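"""Patchification of surface point clouds: FPS centers, KNN membership, masking.

Self-attention over thousands of points is quadratic, so the surface is
divided into g irregular, possibly overlapping patches: g centers chosen by
farthest point sampling and, per center, its k' nearest points. During
pretraining a ratio m of patches is masked; fine-tuning and inference use
m = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class PatchSet:
    """g patches over one point cloud (indices into that cloud)."""

    points: np.ndarray  # (N, 3) the underlying cloud
    center_idx: np.ndarray  # (g,)
    members: np.ndarray  # (g, k')
    mask: np.ndarray  # (g,) bool
    m: float = 0.0

    @property
    def g(self) -> int:
        return self.center_idx.shape[0]

    @property
    def k_prime(self) -> int:
        return self.members.shape[1]

    @property
    def centers(self) -> np.ndarray:
        return self.points[self.center_idx]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def n_visible(self) -> int:
        return self.g - self.n_masked

    def member_coords(self) -> np.ndarray:
        """Patch coordinates, shape (g, k', 3)."""
        return self.points[self.members]


def farthest_point_sample(points: np.ndarray, g: int) -> np.ndarray:
    """Greedy farthest point sampling, fully deterministic.

    The first center is the point farthest from the centroid; each following
    center maximises its minimum distance to the centers chosen so far. Ties
    go to the lowest index, so the result is a pure function of the input.
    """
    points = np.asarray(points, dtype=np.float64)
    n = points.shape[0]
    if g > n:
        raise ValueError(f"cannot sample {g} centers from {n} points")
    centroid = points.mean(axis=0)
    first = int(np.argmax(np.linalg.norm(points - centroid, axis=1)))  # argmax: lowest tie index
    chosen = [first]
    min_d = np.linalg.norm(points - points[first], axis=1)
    for _ in range(1, g):
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen, dtype=np.int64)


def knn_group(points: np.ndarray, center_idx: np.ndarray, k_prime: int) -> PatchSet:
    """Per center, its k' nearest points (ascending distance, ties by index)."""
    points = np.asarray(points, dtype=np.float64)
    center_idx = np.asarray(center_idx, dtype=np.int64)
    n = points.shape[0]
    if k_prime > n:
        raise ValueError(f"k'={k_prime} exceeds point count {n}")
    d = np.linalg.norm(points[center_idx][:, None, :] - points[None, :, :], axis=2)
    order = np.argsort(d, axis=1, kind="stable")
    members = order[:, :k_prime]
    return PatchSet(
        points=points,
        center_idx=center_idx,
        members=members,
        mask=np.zeros(center_idx.shape[0], dtype=bool),
        m=0.0,
    )


def apply_mask(patchset: PatchSet, m: float, seed: int) -> PatchSet:
    """Mask round(m*g) patches uniformly at random (seeded, no replacement)."""
    if not (0 <= m < 1):
        raise ValueError(f"mask ratio m={m} outside [0, 1)")
    g = patchset.g
    n_mask = round_half_up(m * g)
    mask = np.zeros(g, dtype=bool)
    if n_mask:
        rng = np.random.default_rng(seed)
        mask[rng.choice(g, size=n_mask, replace=False)] = True
    return replace(patchset, mask=mask, m=m)


def make_patches(points: np.ndarray, g: int, k_prime: int, m: float = 0.0,
                 seed: int = 0) -> PatchSet:
    """FPS + KNN + (optional) masking in one call."""
    centers = farthest_point_sample(points, g)
    ps = knn_group(points, centers, k_prime)
    return apply_mask(ps, m, seed) if m > 0 else ps
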