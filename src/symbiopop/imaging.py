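"""Bacterial-load quantification from 3D fluorescence stacks.

Load is the total physical volume of above-threshold voxels in a z-stack of
a single spore.  The threshold default is Otsu's method (a reproducible
substitute for visual gauging), voxels equal to the threshold count as
background, and connected components use 26-connectivity for the
particle-diameter sanity check.  Intensity-bin classification emulates the
low/medium/high FACS gates with deterministic terciles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label

__all__ = [
    "VoxelStack",
    "LoadResult",
    "otsu_threshold",
    "quantify_load",
    "classify_intensity_bins",
]

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}

BIN_NAMES_3 = ("low", "medium", "high")


@dataclass(frozen=True)
class VoxelStack:
    """A 3D non-negative intensity array with physical voxel dimensions.

    ``intensities`` is indexed (z, y, x); ``voxel_dims`` gives the physical
    edge length of a voxel per axis in micrometres.
    """

    intensities: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={arr.ndim}")
        if any(s < 1 for s in arr.shape):
            raise ValueError(f"all stack dimensions must be >= 1, got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"voxel_dims must be 3 positive sizes, got {self.voxel_dims}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "voxel_dims", dims)

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in cubic micrometres."""
        return float(np.prod(self.voxel_dims))


@dataclass(frozen=True)
class LoadResult:
    """Quantified bacterial load of one stack."""

    n_voxels: int
    volume: float
    threshold_used: float
    n_components: int

    def __post_init__(self) -> None:
        if self.n_components > self.n_voxels:
            raise ValueError("n_components cannot exceed n_voxels")


def otsu_threshold(stack: VoxelStack, nbins: int = 256) -> float:
    """Between-class-variance-maximizing threshold of the stack histogram.

    When the maximizing thresholds form a plateau (an empty intensity gap
    between the classes leaves the between-class variance constant across
    it), the plateau midpoint is returned, placing the threshold centrally
    in the gap rather than at its edge.  A constant stack has no separable
    classes and is rejected.
    """
    arr = stack.intensities
    if arr.min() == arr.max():
        raise ValueError("constant stack: no separable intensity classes")
    counts, edges = np.histogram(arr.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    weights = counts / counts.sum()
    cum_weight = np.cumsum(weights)
    cum_mean = np.cumsum(weights * centers)
    total_mean = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between_var = (total_mean * cum_weight - cum_mean) ** 2 / (
            cum_weight * (1.0 - cum_weight)
        )
    between_var[~np.isfinite(between_var)] = -np.inf
    tied = np.flatnonzero(between_var == between_var.max())
    return float(centers[(tied[0] + tied[-1]) // 2])


def quantify_load(
    stack: VoxelStack,
    threshold: float | None = None,
    connectivity: int = 26,
) -> LoadResult:
    """Count voxels strictly above threshold and their physical volume.

    ``threshold=None`` applies :func:`otsu_threshold`.  Voxels exactly at
    the threshold are background.  ``connectivity`` is the 3D neighbourhood
    (6, 18 or 26) used to label components.
    """
    if connectivity not in _CONNECTIVITY_TO_SKIMAGE:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_TO_SKIMAGE)}")
    if threshold is None:
        threshold = otsu_threshold(stack)
    threshold = float(threshold)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = stack.intensities > threshold
    n_voxels = int(mask.sum())
    if n_voxels:
        _, n_components = label(
            mask, connectivity=_CONNECTIVITY_TO_SKIMAGE[connectivity], return_num=True
        )
    else:
        n_components = 0
    return LoadResult(
        n_voxels=n_voxels,
        volume=n_voxels * stack.voxel_volume,
        threshold_used=threshold,
        n_components=n_components,
    )


def classify_intensity_bins(
    total_intensities: Sequence[float],
    n_bins: int = 3,
) -> list[str]:
    """Assign per-spore total intensities to quantile bins.

    With the default ``n_bins=3`` the labels are ``low``/``medium``/``high``,
    emulating the L/M/H sorting gates deterministically.  Ties are broken
    stably by input order; fewer than ``n_bins`` distinct values is an error.
    """
    values = np.asarray(total_intensities, dtype=float)
    if values.ndim != 1:
        raise ValueError("total_intensities must be one-dimensional")
    if len(np.unique(values)) < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct intensity values, "
            f"got {len(np.unique(values))}"
        )
    if n_bins == 3:
        names = BIN_NAMES_3
    else:
        names = tuple(f"bin{i}" for i in range(n_bins))
    order = np.argsort(values, kind="stable")
    n = len(values)
    labels = [""] * n
    for rank, idx in enumerate(order):
        labels[idx] = names[min(rank * n_bins // n, n_bins - 1)]
    return labels
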