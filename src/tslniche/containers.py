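"""In-memory containers shared across the pipeline.

Axis conventions: volumes are indexed (z, y, x), 0-based; multi-channel
stacks are (channel, z, y, x). World coordinates are axis-parallel
micrometres with the origin at the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelStack", "LabelVolume", "SpilloverMatrix", "DensityGrid"]


@dataclass
class ChannelStack:
    """Named multi-channel 3D intensity volume with physical voxel dimensions.

    Parameters
    ----------
    intensities
        Array of shape (channel, z, y, x), arbitrary fluorescence units.
    channel_names
        One label per channel, unique, order bound to the first axis.
    voxel_dims
        Physical voxel size in µm per (z, y, x) axis.
    bit_depth
        Optional acquisition bit depth, metadata only.
    """

    intensities: np.ndarray
    channel_names: list[str]
    voxel_dims: tuple[float, float, float]
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"intensities must be (channel, z, y, x); got ndim={self.intensities.ndim}"
            )
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.intensities.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.intensities.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be three positive µm values, got {self.voxel_dims}")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {self.channel_names})"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) volume for one named channel (a view)."""
        return self.intensities[self.index(name)]

    def with_intensities(self, intensities: np.ndarray) -> "ChannelStack":
        """Copy of this stack with replaced intensities, metadata preserved."""
        return ChannelStack(
            intensities=intensities,
            channel_names=list(self.channel_names),
            voxel_dims=self.voxel_dims,
            bit_depth=self.bit_depth,
        )


@dataclass
class LabelVolume:
    """Integer segmentation masks: 0 = background, positive ints = cell ids."""

    labels: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be (z, y, x); got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be three positive µm values, got {self.voxel_dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        """Sorted array of positive label ids present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SpilloverMatrix:
    """Channel-mixing matrix S with observed = S @ true.

    Rows are detection channels, columns are source channels, both in the
    order of ``channel_names``. Must be square, have positive diagonal and
    be invertible.
    """

    coefficients: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.channel_names = list(self.channel_names)
        k = len(self.channel_names)
        if self.coefficients.shape != (k, k):
            raise ValueError(
                f"spillover matrix shape {self.coefficients.shape} does not match "
                f"{k} channels {self.channel_names}"
            )
        if np.any(np.diag(self.coefficients) <= 0):
            bad = [
                self.channel_names[i]
                for i in np.nonzero(np.diag(self.coefficients) <= 0)[0]
            ]
            raise ValueError(f"spillover diagonal must be positive; offending channels: {bad}")
        cond = np.linalg.cond(self.coefficients)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                f"spillover matrix is singular or ill-conditioned "
                f"(condition number {cond:.3g}) for channels {self.channel_names}"
            )


@dataclass
class DensityGrid:
    """Weighted kernel density evaluated on a regular world-coordinate grid.

    ``values`` has shape (nz, ny, nx) and units weight·µm⁻³; node ``i`` along
    axis ``a`` sits at ``origin[a] + i * spacing[a]`` µm.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray
    axes: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("DensityGrid values must be 3D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if self.axes is None:
            self.axes = tuple(
                self.origin[a] + self.spacing[a] * np.arange(self.values.shape[a])
                for a in range(3)
            )

    def sum_z(self, z_min: float | None = None, z_max: float | None = None) -> np.ndarray:
        """Plain node sum of the 3D density over a z slab [z_min, z_max] µm.

        No division by slab thickness is applied; the result is a 2D map for
        visualisation, not a volume-normalised density.
        """
        z_nodes = self.axes[0]
        lo = z_nodes[0] if z_min is None else z_min
        hi = z_nodes[-1] if z_max is None else z_max
        sel = (z_nodes >= lo - 1e-9) & (z_nodes <= hi + 1e-9)
        if not sel.any():
            raise ValueError(f"z slab [{lo}, {hi}] µm contains no grid nodes")
        return self.values[sel].sum(axis=0)
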