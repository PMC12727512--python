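"""Per-cell feature extraction from nuclear label masks.

Nuclear masks are expanded by a collision-free nearest-label rule to build
membrane/cytoplasmic masks (expansion − nucleus), then masked mean channel
intensities and centroids are tabulated into the CellTable that every
downstream stage consumes.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ChannelStack, LabelVolume

__all__ = ["expand_labels_membrane", "quantify_cells", "centroid_to_world"]


def expand_labels_membrane(
    nuc: LabelVolume, radius: float, *, physical_units: bool = False
) -> tuple[LabelVolume, LabelVolume]:
    """Expand nuclear labels and derive the membrane/cytoplasmic mask.

    Each background voxel within Euclidean distance ``radius`` of its nearest
    nucleus takes that nucleus's label; existing labels are never reassigned
    and expansions cannot collide (every voxel goes to the single nearest
    nucleus; exact distance ties go to the lower label id). The membrane mask
    is the expansion minus the nuclei.

    ``radius`` is in voxel units on the native (possibly anisotropic) grid by
    default; with ``physical_units=True`` it is interpreted in µm using the
    volume's voxel dimensions.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    labels = nuc.labels
    expanded = labels.copy()
    if radius > 0 and labels.any():
        sampling = nuc.voxel_dims if physical_units else (1.0, 1.0, 1.0)
        pad = [int(math.ceil(radius / s)) + 1 for s in sampling]
        shape = labels.shape
        best = np.full(shape, np.inf)
        for lab in nuc.ids():
            mask = labels == lab
            zs, ys, xs = np.nonzero(mask)
            lo = [max(int(v.min()) - p, 0) for v, p in zip((zs, ys, xs), pad)]
            hi = [min(int(v.max()) + p + 1, s) for v, p, s in zip((zs, ys, xs), pad, shape)]
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            d = ndimage.distance_transform_edt(~mask[sl], sampling=sampling)
            # strict < plus ascending label order implements the lowest-label tie rule
            upd = (d <= radius + 1e-9) & (labels[sl] == 0) & (d < best[sl])
            best_view = best[sl]
            best_view[upd] = d[upd]
            exp_view = expanded[sl]
            exp_view[upd] = lab
    membrane = np.where(labels == 0, expanded, 0)
    return (
        LabelVolume(expanded, nuc.voxel_dims),
        LabelVolume(membrane.astype(labels.dtype), nuc.voxel_dims),
    )


def quantify_cells(
    stack: ChannelStack, nuc: LabelVolume, mem: LabelVolume | None = None
) -> pd.DataFrame:
    """Tabulate per-cell centroids and masked mean intensities.

    For every cell and channel, mean = sum of masked voxel intensities /
    number of mask voxels. Centroids are the mean nuclear voxel indices
    (0-based, (z, y, x)) plus their world-coordinate counterparts in µm.
    Cells with an empty membrane mask get NaN membrane means.
    """
    if stack.spatial_shape != nuc.shape:
        raise ValueError(
            f"stack spatial shape {stack.spatial_shape} != label shape {nuc.shape}"
        )
    if mem is not None and mem.shape != nuc.shape:
        raise ValueError(f"membrane shape {mem.shape} != nuclear shape {nuc.shape}")

    ids = nuc.ids()
    if ids.size == 0:
        cols = ["cell_id", "centroid_z", "centroid_y", "centroid_x",
                "centroid_z_um", "centroid_y_um", "centroid_x_um",
                "nuclear_voxels", "membrane_voxels"]
        cols += [f"nuclear_mean_{c}" for c in stack.channel_names]
        cols += [f"membrane_mean_{c}" for c in stack.channel_names]
        return pd.DataFrame(columns=cols)

    nmax = int(ids.max())
    flat_nuc = nuc.labels.ravel()
    n_counts = np.bincount(flat_nuc, minlength=nmax + 1)

    if mem is not None:
        mem_ids = mem.ids()
        orphans = np.setdiff1d(mem_ids, ids)
        if orphans.size:
            raise ValueError(
                f"membrane labels without a nuclear counterpart: {orphans.tolist()}"
            )
        flat_mem = mem.labels.ravel()
        m_counts = np.bincount(flat_mem, minlength=nmax + 1)

    zz, yy, xx = np.indices(nuc.shape)
    cz = np.bincount(flat_nuc, weights=zz.ravel(), minlength=nmax + 1)
    cy = np.bincount(flat_nuc, weights=yy.ravel(), minlength=nmax + 1)
    cx = np.bincount(flat_nuc, weights=xx.ravel(), minlength=nmax + 1)

    data: dict[str, np.ndarray] = {"cell_id": ids}
    with np.errstate(invalid="ignore", divide="ignore"):
        cen = np.stack([cz, cy, cx], axis=0) / n_counts[None, :]
    data["centroid_z"], data["centroid_y"], data["centroid_x"] = (cen[a][ids] for a in range(3))
    for a, name in enumerate(("z", "y", "x")):
        data[f"centroid_{name}_um"] = data[f"centroid_{name}"] * stack.voxel_dims[a]
    data["nuclear_voxels"] = n_counts[ids]
    data["membrane_voxels"] = m_counts[ids] if mem is not None else np.zeros(ids.size, int)

    for c, ch in enumerate(stack.channel_names):
        flat_int = stack.intensities[c].ravel()
        sums = np.bincount(flat_nuc, weights=flat_int, minlength=nmax + 1)
        data[f"nuclear_mean_{ch}"] = sums[ids] / n_counts[ids]
        if mem is not None:
            msums = np.bincount(flat_mem, weights=flat_int, minlength=nmax + 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                mmeans = msums[ids] / m_counts[ids]
            mmeans[m_counts[ids] == 0] = np.nan  # empty membrane reported as missing
            data[f"membrane_mean_{ch}"] = mmeans
        else:
            data[f"membrane_mean_{ch}"] = np.full(ids.size, np.nan)
    return pd.DataFrame(data)


def centroid_to_world(
    centroid_voxel: Sequence[float], voxel_dims: Sequence[float]
) -> tuple[float, float, float]:
    """Convert a (z, y, x) voxel-index centroid to µm world coordinates."""
    if any(d <= 0 for d in voxel_dims):
        raise ValueError(f"voxel_dims must be positive, got {tuple(voxel_dims)}")
    return tuple(float(c) * float(d) for c, d in zip(centroid_voxel, voxel_dims))
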