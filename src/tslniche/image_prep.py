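"""Deterministic raw-stack preprocessing.

Two corrections are applied before any quantification: linear spectral
spillover compensation (observed = S @ true, solved per voxel) and a global
exponential depth-attenuation correction fitted on a reference channel.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .containers import ChannelStack, SpilloverMatrix

__all__ = ["compensate_spillover", "correct_z_attenuation"]


def compensate_spillover(stack: ChannelStack, spillover: SpilloverMatrix) -> ChannelStack:
    """Linear unmixing of channel crosstalk.

    The mixing convention is ``observed = S @ true`` with S rows indexed by
    detection channels; the corrected stack is ``S⁻¹ @ observed`` per voxel,
    with negative unmixed intensities clamped to zero.
    """
    if spillover.channel_names != stack.channel_names:
        raise ValueError(
            "spillover channels do not match stack channels: "
            f"{spillover.channel_names} vs {stack.channel_names}"
        )
    S = spillover.coefficients
    c = stack.n_channels
    obs = stack.intensities.reshape(c, -1)
    true = np.linalg.solve(S, obs)
    np.clip(true, 0, None, out=true)
    return stack.with_intensities(true.reshape(stack.intensities.shape))


def correct_z_attenuation(
    stack: ChannelStack, reference_channel: str, *, min_slices: int = 3
) -> tuple[ChannelStack, float]:
    """Fit and undo exponential signal decay along z.

    The model is I(z) = I0 · exp(−z/λ) with z the slice depth in µm. λ is
    fitted by ordinary least squares on the log of per-slice medians of the
    reference channel's nonzero voxels, then every channel slice is divided
    by exp(−z/λ). Returns the corrected stack and the fitted λ (µm);
    ``math.inf`` marks the flat (no attenuation) branch and ``math.nan`` a
    single-slice input where the fit is undefined.
    """
    ref = stack.channel(reference_channel)
    nz = ref.shape[0]
    if nz == 1:
        return stack.with_intensities(stack.intensities.copy()), math.nan

    depths, logmeds = [], []
    for z in range(nz):
        sl = ref[z]
        vals = sl[sl != 0]
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        if med <= 0:
            raise ValueError(
                f"non-positive nonzero-voxel median ({med}) in reference channel "
                f"{reference_channel!r} at slice {z}; cannot fit on the log scale"
            )
        depths.append(z * stack.voxel_dims[0])
        logmeds.append(math.log(med))
    if len(depths) < min_slices:
        raise ValueError(
            f"need >= {min_slices} z-slices with nonzero reference signal, "
            f"found {len(depths)}"
        )

    slope, _ = np.polyfit(np.asarray(depths), np.asarray(logmeds), 1)
    if slope > -1e-12:
        if slope > 1e-12:
            lam = -1.0 / slope
            warnings.warn(
                f"fitted attenuation length is non-positive (lambda = {lam:.3g} µm: "
                "intensity increases with depth); no correction applied",
                stacklevel=2,
            )
            return stack.with_intensities(stack.intensities.copy()), lam
        return stack.with_intensities(stack.intensities.copy()), math.inf

    lam = -1.0 / slope
    z_um = np.arange(nz) * stack.voxel_dims[0]
    gain = np.exp(z_um / lam)  # divide by exp(-z/lambda)
    corrected = stack.intensities * gain[None, :, None, None]
    return stack.with_intensities(corrected), lam
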