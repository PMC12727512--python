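"""Seeded synthetic lymph-node volumes and cytometry event tables.

The imaging generator emulates a cleared tdLN tile: an XCR1+ cDC1 filament
network, plus T cells rendered as non-overlapping ellipsoidal nuclei with a
membrane/cytoplasmic shell. A configurable fraction of T cells is placed
inside dendritic-cell niches (within ``cluster_radius`` µm of the cDC1
skeleton); the rest are dispersed uniformly. Nuclear markers (TCF-1, Ki-67)
are painted inside nuclei, membrane markers (PD-1, SLAMF6) on the shell, and
NFAT1 is routed to nucleus or shell according to a per-cell translocation
flag. Optional depth attenuation, spectral spillover and additive noise
exercise the preprocessing stages.

The cytometry generator emulates multi-mouse tetramer/CD3 staining with the
hierarchical structure the downstream models assume:

    log(tetramer/CD3) = mu(subset, treatment) + u0_mouse + u1_mouse[subset] + eps

with lognormal staining intensities and optional simultaneous tetramer+CD3
downregulation on blockade arms (the monoclonal OT-I control, under which
the tetramer/CD3 ratio is invariant by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import ChannelStack, LabelVolume

__all__ = [
    "SynthImageParams",
    "SynthCytometryParams",
    "simulate_ln_image",
    "simulate_cytometry",
    "tumour_volume",
    "KNOWN_TREATMENTS",
    "SUBSETS",
]

KNOWN_TREATMENTS = ("IgG", "aPDL1", "aPDL2", "aPDL1L2", "aPD1")
SUBSETS = ("SLAMF6posTSL", "SLAMF6negTSL", "Teff")

#: default channel -> compartment routing for painted markers
DEFAULT_CHANNEL_ROLES = {
    "TCF1": "nuclear",
    "Ki67": "nuclear",
    "PD1": "membrane",
    "SLAMF6": "membrane",
    "NFAT1": "nfat",
}

_DEFAULT_PHENOTYPE_MEANS = {
    # niche-resident stem-like cells: TCF-1/SLAMF6/PD-1 high
    "TSL": {"TCF1": 180.0, "PD1": 160.0, "SLAMF6": 150.0, "Ki67": 120.0, "NFAT1": 140.0},
    # dispersed effector cells: stem-like markers low
    "Teff": {"TCF1": 40.0, "PD1": 60.0, "SLAMF6": 30.0, "Ki67": 120.0, "NFAT1": 140.0},
    "DC": {"XCR1": 200.0},
}


@dataclass
class SynthImageParams:
    """Parameters of the synthetic lymph-node imaging volume.

    Voxel dimensions default to the acquisition geometry the pipeline targets
    (0.361 µm xy, 2 µm z step). Lengths are µm, intensities arbitrary units.
    """

    volume_shape: tuple[int, int, int] = (40, 192, 192)  # (z, y, x) voxels
    voxel_dims: tuple[float, float, float] = (2.0, 0.361, 0.361)  # µm
    n_dc: int = 8
    dc_skeleton_scale: float = 60.0  # filament length, µm
    n_tcells: int = 150
    clustered_fraction: float = 0.5
    cluster_radius: float = 12.0  # µm
    phenotype_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PHENOTYPE_MEANS.items()}
    )
    channel_roles: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES)
    )
    nuclear_radius_range: tuple[float, float] = (2.0, 3.2)  # µm
    shell_thickness: float = 2.2  # µm, membrane/cytoplasmic rim
    clustered_phenotype: str = "TSL"
    dispersed_phenotype: str = "Teff"
    nfat_nuclear_if_clustered: bool = True
    nfat_cytoplasmic_level: float = 0.25  # off-compartment NFAT fraction
    dc_sigma: float = 2.0  # µm smoothing of the filament skeleton
    dc_background: float = 5.0  # a.u. tissue autofluorescence on the DC channel
    noise_sd: float = 5.0
    attenuation_lambda: float | None = None  # µm; None = no depth decay
    spillover_matrix: np.ndarray | None = None
    seed: int = 0
    max_retries: int = 1000

    def validate(self) -> None:
        if not (0.0 <= self.clustered_fraction <= 1.0):
            raise ValueError(f"clustered_fraction must be in [0, 1], got {self.clustered_fraction}")
        if any(s < 1 for s in self.volume_shape):
            raise ValueError(f"all volume_shape entries must be >= 1, got {self.volume_shape}")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        if self.n_tcells < 0 or self.n_dc < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.nuclear_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid nuclear_radius_range {self.nuclear_radius_range}")
        if self.spillover_matrix is not None:
            S = np.asarray(self.spillover_matrix, dtype=float)
            if S.ndim != 2 or S.shape[0] != S.shape[1]:
                raise ValueError("spillover_matrix must be square")
            if np.any(np.diag(S) <= 0):
                raise ValueError("spillover_matrix diagonal must be positive")


@dataclass
class SynthCytometryParams:
    """Parameters of the synthetic multi-mouse cytometry experiment."""

    cohorts: int = 1
    mice_per_arm: int = 6
    treatments: tuple[str, ...] = ("IgG", "aPDL1L2")
    subset_proportions: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "IgG": (0.40, 0.30, 0.30),
            "aPDL1L2": (0.25, 0.25, 0.50),
        }
    )
    log_affinity_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("SLAMF6posTSL", "IgG"): 0.50,
            ("SLAMF6negTSL", "IgG"): 0.20,
            ("Teff", "IgG"): 0.00,
            ("SLAMF6posTSL", "aPDL1L2"): 0.10,
            ("SLAMF6negTSL", "aPDL1L2"): 0.05,
            ("Teff", "aPDL1L2"): 0.00,
        }
    )
    mouse_sd_intercept: float = 0.15
    mouse_sd_slope: float = 0.10
    residual_sd: float = 0.50
    events_per_mouse: int = 500
    monoclonal: bool = False
    downregulation_factor: float = 1.0  # applied to tetramer AND CD3 on blockade arms
    log_cd3_mean: float = float(np.log(1000.0))
    log_cd3_sd: float = 0.30
    tissue: str = "tdLN"
    seed: int = 0

    def validate(self) -> None:
        if self.cohorts < 1 or self.mice_per_arm < 1 or self.events_per_mouse < 1:
            raise ValueError("cohorts, mice_per_arm and events_per_mouse must be >= 1")
        for t in self.treatments:
            if t not in KNOWN_TREATMENTS:
                raise ValueError(
                    f"unknown treatment label {t!r}; known: {KNOWN_TREATMENTS}"
                )
            p = self.subset_proportions.get(t)
            if p is None:
                raise ValueError(f"no subset_proportions for treatment {t!r}")
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"subset_proportions for {t!r} must sum to 1, got {sum(p)}")
            for s in SUBSETS:
                if (s, t) not in self.log_affinity_means:
                    raise ValueError(f"missing log_affinity_means for ({s!r}, {t!r})")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.mouse_sd_intercept < 0 or self.mouse_sd_slope < 0:
            raise ValueError("mouse SDs must be >= 0")
        if not (0.0 < self.downregulation_factor <= 1.0):
            raise ValueError("downregulation_factor must be in (0, 1]")


def tumour_volume(width: float, length: float) -> float:
    """Caliper tumour volume in mm³: width² × length / 2."""
    if width < 0 or length < 0:
        raise ValueError(f"width and length must be non-negative, got ({width}, {length})")
    return width**2 * length / 2.0


# ---------------------------------------------------------------------------
# imaging volume
# ---------------------------------------------------------------------------


def _ellipsoid(center: np.ndarray, radii_vox: np.ndarray, shape: tuple[int, int, int]):
    """Return (slices, boolean mask) of an axis-aligned ellipsoid, clipped."""
    lo = np.maximum(np.floor(center - radii_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii_vox).astype(int) + 1, np.asarray(shape))
    if np.any(hi <= lo):
        return None, None
    grids = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii_vox))
    mask = q <= 1.0
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return sl, mask


def _dc_skeleton(params: SynthImageParams, rng: np.random.Generator):
    """Random-walk filament skeleton; returns (binary volume, point list)."""
    shape = params.volume_shape
    dims = np.asarray(params.voxel_dims)
    skel = np.zeros(shape, dtype=float)
    pts: list[np.ndarray] = []
    step_um = min(params.voxel_dims[1:])  # one xy pixel per step
    n_steps = max(int(params.dc_skeleton_scale / step_um), 1)
    for _ in range(params.n_dc):
        pos = rng.uniform(0, 1, 3) * (np.asarray(shape) - 1)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(n_steps):
            idx = np.round(pos).astype(int)
            if np.all(idx >= 0) and np.all(idx < shape):
                skel[tuple(idx)] = 1.0
                pts.append(idx.copy())
            turn = rng.normal(size=3)
            turn /= np.linalg.norm(turn)
            direction = 0.8 * direction + 0.2 * turn
            direction /= np.linalg.norm(direction)
            pos = pos + direction * (step_um / dims)  # step_um in voxel units/axis
            pos = np.clip(pos, 0, np.asarray(shape) - 1)
    return skel, pts


def simulate_ln_image(
    params: SynthImageParams,
) -> tuple[ChannelStack, LabelVolume, pd.DataFrame]:
    """Generate a synthetic lymph-node tile with ground-truth annotations.

    Returns
    -------
    stack : ChannelStack
        Channels: ``XCR1`` (cDC1 network) plus every marker named in
        ``params.phenotype_means`` for T cell phenotypes.
    labels : LabelVolume
        Nuclear masks; contiguous positive ids 1..n in placement order.
    truth : pandas.DataFrame
        One row per cell: ``cell_id``, ``phenotype``, ``clustered``,
        ``nfat_nuclear``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = params.volume_shape
    dims = np.asarray(params.voxel_dims)

    marker_channels: list[str] = []
    for pheno, means in params.phenotype_means.items():
        if pheno == "DC":
            continue
        for ch in means:
            if ch not in marker_channels:
                marker_channels.append(ch)
    channel_names = ["XCR1"] + marker_channels
    stacks = {ch: np.zeros(shape, dtype=float) for ch in channel_names}

    # cDC1 network: smoothed random-walk filaments, scaled to [0, 1]
    skel, skel_pts = _dc_skeleton(params, rng)
    sigma_vox = params.dc_sigma / dims
    dc = gaussian_filter(skel, sigma=sigma_vox, mode="constant")
    if dc.max() > 0:
        dc = dc / dc.max()
    dc_amp = dict(params.phenotype_means.get("DC", {})).get("XCR1", 200.0)
    # constant autofluorescence floor keeps per-slice medians comparable,
    # which is what the depth-attenuation fit relies on
    stacks["XCR1"] = dc * dc_amp + params.dc_background

    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)  # nuclei + shells: keeps cells disjoint
    truth_rows = []

    n_clustered = int(round(params.clustered_fraction * params.n_tcells))
    shell_vox = np.maximum(params.shell_thickness / dims, 0.0)

    for i in range(params.n_tcells):
        clustered = i < n_clustered and len(skel_pts) > 0
        pheno = params.clustered_phenotype if clustered else params.dispersed_phenotype
        r_um = rng.uniform(*params.nuclear_radius_range)
        radii = np.maximum(r_um / dims, 0.51)  # >= 1 voxel across each axis

        placed = False
        for _ in range(params.max_retries):
            if clustered:
                anchor = np.asarray(skel_pts[rng.integers(len(skel_pts))], dtype=float)
                # uniform offset in a ball of cluster_radius µm
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                off_um = v * params.cluster_radius * rng.uniform() ** (1 / 3)
                center = anchor + off_um / dims
            else:
                center = rng.uniform(0, 1, 3) * (np.asarray(shape) - 1)
            outer = radii + shell_vox
            if np.any(center - outer < 0) or np.any(center + outer > np.asarray(shape) - 1):
                continue
            sl_o, m_o = _ellipsoid(center, outer, shape)
            if sl_o is None or occupied[sl_o][m_o].any():
                continue
            sl_n, m_n = _ellipsoid(center, radii, shape)
            cell_id = len(truth_rows) + 1
            labels[sl_n][m_n] = cell_id
            occupied[sl_o][m_o] = True
            shell = m_o.copy()
            # carve the nucleus out of the outer ellipsoid within its own box
            inner_sl = tuple(
                slice(s_n.start - s_o.start, s_n.stop - s_o.start)
                for s_n, s_o in zip(sl_n, sl_o)
            )
            shell_region = shell[inner_sl]
            shell_region[m_n] = False
            nfat_nuclear = clustered == params.nfat_nuclear_if_clustered

            means = params.phenotype_means[pheno]
            for ch, mean in means.items():
                role = params.channel_roles.get(ch, "nuclear")
                if role == "nuclear":
                    stacks[ch][sl_n][m_n] = mean
                elif role == "membrane":
                    stacks[ch][sl_o][shell] = np.maximum(stacks[ch][sl_o][shell], mean)
                elif role == "nfat":
                    lo_level = params.nfat_cytoplasmic_level * mean
                    if nfat_nuclear:
                        stacks[ch][sl_n][m_n] = mean
                        stacks[ch][sl_o][shell] = np.maximum(stacks[ch][sl_o][shell], lo_level)
                    else:
                        stacks[ch][sl_n][m_n] = lo_level
                        stacks[ch][sl_o][shell] = np.maximum(stacks[ch][sl_o][shell], mean)
                else:
                    raise ValueError(f"unknown channel role {role!r} for channel {ch!r}")
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "phenotype": pheno,
                    "clustered": bool(clustered),
                    "nfat_nuclear": bool(nfat_nuclear),
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place T cell {i + 1}/{params.n_tcells} after "
                f"{params.max_retries} retries; volume too crowded"
            )

    intens = np.stack([stacks[ch] for ch in channel_names], axis=0)

    if params.attenuation_lambda is not None:
        z_um = np.arange(shape[0]) * dims[0]
        decay = np.exp(-z_um / params.attenuation_lambda)
        intens = intens * decay[None, :, None, None]

    if params.spillover_matrix is not None:
        S = np.asarray(params.spillover_matrix, dtype=float)
        if S.shape[0] != len(channel_names):
            raise ValueError(
                f"spillover_matrix is {S.shape[0]}x{S.shape[1]} but the stack has "
                f"{len(channel_names)} channels"
            )
        intens = np.einsum("ij,jzyx->izyx", S, intens)

    if params.noise_sd > 0:
        intens = np.clip(intens + rng.normal(0, params.noise_sd, intens.shape), 0, None)

    stack = ChannelStack(intens, channel_names, tuple(params.voxel_dims))
    label_vol = LabelVolume(labels, tuple(params.voxel_dims))
    truth = pd.DataFrame(
        truth_rows, columns=["cell_id", "phenotype", "clustered", "nfat_nuclear"]
    )
    return stack, label_vol, truth


# ---------------------------------------------------------------------------
# cytometry events
# ---------------------------------------------------------------------------

_MARKER_LOG_MEANS = {
    # (tcf1, slamf6, pd1) log-intensity location per subset
    "SLAMF6posTSL": (7.0, 6.8, 6.5),
    "SLAMF6negTSL": (6.8, 4.5, 5.5),
    "Teff": (4.5, 4.0, 5.0),
}


def simulate_cytometry(
    params: SynthCytometryParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic tetramer/CD3 cytometry event table.

    Returns
    -------
    events : pandas.DataFrame
        Columns ``event_id, cohort_id, mouse_id, treatment, tissue, subset,
        tetramer, cd3, cd8, tcf1, slamf6, pd1``. Intensities are lognormal.
    truth : pandas.DataFrame
        Per event: ``event_id, mouse_id, subset, clustered`` (always False for
        cytometry) and ``true_log_affinity_shift`` = mu + u0 + u1.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    rows = []
    truth_rows = []
    event_id = 0
    for cohort in range(params.cohorts):
        for treatment in params.treatments:
            props = np.asarray(params.subset_proportions[treatment], dtype=float)
            blockade = treatment != "IgG"
            scale = (
                params.downregulation_factor
                if (params.monoclonal and blockade)
                else 1.0
            )
            for m in range(params.mice_per_arm):
                mouse_id = f"c{cohort}_{treatment}_m{m}"
                u0 = rng.normal(0, params.mouse_sd_intercept)
                # random state slopes for non-reference subsets (reference: SLAMF6posTSL)
                u1 = {
                    s: (rng.normal(0, params.mouse_sd_slope) if k > 0 else 0.0)
                    for k, s in enumerate(SUBSETS)
                }
                subsets = rng.choice(len(SUBSETS), size=params.events_per_mouse, p=props)
                for s_idx in subsets:
                    subset = SUBSETS[s_idx]
                    mu = params.log_affinity_means[(subset, treatment)]
                    shift = mu + u0 + u1[subset]
                    eps = rng.normal(0, params.residual_sd)
                    log_cd3 = rng.normal(params.log_cd3_mean, params.log_cd3_sd)
                    cd3 = np.exp(log_cd3) * scale
                    tet = np.exp(log_cd3 + shift + eps) * scale
                    t_mu = _MARKER_LOG_MEANS[subset]
                    tcf1, slamf6, pd1 = np.exp(rng.normal(t_mu, 0.4))
                    cd8 = np.exp(rng.normal(6.0, 0.3))
                    event_id += 1
                    rows.append(
                        (
                            event_id, cohort, mouse_id, treatment, params.tissue,
                            subset, tet, cd3, cd8, tcf1, slamf6, pd1,
                        )
                    )
                    truth_rows.append((event_id, mouse_id, subset, False, shift))

    events = pd.DataFrame(
        rows,
        columns=[
            "event_id", "cohort_id", "mouse_id", "treatment", "tissue",
            "subset", "tetramer", "cd3", "cd8", "tcf1", "slamf6", "pd1",
        ],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "mouse_id", "subset", "clustered", "true_log_affinity_shift"],
    )
    return events, truth
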