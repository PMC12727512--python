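import numpy as np
import pytest

from tslniche import (
    SynthCytometryParams,
    SynthImageParams,
    expand_labels_membrane,
    quantify_cells,
    simulate_cytometry,
    simulate_ln_image,
)


@pytest.fixture(scope="session")
def small_image_params():
    """A noise-free tile small enough for exhaustive checks."""
    return SynthImageParams(
        volume_shape=(16, 128, 128),
        n_dc=3,
        n_tcells=30,
        nuclear_radius_range=(1.5, 2.5),
        cluster_radius=8.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_image(small_image_params):
    return simulate_ln_image(small_image_params)


@pytest.fixture(scope="session")
def quantified(small_image):
    """(stack, nuc, mem, table, truth) after membrane expansion and quantification."""
    stack, nuc, truth = small_image
    _, mem = expand_labels_membrane(nuc, 6)
    table = quantify_cells(stack, nuc, mem)
    return stack, nuc, mem, table, truth


@pytest.fixture(scope="session")
def small_events():
    params = SynthCytometryParams(mice_per_arm=3, events_per_mouse=200, seed=23)
    return simulate_cytometry(params)


def brute_force_nearest_label(labels: np.ndarray, radius: float) -> np.ndarray:
    """Reference label expansion: per-voxel scan of all nucleus voxels.

    Background voxels take the label of the nearest nucleus voxel within
    ``radius`` (Euclidean, voxel units); exact ties go to the lower label.
    """
    out = labels.copy()
    fg = np.argwhere(labels > 0)
    fg_labels = labels[tuple(fg.T)]
    for v in np.argwhere(labels == 0):
        d2 = ((fg - v) ** 2).sum(axis=1)
        best_d2 = np.inf
        best_lab = 0
        for dd, lab in zip(d2, fg_labels):
            if dd < best_d2 or (dd == best_d2 and lab < best_lab):
                best_d2 = dd
                best_lab = int(lab)
        if best_d2 <= radius**2 + 1e-9:
            out[tuple(v)] = best_lab
    return out
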