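"""The imputed TCR-affinity index and its transformations.

Tetramer staining divided by CD3 staining is a per-cell proxy for TCR–pMHC
affinity normalised for receptor level. Because tetramer batches vary, the
log index is standardized within each experimental cohort against a pooled
reference population (control-IgG SLAMF6+ stem-like cells by default); a
normalised mean-index ratio, a positivity translation for log transforms,
and equal-frequency quantile binning complete the statistic's toolbox.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "affinity_index",
    "standardize_log_affinity",
    "normalized_affinity_ratio",
    "translate_positive",
    "affinity_bins",
]

REFERENCE_SUBSET = "SLAMF6posTSL"
REFERENCE_TREATMENT = "IgG"

#: the cell states the downstream models compare
SUBSET_VOCAB = ("SLAMF6posTSL", "SLAMF6negTSL", "Teff")


def affinity_index(tetramer, cd3):
    """Imputed affinity index: tetramer / CD3 staining intensity."""
    tet = np.asarray(tetramer, dtype=float)
    c = np.asarray(cd3, dtype=float)
    if np.any(c <= 0):
        raise ValueError("cd3 staining intensity must be > 0 for every event")
    out = tet / c
    return float(out) if out.ndim == 0 else out


def _reference_mask(
    events: pd.DataFrame, reference_subset: str, reference_treatment: str
) -> pd.Series:
    return (events["subset"] == reference_subset) & (
        events["treatment"] == reference_treatment
    )


def standardize_log_affinity(
    events: pd.DataFrame,
    reference_subset: str = REFERENCE_SUBSET,
    reference_treatment: str = REFERENCE_TREATMENT,
    grouping: str = "cohort_id",
    *,
    ddof: int = 0,
) -> pd.Series:
    """z-standardize log(tetramer/CD3) against the pooled cohort reference.

    Within each cohort, z = (log index − mean_ref) / SD_ref where the
    reference statistics are computed over the cohort's pooled
    ``reference_subset`` events of the ``reference_treatment`` arm
    (population SD by default). The reference events themselves therefore
    have mean 0 and SD 1.
    """
    log_idx = np.log(affinity_index(events["tetramer"], events["cd3"]))
    log_idx = pd.Series(log_idx, index=events.index)
    ref_mask = _reference_mask(events, reference_subset, reference_treatment)
    z = pd.Series(np.nan, index=events.index, name="z_log_affinity")
    for cohort, grp in events.groupby(grouping):
        ref_vals = log_idx[grp.index[ref_mask.loc[grp.index]]]
        if len(ref_vals) < 2 or ref_vals.nunique() < 2:
            raise ValueError(
                f"cohort {cohort!r} lacks >= 2 distinct reference events "
                f"({reference_treatment}:{reference_subset})"
            )
        mu = ref_vals.mean()
        sd = ref_vals.std(ddof=ddof)
        z.loc[grp.index] = (log_idx.loc[grp.index] - mu) / sd
    return z


def normalized_affinity_ratio(
    events: pd.DataFrame,
    reference_subset: str = REFERENCE_SUBSET,
    reference_treatment: str = REFERENCE_TREATMENT,
    grouping: str = "cohort_id",
    by: tuple[str, ...] = ("mouse_id", "subset", "treatment"),
) -> pd.DataFrame:
    """Per-group mean affinity index normalised to the pooled cohort reference.

    For each (cohort, *by) group, the mean index is divided by the mean index
    of the cohort's pooled reference events; the reference subset of the
    reference arm therefore averages 1 in every cohort. Groups that exist in
    the (subset × treatment) design but have no events are reported with a
    missing ratio and ``missing=True``.
    """
    ev = events.copy()
    ev["affinity_index"] = affinity_index(ev["tetramer"], ev["cd3"])
    ref_mask = _reference_mask(ev, reference_subset, reference_treatment)
    out = []
    for cohort, grp in ev.groupby(grouping):
        ref = grp.loc[ref_mask.loc[grp.index], "affinity_index"]
        if len(ref) == 0 or ref.mean() <= 0:
            raise ValueError(f"cohort {cohort!r}: pooled reference mean must be > 0")
        ref_mean = ref.mean()
        agg = (
            grp.groupby(list(by), observed=True)["affinity_index"]
            .agg(["mean", "size"])
            .reset_index()
        )
        if "subset" in by:
            # complete the (unit x subset) design so empty subsets surface as
            # flagged-missing rows instead of silently disappearing
            units = grp[[c for c in by if c != "subset"]].drop_duplicates()
            all_subsets = sorted(set(grp["subset"].unique()) | set(SUBSET_VOCAB))
            grid = units.merge(pd.DataFrame({"subset": all_subsets}), how="cross")
            agg = grid.merge(agg, on=list(by), how="left")
        agg.insert(0, grouping, cohort)
        agg["normalized_ratio"] = agg["mean"] / ref_mean
        agg = agg.rename(columns={"mean": "mean_affinity_index", "size": "n_events"})
        out.append(agg)
    res = pd.concat(out, ignore_index=True)
    res["n_events"] = res["n_events"].fillna(0).astype(int)
    res["missing"] = res["n_events"] == 0
    return res


def translate_positive(indices_pooled) -> np.ndarray:
    """Shift pooled indices by (1 − min) so every log-index is non-negative.

    Applied to all events of a cohort pooled across treatment arms before
    log transformation whenever any index is <= 0.
    """
    v = np.asarray(indices_pooled, dtype=float)
    if v.size == 0:
        raise ValueError("cannot translate an empty index set")
    return v + (1.0 - v.min())


def affinity_bins(events: pd.DataFrame, k: int = 5) -> pd.Series:
    """Equal-frequency quantile bins 1..k of the affinity index.

    Events are ranked by ascending affinity index with ties broken by
    ``event_id``; bin i holds ranks (⌈(i−1)n/k⌉, ⌈i·n/k⌉]. With n divisible
    by k and distinct values each bin holds exactly n/k events (~20% each
    for k = 5).
    """
    n = len(events)
    if n < k:
        raise ValueError(f"need at least k={k} events, got {n}")
    idx = affinity_index(events["tetramer"], events["cd3"])
    if np.unique(idx).size == 1:
        warnings.warn(
            "all affinity indices identical; bins assigned by event_id order",
            stacklevel=2,
        )
    order = np.lexsort((events["event_id"].to_numpy(), np.asarray(idx)))
    cuts = np.ceil(np.arange(1, k + 1) * n / k).astype(int)
    bins = np.empty(n, dtype=int)
    start = 0
    for i, stop in enumerate(cuts, start=1):
        bins[order[start:stop]] = i
        start = stop
    return pd.Series(bins, index=events.index, name="bin")
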