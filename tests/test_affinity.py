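import numpy as np
import pandas as pd
import pytest

from tslniche import (
    SynthCytometryParams,
    affinity_bins,
    affinity_index,
    normalized_affinity_ratio,
    simulate_cytometry,
    standardize_log_affinity,
    translate_positive,
)


def events_frame(tet, cd3, subset="SLAMF6posTSL", treatment="IgG", cohort=0):
    n = len(tet)
    return pd.DataFrame(
        {
            "event_id": np.arange(n),
            "cohort_id": cohort,
            "mouse_id": "m0",
            "treatment": treatment,
            "subset": subset,
            "tetramer": tet,
            "cd3": cd3,
        }
    )


class TestAffinityIndex:
    @pytest.mark.parametrize("tet,cd3,expected", [(100, 100, 1.0), (250, 125, 2.0)])
    def test_ratio(self, tet, cd3, expected):
        assert affinity_index(tet, cd3) == expected

    def test_zero_cd3_rejected(self):
        with pytest.raises(ValueError):
            affinity_index(50, 0)

    def test_scale_invariance(self):
        """Simultaneous tetramer+CD3 rescaling (receptor downregulation under
        blockade of a monoclonal TCR) leaves the index exactly unchanged."""
        rng = np.random.default_rng(0)
        tet = rng.lognormal(6, 1, 100)
        cd3 = rng.lognormal(6.5, 0.5, 100)
        # power-of-two factors rescale both stains without any rounding at all
        np.testing.assert_array_equal(
            affinity_index(tet, cd3), affinity_index(0.5 * tet, 0.5 * cd3)
        )
        # arbitrary factors agree to the last unit in the last place
        np.testing.assert_allclose(
            affinity_index(tet, cd3), affinity_index(0.37 * tet, 0.37 * cd3), rtol=5e-16
        )


class TestStandardize:
    def test_reference_events_self_standardize(self):
        rng = np.random.default_rng(1)
        ev = events_frame(rng.lognormal(5, 1, 500), rng.lognormal(5, 0.5, 500))
        z = standardize_log_affinity(ev)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_shifted_subset_mean(self):
        rng = np.random.default_rng(2)
        n = 5000
        log_cd3 = rng.normal(5, 0.3, 2 * n)
        log_ratio = np.concatenate([rng.normal(0, 0.5, n), rng.normal(0.5, 0.5, n)])
        ev = events_frame(np.exp(log_cd3 + log_ratio), np.exp(log_cd3))
        ev.loc[n:, "subset"] = "Teff"
        z = standardize_log_affinity(ev)
        sd_ref = np.log(ev.tetramer[:n] / ev.cd3[:n]).std(ddof=0)
        delta = 0.5
        mc_se = 3 / np.sqrt(n)  # generous Monte-Carlo margin
        assert z[ev.subset == "Teff"].mean() == pytest.approx(delta / sd_ref, abs=mc_se * 3)

    def test_per_cohort_scaling(self):
        """Cohorts with different reference spreads give matching per-cohort z."""
        rng = np.random.default_rng(3)
        n = 4000
        frames = []
        for cohort, sd in ((0, 1.0), (1, 2.0)):
            log_cd3 = rng.normal(5, 0.2, n)
            log_ratio = rng.normal(0.0, sd, n)
            f = events_frame(np.exp(log_cd3 + log_ratio), np.exp(log_cd3), cohort=cohort)
            f["event_id"] += cohort * n
            frames.append(f)
        ev = pd.concat(frames, ignore_index=True)
        z = standardize_log_affinity(ev)
        z0, z1 = z[ev.cohort_id == 0], z[ev.cohort_id == 1]
        assert z0.std(ddof=0) == pytest.approx(z1.std(ddof=0), abs=1e-9)
        raw = np.log(ev.tetramer / ev.cd3)
        assert raw[ev.cohort_id == 1].std(ddof=0) > 1.5 * raw[ev.cohort_id == 0].std(ddof=0)

    def test_missing_reference_cohort_named(self):
        ev = events_frame(np.ones(5) * 2, np.ones(5), subset="Teff", cohort=7)
        with pytest.raises(ValueError, match="7"):
            standardize_log_affinity(ev)


class TestNormalizedRatio:
    def test_reference_subset_maps_to_one(self):
        rng = np.random.default_rng(4)
        ev = events_frame(rng.lognormal(5, 0.5, 300), rng.lognormal(5, 0.3, 300))
        res = normalized_affinity_ratio(ev)
        ref = res[(res.subset == "SLAMF6posTSL") & (res.treatment == "IgG")]
        # single mouse holds the whole reference pool, so its ratio is exactly 1
        assert ref.normalized_ratio.iloc[0] == pytest.approx(1.0)

    def test_doubled_subset(self):
        tet = np.concatenate([np.full(10, 100.0), np.full(10, 200.0)])
        ev = events_frame(tet, np.full(20, 100.0))
        ev.loc[10:, "subset"] = "Teff"
        res = normalized_affinity_ratio(ev).set_index("subset")
        assert res.loc["Teff", "normalized_ratio"] == pytest.approx(2.0)

    def test_empty_subset_flagged_missing(self):
        ev = events_frame(np.full(10, 100.0), np.full(10, 100.0))
        ev.loc[5:, "subset"] = "Teff"
        res = normalized_affinity_ratio(ev)
        missing = res[res.missing]
        assert "SLAMF6negTSL" in missing.subset.to_numpy()
        assert missing.normalized_ratio.isna().all()


class TestTranslatePositive:
    def test_formula(self):
        np.testing.assert_allclose(
            translate_positive([0.2, 0.5, 1.3]), [1.0, 1.3, 2.1]
        )

    def test_fixed_point_when_min_is_one(self):
        np.testing.assert_allclose(translate_positive([1.0, 2.0]), [1.0, 2.0])

    def test_log_non_negative(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 2, 1000)
        assert (np.log(translate_positive(v)) >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            translate_positive([])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(6)
        v = rng.normal(0, 1, 200)
        shifted = translate_positive(v)
        np.testing.assert_array_equal(np.argsort(v), np.argsort(shifted))


class TestAffinityBins:
    def test_even_split(self):
        rng = np.random.default_rng(7)
        ev = events_frame(rng.lognormal(5, 1, 100), np.full(100, 100.0))
        bins = affinity_bins(ev, 5)
        assert (bins.value_counts() == 20).all()

    def test_uneven_split_rank_rule(self):
        # n=7, k=5: cut points ceil(i*7/5) = 2,3,5,6,7 -> sizes {2,1,2,1,1}
        ev = events_frame(np.arange(1.0, 8.0), np.full(7, 1.0))
        bins = affinity_bins(ev, 5)
        assert bins.value_counts().sort_index().tolist() == [2, 1, 2, 1, 1]

    def test_bins_ordered_by_index(self):
        rng = np.random.default_rng(8)
        ev = events_frame(rng.lognormal(5, 1, 50), np.full(50, 100.0))
        bins = affinity_bins(ev, 5)
        idx = ev.tetramer / ev.cd3
        for lo, hi in ((1, 2), (2, 3), (3, 4), (4, 5)):
            assert idx[bins == lo].max() <= idx[bins == hi].min()

    def test_ties_resolved_by_event_id_with_warning(self):
        ev = events_frame(np.full(10, 5.0), np.full(10, 1.0))
        with pytest.warns(UserWarning, match="identical"):
            bins = affinity_bins(ev, 5)
        np.testing.assert_array_equal(bins.to_numpy(), [1, 1, 2, 2, 3, 3, 4, 4, 5, 5])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        ev = events_frame(rng.lognormal(5, 1, 60), np.full(60, 100.0))
        bins = affinity_bins(ev, 5)
        perm = ev.sample(frac=1.0, random_state=1)
        bins_perm = affinity_bins(perm, 5)
        merged = pd.concat(
            [ev.assign(bin=bins).set_index("event_id")["bin"],
             perm.assign(bin=bins_perm).set_index("event_id")["bin"]],
            axis=1, keys=["orig", "perm"],
        )
        assert (merged["orig"] == merged["perm"]).all().all()

    def test_too_few_events_rejected(self):
        ev = events_frame(np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            affinity_bins(ev, 5)


def test_monotone_trend_recovery():
    """Raising the generator's mean log-affinity across synthetic 'timepoints'
    raises the normalized mean index monotonically."""
    means = []
    for tp, delta in enumerate((0.0, 0.3, 0.6)):
        base = {
            ("SLAMF6posTSL", "IgG"): 0.2 + delta,
            ("SLAMF6negTSL", "IgG"): 0.1 + delta,
            ("Teff", "IgG"): 0.0 + delta,
        }
        params = SynthCytometryParams(
            treatments=("IgG",),
            subset_proportions={"IgG": (0.4, 0.3, 0.3)},
            log_affinity_means=base,
            mice_per_arm=6,
            events_per_mouse=400,
            seed=100 + tp,
        )
        ev, _ = simulate_cytometry(params)
        means.append(float((ev.tetramer / ev.cd3).mean()))
    assert means[0] < means[1] < means[2]
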