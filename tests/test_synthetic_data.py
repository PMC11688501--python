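import warnings

import numpy as np
import pandas as pd
import pytest

from reservoirlink.neutral_model import occurrence_abundance, predict_occurrence
from reservoirlink.synthetic_data import (
    SyntheticTruth,
    assemble_neutral_samples,
    generate_exchange_timeseries,
    generate_paired_sites,
    generate_source_pool,
    inject_nonneutral_taxa,
    injection_candidates,
)


class TestSourcePool:
    def test_sums_to_one(self):
        pool = generate_source_pool(50, 2.0, seed=0)
        assert pool.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        a = generate_source_pool(50, 2.0, seed=7)
        b = generate_source_pool(50, 2.0, seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_small_sigma_near_uniform(self):
        pool = generate_source_pool(100, 1e-4, seed=0)
        assert pool.max() / pool.min() == pytest.approx(1.0, abs=1e-2)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            generate_source_pool(1, 2.0)
        with pytest.raises(ValueError):
            generate_source_pool(10, 0.0)


class TestNeutralAssembly:
    def test_zero_pool_taxon_never_observed(self):
        pool = pd.Series([0.6, 0.4, 0.0], index=["a", "b", "c"])
        table, _ = assemble_neutral_samples(pool, m=0.5, N=1000, n_samples=20, seed=1)
        assert (table.data["c"] == 0).all()

    def test_fixed_seed_reproducible(self):
        pool = generate_source_pool(30, 1.5, seed=3)
        t1, _ = assemble_neutral_samples(pool, 0.2, 2000, 10, seed=9)
        t2, _ = assemble_neutral_samples(pool, 0.2, 2000, 10, seed=9)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_read_depth_exact(self):
        pool = generate_source_pool(30, 1.5, seed=3)
        table, _ = assemble_neutral_samples(pool, 0.2, 2000, 10, seed=9)
        assert (table.sample_sums() == 2000).all()

    def test_occurrence_matches_closed_form_at_high_migration(self):
        """Monte-Carlo occurrence tracks the analytic neutral prediction."""
        pool = generate_source_pool(200, 2.0, seed=5)
        table, _ = assemble_neutral_samples(pool, m=1.0, N=20000, n_samples=300, seed=6)
        f_obs = (table.data > 0).mean(axis=0).to_numpy()
        f_hat = predict_occurrence(pool.to_numpy(), m=1.0, N=20000)
        assert np.abs(f_obs - f_hat).mean() < 0.05

    def test_occurrence_nondecreasing_in_pool_abundance(self):
        pool = generate_source_pool(100, 2.0, seed=2)
        table, _ = assemble_neutral_samples(pool, m=0.3, N=5000, n_samples=200, seed=3)
        f = (table.data > 0).mean(axis=0)
        order = pool.sort_values().index
        # binned means are monotone (per-taxon noise allows local flips)
        binned = f[order].rolling(20, min_periods=20).mean().dropna()
        assert (np.diff(binned) > -0.05).all()

    def test_invalid_m_rejected(self):
        pool = generate_source_pool(10, 1.0, seed=0)
        with pytest.raises(ValueError, match="m must be"):
            assemble_neutral_samples(pool, 0.0, 1000, 5)


@pytest.fixture(scope="module")
def neutral():
    pool = generate_source_pool(200, 2.0, seed=20)
    return assemble_neutral_samples(pool, m=0.1, N=5000, n_samples=60, seed=21)


class TestInjection:

    def test_effect_zero_is_identity(self, neutral):
        table, truth = neutral
        out, truth2 = inject_nonneutral_taxa(table, truth, 10, 10, 0.0, seed=0)
        pd.testing.assert_frame_equal(out.data, table.data)
        assert not truth2.injected_over and not truth2.injected_under

    def test_over_taxa_exceed_prediction(self, neutral):
        table, truth = neutral
        out, truth2 = inject_nonneutral_taxa(table, truth, 10, 10, 0.3, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pf = occurrence_abundance(out)
        fhat = predict_occurrence(pf["p"], truth.m, truth.depth)
        fhat = pd.Series(fhat, index=pf.index)
        for t in truth2.injected_over:
            assert pf.loc[t, "f"] >= fhat[t] + 0.25
        for t in truth2.injected_under:
            assert pf.loc[t, "f"] <= fhat[t] - 0.25

    def test_labels_match_modified_taxa(self, neutral):
        table, truth = neutral
        out, truth2 = inject_nonneutral_taxa(table, truth, 5, 5, 0.3, seed=2)
        changed = set(out.data.columns[(out.data != table.data).any(axis=0)])
        assert changed == truth2.injected_over | truth2.injected_under
        assert not truth2.injected_over & truth2.injected_under

    def test_minority_constraint_enforced(self, neutral):
        table, truth = neutral
        with pytest.raises(ValueError, match="minority"):
            inject_nonneutral_taxa(table, truth, 15, 15, 0.3, seed=0)

    def test_invalid_effect_rejected(self, neutral):
        table, truth = neutral
        with pytest.raises(ValueError, match="effect"):
            inject_nonneutral_taxa(table, truth, 5, 5, 1.0, seed=0)


class TestPairedSites:
    def test_metadata_links_polyps_to_sites_with_water(self):
        water, polyp, meta, truth = generate_paired_sites(
            n_sites=4, polyps_per_site=3, gradient_strength=1.0, seed=1,
            n_taxa=60, water_samples_per_site=2, depth=2000,
        )
        idx = meta.indexed()
        water_sites = set(idx.loc[list(water.sample_ids), "site"])
        for pid in polyp.sample_ids:
            assert idx.at[pid, "site"] in water_sites

    def test_core_taxa_absent_from_water(self):
        water, polyp, meta, truth = generate_paired_sites(
            n_sites=4, polyps_per_site=3, seed=2, n_taxa=60, depth=2000,
        )
        core = truth.extras["core_taxa"]
        assert (water.data[core] == 0).all().all()
        assert (polyp.data[core].sum(axis=0) > 0).any()

    def test_deterministic_under_seed(self):
        a = generate_paired_sites(n_sites=4, polyps_per_site=2, seed=5,
                                  n_taxa=40, depth=1000)
        b = generate_paired_sites(n_sites=4, polyps_per_site=2, seed=5,
                                  n_taxa=40, depth=1000)
        pd.testing.assert_frame_equal(a[1].data, b[1].data)

    def test_invalid_gradient_rejected(self):
        with pytest.raises(ValueError, match="gradient"):
            generate_paired_sites(gradient_strength=-1.0)


@pytest.fixture(scope="module")
def small():
    return generate_exchange_timeseries(
        n_populations=1, jars=3, weeks=3, turnover_rate=0.3, seed=8,
        n_taxa=80, depth=3000,
    )


class TestExchangeTimeseries:

    def test_turnover_conserves_dominant_structure(self, small):
        _, _, truth = small
        pools = truth.extras["pools"]
        for w in (1, 2, 3):
            nat = pools[("pop0", "native", w)]
            frn = pools[("pop0", "foreign", w)]
            # sorted abundance spectra identical: identity turnover only
            np.testing.assert_allclose(
                np.sort(nat[nat > 0].to_numpy())[::-1],
                np.sort(frn[frn > 0].to_numpy())[::-1], atol=1e-12,
            )

    def test_turnover_sets_are_novel_taxa(self, small):
        table, _, truth = small
        base = set(truth.source_pool.index)
        for (pop, w), novel in truth.extras["turnover_sets"].items():
            assert novel
            assert not (novel & base)

    def test_common_gain_taxon_rises_everywhere(self, small):
        _, _, truth = small
        gid = truth.extras["common_gain_taxon"]
        pools = truth.extras["pools"]
        assert pools[("pop0", "none", 0)][gid] == 0
        for trt in ("native", "foreign"):
            assert pools[("pop0", trt, 3)][gid] > pools[("pop0", trt, 1)][gid]

    def test_week0_samples_have_treatment_none(self, small):
        _, meta, _ = small
        df = meta.data
        assert (df.loc[df["timepoint"] == 0, "treatment"] == "none").all()
        assert (df.loc[df["timepoint"] > 0, "treatment"] != "none").all()

    def test_deterministic_under_seed(self):
        a = generate_exchange_timeseries(n_populations=1, jars=2, weeks=2,
                                         turnover_rate=0.2, seed=3, n_taxa=40,
                                         depth=1000)
        b = generate_exchange_timeseries(n_populations=1, jars=2, weeks=2,
                                         turnover_rate=0.2, seed=3, n_taxa=40,
                                         depth=1000)
        pd.testing.assert_frame_equal(a[0].data, b[0].data)

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError, match="weeks"):
            generate_exchange_timeseries(weeks=0)
        with pytest.raises(ValueError, match="turnover"):
            generate_exchange_timeseries(turnover_rate=1.0)


class TestSyntheticTruth:
    def test_pool_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticTruth(m=0.1, depth=1000,
                           source_pool=pd.Series([0.5, 0.4], index=["a", "b"]))

    def test_injected_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            SyntheticTruth(m=0.1, depth=1000,
                           source_pool=pd.Series([0.5, 0.5], index=["a", "b"]),
                           injected_over=frozenset({"a"}),
                           injected_under=frozenset({"a"}))
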