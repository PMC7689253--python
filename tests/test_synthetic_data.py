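"""Simulators: determinism, noiseless round-trips, fixture self-consistency."""

import numpy as np
import pandas as pd
import pytest

from sipflux import IncubationSetup, compute_potentials
from sipflux.synthetic_data import (
    PAPER_DEPTH_TRUTHS,
    CommunitySimConfig,
    DepthTruth,
    GradientSimConfig,
    SimConfig,
    build_paper_fixtures,
    default_density_grid,
    simulate_community,
    simulate_gradient,
    simulate_microcosm,
)


def depth_means(measurements: pd.DataFrame) -> pd.DataFrame:
    pot = compute_potentials(measurements, IncubationSetup())
    labeled = pot[pot.treatment == "labeled"]
    return labeled.groupby("depth_label").agg(
        total=("total_ch4_oxidation", "mean"),
        n2=("n2_fixation", "mean"),
        frac=("co2_fraction", "mean"),
    )


class TestMicrocosmSimulator:
    def test_noiseless_round_trip_recovers_truth(self):
        table = simulate_microcosm(SimConfig(noise_sd=0.0, control_drift_sd_pct=0.0))
        means = depth_means(table)
        for depth, truth in PAPER_DEPTH_TRUTHS.items():
            assert means.loc[depth, "total"] == pytest.approx(truth.ch4_total, rel=1e-9)
            assert means.loc[depth, "n2"] == pytest.approx(truth.n2_fixation, rel=1e-9)
            assert means.loc[depth, "frac"] == pytest.approx(truth.co2_share, rel=1e-9)

    def test_seeded_determinism(self):
        a = simulate_microcosm(SimConfig(seed=42))
        b = simulate_microcosm(SimConfig(seed=42))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_microcosm(SimConfig(seed=43))
        assert not a.equals(c)

    def test_monte_carlo_recovery_unbiased(self):
        """Across 200 seeded simulations at default noise, the mean recovered
        potential for every depth sits within 3 standard errors of truth."""
        n_sim = 200
        totals = {d: [] for d in PAPER_DEPTH_TRUTHS}
        n2s = {d: [] for d in PAPER_DEPTH_TRUTHS}
        for seed in range(n_sim):
            means = depth_means(simulate_microcosm(SimConfig(seed=seed)))
            for depth in PAPER_DEPTH_TRUTHS:
                totals[depth].append(means.loc[depth, "total"])
                n2s[depth].append(means.loc[depth, "n2"])
        for depth, truth in PAPER_DEPTH_TRUTHS.items():
            for observed, expected in (
                (np.asarray(totals[depth]), truth.ch4_total),
                (np.asarray(n2s[depth]), truth.n2_fixation),
            ):
                se = observed.std(ddof=1) / np.sqrt(n_sim)
                assert abs(observed.mean() - expected) < 3 * se, depth

    def test_replicate_spread_tracks_noise_setting(self):
        """Empirical sd of replicate potentials scales with the configured
        relative noise on atom-% excess."""
        rel_sds = []
        for seed in range(100):
            pot = compute_potentials(
                simulate_microcosm(SimConfig(seed=seed)), IncubationSetup()
            )
            lab = pot[(pot.treatment == "labeled") & (pot.depth_label == "mid_40_60")]
            rel_sds.append(
                lab["co2_potential"].std(ddof=1) / lab["co2_potential"].mean()
            )
        # n=3 replicate relative sd should average near the configured 0.05
        assert np.mean(rel_sds) == pytest.approx(0.05, abs=0.015)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            DepthTruth(10.0, 1.5, 0.1, 1.0, 5.0, 0.5)


class TestGradientSimulator:
    def test_default_grid_contains_anchor_densities(self):
        grid = default_density_grid()
        assert 1.720 in grid and 1.734 in grid
        assert np.all(np.diff(grid) > 0)
        assert grid.min() >= 1.70 and grid.max() <= 1.75

    def test_wide_band_limit_is_near_uniform(self):
        table = simulate_gradient(GradientSimConfig(band_width=10.0, noise_sd=0.0))
        sub = table[
            (table.gene_name == "pmoA") & (table.treatment_label == "labeled_13C")
        ]
        copies = sub["copy_number"].to_numpy()
        assert copies.max() / copies.min() < 1.001
        wmean = (sub["buoyant_density_g_per_ml"] * copies).sum() / copies.sum()
        grid = sub["buoyant_density_g_per_ml"].to_numpy()
        assert wmean == pytest.approx((grid.min() + grid.max()) / 2, abs=0.001)

    def test_seeded_determinism(self):
        a = simulate_gradient(GradientSimConfig(seed=7))
        b = simulate_gradient(GradientSimConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GradientSimConfig(density_grid=(1.5, 1.7, 1.72, 1.74))


class TestCommunitySimulator:
    def test_large_library_matches_targets(self):
        """Law of large numbers: with no overdispersion and a large library,
        empirical RA sits within 0.5 pp of the configured proportions."""
        config = CommunitySimConfig(library_size=200_000, overdispersion=0.0, seed=1)
        table = simulate_community(config)
        for (depth, timepoint), pct in config.guild_pct.items():
            sub = table[(table.depth_label == depth) & (table.timepoint == timepoint)]
            ra = 100 * sub["count"] / sub["count"].sum()
            assert np.allclose(ra.to_numpy(), pct, atol=0.5)

    def test_seeded_determinism(self):
        a = simulate_community(CommunitySimConfig(seed=7))
        b = simulate_community(CommunitySimConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            CommunitySimConfig(
                guild_pct={("top_0_20", "day0"): (50.0, 30.0, 10.0, 5.0, 4.0)}
            )


class TestPaperFixtures:
    def test_fixture_clone_library_sizes(self, fixtures):
        clones = fixtures["clones"]
        bact = clones[clones.domain == "bacteria"].groupby("depth_label")["clone_count"].sum()
        arch = clones[clones.domain == "archaea"].groupby("depth_label")["clone_count"].sum()
        assert bact.to_dict() == {"top_0_20": 52, "mid_40_60": 50, "deep_60_80": 47}
        assert arch.to_dict() == {"top_0_20": 32, "mid_40_60": 31, "deep_60_80": 31}
        assert bact.sum() == 149 and arch.sum() == 94
        top = clones[(clones.domain == "bacteria") & (clones.depth_label == "top_0_20")]
        assert int(top[top.taxon == "Methylobacter"]["clone_count"].iloc[0]) == 15

    def test_fixture_fold_ratios_and_partition(self, fixtures):
        means = depth_means(fixtures["measurements"])
        assert round(means.loc["mid_40_60", "total"] / means.loc["top_0_20", "total"], 1) == 2.5
        assert round(means.loc["mid_40_60", "total"] / means.loc["deep_60_80", "total"], 1) == 1.2
        assert round(means.loc["mid_40_60", "n2"] / means.loc["deep_60_80", "n2"], 1) == 4.4
        assert round(means.loc["mid_40_60", "n2"] / means.loc["top_0_20", "n2"], 1) == 1.4
        # CO2 share spans the reported 67-81% band, increasing with depth
        fracs = means["frac"]
        assert 0.67 <= fracs.min() and fracs.max() <= 0.81
        assert (
            fracs["top_0_20"] < fracs["mid_40_60"] < fracs["deep_60_80"]
        )

    def test_fixture_replicate_sd_matches_reported(self, fixtures):
        pot = compute_potentials(fixtures["measurements"], IncubationSetup())
        mid = pot[(pot.treatment == "labeled") & (pot.depth_label == "mid_40_60")]
        assert mid["total_ch4_oxidation"].std(ddof=1) == pytest.approx(3.10, rel=1e-6)
        assert mid["n2_fixation"].std(ddof=1) == pytest.approx(0.04, rel=1e-6)

    def test_fixtures_deterministic(self):
        a, b = build_paper_fixtures(), build_paper_fixtures()
        for key in ("measurements", "gradients", "community", "clones"):
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_metadata_records_assumptions(self, fixtures):
        meta = fixtures["metadata"]
        assert meta["assumptions"]
        assert meta["anchors"]["co2_share"]["mid_40_60"] == 0.74
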