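"""Generator correctness: determinism, drift calibration, planted devices."""

import numpy as np
import pandas as pd
import pytest

from flockscape.genio import MISSING
from flockscape.sim import (CensusPlan, ClimatePlan, IntrogressionPlan,
                            RohPlan, SimConfig, simulate_census,
                            simulate_climate, simulate_features,
                            simulate_panel, wright_fisher_drift)
from flockscape.demography import growth_rate


def test_same_seed_identical_outputs(small_config):
    p1, t1 = simulate_panel(small_config)
    p2, t2 = simulate_panel(small_config)
    np.testing.assert_array_equal(p1.genotypes, p2.genotypes)
    pd.testing.assert_frame_equal(p1.snp_map, p2.snp_map)
    for b in t1.founder_freqs:
        np.testing.assert_array_equal(t1.founder_freqs[b], t2.founder_freqs[b])


def test_no_drift_limit_huge_ne():
    """At Ne = 1e6 and t = 1 the cohort frequencies barely move."""
    cfg = SimConfig(seed=1, n_breeds=1, samples_per_breed_per_cohort=2,
                    ne_per_breed=[10**6], generations_between_cohorts=1,
                    breed_divergence_generations=0, n_chrom=2,
                    snps_per_chrom=5000, missing_rate=0.0)
    _, truth = simulate_panel(cfg)
    b = cfg.breeds[0]
    diff = np.abs(truth.current_freqs[b] - truth.founder_freqs[b])
    assert diff.mean() < 0.005


def test_zero_missing_rate(small_config):
    cfg = SimConfig(**{**small_config.__dict__, "missing_rate": 0.0})
    panel, _ = simulate_panel(cfg)
    assert not (panel.genotypes == MISSING).any()


def test_drift_variance_matches_wright_fisher_formula():
    """Var(p_t) ~= p0 q0 (1 - (1 - 1/(2Ne))^t) over 10k replicate SNPs."""
    rng = np.random.default_rng(5)
    p0, ne, t = 0.3, 80, 12
    drifted = wright_fisher_drift(np.full(10_000, p0), ne, t, rng)
    expected = p0 * (1 - p0) * (1 - (1 - 1 / (2 * ne)) ** t)
    assert np.var(drifted) == pytest.approx(expected, rel=0.05)


def test_genotypes_match_hwe_at_truth_freqs(small_panel):
    """Cohort allele frequencies estimated from genotypes track the truth
    frequencies they were drawn from."""
    panel, truth = small_panel
    s = panel.samples
    for b in ["B00", "B03"]:
        idx = s.index[(s["breed"] == b) & (s["cohort"] == "historical")]
        g = panel.genotypes[idx.to_numpy()].astype(float)
        g[g == MISSING] = np.nan
        phat = np.nanmean(g, axis=0) / 2
        resid = phat - truth.founder_freqs[b]
        assert np.nanmean(np.abs(resid)) < 0.12  # binomial noise at n=12


def test_tract_longer_than_chromosome_rejected():
    cfg = SimConfig(seed=2, n_breeds=2, samples_per_breed_per_cohort=4,
                    n_chrom=1, snps_per_chrom=50, mean_spacing_kb=10,
                    introgression=IntrogressionPlan("B00", "B01",
                                                    tract_length_mb=100.0))
    with pytest.raises(ValueError, match="exceeds chromosome"):
        simulate_panel(cfg)


def test_introgression_moves_target_freqs_toward_donor():
    cfg = SimConfig(seed=3, n_breeds=2, samples_per_breed_per_cohort=10,
                    n_chrom=4, snps_per_chrom=400, missing_rate=0.0,
                    introgression=IntrogressionPlan(
                        "B00", "B01", genome_fraction=0.2,
                        tract_length_mb=4.0, alpha=1.0))
    _, truth = simulate_panel(cfg)
    chrom = truth.snp_map["chrom"].to_numpy()
    bp = truth.snp_map["bp"].to_numpy()
    inside = np.zeros(len(bp), dtype=bool)
    for t in truth.tracts.itertuples(index=False):
        inside |= (chrom == t.chrom) & (bp >= t.start_bp) & (bp <= t.end_bp)
    assert inside.any()
    np.testing.assert_allclose(truth.current_freqs["B00"][inside],
                               truth.current_freqs["B01"][inside])


def test_planted_roh_segments_are_homozygous():
    cfg = SimConfig(seed=4, n_breeds=1, samples_per_breed_per_cohort=6,
                    n_chrom=2, snps_per_chrom=300, mean_spacing_kb=25,
                    missing_rate=0.0,
                    roh_plan=RohPlan(n_individuals=2,
                                     segments_per_individual=1,
                                     length_mb_range=(2.0, 3.0)))
    panel, truth = simulate_panel(cfg)
    assert len(truth.roh_segments) == 2
    chrom = panel.snp_map["chrom"].to_numpy()
    bp = panel.snp_map["bp"].to_numpy()
    ids = panel.samples["sample_id"].tolist()
    for seg in truth.roh_segments.itertuples(index=False):
        i = ids.index(seg.sample_id)
        inside = (chrom == seg.chrom) & (bp >= seg.start_bp) & (bp <= seg.end_bp)
        assert not (panel.genotypes[i, inside] == 1).any()


class TestCensus:
    def test_constant_when_growth_one_no_noise(self):
        cfg = SimConfig(seed=5, n_breeds=1, samples_per_breed_per_cohort=2,
                        n_chrom=1, snps_per_chrom=10,
                        census_plan=CensusPlan(initial_animals=500,
                                               growth=1.0, noise_sd=0.0))
        census = simulate_census(cfg)
        assert census["n_animals"].nunique() == 1

    def test_exact_geometric_growth(self):
        cfg = SimConfig(seed=5, n_breeds=1, samples_per_breed_per_cohort=2,
                        n_chrom=1, snps_per_chrom=10,
                        census_plan=CensusPlan(initial_animals=100,
                                               growth=1.1, noise_sd=0.0,
                                               years=(2020, 2022)))
        census = simulate_census(cfg)
        assert census["n_animals"].tolist() == [100, 110, 121]

    def test_growth_rate_recovery_self_consistency(self):
        """The demography module recovers the configured growth rate from a
        noise-free simulated census."""
        cfg = SimConfig(seed=6, n_breeds=1, samples_per_breed_per_cohort=2,
                        n_chrom=1, snps_per_chrom=10,
                        census_plan=CensusPlan(initial_animals=5000,
                                               growth=1.07, noise_sd=0.0))
        census = simulate_census(cfg)
        _, mean_r = growth_rate(census["year"].to_numpy(),
                                census["n_animals"].to_numpy())
        assert mean_r == pytest.approx(1.07, abs=0.01)


class TestClimate:
    def test_zero_trend_zero_noise_gives_zero_delta(self):
        cfg = SimConfig(seed=8, n_breeds=2, samples_per_breed_per_cohort=2,
                        n_chrom=1, snps_per_chrom=10,
                        climate_plan=ClimatePlan(n_variables=3, trend_mean=0.0,
                                                 trend_sd=0.0,
                                                 farm_noise_sd=0.0))
        _, truth = simulate_panel(cfg)
        clim = simulate_climate(cfg, truth)
        wide = clim.pivot_table(index=["breed", "farm_id", "variable"],
                                columns="period", values="value")
        np.testing.assert_allclose(wide["period2"] - wide["period1"], 0.0)

    def test_breed_delta_equals_configured_trend(self):
        cfg = SimConfig(seed=9, n_breeds=3, samples_per_breed_per_cohort=2,
                        n_chrom=1, snps_per_chrom=10,
                        climate_plan=ClimatePlan(n_variables=2,
                                                 farm_noise_sd=0.0))
        _, truth = simulate_panel(cfg)
        clim = simulate_climate(cfg, truth)
        wide = clim.pivot_table(index=["breed", "variable", "farm_id"],
                                columns="period", values="value")
        deltas = (wide["period2"] - wide["period1"]).groupby(
            ["breed", "variable"]).mean()
        for (b, v), trend in truth.breed_trends.set_index(
                ["breed", "variable"])["trend"].items():
            assert deltas[(b, v)] == pytest.approx(trend, abs=1e-9)

    def test_adaptive_truth_fst_correlates_with_trend(self):
        """With coupling on, the squared truth frequency shift of adaptive
        SNPs grows with the breed's climate trend (construction oracle)."""
        cfg = SimConfig(seed=10, n_breeds=10, samples_per_breed_per_cohort=2,
                        n_chrom=1, snps_per_chrom=400, ne_per_breed=[500] * 10,
                        climate_plan=ClimatePlan(n_variables=1,
                                                 trend_mean=1.0, trend_sd=1.0,
                                                 n_adaptive_snps=30,
                                                 coupling=0.03))
        _, truth = simulate_panel(cfg)
        idx = truth.adaptive["snp_index"].to_numpy()
        trends = truth.breed_trends.set_index("breed")["trend"]
        shifts, ts = [], []
        for b in cfg.breeds:
            d2 = (truth.current_freqs[b][idx] - truth.founder_freqs[b][idx]) ** 2
            shifts.append(d2.mean())
            ts.append(trends[b])
        assert np.corrcoef(ts, shifts)[0, 1] > 0.5


class TestFeatures:
    def test_zero_features(self, small_panel):
        _, truth = small_panel
        cfg = SimConfig(seed=7, n_breeds=4, samples_per_breed_per_cohort=12,
                        n_chrom=2, snps_per_chrom=150)
        ft = simulate_features(cfg, truth, n_genes=0, n_qtl=0)
        assert len(ft) == 0

    def test_all_features_within_chromosome_bounds(self, small_config,
                                                   small_panel):
        _, truth = small_panel
        ft = simulate_features(small_config, truth, n_genes=100, n_qtl=50)
        assert (ft.df["start_bp"] >= 1).all()
        assert (ft.df["end_bp"] <= small_config.chrom_length_bp).all()
        assert ft.df["chrom"].between(1, small_config.n_chrom).all()
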