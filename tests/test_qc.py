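"""QC behaviour against brute-force oracles and closed-form expectations."""

import numpy as np
import pandas as pd
import pytest

from flockscape.genio import MISSING
from flockscape.qc import (QcParams, balance_breeds, classical_mds,
                           filter_panel, flag_relatives, ibs_mds, ld_prune,
                           minor_allele_freq)

from conftest import make_panel


class TestFilterPanel:
    def test_complete_panel_unchanged(self):
        g = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1]], dtype=np.int8)
        panel = make_panel(g)
        out, report = filter_panel(panel, QcParams())
        assert out.n_samples == 3 and out.n_snps == 3
        assert report.empty

    def test_low_call_rate_individual_dropped(self):
        g = np.ones((3, 20), dtype=np.int8)
        g[0, :2] = MISSING  # call rate 0.90 < 0.95
        panel = make_panel(g)
        out, report = filter_panel(panel, QcParams())
        assert out.n_samples == 2
        assert report.iloc[0]["kind"] == "sample"
        assert report.iloc[0]["reason"] == "call_rate"

    def test_counts_match_bruteforce_tally(self):
        """Surviving rows/columns equal an independent per-row/column tally
        applied in the documented order on a random 100 x 500 panel."""
        rng = np.random.default_rng(11)
        g = rng.integers(0, 3, size=(100, 500)).astype(np.int8)
        g[rng.random(g.shape) < 0.04] = MISSING
        # plant pathological rows/columns
        g[3, :100] = MISSING
        g[:, 7] = 0
        g[:90, 8] = 0
        params = QcParams()
        panel = make_panel(g)
        out, _ = filter_panel(panel, params)

        keep_rows = [i for i in range(100)
                     if (g[i] != MISSING).mean() >= params.ind_call_rate_min]
        g2 = g[keep_rows]
        keep_cols = [j for j in range(500)
                     if (g2[:, j] != MISSING).mean() >= params.snp_call_rate_min]
        g3 = g2[:, keep_cols]
        final_cols = []
        for k, j in enumerate(keep_cols):
            col = g3[:, k]
            obs = col != MISSING
            p = col[obs].sum() / (2 * obs.sum())
            if not min(p, 1 - p) < params.maf_min:
                final_cols.append(j)
        assert out.n_samples == len(keep_rows)
        assert out.snp_map["snp_id"].tolist() == [f"m{j}" for j in final_cols]

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        g = rng.integers(0, 3, size=(40, 80)).astype(np.int8)
        g[rng.random(g.shape) < 0.04] = MISSING
        panel = make_panel(g)
        once, _ = filter_panel(panel, QcParams())
        twice, report = filter_panel(once, QcParams())
        assert report.empty
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)

    def test_empty_after_filtering_raises(self):
        g = np.full((3, 3), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="empty"):
            filter_panel(make_panel(g), QcParams())


class TestLdPrune:
    def test_duplicated_column_one_removed(self):
        rng = np.random.default_rng(13)
        base = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        other = rng.integers(0, 3, size=(50, 3)).astype(np.int8)
        g = np.hstack([base, base, other])
        kept = ld_prune(make_panel(g), QcParams())
        assert ("m0" in kept) != ("m1" in kept)  # exactly one survives

    def test_independent_snps_mostly_retained(self):
        rng = np.random.default_rng(14)
        g = rng.binomial(2, 0.5, size=(200, 60)).astype(np.int8)
        kept = ld_prune(make_panel(g), QcParams())
        assert len(kept) >= 58

    def test_toy_matches_exhaustive_rule(self):
        """5-SNP toy: retained set equals literal application of the greedy
        remove-lower-MAF rule on the hand-computed r^2 matrix."""
        rng = np.random.default_rng(15)
        n = 80
        a = rng.binomial(2, 0.5, size=n).astype(np.int8)
        b = a.copy()
        b[:6] = rng.binomial(2, 0.5, size=6)        # r2(a,b) high
        c = rng.binomial(2, 0.2, size=n).astype(np.int8)
        d = (2 - a).astype(np.int8)                  # r2(a,d) = 1
        e = rng.binomial(2, 0.5, size=n).astype(np.int8)
        g = np.column_stack([a, b, c, d, e])
        params = QcParams()
        panel = make_panel(g)
        kept = set(ld_prune(panel, params))

        # independent literal evaluation
        maf = minor_allele_freq(g)
        retained = set(range(5))
        changed = True
        while changed:
            changed = False
            live = sorted(retained)
            for x in range(len(live)):
                for y in range(x + 1, len(live)):
                    jx, jy = live[x], live[y]
                    if jx not in retained or jy not in retained:
                        continue
                    r = np.corrcoef(g[:, jx].astype(float),
                                    g[:, jy].astype(float))[0, 1]
                    if r * r > params.ld_r2_max:
                        if maf[jx] < maf[jy]:
                            retained.discard(jx)
                        elif maf[jy] < maf[jx]:
                            retained.discard(jy)
                        else:
                            retained.discard(max(jx, jy))
                        changed = True
        assert kept == {f"m{j}" for j in retained}

    def test_independent_of_sample_order(self):
        rng = np.random.default_rng(16)
        g = rng.binomial(2, 0.4, size=(60, 30)).astype(np.int8)
        g[:, 5] = g[:, 4]
        panel = make_panel(g)
        perm = rng.permutation(60)
        shuffled = panel.take_samples(perm)
        assert ld_prune(panel, QcParams()) == ld_prune(shuffled, QcParams())


class TestFlagRelatives:
    def test_identical_rows_flagged_duplicate(self):
        rng = np.random.default_rng(17)
        row = rng.integers(0, 3, size=200).astype(np.int8)
        g = np.vstack([row, row, rng.integers(0, 3, size=200)]).astype(np.int8)
        flags = flag_relatives(make_panel(g), QcParams())
        dup = flags[flags["flag"] == "duplicate"]
        assert {"s000", "s001"} == set(dup.iloc[0][["id1", "id2"]])

    def test_simulated_parent_offspring_flagged(self):
        """Child inherits one allele from the parent at every locus, so the
        opposing-homozygote rate is ~0 (pedigree construction oracle)."""
        rng = np.random.default_rng(18)
        m = 500
        p = rng.uniform(0.2, 0.8, size=m)
        parent = rng.binomial(2, p).astype(np.int8)
        transmitted = np.where(parent == 1, rng.integers(0, 2, m), parent // 2)
        child = (transmitted + rng.binomial(1, p)).astype(np.int8)
        other = rng.binomial(2, p).astype(np.int8)
        g = np.vstack([parent, child, other])
        flags = flag_relatives(make_panel(g), QcParams())
        po = flags[flags["flag"] == "parent_offspring_like"]
        assert {"s000", "s001"} in [set(r) for r in
                                    po[["id1", "id2"]].to_numpy().tolist()]

    def test_unrelated_pair_at_half_freq_not_flagged(self):
        """At p = 0.5 the expected opposing-homozygote rate is
        2 * 0.25 * 0.25 = 0.125, far above the 0.02 screen."""
        rng = np.random.default_rng(19)
        g = rng.binomial(2, 0.5, size=(2, 2000)).astype(np.int8)
        flags = flag_relatives(make_panel(g), QcParams())
        assert flags.empty
        # empirical rate agrees with the closed form
        opp = ((g[0] == 0) & (g[1] == 2)) | ((g[0] == 2) & (g[1] == 0))
        assert opp.mean() == pytest.approx(0.125, abs=0.03)


class TestMds:
    def test_identical_samples_identical_coordinates(self):
        g = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (3, 1))
        g = np.vstack([g, np.array([2, 1, 0, 1], dtype=np.int8)])
        coords = ibs_mds(make_panel(g), n_dims=2)
        xyz = coords[["C1", "C2"]].to_numpy()
        np.testing.assert_allclose(xyz[0], xyz[1], atol=1e-7)
        np.testing.assert_allclose(xyz[0], xyz[2], atol=1e-7)

    def test_classical_mds_reconstructs_euclidean_distances(self):
        """Full-rank embedding of a Euclidean distance matrix reproduces it
        (classical MDS identity)."""
        rng = np.random.default_rng(20)
        pts = rng.normal(size=(12, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(D, n_dims=12)
        D2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.abs(D - D2).max() < 1e-8

    def test_divergent_breeds_separate_on_first_dimension(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(21)
        m = 400
        g1 = rng.binomial(2, 0.1, size=(15, m)).astype(np.int8)
        g2 = rng.binomial(2, 0.9, size=(15, m)).astype(np.int8)
        panel = make_panel(np.vstack([g1, g2]),
                           breeds=["A"] * 15 + ["B"] * 15)
        coords = ibs_mds(panel, n_dims=2)
        labels = [0] * 15 + [1] * 15
        assert silhouette_score(coords[["C1"]].to_numpy(), labels) > 0.5

    def test_zero_shared_snps_pair_raises(self):
        g = np.array([[1, MISSING], [MISSING, 1], [1, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no called"):
            ibs_mds(make_panel(g), n_dims=1)


class TestBalanceBreeds:
    @staticmethod
    def _coords(panel, seed=0):
        return ibs_mds(panel, n_dims=10)

    def test_small_breed_unchanged_tiny_breed_dropped(self):
        rng = np.random.default_rng(22)
        g = rng.binomial(2, 0.5, size=(24, 60)).astype(np.int8)
        breeds = ["A"] * 15 + ["B"] * 9
        panel = make_panel(g, breeds=breeds)
        kept = balance_breeds(panel, self._coords(panel), QcParams())
        ids = panel.samples["sample_id"]
        assert set(kept) == set(ids[:15])  # A kept whole, B (<10) dropped

    def test_oversized_breed_capped_preserving_spread(self):
        """Retained subset's coordinate covariance trace is at least that of
        a median random subset of the same size (diversity preservation)."""
        rng = np.random.default_rng(23)
        m = 300
        freqs = rng.uniform(0.1, 0.9, size=m)
        g = rng.binomial(2, freqs, size=(60, m)).astype(np.int8)
        panel = make_panel(g, breeds=["A"] * 60)
        coords = self._coords(panel)
        params = QcParams(max_breed_n=20)
        kept = balance_breeds(panel, coords, params)
        assert 0 < len(kept) <= 20
        X = coords.set_index("sample_id")
        cols = [c for c in X.columns if c.startswith("C")]
        trace_kept = X.loc[kept, cols].to_numpy().var(axis=0).sum()
        traces = []
        for _ in range(20):
            sub = rng.choice(60, size=len(kept), replace=False)
            traces.append(X.iloc[sub][cols].to_numpy().var(axis=0).sum())
        assert trace_kept >= np.median(traces)
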