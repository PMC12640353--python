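"""Fst components vs a literal formula oracle, Reynolds/NJ, IBD medians."""

import numpy as np
import pandas as pd
import pytest

from flockscape.differentiation import (_bipartitions, fst_components,
                                        fst_per_snp, genome_wide_fst,
                                        group_freq_het, ibd_sharing_summary,
                                        nj_tree, reynolds_from_freqs,
                                        temporal_fst, top_fst_fraction)
from flockscape.genio import MISSING

from conftest import make_panel


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Symbol-by-symbol transcription of the two-population Weir-Cockerham
    (1984) variance components, evaluated with plain floats."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    return a, b, c


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        comp = fst_components([20], [1.0], [0.0], [20], [0.0], [0.0])
        assert comp.iloc[0]["theta"] == pytest.approx(1.0)

    def test_monomorphic_undefined_and_excluded(self):
        comp = fst_components([20, 20], [0.0, 0.3], [0.0, 0.4],
                              [20, 20], [0.0, 0.5], [0.0, 0.5])
        assert np.isnan(comp.iloc[0]["theta"])
        gw = genome_wide_fst(comp)
        only = fst_components([20], [0.3], [0.4], [20], [0.5], [0.5])
        assert gw == pytest.approx(genome_wide_fst(only))

    def test_matches_literal_formula_oracle(self):
        rng = np.random.default_rng(40)
        for _ in range(10):
            n1, n2 = rng.integers(2, 40, size=2)
            p1, p2 = rng.uniform(0.05, 0.95, size=2)
            h1, h2 = rng.uniform(0, 0.5, size=2)
            comp = fst_components([n1], [p1], [h1], [n2], [p2], [h2])
            a, b, c = wc_oracle(n1, p1, h1, n2, p2, h2)
            assert comp.iloc[0]["a"] == pytest.approx(a, abs=1e-12)
            assert comp.iloc[0]["b"] == pytest.approx(b, abs=1e-12)
            assert comp.iloc[0]["c"] == pytest.approx(c, abs=1e-12)

    def test_group_smaller_than_two_rejected(self):
        g = np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8)
        panel = make_panel(g)
        with pytest.raises(ValueError, match="at least 2"):
            fst_per_snp(panel, [0], [1, 2])

    def test_random_split_of_one_group_near_zero(self):
        """Fst between random halves of a homogeneous sample is ~0."""
        rng = np.random.default_rng(41)
        freqs = rng.uniform(0.1, 0.9, size=5000)
        g = rng.binomial(2, freqs, size=(60, 5000)).astype(np.int8)
        panel = make_panel(g)
        comp = fst_per_snp(panel, np.arange(30), np.arange(30, 60))
        assert abs(genome_wide_fst(comp)) < 0.005


class TestTopFraction:
    def test_exact_count_distinct_values(self):
        rng = np.random.default_rng(42)
        comp = pd.DataFrame({"snp_id": [f"s{i}" for i in range(1000)],
                             "theta": rng.permutation(1000) / 1000.0})
        assert len(top_fst_fraction(comp, 0.01)) == 10

    def test_all_equal_all_selected(self):
        comp = pd.DataFrame({"snp_id": list("abcd"), "theta": [0.2] * 4})
        assert len(top_fst_fraction(comp, 0.01)) == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_and_slice_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        vals = np.round(rng.normal(size=300), 2)  # ties likely
        vals[rng.random(300) < 0.05] = np.nan
        comp = pd.DataFrame({"snp_id": [f"s{i}" for i in range(300)],
                             "theta": vals})
        got = set(top_fst_fraction(comp, 0.05))
        finite = np.abs(vals[~np.isnan(vals)])
        thr = np.quantile(np.sort(finite), 0.95)
        expected = {f"s{i}" for i in range(300)
                    if not np.isnan(vals[i]) and abs(vals[i]) >= thr}
        assert got == expected


class TestTemporalFst:
    def test_drift_f_doubles_theta(self):
        rng = np.random.default_rng(43)
        g = rng.binomial(2, 0.5, size=(20, 500)).astype(np.int8)
        panel = make_panel(g, cohorts=["historical"] * 10 + ["current"] * 10)
        res = temporal_fst(panel, "X")
        assert res["drift_f"] == pytest.approx(2 * res["theta"])


class TestReynolds:
    def test_identical_freqs_zero(self):
        f = np.array([[0.2, 0.7, 0.5], [0.2, 0.7, 0.5]])
        assert reynolds_from_freqs(f)[0, 1] == 0.0

    def test_fixed_difference_one(self):
        f = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert reynolds_from_freqs(f)[0, 1] == pytest.approx(1.0)

    def test_five_locus_hand_case(self):
        """Per-locus spreadsheet-style evaluation of the ratio of sums."""
        p1 = np.array([0.1, 0.4, 0.5, 0.9, 0.3])
        p2 = np.array([0.2, 0.1, 0.5, 0.6, 0.8])
        num = den = 0.0
        for a, b in zip(p1, p2):
            num += (a - b) ** 2 + ((1 - a) - (1 - b)) ** 2
            den += 2 * (1 - (a * b + (1 - a) * (1 - b)))
        got = reynolds_from_freqs(np.vstack([p1, p2]))[0, 1]
        assert got == pytest.approx(num / den)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(44)
        f = rng.uniform(0.05, 0.95, size=(5, 100))
        D = reynolds_from_freqs(f)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)


class TestNj:
    def test_recovers_additive_four_taxon_topology(self):
        # ((A,B),(C,D)) with unit external and internal branches
        D = np.array([[0, 2, 3, 3],
                      [2, 0, 3, 3],
                      [3, 3, 0, 2],
                      [3, 3, 2, 0]], dtype=float)
        tree = nj_tree(list("ABCD"), D)
        parts = _bipartitions(tree, frozenset("ABCD"))
        assert frozenset("AB") in parts or frozenset("CD") in parts

    def test_identical_populations_zero_length_cherry(self):
        rng = np.random.default_rng(45)
        f = rng.uniform(0.2, 0.8, size=(1, 200))
        freqs = np.vstack([f, f, rng.uniform(0.2, 0.8, size=(2, 200))])
        D = reynolds_from_freqs(freqs)
        tree = nj_tree(["P1", "P2", "P3", "P4"], D)
        t1 = tree.find("P1")
        t2 = tree.find("P2")
        assert t1.parent is t2.parent
        assert t1.length + t2.length == pytest.approx(0.0, abs=1e-12)


class TestIbdSharing:
    @staticmethod
    def _seg(id1, id2, b1, b2, mb, lod=5.0):
        return {"id1": id1, "id2": id2, "breed1": b1, "breed2": b2,
                "chrom": 1, "start_bp": 1, "end_bp": int(mb * 1e6),
                "lod": lod}

    def test_nothing_survives_filters(self):
        segs = pd.DataFrame([self._seg("a", "b", "X", "Y", 1.0),
                             self._seg("a", "b", "X", "Y", 2.0, lod=1.0)])
        med, edges = ibd_sharing_summary(segs)
        assert (med["median_shared_mb"] == 0).all()
        assert edges.empty

    def test_single_pair_single_segment(self):
        segs = pd.DataFrame([self._seg("a", "b", "X", "Y", 2.0)])
        med, _ = ibd_sharing_summary(segs)
        assert med.iloc[0]["median_shared_mb"] == pytest.approx(2.0, rel=1e-5)

    def test_matches_bruteforce_group_median_oracle(self):
        rng = np.random.default_rng(46)
        breeds = ["X", "Y", "Z", "W"]
        rows = []
        for _ in range(500):
            b1, b2 = rng.choice(breeds, size=2, replace=False)
            rows.append(self._seg(f"{b1}{rng.integers(5)}",
                                  f"{b2}{rng.integers(5)}", b1, b2,
                                  float(rng.uniform(0.5, 10)),
                                  lod=float(rng.uniform(0, 10))))
        segs = pd.DataFrame(rows)
        med, _ = ibd_sharing_summary(segs)
        got = {(r.breed1, r.breed2): r.median_shared_mb
               for r in med.itertuples(index=False)}
        # brute force
        from collections import defaultdict
        pair_tot = defaultdict(float)
        for r in segs.itertuples(index=False):
            mb = (r.end_bp - r.start_bp + 1) / 1e6
            if mb >= 1.5 and r.lod >= 3.0:
                bp = tuple(sorted((r.breed1, r.breed2)))
                ip = tuple(sorted((r.id1, r.id2)))
                pair_tot[(bp, ip)] += mb
        by_bp = defaultdict(list)
        for (bp, ip), tot in pair_tot.items():
            by_bp[bp].append(tot)
        for i, b1 in enumerate(sorted(breeds)):
            for b2 in sorted(breeds)[i + 1:]:
                expected = float(np.median(by_bp[(b1, b2)])) \
                    if (b1, b2) in by_bp else 0.0
                assert got[(b1, b2)] == pytest.approx(expected)

    def test_malformed_rows_rejected(self):
        segs = pd.DataFrame([{"id1": "a", "id2": "b", "breed1": "X",
                              "breed2": "Y", "chrom": 1, "start_bp": 100,
                              "end_bp": 5, "lod": 5.0}])
        with pytest.raises(ValueError, match="rows"):
            ibd_sharing_summary(segs)
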