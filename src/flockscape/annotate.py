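"""Candidate-SNP annotation: flanking windows, feature overlap, and
hypergeometric QTL-category enrichment with Benjamini-Hochberg correction.

Enrichment counts SNPs, not features: with N the array SNPs whose +-20 kb
windows hit any QTL, K of them hitting a given category, n the candidate
SNPs hitting any QTL and k of those hitting the category, the upper-tail
hypergeometric probability P(X >= k) tests whether the candidates are
enriched in that category relative to the chip background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genio import FeatureTable

__all__ = ["snp_windows", "overlap_features", "qtl_enrichment", "bh_adjust",
           "hypergeom_upper_tail"]


def snp_windows(snp_ids, snp_map: pd.DataFrame,
                flank_bp: int = 20000) -> pd.DataFrame:
    """1-based inclusive interval [max(1, bp - flank), bp + flank] around
    each SNP; windows are not merged."""
    lookup = snp_map.set_index("snp_id")
    unknown = [s for s in snp_ids if s not in lookup.index]
    if unknown:
        raise KeyError(f"SNP ids not in map: {unknown[:5]}")
    sub = lookup.loc[list(snp_ids)]
    return pd.DataFrame({
        "snp_id": list(snp_ids),
        "chrom": sub["chrom"].to_numpy(),
        "start_bp": np.maximum(1, sub["bp"].to_numpy() - flank_bp),
        "end_bp": sub["bp"].to_numpy() + flank_bp,
    })


def overlap_features(windows: pd.DataFrame,
                     features: FeatureTable) -> pd.DataFrame:
    """Features intersecting each window by >= 1 bp (inclusive coordinates).

    Returns one row per (snp_id, feature) hit with the fraction of the
    feature covered by the window (1.0 = complete overlap).
    """
    f = features.df
    rows = []
    for w in windows.itertuples(index=False):
        same = f[f["chrom"] == w.chrom]
        ov_start = np.maximum(same["start_bp"].to_numpy(), w.start_bp)
        ov_end = np.minimum(same["end_bp"].to_numpy(), w.end_bp)
        hit = ov_start <= ov_end
        if not hit.any():
            continue
        sub = same[hit]
        ov_len = (ov_end[hit] - ov_start[hit] + 1).astype(float)
        feat_len = (sub["end_bp"] - sub["start_bp"] + 1).to_numpy(dtype=float)
        for (frow, ol, fl) in zip(sub.itertuples(index=False), ov_len, feat_len):
            rows.append((w.snp_id, frow.feature_id, frow.category, ol / fl))
    return pd.DataFrame(rows, columns=["snp_id", "feature_id", "category",
                                       "feature_overlap_fraction"])


def hypergeom_upper_tail(k: int, K: int, N: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) — the R idiom
    ``phyper(k-1, K, N-K, n, lower.tail = FALSE)``."""
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def qtl_enrichment(candidate_snps, universe_snps, snp_map: pd.DataFrame,
                   features: FeatureTable,
                   flank_bp: int = 20000) -> pd.DataFrame:
    """Per-QTL-category hypergeometric enrichment of candidate SNPs.

    Both SNP sets are windowed identically (+-``flank_bp``); the universe is
    the full post-QC chip.  Categories with no array SNP overlap (K = 0)
    are skipped.  BH correction is applied across the categories of this
    run.
    """
    candidate_snps = list(candidate_snps)
    universe_snps = list(universe_snps)
    if not set(candidate_snps) <= set(universe_snps):
        raise ValueError("candidates must be a subset of the universe")
    qtl = FeatureTable(
        features.df[features.df["category"].str.startswith("qtl")])
    uni_hits = overlap_features(snp_windows(universe_snps, snp_map, flank_bp),
                                qtl)
    cand_set = set(candidate_snps)
    cand_hits = uni_hits[uni_hits["snp_id"].isin(cand_set)]
    N = uni_hits["snp_id"].nunique()
    n = cand_hits["snp_id"].nunique()
    rows = []
    for cat in sorted(qtl.df["category"].unique()):
        K = uni_hits.loc[uni_hits["category"] == cat, "snp_id"].nunique()
        if K == 0:
            continue
        k = cand_hits.loc[cand_hits["category"] == cat, "snp_id"].nunique()
        rows.append((cat, k, K, n, N, hypergeom_upper_tail(k, K, N, n)))
    out = pd.DataFrame(rows, columns=["category", "k", "K", "n", "N", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
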