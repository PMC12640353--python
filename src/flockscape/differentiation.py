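"""Allele-frequency differentiation between groups: per-SNP Weir &
Cockerham (1984) Fst, top-fraction selection, Reynolds distances with
bootstrapped neighbour-joining trees, and IBD haplotype-sharing summaries.

The two-group W&C estimator computes, per SNP, the variance components
a (between populations), b (between individuals within populations) and
c (within individuals) from sample sizes, allele frequencies and observed
heterozygosities, and theta = a / (a + b + c).  The genome-wide value is
the ratio of sums Sum(a) / Sum(a + b + c) over defined SNPs (ratio of sums,
not mean of per-SNP ratios).  Temporal Fst between cohorts of one breed
sampled t generations apart has drift expectation roughly t / (2 Ne).

Reynolds' coancestry distance between populations is
    theta_Rey = Sum_l Sum_alleles (p1 - p2)^2
              / (2 * Sum_l (1 - Sum_alleles p1 * p2)),
with numerator and denominator each summed over loci before dividing; it is
suited to short divergence times where drift dominates mutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .genio import MISSING, GenotypePanel, write_newick
from .sim import substream

__all__ = ["fst_components", "fst_per_snp", "genome_wide_fst",
           "top_fst_fraction", "reynolds_matrix", "nj_tree",
           "bootstrap_nj_tree", "ibd_sharing_summary", "group_freq_het"]


def group_freq_het(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                   np.ndarray]:
    """Per-SNP (n called, alt freq, observed het fraction) for one group."""
    obs = genotypes != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, ((genotypes == 1) & obs).sum(axis=0)
                     / np.maximum(n, 1), np.nan)
    return n, p, h


def fst_components(n1, p1, h1, n2, p2, h2) -> pd.DataFrame:
    """Weir & Cockerham (1984) a, b, c and theta for two populations,
    vectorised over SNPs.  SNPs with either group uncalled, a group of
    size < 2, or a + b + c = 0 are flagged undefined (theta = NaN)."""
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float); h2 = np.asarray(h2, float)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    bad = (n1 < 2) | (n2 < 2) | np.isnan(p1) | np.isnan(p2) | (denom == 0)
    theta = np.where(bad, np.nan, theta)
    return pd.DataFrame({"n1": n1, "n2": n2, "p1": p1, "p2": p2,
                         "h1": h1, "h2": h2, "a": np.where(bad, np.nan, a),
                         "b": np.where(bad, np.nan, b),
                         "c": np.where(bad, np.nan, c), "theta": theta})


def fst_per_snp(panel: GenotypePanel, group_a, group_b) -> pd.DataFrame:
    """Per-SNP W&C components between two sample-index groups of the panel.

    Groups are boolean masks or index arrays over samples; each must hold
    at least 2 samples.
    """
    ga = panel.genotypes[np.asarray(group_a)]
    gb = panel.genotypes[np.asarray(group_b)]
    if ga.shape[0] < 2 or gb.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    comp = fst_components(*group_freq_het(ga), *group_freq_het(gb))
    comp.insert(0, "snp_id", panel.snp_map["snp_id"].to_numpy())
    comp.insert(1, "chrom", panel.snp_map["chrom"].to_numpy())
    comp.insert(2, "bp", panel.snp_map["bp"].to_numpy())
    return comp


def genome_wide_fst(components: pd.DataFrame) -> float:
    """Ratio-of-sums Fst over defined SNPs: Sum(a) / Sum(a+b+c)."""
    ok = components["theta"].notna()
    num = components.loc[ok, "a"].sum()
    den = (components.loc[ok, ["a", "b", "c"]].sum(axis=1)).sum()
    if den == 0:
        raise ValueError("no defined SNPs for genome-wide Fst")
    return float(num / den)


def temporal_fst(panel: GenotypePanel, breed: str) -> dict:
    """Temporal differentiation between the two cohorts of one breed.

    Returns the per-SNP components, the genome-wide W&C theta, and the
    drift-calibrated temporal F.  In a temporal pair, only one of the two
    samples has drifted away from the other, so the between-sample variance
    is F * p0 * (1 - p0) — half of what the symmetric two-population W&C
    model attributes to divergence 2 * F_avg — and the per-lineage drift
    parameter F = 1 - (1 - 1/(2 Ne))^t (about t / (2 Ne) for small t/Ne)
    is recovered as twice the genome-wide theta.
    """
    s = panel.samples
    hist = s.index[(s["breed"] == breed) & (s["cohort"] == "historical")]
    curr = s.index[(s["breed"] == breed) & (s["cohort"] == "current")]
    comp = fst_per_snp(panel, hist.to_numpy(), curr.to_numpy())
    theta = genome_wide_fst(comp)
    return {"components": comp, "theta": theta, "drift_f": 2.0 * theta}


def top_fst_fraction(components: pd.DataFrame,
                     fraction: float = 0.01) -> list:
    """SNPs with |theta| at or above the (1 - fraction) quantile of defined
    |theta| values; ties at the threshold are all included."""
    ok = components["theta"].notna()
    if not ok.any():
        raise ValueError("all SNPs undefined")
    abs_theta = components.loc[ok, "theta"].abs()
    threshold = float(np.quantile(abs_theta.to_numpy(), 1.0 - fraction))
    sel = ok & (components["theta"].abs() >= threshold)
    return components.loc[sel, "snp_id"].tolist()


# ---------------------------------------------------------------------------
# Reynolds distances and NJ trees
# ---------------------------------------------------------------------------

def _population_freqs(panel: GenotypePanel, by: str = "breed"
                      ) -> tuple[list, np.ndarray]:
    labels = []
    freqs = []
    for lab, grp in panel.samples.groupby(by, sort=True):
        g = panel.genotypes[grp.index.to_numpy()]
        _, p, _ = group_freq_het(g)
        labels.append(lab)
        freqs.append(p)
    return labels, np.vstack(freqs)


def reynolds_from_freqs(freqs: np.ndarray) -> np.ndarray:
    """Reynolds distance matrix from a populations x loci frequency matrix;
    loci missing (NaN) in either population of a pair are skipped."""
    k = freqs.shape[0]
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p1, p2 = freqs[i], freqs[j]
            ok = ~np.isnan(p1) & ~np.isnan(p2)
            if not ok.any():
                raise ValueError(f"populations {i} and {j} share no defined loci")
            q1, q2 = 1 - p1[ok], 1 - p2[ok]
            num = ((p1[ok] - p2[ok]) ** 2 + (q1 - q2) ** 2).sum()
            den = 2.0 * (1.0 - (p1[ok] * p2[ok] + q1 * q2)).sum()
            D[i, j] = D[j, i] = num / den if den > 0 else 0.0
    return D


def reynolds_matrix(panel: GenotypePanel, by: str = "breed"
                    ) -> tuple[list, np.ndarray]:
    """Population labels and pairwise Reynolds distance matrix."""
    labels, freqs = _population_freqs(panel, by)
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    counts = panel.samples.groupby(by, sort=True).size()
    if (counts < 2).any():
        raise ValueError(f"populations with < 2 samples: "
                         f"{counts[counts < 2].index.tolist()}")
    return labels, reynolds_from_freqs(freqs)


def nj_tree(labels, D: np.ndarray) -> TreeNode:
    """Saitou-Nei neighbour joining; negative branch lengths clamped to 0."""
    tree = nj(SkbioDM(D, ids=list(labels)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set:
    """Non-trivial bipartitions as canonical frozensets of the smaller side
    (lexicographic tie-break)."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canon)
    return parts


def bootstrap_nj_tree(panel: GenotypePanel, n_boot: int = 100,
                      seed: int = 0, by: str = "breed"
                      ) -> tuple[TreeNode, str]:
    """NJ tree on the full-data Reynolds matrix with bootstrap supports.

    Bootstrap replicates resample SNP columns with replacement, recompute
    the distance matrix and NJ topology, and count bipartitions; supports
    are percentages over ``n_boot`` attached to internal nodes.  Returns
    the tree and its Newick string.
    """
    labels, freqs = _population_freqs(panel, by)
    if len(labels) < 4:
        raise ValueError("need at least 4 populations for a supported tree")
    tree = nj_tree(labels, reynolds_from_freqs(freqs))
    taxa = frozenset(labels)
    counts: dict[frozenset, int] = {p: 0 for p in _bipartitions(tree, taxa)}
    rng = substream(seed, "nj-bootstrap")
    m = freqs.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        bt = nj_tree(labels, reynolds_from_freqs(freqs[:, cols]))
        for p in _bipartitions(bt, taxa):
            if p in counts:
                counts[p] += 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, taxa - side,
                    key=lambda s: (len(s), tuple(sorted(s))))
        if canon in counts:
            node.support = 100.0 * counts[canon] / n_boot
    return tree, write_newick(tree)


# ---------------------------------------------------------------------------
# IBD haplotype sharing
# ---------------------------------------------------------------------------

def ibd_sharing_summary(segments: pd.DataFrame, min_mb: float = 1.5,
                        min_lod: float = 3.0, top_fraction: float = 0.05
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-breed haplotype-sharing medians from an IBD segment table.

    ``segments`` columns: id1, id2, breed1, breed2, chrom, start_bp,
    end_bp, lod.  Segments shorter than ``min_mb`` or with LOD below
    ``min_lod`` are discarded; per cross-breed individual pair the
    surviving shared lengths are summed; per breed pair the median over
    sharing individual pairs is taken (breed pairs with no surviving
    segment get 0).  Top edges are breed pairs above the
    (1 - top_fraction) quantile of the nonzero medians.
    """
    required = ["id1", "id2", "breed1", "breed2", "chrom", "start_bp",
                "end_bp", "lod"]
    missing = set(required) - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns {sorted(missing)}")
    seg = segments.copy()
    seg["length_mb"] = (seg["end_bp"] - seg["start_bp"] + 1) / 1e6
    bad = seg["length_mb"] <= 0
    if bad.any():
        raise ValueError(f"non-positive segment lengths at rows "
                         f"{seg.index[bad].tolist()[:10]}")
    keep = seg[(seg["length_mb"] >= min_mb) & (seg["lod"] >= min_lod)
               & (seg["breed1"] != seg["breed2"])]
    all_breeds = sorted(set(segments["breed1"]) | set(segments["breed2"]))
    medians = {}
    if len(keep):
        bp = keep.apply(lambda r: tuple(sorted((r["breed1"], r["breed2"]))),
                        axis=1)
        ip = keep.apply(lambda r: tuple(sorted((r["id1"], r["id2"]))), axis=1)
        keep = keep.assign(_bpair=bp, _ipair=ip)
        per_pair = keep.groupby(["_bpair", "_ipair"])["length_mb"].sum()
        medians = per_pair.groupby(level="_bpair").median().to_dict()
    rows = []
    for i, b1 in enumerate(all_breeds):
        for b2 in all_breeds[i + 1:]:
            rows.append((b1, b2, medians.get((b1, b2), 0.0)))
    med = pd.DataFrame(rows, columns=["breed1", "breed2", "median_shared_mb"])
    nonzero = med.loc[med["median_shared_mb"] > 0, "median_shared_mb"]
    if len(nonzero):
        thr = float(np.quantile(nonzero.to_numpy(), 1.0 - top_fraction))
        edges = med[med["median_shared_mb"] >= thr].copy()
    else:
        edges = med.iloc[0:0].copy()
    return med, edges
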